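import numpy as np
import pytest

from mirtgf.model_core import (
    DimensionalParameters,
    ModelParameters,
    calibrated_parameters,
    calibrated_thresholds_dict,
)
from mirtgf.phenotype import PhenotypeThresholds


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """The packaged calibrated parameter set."""
    return calibrated_parameters()


@pytest.fixture(scope="session")
def thresholds() -> PhenotypeThresholds:
    return PhenotypeThresholds(**calibrated_thresholds_dict())


def random_model_parameters(rng: np.random.Generator) -> ModelParameters:
    """A random valid dimensionless parameter set for property tests."""
    u = rng.uniform
    return ModelParameters(
        lam_R1=u(0.0, 0.2), lam_R2=u(0.0, 0.2), lam_R3=u(0.0, 0.2),
        lam_T=u(0.0, 0.1), lam_S=u(0.0, 0.1),
        k1=u(0.0, 0.5), k2=u(0.2, 2.0), k3=u(0.0, 0.5), k4=u(0.2, 2.0),
        k5=u(0.0, 0.5), k6=u(0.2, 2.0), k7=u(0.0, 1.0), k8=u(0.2, 2.0),
        k9=u(0.0, 1.0), k10=u(0.2, 2.0),
        alpha=u(0.0, 50.0), beta=u(0.0, 50.0), gamma=u(0.0, 50.0),
        delta=u(0.0, 8.0), eps=u(0.0, 8.0), zeta=u(0.0, 8.0),
        eta=u(0.0, 8.0), theta=u(0.0, 8.0), kappa=u(0.0, 8.0),
        lam=u(0.0, 0.05),
        mu_A1=u(0.02, 0.5), mu_A2=u(0.02, 0.5), mu_A3=u(0.02, 0.5),
        mu_R1=u(0.02, 0.5), mu_R2=u(0.02, 0.5), mu_R3=u(0.02, 0.5),
        mu_T=u(0.02, 0.5), mu_S=u(0.02, 0.5),
        se_source_multiplier=u(1.0, 2.0),
    )


def random_dimensional_parameters(rng: np.random.Generator) -> DimensionalParameters:
    """A random valid dimensional parameter set with non-trivial scales."""
    u = rng.uniform
    return DimensionalParameters(
        f_miR21=u(0.0, 0.5), f_miR142=u(0.0, 0.5), f_miR10=u(0.0, 0.5),
        f_TGFb=u(0.0, 0.3), f_SMAD=u(0.0, 0.3),
        tau1=u(0.0, 1.0), tau2=u(0.0, 1.0), tau3=u(0.0, 1.0),
        tau4=u(0.0, 1.0), tau5=u(0.0, 1.0),
        phi1=u(0.2, 3.0), phi2=u(0.2, 3.0), phi3=u(0.2, 3.0),
        phi4=u(0.2, 3.0), phi5=u(0.2, 3.0),
        ups1=u(0.0, 5.0), ups2=u(0.0, 5.0), ups3=u(0.0, 5.0),
        ups4=u(0.0, 5.0), ups5=u(0.0, 5.0),
        mu_antimiR21=u(0.02, 0.5), mu_antimiR142=u(0.02, 0.5),
        mu_antimiR10=u(0.02, 0.5),
        mu_miR21=u(0.02, 0.5), mu_miR142=u(0.02, 0.5), mu_miR10=u(0.02, 0.5),
        mu_TGFb=u(0.02, 0.5), mu_SMAD=u(0.02, 0.5),
        lambda_TGFb=u(0.0, 0.1),
        A1s=u(0.3, 3.0), A2s=u(0.3, 3.0), A3s=u(0.3, 3.0),
        R1s=u(0.3, 3.0), R2s=u(0.3, 3.0), R3s=u(0.3, 3.0),
        Ts=u(0.3, 3.0), Ss=u(0.3, 3.0),
    )
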