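"""Core ODE system for antagomir-mediated seizure regulation.

The model tracks eight intracellular concentrations, all expressed in fold
change (FC) over the untreated control baseline:

* ``A1, A2, A3`` -- injected antagomirs (anti-miR-21a-5p, anti-miR-142a-5p,
  anti-miR-10a-5p), which decay exponentially and inhibit their target miRNAs;
* ``R1, R2, R3`` -- the seizure-modifying miRNAs (miR-21a-5p, miR-142a-5p,
  miR-10a-5p), produced by a constant source plus Hill-type autocatalysis
  inhibited by the matching antagomir;
* ``T`` -- TGF-beta receptor-complex signaling, whose autocatalysis is jointly
  repressed by the three miRNAs;
* ``S`` -- SMAD2/3:4 transcriptional activity, repressed by the miRNAs and
  activated by TGF-beta.

All inhibition acts through squared-concentration (Hill exponent 2) terms; the
full dimensional system and the scale map that reduces it to the dimensionless
form used everywhere else in the package are both provided here, together with
structural variants in which a subset of the miRNA branches is removed.

Time is measured in hours; the convention throughout is that antagomir
administration starts at t = -24 h, status epilepticus (SE) is induced at
t = 0 h and the brain is analyzed at t = +24 h.  SE induction itself is
represented as a step increase of the miRNA source rates for t >= 0
(``se_source_multiplier``), the minimal mechanism consistent with the observed
post-SE miRNA up-regulation.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "STATE_NAMES",
    "N_STATE",
    "MirnaMask",
    "FULL_MASK",
    "ModelParameters",
    "DimensionalParameters",
    "inhibition_terms",
    "rhs_dimensionless",
    "rhs_dimensional",
    "nondimensionalize",
    "model_variant",
    "state_array",
    "calibrated_parameters",
    "calibrated_thresholds_dict",
    "load_parameter_file",
]

#: Canonical ordering of the state vector.
STATE_NAMES = ("A1", "A2", "A3", "R1", "R2", "R3", "T", "S")
N_STATE = 8

# Index aliases used throughout the package.
IDX = {name: i for i, name in enumerate(STATE_NAMES)}
IDX_A = slice(0, 3)
IDX_R = slice(3, 6)
IDX_T = 6
IDX_S = 7


class ModelError(ValueError):
    """Raised on invalid model inputs (negative states, bad parameters)."""


@dataclasses.dataclass(frozen=True)
class MirnaMask:
    """Selection of miRNA branches present in a structural model variant.

    All eight combinations are legal; a masked-out branch contributes nothing
    to the T/S inhibition denominators and its own derivative is forced to
    zero, so every variant shares the same 8-component state layout.
    """

    include_R1: bool = True
    include_R2: bool = True
    include_R3: bool = True

    def flags(self) -> np.ndarray:
        return np.array(
            [self.include_R1, self.include_R2, self.include_R3], dtype=float
        )

    def n_active(self) -> int:
        return int(self.include_R1) + int(self.include_R2) + int(self.include_R3)


FULL_MASK = MirnaMask()

# Fields of ModelParameters grouped by role; also defines serialization order.
_SOURCE_FIELDS = ("lam_R1", "lam_R2", "lam_R3", "lam_T", "lam_S")
_HILL_FIELDS = tuple(f"k{i}" for i in range(1, 11))
_STRENGTH_FIELDS = (
    "alpha", "beta", "gamma",          # antagomir -> miRNA
    "delta", "eps", "zeta",            # miRNA -> TGF-beta
    "eta", "theta", "kappa",           # miRNA -> SMAD
)
_DECAY_FIELDS = ("mu_A1", "mu_A2", "mu_A3", "mu_R1", "mu_R2", "mu_R3", "mu_T", "mu_S")

#: The nine inhibition-strength parameters probed by the sensitivity analysis.
INHIBITION_STRENGTHS = _STRENGTH_FIELDS


@dataclasses.dataclass
class ModelParameters:
    """Dimensionless rates and strengths of the governing equations.

    ``se_source_multiplier`` (>= 1) scales the miRNA sources ``lam_R1..3``
    for t >= 0 and is the model's surrogate for SE induction.
    """

    lam_R1: float
    lam_R2: float
    lam_R3: float
    lam_T: float
    lam_S: float
    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    k9: float
    k10: float
    alpha: float
    beta: float
    gamma: float
    delta: float
    eps: float
    zeta: float
    eta: float
    theta: float
    kappa: float
    lam: float
    mu_A1: float
    mu_A2: float
    mu_A3: float
    mu_R1: float
    mu_R2: float
    mu_R3: float
    mu_T: float
    mu_S: float
    se_source_multiplier: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for name in self.field_names():
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ModelError(f"parameter {name} is not finite: {value!r}")
        for name in _DECAY_FIELDS:
            if getattr(self, name) <= 0:
                raise ModelError(f"decay rate {name} must be strictly positive")
        for name in ("k2", "k4", "k6", "k8", "k10"):
            if getattr(self, name) <= 0:
                raise ModelError(f"saturation constant {name} must be strictly positive")
        for name in _SOURCE_FIELDS + _STRENGTH_FIELDS + ("k1", "k3", "k5", "k7", "k9", "lam"):
            if getattr(self, name) < 0:
                raise ModelError(f"parameter {name} must be non-negative")
        if self.se_source_multiplier < 1.0:
            raise ModelError("se_source_multiplier must be >= 1")

    # -- utilities -------------------------------------------------------
    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.field_names()}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParameters":
        unknown = set(d) - set(cls.field_names())
        if unknown:
            raise ModelError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    # Grouped array views used by the vectorized right-hand sides.
    def mirna_sources(self) -> np.ndarray:
        return np.array([self.lam_R1, self.lam_R2, self.lam_R3])

    def mirna_autocat(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([self.k1, self.k3, self.k5]),
                np.array([self.k2, self.k4, self.k6]))

    def antagomir_strengths(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    def t_strengths(self) -> np.ndarray:
        return np.array([self.delta, self.eps, self.zeta])

    def s_strengths(self) -> np.ndarray:
        return np.array([self.eta, self.theta, self.kappa])

    def decay_rates(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _DECAY_FIELDS])


@dataclasses.dataclass
class DimensionalParameters:
    """Dimensional rates of the mass-balance system plus characteristic scales.

    Units: sources in concentration/hour, autocatalytic rates tau_i in
    concentration/hour, saturation constants phi_i in concentration units,
    inhibition coefficients ups_i in 1/concentration^2, decay and activation
    rates in 1/hour, scales in concentration units.
    """

    f_miR21: float
    f_miR142: float
    f_miR10: float
    f_TGFb: float
    f_SMAD: float
    tau1: float
    tau2: float
    tau3: float
    tau4: float
    tau5: float
    phi1: float
    phi2: float
    phi3: float
    phi4: float
    phi5: float
    ups1: float
    ups2: float
    ups3: float
    ups4: float
    ups5: float
    mu_antimiR21: float
    mu_antimiR142: float
    mu_antimiR10: float
    mu_miR21: float
    mu_miR142: float
    mu_miR10: float
    mu_TGFb: float
    mu_SMAD: float
    lambda_TGFb: float
    A1s: float = 1.0
    A2s: float = 1.0
    A3s: float = 1.0
    R1s: float = 1.0
    R2s: float = 1.0
    R3s: float = 1.0
    Ts: float = 1.0
    Ss: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value):
                raise ModelError(f"parameter {f.name} is not finite")
        for name in ("mu_antimiR21", "mu_antimiR142", "mu_antimiR10", "mu_miR21",
                     "mu_miR142", "mu_miR10", "mu_TGFb", "mu_SMAD"):
            if getattr(self, name) <= 0:
                raise ModelError(f"decay rate {name} must be strictly positive")
        for name in ("A1s", "A2s", "A3s", "R1s", "R2s", "R3s", "Ts", "Ss"):
            if getattr(self, name) <= 0:
                raise ModelError(f"scale {name} must be strictly positive")
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ModelError(f"parameter {f.name} must be non-negative")


def state_array(
    A1: float = 0.0, A2: float = 0.0, A3: float = 0.0,
    R1: float = 1.0, R2: float = 1.0, R3: float = 1.0,
    T: float = 1.0, S: float = 1.0,
) -> np.ndarray:
    """Build a state vector; defaults to the anti-seizure baseline (1.0 FC)."""
    return np.array([A1, A2, A3, R1, R2, R3, T, S], dtype=float)


def _check_state(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape[0] != N_STATE:
        raise ModelError(f"state must have {N_STATE} components, got {state.shape}")
    if not np.all(np.isfinite(state)):
        raise ModelError("state contains non-finite components")
    if np.any(state < 0):
        raise ModelError("state contains negative components")
    return state


def inhibition_terms(state: np.ndarray) -> tuple[float, float, float, float, float]:
    """The five inhibition functions G1..G5.

    G1..G3 are the squared antagomir levels acting on their matched miRNAs;
    G4 = G5 = R1^2 + R2^2 + R3^2 is the joint miRNA pressure on T and S.
    Each is non-negative and strictly increasing in every argument it uses.
    """
    state = _check_state(state)
    a = state[IDX_A]
    r = state[IDX_R]
    g123 = a * a
    g45 = float(np.dot(r, r))
    return float(g123[0]), float(g123[1]), float(g123[2]), g45, g45


def se_multiplier(t: float, params: ModelParameters) -> float:
    """Source multiplier m(t): 1 before SE induction, the SE factor after."""
    return params.se_source_multiplier if t >= 0.0 else 1.0


def rhs_dimensionless(
    t: float,
    state: np.ndarray,
    params: ModelParameters,
    mask: MirnaMask = FULL_MASK,
    *,
    check: bool = True,
) -> np.ndarray:
    """Time derivative of the dimensionless state at time t (per hour).

    ``state`` may be a single vector of shape (8,) or a batch of shape
    (8, n); the derivative has the same shape.  With ``check=False`` the
    validity checks are skipped (hot path inside integrators).
    """
    y = np.asarray(state, dtype=float)
    if check:
        if not np.all(np.isfinite(y)):
            raise ModelError("state contains non-finite components")
    a = y[IDX_A]
    r = y[IDX_R]
    T = y[IDX_T]
    S = y[IDX_S]

    inc = mask.flags()
    if y.ndim == 2:
        inc = inc[:, None]

    m = se_multiplier(t, params)
    tau, k_even = params.mirna_autocat()
    if y.ndim == 2:
        tau = tau[:, None]
        k_even = k_even[:, None]
    ab_strength = params.antagomir_strengths()
    lam_R = params.mirna_sources()
    mu_R = np.array([params.mu_R1, params.mu_R2, params.mu_R3])
    mu_A = np.array([params.mu_A1, params.mu_A2, params.mu_A3])
    if y.ndim == 2:
        ab_strength = ab_strength[:, None]
        lam_R = lam_R[:, None]
        mu_R = mu_R[:, None]
        mu_A = mu_A[:, None]

    dA = -mu_A * a
    k_even2 = k_even * k_even
    dR = inc * (
        lam_R * m + tau * k_even2 / (k_even2 + ab_strength * a * a) - mu_R * r
    )

    r2 = r * r * inc  # masked branches contribute zero pressure
    gT = np.sum(params.t_strengths()[:, None] * r2 if y.ndim == 2
                else params.t_strengths() * r2, axis=0)
    gS = np.sum(params.s_strengths()[:, None] * r2 if y.ndim == 2
                else params.s_strengths() * r2, axis=0)
    k8_2 = params.k8 ** 2
    k10_2 = params.k10 ** 2
    dT = params.lam_T + params.k7 * k8_2 / (k8_2 + gT) - params.mu_T * T
    dS = (params.lam_S + params.lam * T
          + params.k9 * k10_2 / (k10_2 + gS) - params.mu_S * S)

    out = np.empty_like(y)
    out[IDX_A] = dA
    out[IDX_R] = dR
    out[IDX_T] = dT
    out[IDX_S] = dS
    return out


def rhs_dimensional(
    t: float, state_bar: np.ndarray, params: DimensionalParameters
) -> np.ndarray:
    """Time derivative of the dimensional (barred) system.

    Each miRNA balances a constant source, Hill-inhibited autocatalysis and
    first-order decay; T and S add the joint miRNA repression and the
    TGF-beta -> SMAD activation term.
    """
    y = np.asarray(state_bar, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ModelError("state contains non-finite components")
    a = y[IDX_A]
    r = y[IDX_R]
    T = y[IDX_T]
    S = y[IDX_S]

    mu_A = np.array([params.mu_antimiR21, params.mu_antimiR142, params.mu_antimiR10])
    mu_R = np.array([params.mu_miR21, params.mu_miR142, params.mu_miR10])
    f_R = np.array([params.f_miR21, params.f_miR142, params.f_miR10])
    tau = np.array([params.tau1, params.tau2, params.tau3])
    phi = np.array([params.phi1, params.phi2, params.phi3])
    ups = np.array([params.ups1, params.ups2, params.ups3])

    g123 = a * a
    g45 = float(np.dot(r, r))

    dA = -mu_A * a
    phi2 = phi * phi
    dR = f_R + tau * phi2 / (phi2 + ups * g123) - mu_R * r
    dT = (params.f_TGFb
          + params.tau4 * params.phi4 ** 2 / (params.phi4 ** 2 + params.ups4 * g45)
          - params.mu_TGFb * T)
    dS = (params.f_SMAD + params.lambda_TGFb * T
          + params.tau5 * params.phi5 ** 2 / (params.phi5 ** 2 + params.ups5 * g45)
          - params.mu_SMAD * S)

    out = np.empty_like(y)
    out[IDX_A] = dA
    out[IDX_R] = dR
    out[IDX_T] = dT
    out[IDX_S] = dS
    return out


def nondimensionalize(params: DimensionalParameters) -> ModelParameters:
    """Map dimensional parameters onto the dimensionless system.

    Sources and autocatalytic rates are divided by the characteristic scale
    of the species they feed; saturation constants carry over; inhibition
    strengths absorb the squared scale of the inhibiting species.  The
    TGF-beta -> SMAD activation rate picks up the scale ratio T*/S* so that
    trajectories of the two systems correspond exactly under the scale map
    (the ratio is 1 whenever the two scales coincide).
    ``se_source_multiplier`` defaults to 1 (no SE surrogate).
    """
    p = params
    return ModelParameters(
        lam_R1=p.f_miR21 / p.R1s,
        lam_R2=p.f_miR142 / p.R2s,
        lam_R3=p.f_miR10 / p.R3s,
        lam_T=p.f_TGFb / p.Ts,
        lam_S=p.f_SMAD / p.Ss,
        k1=p.tau1 / p.R1s, k2=p.phi1,
        k3=p.tau2 / p.R2s, k4=p.phi2,
        k5=p.tau3 / p.R3s, k6=p.phi3,
        k7=p.tau4 / p.Ts, k8=p.phi4,
        k9=p.tau5 / p.Ss, k10=p.phi5,
        alpha=p.ups1 * p.A1s ** 2,
        beta=p.ups2 * p.A2s ** 2,
        gamma=p.ups3 * p.A3s ** 2,
        delta=p.ups4 * p.R1s ** 2,
        eps=p.ups4 * p.R2s ** 2,
        zeta=p.ups4 * p.R3s ** 2,
        eta=p.ups5 * p.R1s ** 2,
        theta=p.ups5 * p.R2s ** 2,
        kappa=p.ups5 * p.R3s ** 2,
        lam=p.lambda_TGFb * p.Ts / p.Ss,
        mu_A1=p.mu_antimiR21,
        mu_A2=p.mu_antimiR142,
        mu_A3=p.mu_antimiR10,
        mu_R1=p.mu_miR21,
        mu_R2=p.mu_miR142,
        mu_R3=p.mu_miR10,
        mu_T=p.mu_TGFb,
        mu_S=p.mu_SMAD,
        se_source_multiplier=1.0,
    )


def model_variant(params: ModelParameters, mask: MirnaMask) -> ModelParameters:
    """Parameters for a structural variant with a subset of miRNA branches.

    Masked-out branches lose their source and their inhibition strengths on
    T and S; included branches are untouched.
    """
    changes: dict[str, float] = {}
    groups = (
        ("lam_R1", "delta", "eta"),
        ("lam_R2", "eps", "theta"),
        ("lam_R3", "zeta", "kappa"),
    )
    for included, fields in zip(mask.flags(), groups):
        if not included:
            for f in fields:
                changes[f] = 0.0
    return params.replace(**changes) if changes else params


# ---------------------------------------------------------------------------
# Parameter fixture loading
# ---------------------------------------------------------------------------

def load_parameter_file(path) -> dict:
    """Read a YAML parameter file; returns the raw mapping.

    Recognized top-level sections: ``model`` (ModelParameters fields),
    ``dimensional`` (DimensionalParameters fields) and ``thresholds``
    (th_T / th_S).  When only ``dimensional`` is given, the dimensionless
    parameters are derived via the scale map.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ModelError(f"parameter file {path} must contain a mapping")
    return raw


def parameters_from_file(path) -> ModelParameters:
    raw = load_parameter_file(path)
    if "model" in raw:
        return ModelParameters.from_dict(raw["model"])
    if "dimensional" in raw:
        return nondimensionalize(DimensionalParameters(**raw["dimensional"]))
    raise ModelError(f"{path}: expected a 'model' or 'dimensional' section")


def _fixture_path() -> object:
    return importlib.resources.files("mirtgf.data") / "params_calibrated.yaml"


def calibrated_parameters() -> ModelParameters:
    """The packaged calibrated parameter set (synthetic, see methods note)."""
    with importlib.resources.as_file(_fixture_path()) as p:
        return parameters_from_file(p)


def calibrated_thresholds_dict() -> dict[str, float]:
    """The packaged phenotype thresholds accompanying the calibrated set."""
    with importlib.resources.as_file(_fixture_path()) as p:
        raw = load_parameter_file(p)
    return {k: float(v) for k, v in raw["thresholds"].items()}
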