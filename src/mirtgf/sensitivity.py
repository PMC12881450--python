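"""Extended Fourier Amplitude Sensitivity Test (eFAST).

eFAST attributes the variance of a model output to its input parameters by
driving each parameter along a space-filling search curve at a dedicated
integer frequency and reading the strength of that frequency (and its
harmonics) out of the output's Fourier spectrum.  The parameter of interest
is assigned the highest admissible frequency; the complementary set shares
low, well-separated frequencies.  Two indices are computed per parameter:

* ``S1`` (first order): the variance fraction carried by the focal
  frequency and its first M harmonics;
* ``ST`` (total order): one minus the variance fraction carried by the
  low-frequency band of the complementary set, which also captures all
  interactions involving the focal parameter.

Confidence intervals come from repeating the search with NR independent
random phase shifts (resampling curves).

Here the indices probe the nine inhibition-strength parameters
(alpha..kappa) against the model species at the brain-analysis time point
t = 24 h, under either the scrambled-control or the antagomir arm.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    FULL_MASK,
    INHIBITION_STRENGTHS,
    MirnaMask,
    ModelError,
    ModelParameters,
)
from .protocols import DosingProtocol, build_protocol, simulate_species_batch

__all__ = [
    "SensitivitySpec",
    "SensitivityResult",
    "efast_sample",
    "efast_indices",
    "efast_analyze_function",
    "model_response",
    "efast_model_indices",
    "default_ranges",
]

_OUTPUT_SPECIES = ("R1", "R2", "R3", "T", "S")


@dataclasses.dataclass
class SensitivitySpec:
    """Configuration of one eFAST experiment."""

    parameters: tuple[str, ...]
    ranges: dict[str, tuple[float, float]]
    N: int = 1000
    M: int = 4
    NR: int = 5
    seed: int = 0
    output: str = "T"
    arm: str = "control"
    eval_time: float = 24.0

    def __post_init__(self) -> None:
        if self.N < 65:
            raise ModelError("N must be >= 65")
        if self.M < 1 or self.NR < 1:
            raise ModelError("M and NR must be >= 1")
        if self.output not in _OUTPUT_SPECIES:
            raise ModelError(f"output must be one of {_OUTPUT_SPECIES}")
        if self.arm not in ("control", "antagomir"):
            raise ModelError("arm must be 'control' or 'antagomir'")
        for name in self.parameters:
            lo, hi = self.ranges[name]
            if not lo <= hi:
                raise ModelError(f"range for {name} must satisfy lo <= hi")

    @property
    def omega_max(self) -> int:
        """Highest focal frequency admitted by the Nyquist condition."""
        w = (self.N - 1) // (2 * self.M)
        if w < 1:
            raise ModelError(f"N={self.N} violates the Nyquist condition for M={self.M}")
        return w


@dataclasses.dataclass
class SensitivityResult:
    """Per-parameter first- and total-order indices with 95% CIs."""

    parameters: tuple[str, ...]
    S1: dict[str, float]
    ST: dict[str, float]
    S1_ci95: dict[str, tuple[float, float]]
    ST_ci95: dict[str, tuple[float, float]]
    degenerate: bool = False
    clipped: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.parameters:
            rows.append({
                "parameter": p,
                "S1": self.S1[p],
                "S1_lo": self.S1_ci95[p][0], "S1_hi": self.S1_ci95[p][1],
                "ST": self.ST[p],
                "ST_lo": self.ST_ci95[p][0], "ST_hi": self.ST_ci95[p][1],
            })
        return pd.DataFrame(rows)


def _complementary_frequencies(spec: SensitivitySpec) -> np.ndarray:
    """Distinct low frequencies for the complementary parameter set."""
    w_max = spec.omega_max
    n_comp = len(spec.parameters) - 1
    if n_comp == 0:
        return np.array([], dtype=int)
    cap = max(1, w_max // (2 * spec.M))
    # Frequencies are spread over the upper-middle of the admissible band
    # [1, cap]: too low and the search curve fills parameter space poorly
    # (biased variance); too high and the M-th harmonics of the complement
    # leak past the omega_max/2 cut that separates it from the focal band.
    f_hi = max(2, int(0.9 * cap))
    f_lo = min(f_hi, max(2, int(np.ceil(cap / 3))))
    if n_comp > cap:
        raise ModelError(
            f"cannot assign {n_comp} distinct complementary frequencies <= {cap}; "
            "increase N or decrease M")
    freqs = np.unique(np.round(np.linspace(f_lo, f_hi, n_comp)).astype(int))
    if freqs.size < n_comp:  # rounding collisions: take a consecutive block
        start = max(1, f_hi - n_comp + 1)
        freqs = np.arange(start, start + n_comp)
    return freqs


def efast_sample(
    spec: SensitivitySpec, focal: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One search curve: design matrix (N, n_params) and frequency vector.

    The focal parameter is driven at ``omega_max``; the others share the low
    complementary frequencies.  Random phases are drawn from ``rng``, so each
    call produces one resampling curve.  Every sampled value lies within the
    declared range, and the marginal distribution of the arcsine-of-sine
    transform is uniform on [lo, hi].
    """
    if focal not in spec.parameters:
        raise ModelError(f"{focal!r} is not in the parameter list")
    n = len(spec.parameters)
    freqs = np.empty(n, dtype=int)
    comp = _complementary_frequencies(spec)
    ci = 0
    for i, name in enumerate(spec.parameters):
        if name == focal:
            freqs[i] = spec.omega_max
        else:
            freqs[i] = comp[ci % max(comp.size, 1)]
            ci += 1

    s = -np.pi + 2.0 * np.pi * np.arange(1, spec.N + 1) / spec.N
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n)
    design = np.empty((spec.N, n))
    for i, name in enumerate(spec.parameters):
        lo, hi = spec.ranges[name]
        x = 0.5 + np.arcsin(np.sin(freqs[i] * s + phases[i])) / np.pi
        design[:, i] = lo + (hi - lo) * x
    return design, freqs


def _spectrum_power(y: np.ndarray) -> np.ndarray:
    """Power 2|c_k|^2 at integer frequencies k = 1..(N-1)//2."""
    N = y.size
    coeffs = np.fft.rfft(y - y.mean()) / N
    k_max = (N - 1) // 2
    return 2.0 * np.abs(coeffs[1:k_max + 1]) ** 2


def efast_indices(
    outputs: np.ndarray, spec: SensitivitySpec, focal_index: int | None = None
) -> tuple[np.ndarray, np.ndarray, bool]:
    """S1 and ST estimates for the focal parameter from NR output curves.

    ``outputs`` has shape (NR, N): one model-response row per resampling
    curve, all driven with the focal parameter at ``omega_max``.  Returns
    per-curve S1 and ST arrays plus a degenerate-output flag (zero total
    variance on some curve, in which case that curve's indices are 0).
    """
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    if outputs.shape[1] != spec.N:
        raise ModelError("outputs length must equal spec.N per curve")
    w = spec.omega_max
    s1 = np.zeros(outputs.shape[0])
    st = np.zeros(outputs.shape[0])
    degenerate = False
    for r, y in enumerate(outputs):
        power = _spectrum_power(y)
        D = power.sum()
        # relative degeneracy guard: variance at or below integrator noise
        floor = 1e-12 * max(1.0, float(np.mean(y)) ** 2)
        if not np.isfinite(D) or D <= floor:
            degenerate = True
            continue
        harmonics = np.arange(1, spec.M + 1) * w
        harmonics = harmonics[harmonics <= power.size]
        D_focal = power[harmonics - 1].sum()
        cut = max(1, w // 2)
        D_comp = power[:cut].sum()
        s1[r] = D_focal / D
        st[r] = 1.0 - D_comp / D
    return s1, st, degenerate


def _summarize(
    spec: SensitivitySpec, per_param: dict[str, tuple[np.ndarray, np.ndarray]],
    degenerate: bool,
) -> SensitivityResult:
    S1: dict[str, float] = {}
    ST: dict[str, float] = {}
    S1_ci: dict[str, tuple[float, float]] = {}
    ST_ci: dict[str, tuple[float, float]] = {}
    clipped = False
    for name, (s1, st) in per_param.items():
        if np.any(s1 < 0) or np.any(s1 > 1) or np.any(st < 0) or np.any(st > 1):
            clipped = True
        s1c = np.clip(s1, 0.0, 1.0)
        stc = np.clip(st, 0.0, 1.0)
        S1[name] = float(s1c.mean())
        ST[name] = float(stc.mean())
        S1_ci[name] = (float(np.percentile(s1c, 2.5)), float(np.percentile(s1c, 97.5)))
        ST_ci[name] = (float(np.percentile(stc, 2.5)), float(np.percentile(stc, 97.5)))
    return SensitivityResult(
        parameters=spec.parameters, S1=S1, ST=ST,
        S1_ci95=S1_ci, ST_ci95=ST_ci,
        degenerate=degenerate, clipped=clipped,
    )


def efast_analyze_function(
    func: Callable[[np.ndarray], np.ndarray], spec: SensitivitySpec
) -> SensitivityResult:
    """Run the full eFAST loop on a plain vectorized function.

    ``func`` maps a design matrix (N, n_params) to N scalar outputs.  Used
    both for analytic benchmark models and as the core of the ODE-backed
    analysis.
    """
    rng = np.random.default_rng(spec.seed)
    per_param: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    degenerate = False
    for focal in spec.parameters:
        outputs = np.empty((spec.NR, spec.N))
        for r in range(spec.NR):
            design, _ = efast_sample(spec, focal, rng)
            outputs[r] = func(design)
        s1, st, dg = efast_indices(outputs, spec)
        degenerate = degenerate or dg
        per_param[focal] = (s1, st)
    return _summarize(spec, per_param, degenerate)


def default_ranges(
    params: ModelParameters,
    names: Sequence[str] = INHIBITION_STRENGTHS,
    rel: float = 0.5,
) -> dict[str, tuple[float, float]]:
    """Symmetric [1-rel, 1+rel] x nominal perturbation ranges."""
    out = {}
    for name in names:
        nominal = float(getattr(params, name))
        out[name] = (nominal * (1.0 - rel), nominal * (1.0 + rel))
    return out


def arm_protocol(arm: str) -> DosingProtocol:
    """Standard study arms: scrambled control or antagomir bolus 1.0."""
    if arm == "control":
        return build_protocol("control")
    return build_protocol("bolus", dose=1.0)


def model_response(
    spec: SensitivitySpec,
    params_base: ModelParameters,
    protocol: DosingProtocol | None = None,
    design: np.ndarray | None = None,
    mask: MirnaMask = FULL_MASK,
) -> np.ndarray:
    """Model outputs along a design: overwrite the probed parameters row by
    row, simulate the arm, record the requested species at ``eval_time``.

    All design rows are integrated in one stacked batch.
    """
    if design is None:
        raise ModelError("model_response requires a design matrix")
    if protocol is None:
        protocol = arm_protocol(spec.arm)
    overrides = {name: design[:, i] for i, name in enumerate(spec.parameters)}
    out = simulate_species_batch(
        params_base, overrides, protocol, [spec.eval_time], mask=mask
    )
    species_idx = _OUTPUT_SPECIES.index(spec.output)
    return out[:, 0, species_idx]


def efast_model_indices(
    params_base: ModelParameters,
    spec: SensitivitySpec,
    mask: MirnaMask = FULL_MASK,
) -> SensitivityResult:
    """eFAST indices of the ODE model for one (arm, output) combination."""
    protocol = arm_protocol(spec.arm)

    def func(design: np.ndarray) -> np.ndarray:
        return model_response(spec, params_base, protocol, design, mask)

    return efast_analyze_function(func, spec)
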