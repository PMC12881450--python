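"""Synthetic observations with known ground truth, and parameter fitting.

The study design this emulates measures miRNA expression at SE induction
(t = 0 h) and all species at the Western-blot time (t = 24 h), in two arms:
scrambled control and antagomir bolus pre-injection, reported as
log2(fold change over control).  The generator simulates both arms under a
known parameter set and adds i.i.d. Gaussian noise on the log2 scale
(Western-blot fold changes are conventionally log-normal).

Fitting minimizes the sum of squared log2 residuals over a declared free
parameter subset by bounded multi-start local least squares.  The default
free subset — miRNA sources and decays, the three antagomir inhibition
strengths, and the SE source multiplier — is identifiable from the
two-timepoint two-arm design; the Hill saturation constants are frozen
(structurally non-identifiable from two timepoints).

The module also houses the calibration fallback that searches parameter
space for a set reproducing the printed administration-strategy bounds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model_core import (
    ModelError,
    ModelParameters,
    calibrated_parameters,
)
from .phenotype import PhenotypeThresholds, classify_trajectory
from .protocols import (
    DosingProtocol,
    build_protocol,
    simulate_protocol,
    simulate_species_batch,
)

__all__ = [
    "ObservationSet",
    "FitResult",
    "DEFAULT_FREE_FIELDS",
    "DoseOutcomeTarget",
    "DEFAULT_CALIBRATION_TARGETS",
    "CalibrationError",
    "default_arm_protocols",
    "generate_observations",
    "fit_parameters",
    "calibrate",
]

SPECIES = ("R1", "R2", "R3", "T", "S")
OBS_TIMES = (0.0, 24.0)

DEFAULT_FREE_FIELDS = (
    "lam_R1", "lam_R2", "lam_R3",
    "mu_R1", "mu_R2", "mu_R3",
    "alpha", "beta", "gamma",
    "se_source_multiplier",
)


def default_arm_protocols() -> dict[str, DosingProtocol]:
    return {
        "control": build_protocol("control"),
        "antagomir": build_protocol("bolus", dose=1.0),
    }


@dataclasses.dataclass
class ObservationSet:
    """log2(FC over control) records by species, arm, time and replicate."""

    frame: pd.DataFrame  # columns: species, arm, time_h, replicate, log2fc
    noise_sd: float
    seed: int | None = None

    def __post_init__(self) -> None:
        required = {"species", "arm", "time_h", "replicate", "log2fc"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ModelError(f"observation frame missing columns {sorted(missing)}")
        if not np.all(np.isfinite(self.frame["log2fc"])):
            raise ModelError("log2fc values must be finite")
        counts = self.frame.groupby(["species", "arm", "time_h"]).size()
        if (counts < 1).any():
            raise ModelError("every (species, arm, time) cell needs >= 1 replicate")

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, noise_sd: float = float("nan")) -> "ObservationSet":
        return cls(frame=pd.read_csv(path), noise_sd=noise_sd)


def _forward_log2(
    params: ModelParameters,
    protocols: dict[str, DosingProtocol],
    overrides: dict[str, np.ndarray] | None = None,
) -> dict[tuple[str, str, float], float]:
    """Noise-free log2 species levels for each (species, arm, time) cell.

    Uses the fast analytic-antagomir integrator; the same forward map is
    shared by the generator and the fitting objective.
    """
    overrides = overrides or {}
    out: dict[tuple[str, str, float], float] = {}
    for arm, proto in protocols.items():
        levels = simulate_species_batch(
            params, overrides, proto, OBS_TIMES, rtol=1e-8, atol=1e-10
        )[0]  # (n_times, 5)
        for ti, t in enumerate(OBS_TIMES):
            for si, sp in enumerate(SPECIES):
                value = levels[ti, si]
                if value <= 0:
                    raise ModelError(f"non-positive level for {sp} ({arm}, t={t})")
                out[(sp, arm, t)] = float(np.log2(value))
    return out


def generate_observations(
    true_params: ModelParameters,
    protocols: dict[str, DosingProtocol] | None = None,
    noise_sd: float = 0.1,
    n_replicates: int = 4,
    seed: int | None = 0,
) -> ObservationSet:
    """Simulate both arms and emit noisy log2(FC) replicate records.

    With ``noise_sd=0`` the records equal the deterministic model outputs;
    the same seed always reproduces the same set.
    """
    if noise_sd < 0:
        raise ModelError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ModelError("n_replicates must be >= 1")
    protocols = protocols or default_arm_protocols()
    clean = _forward_log2(true_params, protocols)
    rng = np.random.default_rng(seed)
    rows = []
    for (sp, arm, t), mu in sorted(clean.items()):
        noise = rng.normal(0.0, noise_sd, size=n_replicates) if noise_sd > 0 \
            else np.zeros(n_replicates)
        for rep in range(n_replicates):
            rows.append({"species": sp, "arm": arm, "time_h": t,
                         "replicate": rep, "log2fc": mu + noise[rep]})
    return ObservationSet(frame=pd.DataFrame(rows), noise_sd=noise_sd, seed=seed)


@dataclasses.dataclass
class FitResult:
    """Outcome of a least-squares fit."""

    params: ModelParameters
    free_fields: tuple[str, ...]
    rss: float
    converged: bool
    n_starts: int
    start_rss: list[float]
    relative_error: dict[str, float] | None = None

    def compare_to_truth(self, truth: ModelParameters) -> dict[str, float]:
        self.relative_error = {
            f: abs(getattr(self.params, f) - getattr(truth, f))
            / max(abs(getattr(truth, f)), 1e-12)
            for f in self.free_fields
        }
        return self.relative_error


def _default_bounds(
    base: ModelParameters, free_fields: tuple[str, ...]
) -> dict[str, tuple[float, float]]:
    bounds = {}
    for f in free_fields:
        if f == "se_source_multiplier":
            bounds[f] = (1.0, 4.0)
        else:
            nominal = float(getattr(base, f))
            bounds[f] = (nominal / 5.0, nominal * 5.0)
    return bounds


def fit_parameters(
    obs: ObservationSet,
    free_fields: tuple[str, ...] = DEFAULT_FREE_FIELDS,
    bounds: dict[str, tuple[float, float]] | None = None,
    init: dict[str, float] | None = None,
    params_base: ModelParameters | None = None,
    protocols: dict[str, DosingProtocol] | None = None,
    n_starts: int = 8,
    seed: int | None = 0,
    *,
    xtol: float = 1e-12,
    ftol: float = 1e-12,
) -> FitResult:
    """Bounded multi-start least squares on the log2 residuals.

    The search runs in log-parameter space (all free fields are positive
    rates/strengths).  The first start is ``init`` (or the base parameters);
    the remaining starts are drawn log-uniformly within the bounds from the
    seeded generator.  Fields outside ``free_fields`` stay frozen at their
    ``params_base`` values.
    """
    if params_base is None:
        params_base = calibrated_parameters()
    protocols = protocols or default_arm_protocols()
    bounds = bounds or _default_bounds(params_base, free_fields)
    for f in free_fields:
        lo, hi = bounds[f]
        if not 0 < lo < hi:
            raise ModelError(f"bounds for {f} must satisfy 0 < lo < hi")

    df = obs.frame
    keys = list(zip(df["species"], df["arm"], df["time_h"].astype(float)))
    target = df["log2fc"].to_numpy(dtype=float)

    log_lo = np.array([np.log(bounds[f][0]) for f in free_fields])
    log_hi = np.array([np.log(bounds[f][1]) for f in free_fields])

    key_index = [(SPECIES.index(sp), OBS_TIMES.index(t), arm)
                 for sp, arm, t in keys]

    def residual_matrix(log_X: np.ndarray) -> np.ndarray:
        """Residual rows for a batch of log-parameter vectors (B, n_free)."""
        log_X = np.atleast_2d(log_X)
        B = log_X.shape[0]
        overrides = {f: np.exp(log_X[:, i])
                     for i, f in enumerate(free_fields)}
        preds = {}
        for arm, proto in protocols.items():
            levels = simulate_species_batch(
                params_base, overrides, proto, OBS_TIMES,
                rtol=1e-8, atol=1e-10)  # (B, n_times, 5)
            preds[arm] = np.log2(np.clip(levels, 1e-12, None))
        out = np.empty((B, target.size))
        for j, (si, ti, arm) in enumerate(key_index):
            out[:, j] = preds[arm][:, ti, si] - target[j]
        return out

    def residuals(log_x: np.ndarray) -> np.ndarray:
        try:
            return residual_matrix(log_x)[0]
        except Exception:
            return np.full(target.size, 1e3)

    def jac(log_x: np.ndarray) -> np.ndarray:
        """Forward-difference Jacobian via one stacked batch integration."""
        h = 1e-6
        n = log_x.size
        X = np.vstack([log_x, np.tile(log_x, (n, 1)) + h * np.eye(n)])
        R = residual_matrix(X)
        return (R[1:] - R[0]).T / h

    rng = np.random.default_rng(seed)
    starts = []
    if init is not None:
        starts.append(np.array([np.log(init[f]) for f in free_fields]))
    else:
        x0 = np.array([np.log(np.clip(getattr(params_base, f),
                                      bounds[f][0], bounds[f][1]))
                       for f in free_fields])
        starts.append(x0)
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(log_lo, log_hi))

    best = None
    start_rss = []
    any_success = False
    for x0 in starts:
        sol = least_squares(
            residuals, np.clip(x0, log_lo, log_hi),
            jac=jac, bounds=(log_lo, log_hi), method="trf",
            xtol=xtol, ftol=ftol, gtol=1e-12,
        )
        rss = float(2.0 * sol.cost)
        start_rss.append(rss)
        any_success = any_success or sol.success
        if best is None or rss < best[0]:
            best = (rss, sol)
    if not any_success:
        raise ModelError(
            "optimizer failed on all starts; per-start RSS: "
            + ", ".join(f"{r:.3g}" for r in start_rss))

    rss, sol = best
    fitted = params_base.replace(
        **{f: float(np.exp(v)) for f, v in zip(free_fields, sol.x)}
    )
    return FitResult(
        params=fitted, free_fields=tuple(free_fields), rss=rss,
        converged=bool(sol.success), n_starts=len(starts), start_rss=start_rss,
    )


# ---------------------------------------------------------------------------
# Calibration fallback
# ---------------------------------------------------------------------------

class CalibrationError(RuntimeError):
    """Calibration could not satisfy the qualitative constraints."""


@dataclasses.dataclass(frozen=True)
class DoseOutcomeTarget:
    """One qualitative constraint on a dosing scenario.

    ``sustained=True`` demands the whole chronic phase stays anti-seizure;
    ``sustained=False`` demands it does not.  For ``kind='control'`` the
    False case additionally demands a full switch to the seizure state
    (both T and S below threshold at some chronic time).
    """

    kind: str
    dose: float
    sustained: bool


DEFAULT_CALIBRATION_TARGETS = (
    DoseOutcomeTarget("control", 0.0, False),
    DoseOutcomeTarget("bolus", 1.0, True),
    DoseOutcomeTarget("bolus", 0.6, False),
    DoseOutcomeTarget("infusion", 0.25, True),
    DoseOutcomeTarget("infusion", 0.125, False),
)

# fields jittered by the random search
_CALIB_SEARCH_FIELDS = (
    "alpha", "beta", "gamma", "delta", "eps", "zeta", "eta", "theta", "kappa",
    "mu_A1", "mu_A2", "mu_A3", "mu_T", "mu_S", "k7", "k9",
)

_CALIB_GRID = np.arange(-24.0, 24.0001, 0.2)
_CHRONIC = _CALIB_GRID >= -1e-9


def _implied_thresholds(params: ModelParameters, ts: dict[str, np.ndarray]) -> PhenotypeThresholds:
    th_T = 0.5 * (ts["control_T"][_CHRONIC].mean() + ts["anta_T"][_CHRONIC].mean())
    th_S = 0.5 * (ts["control_S"][_CHRONIC].mean() + ts["anta_S"][_CHRONIC].mean())
    return PhenotypeThresholds(th_T=float(th_T), th_S=float(th_S))


def _calibration_margins(
    params: ModelParameters,
    targets: tuple[DoseOutcomeTarget, ...],
) -> tuple[np.ndarray, PhenotypeThresholds]:
    """Signed satisfaction margin per target (positive = satisfied)."""
    def run(kind: str, dose: float) -> tuple[np.ndarray, np.ndarray]:
        proto = build_protocol(kind, dose=dose)
        traj = simulate_protocol(params, proto, grid=_CALIB_GRID,
                                 rtol=1e-6, atol=1e-8, max_step=np.inf)
        return traj.column("T"), traj.column("S")

    cache: dict[tuple[str, float], tuple[np.ndarray, np.ndarray]] = {}

    def cached(kind: str, dose: float):
        key = (kind, dose)
        if key not in cache:
            cache[key] = run(kind, dose)
        return cache[key]

    cT, cS = cached("control", 0.0)
    aT, aS = cached("bolus", 1.0)
    thr = _implied_thresholds(params, {
        "control_T": cT, "control_S": cS, "anta_T": aT, "anta_S": aS})

    margins = []
    for tgt in targets:
        T, S = cached(tgt.kind, tgt.dose)
        sustain_margin = min((T[_CHRONIC] - thr.th_T).min(),
                             (S[_CHRONIC] - thr.th_S).min())
        if tgt.sustained:
            margins.append(sustain_margin)
        elif tgt.kind == "control":
            # must fully switch: both T and S below threshold at some time
            margins.append(-np.maximum(T[_CHRONIC] - thr.th_T,
                                       S[_CHRONIC] - thr.th_S).min())
        else:
            margins.append(-sustain_margin)
    return np.array(margins), thr


def calibrate(
    targets: tuple[DoseOutcomeTarget, ...] = DEFAULT_CALIBRATION_TARGETS,
    nominal: ModelParameters | None = None,
    seed: int | None = 0,
    n_iter: int = 200,
    verify: bool = True,
) -> tuple[ModelParameters, PhenotypeThresholds]:
    """Find parameters satisfying the dose-outcome constraints.

    Starting from ``nominal`` (default: the packaged calibrated set), the
    constraints are checked; if already satisfied the set is returned
    unchanged together with its implied midpoint thresholds.  Otherwise a
    seeded log-normal random search with step-size decay perturbs the
    inhibition strengths, decay rates and pathway autocatalysis rates to
    maximize the minimum constraint margin.  Raises
    :class:`CalibrationError` with the best margins if the budget is
    exhausted without a feasible set.
    """
    if not targets:
        raise ModelError("constraint list must be non-empty")
    params = nominal or calibrated_parameters()
    margins, thr = _calibration_margins(params, targets)
    if margins.min() > 0:
        return params, thr

    rng = np.random.default_rng(seed)
    best = (margins.min(), params, thr, margins)
    scale = 0.3
    for it in range(n_iter):
        base = best[1]
        jitter = {
            f: float(getattr(base, f) * np.exp(rng.normal(0.0, scale)))
            for f in _CALIB_SEARCH_FIELDS
        }
        try:
            cand = base.replace(**jitter)
            m, t = _calibration_margins(cand, targets)
        except Exception:
            continue
        if m.min() > best[0]:
            best = (m.min(), cand, t, m)
            if m.min() > 0:
                break
        scale = max(0.05, scale * 0.995)
    if best[0] <= 0:
        raise CalibrationError(
            "calibration budget exhausted; best margins per target: "
            + ", ".join(f"{t.kind}@{t.dose}:{m:.4f}"
                        for t, m in zip(targets, best[3])))
    params, thr = best[1], best[2]
    if verify:
        # confirm with the reference integrator at default accuracy
        for tgt in targets:
            proto = build_protocol(tgt.kind, dose=tgt.dose)
            traj = simulate_protocol(params, proto)
            summary = classify_trajectory(traj, thr)
            if summary.sustained_anti_seizure != tgt.sustained:
                raise CalibrationError(
                    f"verification failed for {tgt.kind}@{tgt.dose}")
    return params, thr
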