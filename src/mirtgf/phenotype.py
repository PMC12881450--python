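"""Seizure / anti-seizure phenotype classification and critical doses.

The phenotype of a state is decided by the TGF-beta and SMAD levels against
fixed thresholds th_T and th_S: the system is *anti-seizure* when both are
above their thresholds, *seizure* when both are below, and *transitional*
otherwise (including exact equality, classified conservatively as neither).

A dose "sustains" the anti-seizure state when every grid point of the
chronic phase (by default [0, 24] h, from SE induction to brain analysis)
is classified anti-seizure.  The critical dose of a strategy is located by
bisection after verifying that the sustained/not-sustained outcome is
monotone along a dose ladder.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .model_core import FULL_MASK, MirnaMask, ModelError, ModelParameters
from .protocols import DosingProtocol, Trajectory, build_protocol, simulate_protocol

__all__ = [
    "ANTI_SEIZURE",
    "SEIZURE",
    "TRANSITIONAL",
    "PhenotypeThresholds",
    "PhenotypeSummary",
    "classify_state",
    "classify_trajectory",
    "sustained_anti_seizure",
    "critical_dose",
]

ANTI_SEIZURE = "anti_seizure"
SEIZURE = "seizure"
TRANSITIONAL = "transitional"


@dataclasses.dataclass(frozen=True)
class PhenotypeThresholds:
    """TGF-beta and SMAD thresholds (FC over control) separating the states."""

    th_T: float
    th_S: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.th_T) and np.isfinite(self.th_S)):
            raise ModelError("thresholds must be finite")
        if self.th_T <= 0 or self.th_S <= 0:
            raise ModelError("thresholds must be strictly positive")


def classify_state(T: float, S: float, thresholds: PhenotypeThresholds) -> str:
    """Label one (T, S) pair.

    Anti-seizure iff T > th_T and S > th_S; seizure iff T < th_T and
    S < th_S; transitional otherwise.
    """
    if T < 0 or S < 0:
        raise ModelError("T and S must be non-negative")
    if T > thresholds.th_T and S > thresholds.th_S:
        return ANTI_SEIZURE
    if T < thresholds.th_T and S < thresholds.th_S:
        return SEIZURE
    return TRANSITIONAL


@dataclasses.dataclass
class PhenotypeSummary:
    """Chronic-phase summary of a labelled trajectory."""

    sustained_anti_seizure: bool
    first_switch_time: float | None
    occupancy: dict[str, float]

    def to_json(self, path, extra: dict | None = None) -> None:
        payload = dict(extra or {})
        payload.update(
            sustained=self.sustained_anti_seizure,
            first_switch_time=self.first_switch_time,
            occupancy=self.occupancy,
        )
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def classify_trajectory(
    traj: Trajectory,
    thresholds: PhenotypeThresholds,
    phase_window: tuple[float, float] = (0.0, 24.0),
) -> PhenotypeSummary:
    """Label every trajectory point and summarize the phase window.

    The trajectory's ``labels`` attribute is filled in place.  The summary
    reports whether *every* window point is anti-seizure, the first window
    time at which the label leaves anti-seizure (None if never), and the
    fraction of window points in each state.
    """
    lo, hi = phase_window
    if hi <= lo:
        raise ModelError("empty phase window")
    sel = traj.window_slice(lo, hi)
    if not np.any(sel):
        raise ModelError("trajectory does not cover the phase window")
    T = traj.column("T")
    S = traj.column("S")
    labels = [classify_state(float(ti), float(si), thresholds)
              for ti, si in zip(T, S)]
    traj.labels = labels

    window_labels = [lab for lab, s in zip(labels, sel) if s]
    window_times = traj.times[sel]
    first_switch = None
    for t_i, lab in zip(window_times, window_labels):
        if lab != ANTI_SEIZURE:
            first_switch = float(t_i)
            break
    occupancy = {
        state: window_labels.count(state) / len(window_labels)
        for state in (ANTI_SEIZURE, SEIZURE, TRANSITIONAL)
    }
    return PhenotypeSummary(
        sustained_anti_seizure=first_switch is None,
        first_switch_time=first_switch,
        occupancy=occupancy,
    )


def sustained_anti_seizure(
    params: ModelParameters,
    thresholds: PhenotypeThresholds,
    protocol: DosingProtocol,
    *,
    t_end: float = 24.0,
    phase_window: tuple[float, float] = (0.0, 24.0),
    mask: MirnaMask = FULL_MASK,
    rtol: float = 1e-8,
) -> bool:
    """True iff the protocol keeps the chronic phase entirely anti-seizure."""
    traj = simulate_protocol(params, protocol, t_end=t_end, mask=mask, rtol=rtol)
    return classify_trajectory(traj, thresholds, phase_window).sustained_anti_seizure


def critical_dose(
    params: ModelParameters,
    thresholds: PhenotypeThresholds,
    kind: str = "bolus",
    bracket: tuple[float, float] = (0.0, 1.5),
    tol: float = 0.01,
    *,
    window: tuple[float, float] = (-24.0, 0.0),
    n_injections: int = 1,
    mask: MirnaMask = FULL_MASK,
    ladder_points: int = 9,
    rtol: float = 1e-8,
) -> float:
    """Bisect for the smallest dose that sustains the anti-seizure state.

    The outcome must not be sustained at ``bracket[0]`` and sustained at
    ``bracket[1]``; monotonicity of the sustained outcome in dose is checked
    on a ladder of ``ladder_points`` doses before bisection begins.  Returns
    d* such that every dose >= d* sustains and doses below d* - tol do not.
    """
    if tol <= 0:
        raise ModelError("tol must be positive")
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ModelError("invalid bracket")

    def outcome(dose: float) -> bool:
        proto = build_protocol(kind, dose=dose, n_injections=n_injections,
                               window=window)
        return sustained_anti_seizure(params, thresholds, proto, mask=mask,
                                      rtol=rtol)

    ladder = np.linspace(lo, hi, ladder_points)
    outcomes = [outcome(d) for d in ladder]
    if all(outcomes):
        # degenerate thresholds: every dose in the bracket sustains
        return lo
    if outcomes[0]:
        raise ModelError(
            f"bracket low end {lo} already sustains the anti-seizure state")
    if not outcomes[-1]:
        raise ModelError(f"bracket high end {hi} does not sustain")
    flips = sum(1 for a, b in zip(outcomes, outcomes[1:]) if a != b)
    if flips != 1:
        raise ModelError(
            "non-monotone sustained outcome on the dose ladder: "
            + ", ".join(f"{d:.4g}:{o}" for d, o in zip(ladder, outcomes))
        )

    # shrink to the flip interval, then bisect
    flip_idx = next(i for i, (a, b) in enumerate(zip(outcomes, outcomes[1:]))
                    if a != b)
    lo, hi = float(ladder[flip_idx]), float(ladder[flip_idx + 1])
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if outcome(mid):
            hi = mid
        else:
            lo = mid
    return hi
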