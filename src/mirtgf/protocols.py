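"""Antagomir administration strategies and their simulation.

Four strategies are supported, mirroring the treatment arms of the study
design:

* ``control`` -- scrambled control, no antagomir (A == 0 throughout);
* ``bolus`` -- a single impulse of each antagomir at the start of the
  control phase (default t = -24 h), decaying freely afterwards;
* ``infusion`` -- the antagomir levels are clamped at a constant value over
  the control phase and released to free decay at its end;
* ``multidose`` -- the total bolus dose split into ``n_injections`` equal
  impulses at equal intervals across the control phase, each impulse adding
  to the current level.

Impulses are handled by stop-add-restart event semantics: integration halts
at the impulse time, the dose is added to the antagomir channels, and
integration resumes.  The antagomir sub-system is linear, so a closed-form
superposition of impulse responses is provided as an independent oracle.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    FULL_MASK,
    IDX_A,
    IDX_R,
    IDX_S,
    IDX_T,
    N_STATE,
    STATE_NAMES,
    MirnaMask,
    ModelError,
    ModelParameters,
    rhs_dimensionless,
    state_array,
)

__all__ = [
    "DosingProtocol",
    "Trajectory",
    "IntegrationError",
    "build_protocol",
    "simulate_protocol",
    "antagomir_closed_form",
    "antagomir_superposition",
    "simulate_species_batch",
]

PROTOCOL_KINDS = ("control", "bolus", "infusion", "multidose")


class IntegrationError(RuntimeError):
    """ODE integration failure, carrying the failing time interval."""

    def __init__(self, message: str, interval: tuple[float, float]):
        super().__init__(f"{message} on interval {interval}")
        self.interval = interval


@dataclasses.dataclass(frozen=True)
class DosingProtocol:
    """Declarative description of one administration strategy.

    ``dose`` is the per-antagomir amount in FC over control: the single
    impulse size for a bolus, the clamp level for an infusion, and the
    *total* divided dose for a multidose schedule.
    """

    kind: str
    dose: float = 0.0
    n_injections: int = 1
    window_start: float = -24.0
    window_end: float = 0.0
    per_antagomir_overrides: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ModelError(f"unknown protocol kind {self.kind!r}")
        if self.dose < 0:
            raise ModelError("dose must be non-negative")
        if self.kind == "control" and self.dose != 0:
            raise ModelError("control protocol requires dose == 0")
        if self.n_injections < 1:
            raise ModelError("n_injections must be >= 1")
        if not self.window_start < self.window_end:
            raise ModelError("window_start must be < window_end")
        if self.kind == "multidose":
            spacing = (self.window_end - self.window_start) / self.n_injections
            if spacing <= 0:
                raise ModelError("multidose injection spacing collapsed to zero")
        if self.per_antagomir_overrides:
            for key in self.per_antagomir_overrides:
                if key not in ("A1", "A2", "A3"):
                    raise ModelError(f"unknown antagomir channel {key!r}")

    # -- derived quantities ---------------------------------------------
    def channel_doses(self) -> np.ndarray:
        """Per-channel dose vector (A1, A2, A3)."""
        doses = np.full(3, float(self.dose))
        if self.per_antagomir_overrides:
            for key, value in self.per_antagomir_overrides.items():
                if value < 0:
                    raise ModelError(f"override for {key} must be non-negative")
                doses[("A1", "A2", "A3").index(key)] = float(value)
        return doses

    def impulses(self) -> list[tuple[float, np.ndarray]]:
        """List of (time, per-channel amount) impulses."""
        if self.kind == "bolus":
            return [(self.window_start, self.channel_doses())]
        if self.kind == "multidose":
            n = self.n_injections
            span = self.window_end - self.window_start
            amount = self.channel_doses() / n
            return [(self.window_start + j * span / n, amount.copy())
                    for j in range(n)]
        return []

    def clamp_levels(self) -> np.ndarray | None:
        """Infusion clamp levels, or None for non-infusion kinds."""
        if self.kind == "infusion":
            return self.channel_doses()
        return None

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "dose": self.dose,
            "n_injections": self.n_injections,
            "window": [self.window_start, self.window_end],
        }
        if self.per_antagomir_overrides:
            d["per_antagomir_overrides"] = dict(self.per_antagomir_overrides)
        return d


def build_protocol(
    kind: str,
    dose: float = 0.0,
    n_injections: int = 1,
    window: tuple[float, float] = (-24.0, 0.0),
    per_antagomir_overrides: dict[str, float] | None = None,
) -> DosingProtocol:
    """Construct a validated :class:`DosingProtocol`."""
    return DosingProtocol(
        kind=kind,
        dose=dose,
        n_injections=n_injections,
        window_start=float(window[0]),
        window_end=float(window[1]),
        per_antagomir_overrides=per_antagomir_overrides,
    )


@dataclasses.dataclass
class Trajectory:
    """Time grid, states, impulse events and optional phenotype labels."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 8)
    events: list[tuple[float, str, float]] = dataclasses.field(default_factory=list)
    labels: list[str] | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ModelError("trajectory times must be strictly increasing")
        if self.states.shape != (self.times.size, N_STATE):
            raise ModelError("states shape does not match times")
        for t_ev, _, _ in self.events:
            if not (self.times[0] - 1e-9 <= t_ev <= self.times[-1] + 1e-9):
                raise ModelError("event time outside trajectory span")

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def at_time(self, t: float) -> np.ndarray:
        """State at grid time t (exact match within 1e-9)."""
        idx = np.argmin(np.abs(self.times - t))
        if abs(self.times[idx] - t) > 1e-9:
            raise ModelError(f"time {t} is not on the trajectory grid")
        return self.states[idx]

    def window_slice(self, t_lo: float, t_hi: float) -> np.ndarray:
        sel = (self.times >= t_lo - 1e-9) & (self.times <= t_hi + 1e-9)
        return sel

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "t", self.times)
        df["phenotype"] = self.labels if self.labels is not None else ""
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_json(self, path) -> None:
        payload = {
            "metadata": self.metadata,
            "events": [[t, ch, amt] for t, ch, amt in self.events],
            "times": self.times.tolist(),
            "states": self.states.tolist(),
            "labels": self.labels,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def antagomir_closed_form(dose: float, mu: float, t0: float, t) -> np.ndarray | float:
    """Analytic antagomir level dose * exp(-mu (t - t0)) for t >= t0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < t0):
        raise ModelError("antagomir_closed_form requires t >= t0")
    out = dose * np.exp(-mu * (t_arr - t0))
    return out if out.ndim else float(out)


def antagomir_superposition(
    events: Sequence[tuple[float, float]], mu: float, t
) -> np.ndarray | float:
    """Superposition of impulse responses for one antagomir channel.

    ``events`` is a sequence of (time, amount); contributions from impulses
    after t are zero.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t_arr)
    for t0, amount in events:
        active = t_arr >= t0 - 1e-12
        out[active] += amount * np.exp(-mu * (t_arr[active] - t0))
    return out if np.ndim(t) else float(out[0])


def _default_grid(t_start: float, t_end: float, dt: float = 0.1) -> np.ndarray:
    n = int(round((t_end - t_start) / dt))
    return t_start + dt * np.arange(n + 1)


def _clean_positive(y: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    if not np.all(np.isfinite(y)):
        raise IntegrationError("non-finite state produced", interval)
    if np.any(y < -1e-7):
        raise IntegrationError("state became significantly negative", interval)
    return np.clip(y, 0.0, None)


def simulate_protocol(
    params: ModelParameters,
    protocol: DosingProtocol,
    t_end: float = 24.0,
    grid: np.ndarray | None = None,
    mask: MirnaMask = FULL_MASK,
    init: np.ndarray | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float = 0.1,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the dosing protocol from the window start to ``t_end``.

    The state is initialized at the anti-seizure baseline (all components
    1.0 FC) with the antagomir channels set by the protocol.  Integration is
    piecewise between event times (impulses, SE induction at t = 0, and the
    infusion-window end); grid points that coincide with an impulse record
    the post-impulse state.
    """
    if t_end < protocol.window_end:
        raise ModelError("t_end must be >= protocol window_end")
    t_start = protocol.window_start
    if grid is None:
        grid = _default_grid(t_start, t_end)
    grid = np.asarray(grid, dtype=float)
    if grid[0] < t_start - 1e-9 or grid[-1] > t_end + 1e-9:
        raise ModelError("grid must lie within [window_start, t_end]")

    y = state_array().copy() if init is None else np.array(init, dtype=float)
    if np.any(y < 0):
        raise ModelError("initial state must be non-negative")

    impulse_map: dict[float, np.ndarray] = {}
    for t_imp, amount in protocol.impulses():
        impulse_map[t_imp] = impulse_map.get(t_imp, 0.0) + amount

    clamp = protocol.clamp_levels()

    breaks = {t_start, t_end}
    breaks.update(impulse_map)
    if t_start < 0.0 < t_end:
        breaks.add(0.0)
    if clamp is not None and protocol.window_end < t_end:
        breaks.add(protocol.window_end)
    break_times = sorted(breaks)

    def rhs_free(t, yy):
        return rhs_dimensionless(t, yy, params, mask, check=False)

    def rhs_clamped(t, yy):
        d = rhs_dimensionless(t, yy, params, mask, check=False)
        d[IDX_A] = 0.0
        return d

    events: list[tuple[float, str, float]] = []
    times_out: list[float] = []
    states_out: list[np.ndarray] = []

    if clamp is not None:
        y[IDX_A] = clamp
        for ch, level in zip(("A1", "A2", "A3"), clamp):
            events.append((t_start, ch, float(level)))

    for seg_idx in range(len(break_times) - 1):
        t0, t1 = break_times[seg_idx], break_times[seg_idx + 1]
        if t0 in impulse_map:
            amount = impulse_map[t0]
            y = y.copy()
            y[IDX_A] += amount
            for ch, amt in zip(("A1", "A2", "A3"), amount):
                if amt > 0:
                    events.append((t0, ch, float(amt)))
        in_clamp = clamp is not None and t0 >= t_start - 1e-12 and t1 <= protocol.window_end + 1e-12
        rhs = rhs_clamped if in_clamp else rhs_free

        last = seg_idx == len(break_times) - 2
        if last:
            sel = (grid >= t0 - 1e-9)
        else:
            sel = (grid >= t0 - 1e-9) & (grid < t1 - 1e-9)
        t_eval = grid[sel]

        # record boundary grid points directly (post-impulse value)
        record_now = t_eval.size and abs(t_eval[0] - t0) < 1e-9
        if record_now:
            times_out.append(t0)
            states_out.append(y.copy())
            t_eval = t_eval[1:]

        interior = t_eval[t_eval < t1 - 1e-12]
        want_t1 = t_eval.size and abs(t_eval[-1] - t1) < 1e-9
        t_eval_solver = np.append(interior, t1)

        sol = solve_ivp(
            rhs, (t0, t1), y, method=method, t_eval=t_eval_solver,
            rtol=rtol, atol=atol, max_step=max_step,
        )
        if not sol.success:
            raise IntegrationError(f"integrator failed: {sol.message}", (t0, t1))
        ys = _clean_positive(sol.y.T, (t0, t1))
        for ti, yi in zip(sol.t[:-1], ys[:-1]):
            times_out.append(ti)
            states_out.append(yi)
        y = ys[-1]
        if want_t1 or last:
            # boundary point belongs to the next segment unless final
            if last and want_t1:
                times_out.append(t1)
                states_out.append(y.copy())

    traj = Trajectory(
        times=np.array(times_out),
        states=np.vstack(states_out),
        events=events,
        metadata={
            "protocol": protocol.to_dict(),
            "mask": [mask.include_R1, mask.include_R2, mask.include_R3],
            "integrator": {"method": method, "rtol": rtol, "atol": atol,
                           "max_step": max_step},
        },
    )
    return traj


# ---------------------------------------------------------------------------
# Fast vectorized evaluation used by the sensitivity and fitting stages
# ---------------------------------------------------------------------------

def _protocol_antagomir(protocol: DosingProtocol, mu_A: np.ndarray, t: float) -> np.ndarray:
    """Analytic antagomir levels under the protocol at scalar time t.

    ``mu_A`` has shape (..., 3); the result broadcasts to the same shape.
    The antagomir equations are linear and decoupled, so bolus/multidose
    levels are impulse-response superpositions and infusion levels are the
    clamp value inside the window followed by free decay.
    """
    mu_A = np.asarray(mu_A, dtype=float)
    out = np.zeros(np.broadcast_shapes(mu_A.shape, (3,)))
    clamp = protocol.clamp_levels()
    if clamp is not None:
        if t <= protocol.window_end + 1e-12:
            out = out + clamp
        else:
            out = out + clamp * np.exp(-mu_A * (t - protocol.window_end))
        return out
    for t_imp, amount in protocol.impulses():
        if t >= t_imp - 1e-12:
            out = out + amount * np.exp(-mu_A * (t - t_imp))
    return out


def simulate_species_batch(
    params: ModelParameters,
    overrides: dict[str, np.ndarray],
    protocol: DosingProtocol,
    eval_times: Sequence[float],
    mask: MirnaMask = FULL_MASK,
    *,
    init: np.ndarray | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> np.ndarray:
    """Integrate many parameter variants of the same protocol at once.

    ``overrides`` maps ModelParameters field names to arrays of length B;
    every other field is held at its ``params`` value.  The antagomir
    channels are evaluated analytically (they are linear and autonomous), so
    only the (R1, R2, R3, T, S) sub-system of each variant is integrated,
    stacked into a single ODE system.  Returns an array of shape
    (B, len(eval_times), 5) with species ordered (R1, R2, R3, T, S).

    This is the hot path behind the eFAST model evaluations and the
    least-squares objective; accuracy is controlled by ``rtol``/``atol``
    (defaults slightly looser than the reference trajectory integrator).
    """
    field_names = ModelParameters.field_names()
    for name in overrides:
        if name not in field_names:
            raise ModelError(f"unknown parameter override {name!r}")
    sizes = {np.asarray(v).size for v in overrides.values()}
    if len(sizes) > 1:
        raise ModelError("override arrays must share a common length")
    B = sizes.pop() if sizes else 1

    def col(name: str) -> np.ndarray:
        if name in overrides:
            return np.asarray(overrides[name], dtype=float).reshape(B)
        return np.full(B, float(getattr(params, name)))

    inc = mask.flags()  # (3,)
    lam_R = np.stack([col("lam_R1"), col("lam_R2"), col("lam_R3")], axis=1) * inc
    tau = np.stack([col("k1"), col("k3"), col("k5")], axis=1)
    k_even2 = np.stack([col("k2"), col("k4"), col("k6")], axis=1) ** 2
    ab = np.stack([col("alpha"), col("beta"), col("gamma")], axis=1)
    mu_R = np.stack([col("mu_R1"), col("mu_R2"), col("mu_R3")], axis=1)
    mu_A = np.stack([col("mu_A1"), col("mu_A2"), col("mu_A3")], axis=1)
    tS = np.stack([col("delta"), col("eps"), col("zeta")], axis=1) * inc
    sS = np.stack([col("eta"), col("theta"), col("kappa")], axis=1) * inc
    lam_T = col("lam_T")
    lam_S = col("lam_S")
    k7 = col("k7")
    k8_2 = col("k8") ** 2
    k9 = col("k9")
    k10_2 = col("k10") ** 2
    lam = col("lam")
    mu_T = col("mu_T")
    mu_S = col("mu_S")
    se_mult = col("se_source_multiplier")

    if init is None:
        y0_row = np.array([1.0, 1.0, 1.0, 1.0, 1.0]) * np.append(inc, [1.0, 1.0])
        y0 = np.tile(y0_row, (B, 1))
    else:
        init = np.asarray(init, dtype=float)
        y0 = np.tile(init[3:], (B, 1)) if init.size == N_STATE else np.tile(init, (B, 1))

    def rhs(t: float, y_flat: np.ndarray) -> np.ndarray:
        y = y_flat.reshape(B, 5)
        r = y[:, :3]
        T = y[:, 3]
        S = y[:, 4]
        a = _protocol_antagomir(protocol, mu_A, t)
        m = np.where(t >= 0.0, se_mult, 1.0)
        dR = (lam_R * m[:, None]
              + tau * k_even2 / (k_even2 + ab * a * a)
              - mu_R * r) * inc
        r2 = r * r
        gT = np.sum(tS * r2, axis=1)
        gS = np.sum(sS * r2, axis=1)
        dT = lam_T + k7 * k8_2 / (k8_2 + gT) - mu_T * T
        dS = lam_S + lam * T + k9 * k10_2 / (k10_2 + gS) - mu_S * S
        out = np.empty_like(y)
        out[:, :3] = dR
        out[:, 3] = dT
        out[:, 4] = dS
        return out.ravel()

    eval_times = np.asarray(eval_times, dtype=float)
    t_start = protocol.window_start
    breaks = {t_start, float(eval_times[-1])}
    breaks.update(t for t, _ in protocol.impulses())
    if t_start < 0.0 < eval_times[-1]:
        breaks.add(0.0)
    if protocol.clamp_levels() is not None and protocol.window_end < eval_times[-1]:
        breaks.add(protocol.window_end)
    break_times = sorted(breaks)

    results = np.empty((B, eval_times.size, 5))
    y = y0.ravel()
    for t0, t1 in zip(break_times[:-1], break_times[1:]):
        sel = (eval_times > t0 + 1e-12) & (eval_times < t1 - 1e-12)
        t_eval = np.append(eval_times[sel], t1)
        sol = solve_ivp(rhs, (t0, t1), y, method="RK45", t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(f"batch integrator failed: {sol.message}", (t0, t1))
        for j_local, te in enumerate(sol.t):
            hits = np.isclose(eval_times, te, atol=1e-9)
            if np.any(hits):
                results[:, np.argmax(hits), :] = sol.y[:, j_local].reshape(B, 5)
        y = sol.y[:, -1]
    # eval time exactly at a break start (e.g. t = window_start)
    for j, te in enumerate(eval_times):
        if np.isclose(te, t_start, atol=1e-9):
            results[:, j, :] = y0
    if not np.all(np.isfinite(results)):
        raise IntegrationError("batch produced non-finite outputs",
                               (break_times[0], break_times[-1]))
    return results
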