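"""Equilibria, stability, nullclines and phase-plane fields.

At a constant antagomir level (treated as an externally clamped input — the
natural reading for infusion conditions; the scrambled-control case is
A = 0) the system has a unique equilibrium given by an explicit cascade:
each miRNA settles where its source plus inhibited autocatalysis balances
decay, TGF-beta settles against the joint miRNA pressure, and SMAD follows
both its own repression and the TGF-beta activation term.

The Jacobian of the full 8-state system is block lower-triangular under the
(A1, A2, A3, R1, R2, R3, T, S) ordering, so its eigenvalues are exactly the
negated decay rates — every equilibrium of a valid parameter set is a
stable node.  Nullclines for the 2-D (miRNA, T) and (miRNA, S) projections
are explicit curves with the six background variables frozen.
"""

from __future__ import annotations

import dataclasses

import numpy as np

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
)

__all__ = [
    "EquilibriumPoint",
    "NullclineSet",
    "steady_state",
    "jacobian",
    "nullclines_2d",
    "vector_field_2d",
]

_STABILITY_TOL = -1e-12


@dataclasses.dataclass
class EquilibriumPoint:
    """An equilibrium state with its local stability classification."""

    state: np.ndarray
    eigenvalues: np.ndarray
    classification: str  # "stable_node" or "other"
    residual: float


@dataclasses.dataclass
class NullclineSet:
    """Sampled nullclines for one 2-D projection.

    ``curve_pathway`` samples the T- (or S-) nullcline as (miRNA value,
    pathway value) pairs; ``curve_mirna`` is the vertical miRNA nullcline
    at its clamped-antagomir equilibrium.  ``background`` holds the six
    frozen variables.
    """

    pair: tuple[str, str]
    curve_pathway: np.ndarray  # shape (n, 2)
    curve_mirna: np.ndarray    # shape (n, 2)
    background: np.ndarray
    intersection: tuple[float, float]


def _mirna_steady(
    params: ModelParameters, A_const: np.ndarray, mask: MirnaMask, m: float
) -> np.ndarray:
    lam_R = params.mirna_sources()
    tau, k_even = params.mirna_autocat()
    ab = params.antagomir_strengths()
    mu_R = np.array([params.mu_R1, params.mu_R2, params.mu_R3])
    k_even2 = k_even * k_even
    r = (lam_R * m + tau * k_even2 / (k_even2 + ab * A_const * A_const)) / mu_R
    return r * mask.flags()


def steady_state(
    params: ModelParameters,
    A_const: np.ndarray | float = 0.0,
    mask: MirnaMask = FULL_MASK,
    *,
    se_phase: bool = False,
) -> EquilibriumPoint:
    """Closed-form equilibrium for a constant (clamped) antagomir level.

    ``se_phase`` selects whether the miRNA sources carry the SE multiplier
    (chronic phase) or not (control phase).  The residual is the maximum
    absolute derivative of the non-antagomir components at the returned
    state; classification follows the Jacobian eigenvalues.
    """
    A_const = np.broadcast_to(np.asarray(A_const, dtype=float), (3,)).copy()
    if np.any(A_const < 0):
        raise ModelError("antagomir levels must be non-negative")
    m = params.se_source_multiplier if se_phase else 1.0

    r = _mirna_steady(params, A_const, mask, m)
    inc = mask.flags()
    r2 = r * r * inc
    gT = float(np.dot(params.t_strengths(), r2))
    gS = float(np.dot(params.s_strengths(), r2))
    k8_2 = params.k8 ** 2
    k10_2 = params.k10 ** 2
    T = (params.lam_T + params.k7 * k8_2 / (k8_2 + gT)) / params.mu_T
    S = (params.lam_S + params.lam * T
         + params.k9 * k10_2 / (k10_2 + gS)) / params.mu_S

    state = np.empty(N_STATE)
    state[IDX_A] = A_const
    state[IDX_R] = r
    state[IDX_T] = T
    state[IDX_S] = S

    t_eval = 1.0 if se_phase else -1.0
    deriv = rhs_dimensionless(t_eval, state, params, mask)
    residual = float(np.max(np.abs(deriv[3:])))

    J = jacobian(params, state, mask)
    eigvals = np.linalg.eigvals(J)
    stable = (np.all(eigvals.real < _STABILITY_TOL)
              and np.all(np.abs(eigvals.imag) < 1e-12))
    return EquilibriumPoint(
        state=state,
        eigenvalues=eigvals,
        classification="stable_node" if stable else "other",
        residual=residual,
    )


def jacobian(
    params: ModelParameters, state: np.ndarray, mask: MirnaMask = FULL_MASK
) -> np.ndarray:
    """Analytic 8x8 Jacobian of the dimensionless right-hand side."""
    y = np.asarray(state, dtype=float)
    a = y[IDX_A]
    r = y[IDX_R]
    inc = mask.flags()

    J = np.zeros((N_STATE, N_STATE))
    mu_A = np.array([params.mu_A1, params.mu_A2, params.mu_A3])
    mu_R = np.array([params.mu_R1, params.mu_R2, params.mu_R3])
    tau, k_even = params.mirna_autocat()
    ab = params.antagomir_strengths()
    k_even2 = k_even * k_even

    # antagomir rows
    J[0, 0], J[1, 1], J[2, 2] = -mu_A

    # miRNA rows: d(dR_i)/dA_i and the decay diagonal
    denom = (k_even2 + ab * a * a) ** 2
    dR_dA = -tau * k_even2 * 2.0 * ab * a / denom * inc
    for i in range(3):
        J[3 + i, i] = dR_dA[i]
        J[3 + i, 3 + i] = -mu_R[i] * inc[i]
        if not inc[i]:
            J[3 + i, 3 + i] = 0.0

    # T row
    tS = params.t_strengths() * inc
    r2 = r * r * inc
    gT = float(np.dot(params.t_strengths(), r2))
    k8_2 = params.k8 ** 2
    for i in range(3):
        J[IDX_T, 3 + i] = -params.k7 * k8_2 * 2.0 * tS[i] * r[i] / (k8_2 + gT) ** 2
    J[IDX_T, IDX_T] = -params.mu_T

    # S row
    sS = params.s_strengths() * inc
    gS = float(np.dot(params.s_strengths(), r2))
    k10_2 = params.k10 ** 2
    for i in range(3):
        J[IDX_S, 3 + i] = -params.k9 * k10_2 * 2.0 * sS[i] * r[i] / (k10_2 + gS) ** 2
    J[IDX_S, IDX_T] = params.lam
    J[IDX_S, IDX_S] = -params.mu_S
    return J


_PAIR_MIRNAS = ("R1", "R2", "R3")
_PAIR_PATHWAYS = ("T", "S")


def _pathway_curve(
    params: ModelParameters,
    mirna: str,
    pathway: str,
    background: np.ndarray,
    r_values: np.ndarray,
    mask: MirnaMask,
) -> np.ndarray:
    """Explicit pathway nullcline value as a function of the miRNA level."""
    i = _PAIR_MIRNAS.index(mirna)
    inc = mask.flags()
    r_bg = np.asarray(background[IDX_R], dtype=float).copy()
    out = np.empty_like(r_values)
    for j, rv in enumerate(r_values):
        r = r_bg.copy()
        r[i] = rv
        r2 = r * r * inc
        if pathway == "T":
            gT = float(np.dot(params.t_strengths(), r2))
            k8_2 = params.k8 ** 2
            out[j] = (params.lam_T + params.k7 * k8_2 / (k8_2 + gT)) / params.mu_T
        else:
            gS = float(np.dot(params.s_strengths(), r2))
            k10_2 = params.k10 ** 2
            T_bg = background[IDX_T]
            out[j] = (params.lam_S + params.lam * T_bg
                      + params.k9 * k10_2 / (k10_2 + gS)) / params.mu_S
    return out


def nullclines_2d(
    params: ModelParameters,
    pair: tuple[str, str],
    background: np.ndarray,
    ranges: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 3.0), (0.0, 3.0)),
    n_samples: int = 200,
    mask: MirnaMask = FULL_MASK,
    *,
    se_phase: bool = False,
) -> NullclineSet:
    """Sample both nullclines of a (miRNA, pathway) projection.

    The pathway nullcline is the explicit balance curve of T (or S) as a
    function of the chosen miRNA with the other variables frozen at the
    background; the miRNA nullcline is the vertical line at the miRNA's
    clamped-antagomir equilibrium value.  Their intersection coincides with
    the projected closed-form equilibrium for the same background.
    """
    mirna, pathway = pair
    if mirna not in _PAIR_MIRNAS or pathway not in _PAIR_PATHWAYS:
        raise ModelError(f"invalid projection pair {pair!r}")
    if n_samples < 2:
        raise ModelError("n_samples must be >= 2")
    (r_lo, r_hi), (p_lo, p_hi) = ranges
    if r_hi <= r_lo or p_hi <= p_lo or r_lo < 0 or p_lo < 0:
        raise ModelError("ranges must be positive and within the non-negative quadrant")

    background = np.asarray(background, dtype=float)
    i = _PAIR_MIRNAS.index(mirna)
    m = params.se_source_multiplier if se_phase else 1.0

    r_values = np.linspace(r_lo, r_hi, n_samples)
    p_values = _pathway_curve(params, mirna, pathway, background, r_values, mask)
    curve_pathway = np.column_stack([r_values, p_values])

    r_star = _mirna_steady(params, background[IDX_A], mask, m)[i]
    p_line = np.linspace(p_lo, p_hi, n_samples)
    curve_mirna = np.column_stack([np.full(n_samples, r_star), p_line])

    p_at_rstar = _pathway_curve(
        params, mirna, pathway, background, np.array([r_star]), mask
    )[0]
    return NullclineSet(
        pair=(mirna, pathway),
        curve_pathway=curve_pathway,
        curve_mirna=curve_mirna,
        background=background,
        intersection=(float(r_star), float(p_at_rstar)),
    )


def vector_field_2d(
    params: ModelParameters,
    pair: tuple[str, str],
    background: np.ndarray,
    grid_mirna: np.ndarray,
    grid_pathway: np.ndarray,
    mask: MirnaMask = FULL_MASK,
    *,
    se_phase: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (d miRNA/dt, d pathway/dt) on a grid, background frozen."""
    mirna, pathway = pair
    if mirna not in _PAIR_MIRNAS or pathway not in _PAIR_PATHWAYS:
        raise ModelError(f"invalid projection pair {pair!r}")
    if np.any(np.asarray(grid_mirna) < 0) or np.any(np.asarray(grid_pathway) < 0):
        raise ModelError("grid must lie in the non-negative quadrant")
    background = np.asarray(background, dtype=float)
    i_m = STATE_NAMES.index(mirna)
    i_p = STATE_NAMES.index(pathway)
    t_eval = 1.0 if se_phase else -1.0

    U = np.empty((len(grid_pathway), len(grid_mirna)))
    V = np.empty_like(U)
    for jj, pv in enumerate(grid_pathway):
        for ii, rv in enumerate(grid_mirna):
            y = background.copy()
            y[i_m] = rv
            y[i_p] = pv
            d = rhs_dimensionless(t_eval, y, params, mask)
            U[jj, ii] = d[i_m]
            V[jj, ii] = d[i_p]
    return U, V
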