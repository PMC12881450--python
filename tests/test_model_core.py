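"""Governing equations, inhibition terms, scale map and structural variants."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mirtgf import model_core as mc
from mirtgf.dynamics import steady_state
from mirtgf.model_core import (
    FULL_MASK,
    MirnaMask,
    ModelError,
    inhibition_terms,
    model_variant,
    nondimensionalize,
    rhs_dimensional,
    rhs_dimensionless,
    state_array,
)

from conftest import random_dimensional_parameters, random_model_parameters


class TestInhibitionTerms:
    @pytest.mark.parametrize(
        "state, expected",
        [
            (state_array(A1=0.0), (0.0, 0.0, 0.0, 3.0, 3.0)),
            (state_array(A1=1, A2=1, A3=1), (1.0, 1.0, 1.0, 3.0, 3.0)),
            (state_array(R1=2, R2=0, R3=0), (0.0, 0.0, 0.0, 4.0, 4.0)),
        ],
    )
    def test_examples(self, state, expected):
        assert inhibition_terms(state) == pytest.approx(expected)

    def test_negative_state_rejected(self):
        bad = state_array()
        bad[0] = -0.1
        with pytest.raises(ModelError):
            inhibition_terms(bad)

    def test_monotone_in_every_argument(self):
        """G terms strictly increase in each concentration they depend on."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = rng.uniform(0.1, 3.0, 8)
            g = inhibition_terms(y)
            for i, g_idx in [(0, 0), (1, 1), (2, 2), (3, 3), (4, 3), (5, 3)]:
                y_up = y.copy()
                y_up[i] += 0.1
                g_up = inhibition_terms(y_up)
                assert g_up[g_idx] > g[g_idx]


class TestRhsDimensionless:
    def test_zero_at_closed_form_equilibrium(self, params):
        eq = steady_state(params, A_const=0.0)
        d = rhs_dimensionless(-1.0, eq.state, params)
        assert np.max(np.abs(d)) < 1e-12

    def test_antagomir_is_pure_decay(self, params):
        y = state_array(A1=1.0, A2=0.3, A3=2.0, R1=0.7, T=2.0)
        d = rhs_dimensionless(5.0, y, params)
        assert d[0] == pytest.approx(-params.mu_A1 * 1.0)
        assert d[1] == pytest.approx(-params.mu_A2 * 0.3)
        assert d[2] == pytest.approx(-params.mu_A3 * 2.0)

    def test_zero_inhibition_strength_saturates_autocatalysis(self, params):
        p = params.replace(alpha=0.0)
        y = state_array(A1=5.0, R1=2.0)
        d = rhs_dimensionless(-1.0, y, p)
        expected = p.lam_R1 + p.k1 - p.mu_R1 * 2.0
        assert d[3] == pytest.approx(expected)

    def test_se_multiplier_steps_at_zero(self, params):
        y = state_array()
        before = rhs_dimensionless(-0.01, y, params)
        after = rhs_dimensionless(0.0, y, params)
        m = params.se_source_multiplier
        assert after[3] - before[3] == pytest.approx(params.lam_R1 * (m - 1))

    def test_masked_branch_frozen(self, params):
        mask = MirnaMask(include_R1=True, include_R2=False, include_R3=True)
        y = state_array(R2=0.8)
        d = rhs_dimensionless(-1.0, y, params, mask)
        assert d[4] == 0.0

    def test_nonfinite_state_rejected(self, params):
        y = state_array()
        y[6] = np.nan
        with pytest.raises(ModelError):
            rhs_dimensionless(0.0, y, params)


class TestNondimensionalize:
    def test_unit_scales_are_identity_on_values(self):
        rng = np.random.default_rng(1)
        dp = random_dimensional_parameters(rng)
        dp = dataclasses.replace(dp, A1s=1, A2s=1, A3s=1, R1s=1, R2s=1,
                                 R3s=1, Ts=1, Ss=1)
        p = nondimensionalize(dp)
        assert p.k1 == pytest.approx(dp.tau1)
        assert p.alpha == pytest.approx(dp.ups1)
        assert p.lam_R1 == pytest.approx(dp.f_miR21)
        assert p.lam == pytest.approx(dp.lambda_TGFb)
        assert p.mu_T == pytest.approx(dp.mu_TGFb)

    def test_inhibition_strength_absorbs_squared_scale(self):
        rng = np.random.default_rng(2)
        dp = dataclasses.replace(random_dimensional_parameters(rng),
                                 A1s=2.0, ups1=0.5)
        assert nondimensionalize(dp).alpha == pytest.approx(2.0)

    def test_rhs_equivalence_on_random_states(self):
        """The scale map converts the dimensional RHS into the
        dimensionless one exactly: dY/dt = (dYbar/dt)/Y* on 100 states."""
        rng = np.random.default_rng(3)
        dp = random_dimensional_parameters(rng)
        p = nondimensionalize(dp)
        scales = np.array([dp.A1s, dp.A2s, dp.A3s, dp.R1s, dp.R2s, dp.R3s,
                           dp.Ts, dp.Ss])
        for _ in range(100):
            y = rng.uniform(0.0, 3.0, 8)
            d_dimless = rhs_dimensionless(-1.0, y, p)
            d_dim = rhs_dimensional(-1.0, y * scales, dp)
            np.testing.assert_allclose(d_dimless, d_dim / scales,
                                       rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_trajectory_equivalence(self, seed):
        """Integrating either system and rescaling gives the same path."""
        rng = np.random.default_rng(100 + seed)
        dp = random_dimensional_parameters(rng)
        p = nondimensionalize(dp)
        scales = np.array([dp.A1s, dp.A2s, dp.A3s, dp.R1s, dp.R2s, dp.R3s,
                           dp.Ts, dp.Ss])
        y0 = rng.uniform(0.1, 2.0, 8)
        t_eval = np.linspace(0.0, 30.0, 7)
        kw = dict(method="LSODA", rtol=1e-10, atol=1e-12, t_eval=t_eval)
        sol_dimless = solve_ivp(
            lambda t, y: rhs_dimensionless(t, y, p), (0, 30), y0, **kw)
        sol_dim = solve_ivp(
            lambda t, y: rhs_dimensional(t, y, dp), (0, 30), y0 * scales, **kw)
        np.testing.assert_allclose(sol_dimless.y, sol_dim.y / scales[:, None],
                                   rtol=1e-6, atol=1e-8)

    def test_nonpositive_scale_rejected(self):
        rng = np.random.default_rng(4)
        dp = random_dimensional_parameters(rng)
        with pytest.raises(ModelError):
            dataclasses.replace(dp, Ts=0.0)


class TestModelVariant:
    def test_full_mask_identity(self, params):
        assert model_variant(params, FULL_MASK) == params

    def test_single_mirna_mask_zeroes_other_branches(self, params):
        p = model_variant(params, MirnaMask(True, False, False))
        assert p.eps == p.zeta == p.theta == p.kappa == 0.0
        assert p.lam_R2 == p.lam_R3 == 0.0
        assert p.delta == params.delta and p.eta == params.eta
        assert p.lam_R1 == params.lam_R1

    @pytest.mark.parametrize("pair_mask, single_masks", [
        (MirnaMask(True, True, False),
         [MirnaMask(True, False, False), MirnaMask(False, True, False)]),
        (MirnaMask(True, False, True),
         [MirnaMask(True, False, False), MirnaMask(False, False, True)]),
        (MirnaMask(False, True, True),
         [MirnaMask(False, True, False), MirnaMask(False, False, True)]),
    ])
    def test_pairwise_suppression_below_both_singles(self, params, pair_mask,
                                                     single_masks):
        """Two miRNAs jointly repress T and S more than either alone."""
        pair_eq = steady_state(model_variant(params, pair_mask), 0.0, pair_mask)
        for sm in single_masks:
            single_eq = steady_state(model_variant(params, sm), 0.0, sm)
            assert pair_eq.state[6] < single_eq.state[6]
            assert pair_eq.state[7] < single_eq.state[7]


class TestInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_positivity_and_boundedness(self, seed):
        """Non-negative initial states stay non-negative and bounded."""
        rng = np.random.default_rng(seed)
        p = random_model_parameters(rng)
        y0 = rng.uniform(0.0, 3.0, 8)
        sol = solve_ivp(lambda t, y: rhs_dimensionless(t, y, p, check=False),
                        (-24, 24), y0, method="LSODA", rtol=1e-8, atol=1e-10)
        assert sol.success
        assert sol.y.min() > -1e-8
        m = p.se_source_multiplier
        src = np.array([p.lam_R1 * m + p.k1, p.lam_R2 * m + p.k3,
                        p.lam_R3 * m + p.k5])
        mu_R = np.array([p.mu_R1, p.mu_R2, p.mu_R3])
        r_bound = src / mu_R
        t_bound = (p.lam_T + p.k7) / p.mu_T
        s_bound = (p.lam_S + p.k9 + p.lam * t_bound) / p.mu_S
        bound = np.concatenate([y0[:3], r_bound, [t_bound, s_bound]])
        assert np.all(sol.y.max(axis=1) <= 10 * np.maximum(bound, y0) + 1e-9)

    def test_steady_state_monotone_in_antagomir_and_strengths(self, params):
        """R* is non-increasing in the clamped antagomir level; T* and S*
        are non-increasing in their inhibition strengths."""
        a_grid = np.linspace(0.0, 3.0, 13)
        r1_values = [steady_state(params, A_const=(a, 0, 0)).state[3]
                     for a in a_grid]
        assert np.all(np.diff(r1_values) <= 1e-12)
        for field, idx in [("delta", 6), ("eps", 6), ("zeta", 6),
                           ("eta", 7), ("theta", 7), ("kappa", 7)]:
            values = [
                steady_state(params.replace(**{field: v}), 0.0).state[idx]
                for v in np.linspace(0.0, 10.0, 9)
            ]
            assert np.all(np.diff(values) <= 1e-12)
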