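"""Dosing protocols: event semantics, closed forms, clamp behavior."""

import numpy as np
import pytest

from mirtgf.dynamics import steady_state
from mirtgf.model_core import IDX_A, ModelError, state_array
from mirtgf.protocols import (
    antagomir_closed_form,
    antagomir_superposition,
    build_protocol,
    simulate_protocol,
    simulate_species_batch,
)


class TestBuildProtocol:
    def test_bolus_single_event_at_window_start(self):
        proto = build_protocol("bolus", dose=1.0)
        impulses = proto.impulses()
        assert len(impulses) == 1
        t, amount = impulses[0]
        assert t == -24.0
        np.testing.assert_allclose(amount, [1.0, 1.0, 1.0])

    def test_multidose_single_injection_degenerates_to_bolus(self):
        bolus = build_protocol("bolus", dose=1.0)
        multi = build_protocol("multidose", dose=1.0, n_injections=1)
        assert [(t, a.tolist()) for t, a in bolus.impulses()] == \
               [(t, a.tolist()) for t, a in multi.impulses()]

    def test_multidose_equal_division_at_equal_intervals(self):
        proto = build_protocol("multidose", dose=1.0, n_injections=4)
        impulses = proto.impulses()
        assert [t for t, _ in impulses] == [-24.0, -18.0, -12.0, -6.0]
        for _, amount in impulses:
            np.testing.assert_allclose(amount, 0.25)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ModelError):
            build_protocol("bolus", dose=-0.5)
        with pytest.raises(ModelError):
            build_protocol("control", dose=0.2)
        with pytest.raises(ModelError):
            build_protocol("multidose", dose=1.0, n_injections=0)

    def test_per_channel_overrides(self):
        proto = build_protocol("bolus", dose=1.0,
                               per_antagomir_overrides={"A2": 0.5})
        np.testing.assert_allclose(proto.channel_doses(), [1.0, 0.5, 1.0])


class TestClosedForm:
    def test_no_decay_is_constant(self):
        assert antagomir_closed_form(1.0, 0.0, -24.0, 10.0) == 1.0

    def test_half_life_identity(self):
        mu = 0.21
        assert antagomir_closed_form(1.0, mu, 0.0, np.log(2) / mu) == \
            pytest.approx(0.5)

    def test_time_before_start_rejected(self):
        with pytest.raises(ModelError):
            antagomir_closed_form(1.0, 0.1, 0.0, -1.0)

    def test_simulated_antagomir_matches_closed_form(self, params):
        proto = build_protocol("bolus", dose=1.0)
        traj = simulate_protocol(params, proto)
        expected = antagomir_closed_form(1.0, params.mu_A1, -24.0, traj.times)
        np.testing.assert_allclose(traj.column("A1"), expected, rtol=1e-7,
                                   atol=1e-10)

    def test_multidose_superposition_matches_integration(self, params):
        proto = build_protocol("multidose", dose=1.0, n_injections=4)
        traj = simulate_protocol(params, proto)
        events = [(t, a[0]) for t, a in proto.impulses()]
        expected = antagomir_superposition(events, params.mu_A1, traj.times)
        np.testing.assert_allclose(traj.column("A1"), expected, atol=1e-8)


class TestSimulateProtocol:
    def test_equilibrium_persists_under_control(self, params):
        p = params.replace(se_source_multiplier=1.0)
        eq = steady_state(p, A_const=0.0)
        traj = simulate_protocol(p, build_protocol("control"), init=eq.state)
        expected = np.tile(eq.state, (traj.times.size, 1))
        np.testing.assert_allclose(traj.states, expected, rtol=1e-7, atol=1e-9)

    def test_impulse_jumps_antagomir_only(self, params):
        """A jumps by exactly the impulse; R, T, S are continuous."""
        proto = build_protocol("multidose", dose=1.0, n_injections=4)
        dt = 1e-4
        grid = np.sort(np.concatenate([
            [-24.0, 24.0], [-18 - dt, -18.0, -12 - dt, -12.0]]))
        traj = simulate_protocol(params, proto, grid=grid)
        for t_imp in (-18.0, -12.0):
            i_pre = np.argmin(np.abs(traj.times - (t_imp - dt)))
            i_post = np.argmin(np.abs(traj.times - t_imp))
            jump = traj.states[i_post, :3] - traj.states[i_pre, :3]
            np.testing.assert_allclose(jump, 0.25, atol=1e-3)
            cont = traj.states[i_post, 3:] - traj.states[i_pre, 3:]
            assert np.max(np.abs(cont)) < 1e-3

    def test_infusion_clamps_then_releases(self, params):
        proto = build_protocol("infusion", dose=0.25)
        traj = simulate_protocol(params, proto)
        window = traj.times <= 0.0
        np.testing.assert_allclose(traj.states[window][:, :3], 0.25,
                                   atol=1e-9)
        after = traj.times > 0.0
        expected = 0.25 * np.exp(-params.mu_A1 * traj.times[after])
        np.testing.assert_allclose(traj.states[after][:, 0], expected,
                                   rtol=1e-6, atol=1e-10)

    def test_infusion_dominance_in_clamp_level(self, params):
        """Higher clamp level: pointwise lower miRNAs, higher T and S."""
        trajs = [simulate_protocol(params, build_protocol("infusion", dose=d))
                 for d in (0.1, 0.2, 0.4)]
        for lo, hi in zip(trajs, trajs[1:]):
            assert np.all(hi.column("R1") <= lo.column("R1") + 1e-9)
            assert np.all(hi.column("T") >= lo.column("T") - 1e-9)
            assert np.all(hi.column("S") >= lo.column("S") - 1e-9)

    def test_multidose_frequency_ladder_monotone_at_24h(self, params):
        """Fixed total dose: more, smaller injections give higher sustained
        T and S levels at the analysis time."""
        t24 = [simulate_protocol(
            params, build_protocol("multidose", dose=1.0, n_injections=n)
        ).at_time(24.0) for n in (1, 2, 4, 8)]
        T = [s[6] for s in t24]
        S = [s[7] for s in t24]
        assert np.all(np.diff(T) >= -1e-9)
        assert np.all(np.diff(S) >= -1e-9)

    def test_tolerance_halving_stability(self, params):
        proto = build_protocol("bolus", dose=1.0)
        a = simulate_protocol(params, proto, rtol=1e-8, atol=1e-10)
        b = simulate_protocol(params, proto, rtol=5e-9, atol=5e-11)
        rel = np.abs(a.states - b.states) / (np.abs(b.states) + 1e-12)
        assert rel.max() < 1e-6

    def test_sources_zero_bolus_decays_linearly(self, params):
        p = params.replace(lam_R1=0, lam_R2=0, lam_R3=0, lam_T=0, lam_S=0,
                           k1=0, k3=0, k5=0, k7=0, k9=0, lam=0,
                           se_source_multiplier=1.0)
        proto = build_protocol("bolus", dose=0.7)
        traj = simulate_protocol(p, proto, init=np.zeros(8))
        expected = 0.7 * np.exp(-p.mu_A2 * (traj.times + 24.0))
        np.testing.assert_allclose(traj.column("A2"), expected, rtol=1e-7,
                                   atol=1e-10)

    def test_t_end_before_window_end_rejected(self, params):
        with pytest.raises(ModelError):
            simulate_protocol(params, build_protocol("bolus", dose=1.0),
                              t_end=-30.0)


class TestBatchIntegrator:
    @pytest.mark.parametrize("kind, dose, n", [
        ("control", 0.0, 1), ("bolus", 1.0, 1),
        ("infusion", 0.25, 1), ("multidose", 1.0, 4),
    ])
    def test_batch_agrees_with_reference_integrator(self, params, kind, dose, n):
        proto = build_protocol(kind, dose=dose, n_injections=n)
        ref = simulate_protocol(params, proto)
        out = simulate_species_batch(params, {}, proto, [0.0, 24.0],
                                     rtol=1e-9, atol=1e-11)
        for ti, t in enumerate((0.0, 24.0)):
            np.testing.assert_allclose(out[0, ti], ref.at_time(t)[3:],
                                       rtol=2e-6, atol=1e-8)

    def test_batch_override_matches_scalar_replace(self, params):
        proto = build_protocol("bolus", dose=1.0)
        alphas = np.array([60.0, 120.0, 200.0])
        out = simulate_species_batch(params, {"alpha": alphas}, proto,
                                     [24.0], rtol=1e-9, atol=1e-11)
        for i, a in enumerate(alphas):
            ref = simulate_protocol(params.replace(alpha=float(a)), proto)
            np.testing.assert_allclose(out[i, 0], ref.at_time(24.0)[3:],
                                       rtol=2e-6, atol=1e-8)
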