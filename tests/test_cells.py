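"""Cell-model operations: gating kinetics, current balance, rebound."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbsloop import _kernels, cells, engine


def test_leak_current_linear_form():
    assert cells.leak_current(-70.0, 0.05, -70.0) == 0.0
    assert cells.leak_current(-30.0, 0.0, -70.0) == 0.0
    assert cells.leak_current(-60.0, 0.05, -70.0) == pytest.approx(0.5)


class TestGatingRate:
    def test_zero_at_steady_state(self, tc_params):
        spec = tc_params.gating["h"]
        v = -55.0
        x = spec.steady_state(v)
        assert cells.gating_rate(x, spec, v) == pytest.approx(0.0, abs=1e-15)

    def test_linear_relaxation_value(self):
        spec = cells.GatingSpec(lambda v: 1.0, lambda v: 2.0)
        assert cells.gating_rate(0.0, spec, -60.0) == pytest.approx(0.5)

    def test_instantaneous_gate_raises(self, tc_params):
        with pytest.raises(ValueError, match="instantaneous"):
            cells.gating_rate(0.5, tc_params.gating["m"], -60.0)

    def test_converges_to_steady_state_exponentially(self, tc_params):
        # fixed voltage: x(t) follows the closed-form exponential
        spec = tc_params.gating["r"]
        v = -75.0
        xinf, tau = spec.steady_state(v), spec.time_constant(v)
        for x0 in (0.0, 0.4, 1.0):
            traj = engine.integrate(
                lambda x: np.atleast_1d(cells.gating_rate(x[0], spec, v)),
                [x0], dt=0.1, duration=5 * tau,
            )
            expected = xinf + (x0 - xinf) * np.exp(-traj.t / tau)
            assert np.allclose(traj.y[:, 0], expected, atol=1e-6)
            assert traj.y.min() >= -1e-9 and traj.y.max() <= 1 + 1e-9


class TestStateBounds:
    """Gates stay in [0, 1] and Ca >= 0 under parameter perturbation."""

    @settings(max_examples=10, deadline=None)
    @given(scale=st.floats(0.9, 1.1), seed=st.integers(0, 10_000))
    def test_pallidal_gates_bounded(self, gpe_params, scale, seed):
        d = dict(gpe_params.raw)
        rng = np.random.default_rng(seed)
        for k in ("g_L", "g_Na", "g_K", "g_T", "g_Ca", "g_AHP"):
            d[k] *= scale * (0.95 + 0.1 * rng.random())
        pa = np.array([d[k] for k in _kernels._PAL_KEYS])
        n = int(500 / 0.01) + 1
        out = _kernels.simulate_pallidal(
            np.array([-60.0, 0.5, 0.3, 0.3, 0.1]), pa, np.zeros(n),
            np.full(n, rng.uniform(-1, 2)), 0.01,
        )
        gates = out[:, 1:4]
        assert gates.min() >= -1e-9 and gates.max() <= 1 + 1e-9
        assert out[:, 4].min() >= 0.0


class TestCurrentBalance:
    """dv/dt equals minus the summed currents over C_m."""

    def test_tc_full(self, tc_params):
        st_ = np.array([-63.0, 0.4, 0.2, 0.0])
        cur = cells.tc_full_currents(st_, tc_params, I_SM=1.3, I_GiTh=0.4)
        dv = cells.tc_full_derivatives(st_, tc_params, 1.3, 0.4)[0]
        assert dv == pytest.approx(-sum(cur.values()) / tc_params.C_m, rel=1e-12)

    def test_stn(self, stn_params):
        st_ = np.array([-58.0, 0.5, 0.3, 0.4, 0.2])
        cur = cells.pallidal_currents(st_, stn_params, I_syn=0.7, I_ext=0.2)
        dv = cells.stn_derivatives(st_, stn_params, 0.7, 0.2)[0]
        assert dv == pytest.approx(-sum(cur.values()) / stn_params.C_m, rel=1e-12)


class TestKernelConsistency:
    """Compiled right-hand sides match the reference implementations."""

    def test_tc(self, tc_params):
        pa = _kernels.tc_param_array(tc_params)
        rng = np.random.default_rng(0)
        for _ in range(20):
            st_ = np.array(
                [rng.uniform(-95, -20), rng.uniform(0, 1), rng.uniform(0, 1), 0.0]
            )
            ref = cells.tc_full_derivatives(st_, tc_params, 1.1, 0.3)[:3]
            ker = _kernels.tc_rhs(st_[0], st_[1], st_[2], pa, 1.1, 0.3)
            assert np.allclose(ref, ker, rtol=1e-12)

    @pytest.mark.parametrize("name", ["stn", "gpe", "gpi"])
    def test_pallidal(self, name):
        p = cells.load_cell_params(name)
        pa = _kernels.pallidal_param_array(p)
        rng = np.random.default_rng(1)
        for _ in range(20):
            st_ = np.array(
                [rng.uniform(-95, -20), *rng.uniform(0, 1, 3), rng.uniform(0, 300)]
            )
            ref = cells.gpe_derivatives(st_, p, 0.6, -0.4)
            ker = _kernels.pal_rhs(*st_, pa, 0.6, -0.4)
            assert np.allclose(ref, np.array(ker), rtol=1e-10)

    def test_reduced(self, reduced_params):
        pa = _kernels.reduced_param_array(reduced_params)
        rng = np.random.default_rng(2)
        for _ in range(20):
            st_ = np.array([rng.uniform(-90, -30), rng.uniform(0, 1)])
            ref = cells.reduced_tc_derivatives(st_, reduced_params, 0.4, 12.0)
            ker = _kernels.reduced_rhs(st_[0], st_[1], pa, 0.4, 12.0)
            assert np.allclose(ref, np.array(ker), rtol=1e-12)


class TestTCFullDynamics:
    def test_rest_is_fixed_point(self, tc_params, tc_rest):
        from scipy.optimize import fsolve

        root = fsolve(
            lambda x: cells.tc_full_derivatives(
                np.append(x, 0.0), tc_params, 0.0, 0.0
            )[:3],
            tc_rest,
        )
        rates = cells.tc_full_derivatives(np.append(root, 0.0), tc_params, 0.0, 0.0)
        assert np.max(np.abs(rates[:3])) < 1e-6

    def test_doubling_capacitance_halves_dvdt(self, tc_params):
        st_ = np.array([-60.0, 0.5, 0.2, 0.0])
        import dataclasses

        p2 = dataclasses.replace(tc_params, C_m=2 * tc_params.C_m)
        dv1 = cells.tc_full_derivatives(st_, tc_params, 2.0, 0.0)[0]
        dv2 = cells.tc_full_derivatives(st_, p2, 2.0, 0.0)[0]
        assert dv2 == pytest.approx(dv1 / 2, rel=1e-12)

    def test_rebound_requires_t_current(self, tc_params, tc_rest):
        """Release from 200 ms of hyperpolarization rebounds only with g_T > 0."""
        import dataclasses

        dt = 0.01
        n = int(400 / dt) + 1
        t = np.arange(n) * dt
        ihyp = np.where(t < 200.0, 1.2, 0.0)
        for g_T, expect in [(tc_params.raw["g_T"], True), (0.0, False)]:
            d = dict(tc_params.raw)
            d["g_T"] = g_T
            pa = np.array([d[k] for k in _kernels._TC_KEYS])
            out = _kernels.simulate_tc_full(tc_rest, pa, np.zeros(n), ihyp, dt)
            ev = engine.detect_events(t, out[:, 0], -20.0, 2.0)
            rebound = np.any((ev > 200.0) & (ev < 250.0))
            assert rebound == expect

    def test_anode_break_monotone_in_duration(self, tc_params, tc_rest):
        """Rebound amplitude grows with hyperpolarization duration up to
        the availability plateau."""
        pa = _kernels.tc_param_array(tc_params)
        dt = 0.01
        peaks = []
        for dur_h in [25.0, 50.0, 100.0, 200.0, 400.0]:
            n = int((dur_h + 100) / dt) + 1
            t = np.arange(n) * dt
            ihyp = np.where(t < dur_h, 1.2, 0.0)
            out = _kernels.simulate_tc_full(tc_rest, pa, np.zeros(n), ihyp, dt)
            post = out[t >= dur_h, 0]
            peaks.append(post.max())
        diffs = np.diff(peaks)
        assert np.all(diffs >= -0.5)  # non-decreasing up to plateau wobble
        assert peaks[-1] > peaks[0]


class TestPallidalDynamics:
    def test_stn_spontaneously_active(self, stn_params):
        pa = _kernels.pallidal_param_array(stn_params)
        n = int(2000 / 0.01) + 1
        z = np.zeros(n)
        out = _kernels.simulate_pallidal(
            np.array([-60.0, 0.5, 0.3, 0.3, 0.1]), pa, z, z, 0.01
        )
        t = np.arange(n) * 0.01
        ev = engine.detect_events(t, out[:, 0], -20.0, 2.0)
        assert len(ev[ev > 500]) >= 3  # fires without any input

    def test_stn_faster_with_depolarization(self, stn_params):
        pa = _kernels.pallidal_param_array(stn_params)
        n = int(2000 / 0.01) + 1
        z = np.zeros(n)
        t = np.arange(n) * 0.01
        rates = []
        for iext in (0.0, 25.0):
            out = _kernels.simulate_pallidal(
                np.array([-60.0, 0.5, 0.3, 0.3, 0.1]), pa, z, np.full(n, iext), 0.01
            )
            rates.append(len(engine.detect_events(t, out[:, 0], -20.0, 2.0)))
        assert rates[1] > 3 * rates[0]

    def test_gpe_cluster_fires_under_inhibition(self, gpe_params):
        """Continuous regular firing at baseline drive; clustered
        episodic firing under strong inhibitory striatal drive."""
        pa = _kernels.pallidal_param_array(gpe_params)
        n = int(4000 / 0.01) + 1
        z = np.zeros(n)
        t = np.arange(n) * 0.01

        def isi_stats(iext):
            out = _kernels.simulate_pallidal(
                np.array([-60.0, 0.5, 0.3, 0.3, 0.1]), pa, z, np.full(n, iext), 0.01
            )
            ev = engine.detect_events(t, out[:, 0], -20.0, 2.0)
            isi = np.diff(ev[ev > 1000])
            return isi.std() / isi.mean(), (isi > 100).sum()

        cv_base, gaps_base = isi_stats(1.0)
        cv_inh, gaps_inh = isi_stats(-0.5)
        assert cv_base < 0.3 and gaps_base == 0
        assert cv_inh > 0.8 and gaps_inh >= 2

    def test_ahp_terminates_firing_episodes(self, gpe_params):
        """Without the AHP current, episodes no longer self-terminate."""
        n = int(4000 / 0.01) + 1
        z = np.zeros(n)
        t = np.arange(n) * 0.01
        gaps = {}
        for g_ahp in (gpe_params.raw["g_AHP"], 0.0):
            d = dict(gpe_params.raw)
            d["g_AHP"] = g_ahp
            pa = np.array([d[k] for k in _kernels._PAL_KEYS])
            out = _kernels.simulate_pallidal(
                np.array([-60.0, 0.5, 0.3, 0.3, 0.1]), pa, z, np.full(n, -0.5), 0.01
            )
            ev = engine.detect_events(t, out[:, 0], -20.0, 2.0)
            isi = np.diff(ev[ev > 1000])
            gaps[g_ahp] = (isi > 100).sum()
        assert gaps[gpe_params.raw["g_AHP"]] >= 2
        assert gaps[0.0] == 0


class TestReducedCell:
    def test_nullcline_intersection_is_fixed_point(self, reduced_params):
        v, vnull, wnull = cells.reduced_nullclines(
            reduced_params, s_Gi=30.0, v_grid=np.linspace(-85, -60, 2001)
        )
        i = np.argmin(np.abs(vnull - wnull))
        st_ = np.array([v[i], wnull[i]])
        rates = cells.reduced_tc_derivatives(st_, reduced_params, 0.0, 30.0)
        assert np.max(np.abs(rates)) < 5e-3

    def test_drive_strictly_inhibitory_above_reversal(self, reduced_params):
        st_ = np.array([-60.0, 0.2])
        dv = [
            cells.reduced_tc_derivatives(st_, reduced_params, 0.0, s)[0]
            for s in (5.0, 10.0, 20.0)
        ]
        assert dv[0] > dv[1] > dv[2]

    def test_phi_scales_w_rate_only(self, reduced_params):
        import dataclasses

        d2 = dict(reduced_params.raw)
        d2["phi"] = 3.0 * reduced_params.phi
        pa1 = _kernels.reduced_param_array(reduced_params)
        pa2 = np.array([d2[k] for k in _kernels._RED_KEYS])
        r1 = _kernels.reduced_rhs(-70.0, 0.4, pa1, 0.3, 12.0)
        r2 = _kernels.reduced_rhs(-70.0, 0.4, pa2, 0.3, 12.0)
        assert r2[0] == pytest.approx(r1[0], rel=1e-12)
        assert r2[1] == pytest.approx(3.0 * r1[1], rel=1e-12)

    def test_negative_drive_rejected(self, reduced_params):
        with pytest.raises(ValueError):
            cells.reduced_tc_derivatives(
                np.array([-70.0, 0.3]), reduced_params, 0.0, -1.0
            )

    def test_non_finite_state_rejected(self, tc_params):
        with pytest.raises(ValueError):
            cells.tc_full_derivatives(
                np.array([np.nan, 0.5, 0.2, 0.0]), tc_params
            )


def test_parameter_file_invariants():
    for name in ("tc_full", "stn", "gpe", "gpi"):
        p = cells.load_cell_params(name)
        assert p.E_K < p.E_L < p.E_Na <= p.E_Ca
        v = np.linspace(-120, 60, 361)
        for gname, spec in p.gating.items():
            x = spec.steady_state(v)
            assert np.all((x >= 0) & (x <= 1)), (name, gname)
            if not spec.is_instantaneous:
                assert np.all(spec.time_constant(v) > 0), (name, gname)
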