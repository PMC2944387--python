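"""Topology construction, regimes, synapses and network integration."""

import numpy as np
import pytest
from scipy.signal import periodogram

from dbsloop import network


class TestBuildTopology:
    def test_sparse_random_degrees(self):
        cm = network.build_topology(16, 16, "sparse_random", seed=1)
        assert np.all(cm.stn_to_gpe.sum(axis=1) == 1)
        assert np.all(cm.gpe_to_stn.sum(axis=1) == 3)
        off_diag = cm.gpe_to_gpe[~np.eye(16, dtype=bool)]
        assert np.all(off_diag)
        assert not np.any(np.diag(cm.gpe_to_gpe))

    def test_sparse_structured_no_reciprocal_pairs(self):
        cm = network.build_topology(16, 16, "sparse_structured")
        for i in range(16):
            for j in range(16):
                if cm.stn_to_gpe[i, j]:
                    assert not cm.gpe_to_stn[j, i]

    def test_sparse_structured_degrees(self):
        cm = network.build_topology(16, 16, "sparse_structured")
        assert np.all(cm.stn_to_gpe.sum(axis=1) == 1)
        assert np.all(cm.gpe_to_stn.sum(axis=1) == 2)
        assert np.all(cm.gpe_to_gpe.sum(axis=1) == 2)

    def test_tight_structured_five_closest_with_wraparound(self):
        cm = network.build_topology(16, 16, "tight_structured")
        # brute force the 5 closest on a ring of 16 around cell 0
        dist = lambda a, b: min((a - b) % 16, (b - a) % 16)
        expected = sorted(range(16), key=lambda s: (dist(0, s), s))[:5]
        assert set(np.flatnonzero(cm.gpe_to_stn[0])) == set(expected)
        assert set(expected) == {14, 15, 0, 1, 2}
        assert np.all(cm.stn_to_gpe.sum(axis=1) == 3)
        assert np.all(cm.gpe_to_stn.sum(axis=1) == 5)

    def test_degree_conservation_brute_recount(self):
        for kind, out_sg, out_gs in [
            ("sparse_random", 1, 3),
            ("sparse_structured", 1, 2),
            ("tight_structured", 3, 5),
        ]:
            cm = network.build_topology(12, 12, kind, seed=4)
            assert sum(int(cm.stn_to_gpe[i, j]) for i in range(12)
                       for j in range(12)) == 12 * out_sg
            assert sum(int(cm.gpe_to_stn[i, j]) for i in range(12)
                       for j in range(12)) == 12 * out_gs

    def test_seed_determinism(self):
        a = network.build_topology(16, 16, "sparse_random", seed=9)
        b = network.build_topology(16, 16, "sparse_random", seed=9)
        assert np.array_equal(a.stn_to_gpe, b.stn_to_gpe)
        assert np.array_equal(a.gpe_to_stn, b.gpe_to_stn)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError, match="unknown"):
            network.build_topology(16, 16, "banana")
        with pytest.raises(ValueError):
            network.build_topology(6, 6, "sparse_structured")


class TestSerialization:
    def test_round_trip(self, tmp_path):
        cm = network.build_topology(16, 16, "sparse_random", seed=3)
        path = tmp_path / "map.json"
        cm.to_json(path)
        back = network.ConnectionMap.from_json(path)
        for name in ("stn_to_gpe", "gpe_to_stn", "gpe_to_gpe", "stn_to_gpi",
                     "gpi_to_tc"):
            assert np.array_equal(getattr(cm, name), getattr(back, name))
        assert back.projections == cm.projections


class TestRegime:
    def test_normal_is_identity_on_baseline(self):
        cm = network.build_topology(10, 10, "sparse_structured")
        new, drives = network.set_regime(cm, network.NORMAL)
        assert new.projections == cm.projections
        assert drives["I_app_gpe"] == network.GPE_BIAS

    def test_parkinsonian_changes_exactly_two_quantities(self):
        cm = network.build_topology(10, 10, "sparse_structured")
        base, base_drives = network.set_regime(cm, network.NORMAL)
        pd, pd_drives = network.set_regime(cm, network.PARKINSONIAN)
        assert pd_drives["I_app_gpe"] < base_drives["I_app_gpe"]
        assert (pd.projections["gpe_to_gpe"]["g"]
                < base.projections["gpe_to_gpe"]["g"])
        for k in pd.projections:
            if k != "gpe_to_gpe":
                assert pd.projections[k] == base.projections[k]
        assert pd_drives["I_app_gpi"] == base_drives["I_app_gpi"]

    def test_round_trip_restores_baseline(self):
        cm = network.build_topology(10, 10, "sparse_structured")
        pd, _ = network.set_regime(cm, network.PARKINSONIAN)
        back, drives = network.set_regime(pd, network.NORMAL)
        assert back.projections == cm.projections
        assert drives["I_app_gpe"] == network.GPE_BIAS

    def test_parkinsonian_spec_invariant(self):
        assert network.PARKINSONIAN.striatal_drive > network.NORMAL.striatal_drive
        assert network.PARKINSONIAN.gpe_gpe_scale < network.NORMAL.gpe_gpe_scale


class TestSynapseRate:
    def test_silent_presynaptic_no_activation(self):
        kin = network.SynKinetics()
        assert network.synapse_rate(0.0, -80.0, kin) == pytest.approx(0.0, abs=1e-9)

    def test_fixed_point_under_sustained_depolarization(self):
        kin = network.SynKinetics(alpha=2.0, beta=0.08)
        # closed form: s* = alpha*H / (alpha*H + beta) at fixed v_pre
        h = 1.0 / (1.0 + np.exp(-(0.0 - kin.theta) / kin.sigma))
        s_star = kin.alpha * h / (kin.alpha * h + kin.beta)
        rate = network.synapse_rate(s_star, 0.0, kin)
        assert rate == pytest.approx(0.0, abs=1e-9)
        assert 0 < s_star <= 1

    def test_bounded(self):
        kin = network.SynKinetics()
        assert network.synapse_rate(1.0, 0.0, kin) <= 0.0
        assert network.synapse_rate(0.0, 0.0, kin) >= 0.0


class TestNetworkDerivatives:
    def _state(self, cm, seed=0):
        rng = np.random.default_rng(seed)
        return {
            "stn": np.column_stack(
                [rng.uniform(-80, -40, cm.n_stn), *[rng.uniform(0, 1, cm.n_stn)
                 for _ in range(3)], rng.uniform(0, 1, cm.n_stn),
                 rng.uniform(0, 1, cm.n_stn)]
            )[:, :6],
            "gpe": np.column_stack(
                [rng.uniform(-80, -40, cm.n_gpe)] + [rng.uniform(0, 1, cm.n_gpe)
                 for _ in range(5)]
            ),
            "gpi": np.column_stack(
                [rng.uniform(-80, -40, cm.n_gpi)] + [rng.uniform(0, 1, cm.n_gpi)
                 for _ in range(5)]
            ),
            "tc": np.column_stack(
                [rng.uniform(-80, -40, cm.n_tc)] + [rng.uniform(0, 1, cm.n_tc)
                 for _ in range(3)]
            ),
        }

    def test_decoupled_equals_isolated_cells(self):
        from dbsloop import cells

        cm = network.build_topology(8, 8, "sparse_random", seed=0)
        for proj in cm.projections.values():
            proj["g"] = 0.0
        drives = {"I_app_gpe": 0.7, "I_app_gpi": 0.2}
        state = self._state(cm)
        out = network.network_derivatives(state, cm, drives)
        p_stn = cells.load_cell_params("stn")
        for j in range(cm.n_stn):
            iso = cells.stn_derivatives(state["stn"][j, :5], p_stn, 0.0, 0.0)
            assert np.allclose(out["stn"][j, :5], iso, rtol=1e-12)

    def test_zero_presynaptic_s_means_zero_synaptic_current(self):
        cm = network.build_topology(8, 8, "sparse_random", seed=0)
        drives = {"I_app_gpe": 0.0, "I_app_gpi": 0.0}
        state = self._state(cm)
        state_zero = {k: v.copy() for k, v in state.items()}
        for k in ("stn", "gpe", "gpi"):
            state_zero[k][:, 5] = 0.0
        out_zero = network.network_derivatives(state_zero, cm, drives)
        # decoupled reference
        cm0 = network.build_topology(8, 8, "sparse_random", seed=0)
        for proj in cm0.projections.values():
            proj["g"] = 0.0
        out_ref = network.network_derivatives(state_zero, cm0, drives)
        for k in out_zero:
            assert np.allclose(out_zero[k][:, 0], out_ref[k][:, 0], rtol=1e-12)

    def test_compiled_step_matches_reference_euler_direction(self):
        """One tiny compiled RK4 step moves the state in the direction of
        the reference derivatives."""
        cm = network.build_topology(8, 8, "sparse_structured", seed=1)
        model = network.NetworkModel(cm, network.NORMAL)
        stn, gpe, gpi, tc = model.initial_state(seed=2)
        state = {"stn": stn.copy(), "gpe": gpe.copy(), "gpi": gpi.copy(),
                 "tc": tc.copy()}
        ref = network.network_derivatives(state, model.cm, model.drives)
        dt = 1e-5
        res = model.simulate(2 * dt, dt=dt, state=(stn, gpe, gpi, tc),
                             record_stride=1)
        for k, arr in [("stn", stn), ("gpe", gpe), ("gpi", gpi), ("tc", tc)]:
            got = (arr - state[k]) / (2 * dt)
            assert np.allclose(got, ref[k], rtol=1e-4, atol=1e-6), k


class TestRegimeDynamics:
    def test_parkinsonian_tremor_band_peak(self):
        """Scaled sparse-structured network: parkinsonian GPi output has
        its dominant slow spectral peak in the 3-8 Hz tremor band."""
        cm = network.build_topology(10, 10, "sparse_structured", seed=1)
        m = network.NetworkModel(cm, network.PARKINSONIAN)
        res = m.simulate(5000.0, dt=0.01, seed=2, record_stride=100)
        s = res["s_gpi_sum"][1000:]
        f, p = periodogram(s - s.mean(), fs=1000.0)
        band = (f > 0.5) & (f < 60.0)
        fpk = f[band][np.argmax(p[band])]
        assert 3.0 <= fpk <= 8.0

    def test_parkinsonian_fluctuation_exceeds_normal(self):
        """Smoothed GPi output fluctuation is larger in the parkinsonian
        regime, averaged over matched seeds."""
        def fluct(regime, seed):
            cm = network.build_topology(16, 16, "sparse_structured", seed=1)
            m = network.NetworkModel(cm, regime)
            res = m.simulate(4000.0, dt=0.01, seed=seed, record_stride=100)
            s = res["s_gpi_sum"][500:]
            sm = np.convolve(s, np.ones(100) / 100, mode="valid")
            return sm.max() - sm.min()

        seeds = [1, 2, 3]
        pd = np.mean([fluct(network.PARKINSONIAN, s) for s in seeds])
        nm = np.mean([fluct(network.NORMAL, s) for s in seeds])
        assert pd > nm
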