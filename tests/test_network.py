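import numpy as np
import pytest

from cortexstim.network import (ColumnConfig, Connection, FS_PARAMS,
                                MC_PARAMS, NeuronParams, Population,
                                RS_PARAMS, alpha_m, alpha_n, beta_m,
                                build_column, calibrate_pulse, default_column,
                                isi_sequence, seed_stimulus, simulate,
                                single_cell_network, step_current)


class TestGatingKinetics:
    def test_removable_singularities(self):
        """Rate functions at their singular voltages equal the limits."""
        assert alpha_m(-54.0) == pytest.approx(1.28)
        assert beta_m(-27.0) == pytest.approx(1.4)
        assert alpha_n(-52.0) == pytest.approx(0.16)

    def test_continuity_near_singularity(self):
        eps = 1e-6
        assert alpha_m(-54.0 + eps) == pytest.approx(1.28, rel=1e-4)
        assert alpha_m(-54.0 - eps) == pytest.approx(1.28, rel=1e-4)

    def test_fs_class_forbids_adaptation_currents(self):
        with pytest.raises(ValueError):
            NeuronParams(cell_class="FS", g_ca=1.0)


class TestSingleCell:
    @pytest.mark.parametrize("params", [RS_PARAMS, FS_PARAMS, MC_PARAMS],
                             ids=["RS", "FS", "MC"])
    def test_silent_at_rest(self, params):
        net = single_cell_network(params)
        raster = simulate(net, None, 1000.0, seed=0)
        assert len(raster) == 0

    def test_rs_adaptation_increasing_isis(self):
        isis = isi_sequence(RS_PARAMS, 2.0, 500.0)
        assert len(isis) >= 6
        assert (np.diff(isis[:5]) > 0).all()

    def test_fs_no_adaptation(self):
        isis = isi_sequence(FS_PARAMS, 2.0, 500.0)
        assert len(isis) >= 10
        assert isis.std() / isis.mean() < 0.02

    def test_interneurons_more_excitable(self):
        """Lower leak -> more spikes at matched near-rheobase drive and a
        lower brief-pulse spiking threshold."""
        n_mc = len(isi_sequence(MC_PARAMS, 1.0, 300.0))
        n_rs = len(isi_sequence(RS_PARAMS, 1.0, 300.0))
        assert n_mc > n_rs
        assert calibrate_pulse(MC_PARAMS) < calibrate_pulse(RS_PARAMS)

    def test_dt_convergence(self):
        """Halving the step moves deterministic spike times < 0.1 ms."""
        times = {}
        for dt in (0.025, 0.0125):
            net = single_cell_network(RS_PARAMS, dt_ms=dt)
            r = simulate(net, step_current(2.0), 200.0, seed=0, dt_ms=dt)
            times[dt] = r.times_ms
        n = min(len(times[0.025]), len(times[0.0125]))
        assert n >= 3
        assert np.abs(times[0.025][:n] - times[0.0125][:n]).max() < 0.1

    def test_physiological_state_bounds(self):
        """V and the gating variables stay in their physical ranges."""
        from cortexstim.network import _State, _derivs, SynapseParams
        net = single_cell_network(RS_PARAMS)
        st = _State(net)
        syn = SynapseParams()
        dt = 0.025
        vmin, vmax = 0.0, -100.0
        for step in range(int(100.0 / dt)):
            i_ext = np.full(1, 5.0)
            k1 = _derivs(net, st, i_ext, syn)
            for name, d in zip(("v", "m", "h", "n", "c", "s_exc", "s_inh"),
                               k1):
                setattr(st, name, getattr(st, name) + dt * d)
            vmin, vmax = min(vmin, st.v[0]), max(vmax, st.v[0])
            for g in (st.m, st.h, st.n, st.s_exc, st.s_inh):
                assert 0.0 <= g[0] <= 1.0
        assert -100.0 <= vmin and vmax <= 60.0


class TestBuildColumn:
    def test_zero_probability_empty_block(self):
        cfg = ColumnConfig(
            [Population("a", "-", 20, RS_PARAMS, True),
             Population("b", "-", 20, RS_PARAMS, True)],
            [Connection("a", "b", 0.0, 1.0)])
        net = build_column(cfg, seed=0)
        assert net.w_exc.sum() == 0.0

    def test_full_probability_complete_block(self):
        cfg = ColumnConfig(
            [Population("a", "-", 10, RS_PARAMS, True),
             Population("b", "-", 10, RS_PARAMS, True)],
            [Connection("a", "b", 1.0, 1.0)])
        net = build_column(cfg, seed=0)
        block = net.w_exc[net.pop_slices["b"], net.pop_slices["a"]]
        assert (block > 0).all()

    def test_edge_count_binomial(self):
        cfg = ColumnConfig(
            [Population("a", "-", 50, RS_PARAMS, True),
             Population("b", "-", 50, RS_PARAMS, True)],
            [Connection("a", "b", 0.2, 1.0)])
        net = build_column(cfg, seed=3)
        block = net.w_exc[net.pop_slices["b"], net.pop_slices["a"]]
        n_edges = (block > 0).sum()
        mean, sd = 50 * 50 * 0.2, np.sqrt(50 * 50 * 0.2 * 0.8)
        assert abs(n_edges - mean) < 3 * sd

    def test_inhibitory_weights_separate_matrix(self):
        net = build_column(default_column(), seed=0)
        bc = net.pop_slices["BC23"]
        assert net.w_exc[:, bc].sum() == 0.0
        assert net.w_inh[:, bc].sum() > 0.0

    def test_unknown_population_rejected(self):
        cfg = ColumnConfig([Population("a", "-", 5, RS_PARAMS, True)],
                           [Connection("a", "ghost", 0.5, 1.0)])
        with pytest.raises(KeyError):
            build_column(cfg, seed=0)

    def test_graph_deterministic_under_seed(self):
        a = build_column(default_column(), seed=11)
        b = build_column(default_column(), seed=11)
        np.testing.assert_array_equal(a.w_exc, b.w_exc)
        np.testing.assert_array_equal(a.w_inh, b.w_inh)


class TestSeeding:
    def test_pulse_calibration_fires_isolated_cell(self):
        amp = calibrate_pulse(RS_PARAMS)
        net = single_cell_network(RS_PARAMS)
        r = simulate(net, step_current(amp, 0.0, 0.2), 4.0, seed=0)
        assert len(r) == 1
        assert r.times_ms[0] <= 2.0

    def test_probability_zero_no_pulses(self):
        net = build_column(default_column(), seed=0)
        stim = seed_stimulus(net, {"exc23": 0.0}, seed=0)
        assert stim.amplitudes.sum() == 0.0

    def test_probability_one_every_cell_spikes_once(self):
        cfg = ColumnConfig([Population("solo", "-", 30, RS_PARAMS, True)], [])
        net = build_column(cfg, seed=0)
        stim = seed_stimulus(net, {"solo": 1.0}, seed=1)
        raster = simulate(net, stim.i_ext_fn(), 6.0, seed=2)
        assert len(raster) == 30
        assert (raster.times_ms <= 2.0).all()

    def test_seeded_fraction_binomial(self):
        cfg = ColumnConfig([Population("solo", "-", 200, RS_PARAMS, True)],
                           [])
        net = build_column(cfg, seed=0)
        fractions = [np.mean(seed_stimulus(net, {"solo": 0.5},
                                           seed=s).amplitudes > 0)
                     for s in range(20)]
        assert abs(np.mean(fractions) - 0.5) < 0.07

    def test_invalid_probability_rejected(self):
        net = build_column(default_column(), seed=0)
        with pytest.raises(ValueError):
            seed_stimulus(net, {"exc23": 1.5})
        with pytest.raises(KeyError):
            seed_stimulus(net, {"ghost": 0.5})


class TestSimulate:
    def test_zero_stimulus_empty_raster(self):
        net = build_column(default_column(), seed=0)
        raster = simulate(net, None, 30.0, seed=0, noise_eta=0.0)
        assert len(raster) == 0

    def test_raster_deterministic_under_seeds(self):
        net = build_column(default_column(), seed=5)
        stim = seed_stimulus(net, {"exc4": 0.8, "exc23": 0.5}, seed=6)
        a = simulate(net, stim.i_ext_fn(), 30.0, seed=7)
        b = simulate(net, stim.i_ext_fn(), 30.0, seed=7)
        np.testing.assert_array_equal(a.times_ms, b.times_ms)
        np.testing.assert_array_equal(a.cell_ids, b.cell_ids)

    def test_moderate_seeding_outlasts_window(self):
        """Moderate excitatory seeding drives recurrent activity well past
        the 0.2 ms input window."""
        cfg = default_column()
        net = build_column(cfg, seed=1)
        stim = seed_stimulus(net, {"exc23": 0.5, "exc4": 0.8, "exc5": 0.3},
                             seed=2)
        raster = simulate(net, stim.i_ext_fn(), 60.0, seed=3)
        assert raster.times_ms.max() > 10.2

    def test_interneuron_seeding_suppresses_excitatory_response(self):
        cfg = default_column()
        net = build_column(cfg, seed=1)
        exc_probs = {"exc23": 0.9, "exc4": 1.0, "exc5": 0.7}
        inh_probs = dict(exc_probs, BC23=0.9, BC4=0.9, BC5=0.9,
                         MC23=1.0, MC4=1.0, MC5=1.0)
        responses = {}
        for tag, probs in (("exc_only", exc_probs), ("with_inh", inh_probs)):
            stim = seed_stimulus(net, probs, seed=2)
            r = simulate(net, stim.i_ext_fn(), 50.0, seed=3)
            responses[tag] = sum(
                r.population_response(p, cfg.population(p).size)
                for p in ("exc23", "exc4")) / 2
        assert responses["with_inh"] < responses["exc_only"]

    def test_population_response_counts_window(self):
        net = build_column(default_column(), seed=1)
        stim = seed_stimulus(net, {"exc4": 1.0}, seed=2)
        raster = simulate(net, stim.i_ext_fn(), 30.0, seed=3)
        full = raster.population_response("exc4", 60)
        early = raster.population_response("exc4", 60, t_stop=0.5)
        assert full >= 1.0
        assert early <= full
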