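"""Generator: protocols, forward rates, spikes, fluorescence, movies, ephys."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import i0, i1

from crtuning import stats, syngen, traces, tuning
from crtuning.syngen import (build_protocol, simulate_spikes,
                             spikes_to_fluorescence, tuning_rate)
from conftest import make_curve


class TestProtocols:
    def test_five_minute_orientation_battery_gives_five_complete_blocks(self):
        p = build_protocol("orientation", 300.0, seed=1)
        assert p.n_trials == 60
        for b in range(5):
            block = p.trials.iloc[12 * b:12 * (b + 1)]
            assert sorted(block["direction"]) == sorted(syngen.DIRECTIONS_CA)
        assert np.allclose(p.trials["offset"] - p.trials["onset"], 2.0)
        assert p.duration_s == 300.0

    def test_one_size_block_shows_each_diameter_once(self):
        p = build_protocol("size", 25.0, seed=2)
        assert sorted(p.trials["diameter"]) == sorted(syngen.SIZES_CA)

    def test_trials_do_not_overlap(self):
        p = build_protocol("sf", 300.0, seed=3)
        assert (p.trials["onset"].to_numpy()[1:]
                >= p.trials["offset"].to_numpy()[:-1]).all()

    def test_same_seed_reproduces_and_seeds_differ(self):
        a = build_protocol("orientation", 300.0, seed=5)
        b = build_protocol("orientation", 300.0, seed=5)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        base = a.trials["direction"].to_numpy()
        differing = sum(
            (build_protocol("orientation", 300.0, seed=s)
             .trials["direction"].to_numpy() != base).any()
            for s in range(100, 200))
        assert differing == 100

    def test_ephys_battery_balances_laser_states_within_blocks(self):
        p = build_protocol("ephys_contrast", 400.0, seed=4)
        block = p.trials.iloc[:80]
        g = block.groupby(["contrast", "direction"])["laser_on"].agg(["sum", "count"])
        assert (g["count"] == 2).all() and (g["sum"] == 1).all()
        assert np.allclose(p.trials["offset"] - p.trials["onset"], 1.5)

    def test_unknown_kind_and_short_duration_raise(self):
        with pytest.raises(syngen.ConfigError):
            build_protocol("plaid", 300.0, seed=0)
        with pytest.raises(syngen.ConfigError):
            build_protocol("orientation", 30.0, seed=0)  # < one 60 s block


class TestForwardRates:
    def test_zero_concentration_with_symmetric_lobes_is_flat(self, flat_cell):
        r = tuning_rate(flat_cell, direction=np.array(syngen.DIRECTIONS_CA))
        assert np.allclose(r, r[0], atol=1e-12)

    def test_rate_peaks_at_preferred_stimulus(self, tuned_cell):
        r_pref = tuning_rate(tuned_cell, direction=30.0, diameter=40.0,
                             sf=0.05, tf=2.0, contrast=100.0,
                             patch_x=0.0, patch_y=0.0)
        r_orth = tuning_rate(tuned_cell, direction=120.0, diameter=40.0,
                             sf=0.05, tf=2.0, contrast=100.0,
                             patch_x=0.0, patch_y=0.0)
        assert r_pref > r_orth
        # approaches baseline + rate_max up to the contrast/size factors
        assert r_pref <= tuned_cell.rate_baseline + tuned_cell.rate_max + 1e-9

    def test_contrast_factor_is_half_at_true_c50(self, tuned_cell):
        assert syngen._contrast_factor(tuned_cell, tuned_cell.c50_true) == \
            pytest.approx(0.5, abs=1e-15)

    def test_rates_are_nonnegative_across_random_stimuli(self, tuned_cell):
        rng = np.random.default_rng(0)
        r = tuning_rate(tuned_cell, direction=rng.uniform(0, 360, 200),
                        diameter=rng.uniform(5, 150, 200),
                        sf=rng.uniform(0.005, 0.5, 200),
                        tf=rng.uniform(0.5, 25, 200),
                        contrast=rng.uniform(1, 100, 200),
                        patch_x=rng.uniform(-40, 40, 200),
                        patch_y=rng.uniform(-20, 20, 200))
        assert (r >= 0).all()

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0])
    def test_discrete_osi_tracks_von_mises_closed_form(self, kappa):
        """12-direction OSI of the noiseless curve vs I1(k)/I0(k)."""
        dirs = np.array(syngen.DIRECTIONS_CA)
        r = np.exp(kappa * (np.cos(2 * np.radians(dirs)) - 1.0))
        osi = tuning.orientation_selectivity(make_curve(dirs, r))
        assert abs(osi - i1(kappa) / i0(kappa)) < 1e-2

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 4.0])
    def test_continuum_osi_matches_von_mises_closed_form(self, kappa):
        """Densely sampled, the model's OSI equals the closed form."""
        dirs = np.arange(0.0, 360.0, 0.5)
        r = np.exp(kappa * (np.cos(2 * np.radians(dirs)) - 1.0))
        osi = tuning.orientation_selectivity(make_curve(dirs, r))
        assert abs(osi - i1(kappa) / i0(kappa)) < 1e-6


class TestPopulation:
    def test_group_structure_of_true_parameters(self):
        pop = syngen.generate_population(3)
        m, u = pop[pop.marked], pop[~pop.marked]
        assert m["osi_true"].mean() < u["osi_true"].mean()
        assert m["si_true"].mean() < u["si_true"].mean()
        # shared distributions: similar DSI means (no construction difference)
        assert abs(m["dsi_true"].mean() - u["dsi_true"].mean()) < 0.08
        assert (pop["depth_um"].between(120, 350)).all()
        assert (pop["dir_bias"].between(0, 1)).all()

    def test_same_seed_reproduces_population(self):
        a = syngen.generate_population(9, dict(n_marked=5, n_unmarked=10))
        b = syngen.generate_population(9, dict(n_marked=5, n_unmarked=10))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_population_parameter_rejected(self):
        with pytest.raises(syngen.ConfigError):
            syngen.generate_population(0, dict(nonsense=1))

    def test_noiseless_size_curves_reproduce_target_si(self, small_population):
        sizes = np.array(syngen.SIZES_CA)
        for _, row in small_population.head(8).iterrows():
            cell = syngen.cell_from_row(row)
            r = tuning_rate(cell, direction=cell.pref_direction, diameter=sizes,
                            patch_x=cell.rf_x, patch_y=cell.rf_y) - cell.rate_baseline
            si = tuning.size_tuning(make_curve(sizes, r))[0]
            assert si == pytest.approx(row["si_true"], abs=1e-3)

    def test_noiseless_preferred_direction_recovered(self, small_population):
        dirs = np.array(syngen.DIRECTIONS_CA)
        for _, row in small_population.iterrows():
            if row["kappa_ori"] < 0.5:
                continue
            cell = syngen.cell_from_row(row)
            r = tuning_rate(cell, direction=dirs) - cell.rate_baseline
            pref, _ = tuning.preferred_stimulus(make_curve(dirs, r))
            d = abs((pref - row["pref_direction"] + 180) % 360 - 180)
            assert d <= 15.0 + 1e-9  # nearest battery step


class TestSpikes:
    def test_poisson_mean_count(self, flat_cell):
        p = build_protocol("orientation", 300.0, seed=21)
        cell = syngen.GroundTruthCell(**{**flat_cell.__dict__,
                                         "rate_max": 0.0, "rate_baseline": 10.0})
        total = sum(simulate_spikes(cell, p, seed).size for seed in range(5))
        expect = 5 * 10.0 * 300.0
        assert abs(total - expect) < 3 * np.sqrt(expect)

    def test_zero_rate_gives_empty_train(self, flat_cell):
        p = build_protocol("orientation", 300.0, seed=21)
        silent = syngen.GroundTruthCell(**{**flat_cell.__dict__,
                                           "rate_max": 0.0, "rate_baseline": 0.0})
        assert simulate_spikes(silent, p, 1).size == 0

    def test_same_seed_identical_train(self, tuned_cell, ori_protocol):
        a = simulate_spikes(tuned_cell, ori_protocol, 33)
        b = simulate_spikes(tuned_cell, ori_protocol, 33)
        assert np.array_equal(a, b)
        assert (np.diff(a) >= 0).all()


class TestFluorescence:
    def test_silence_with_no_noise_is_flat_baseline(self):
        tr = spikes_to_fluorescence([], 10.0, 200.0, 1.8, 1000.0, 0.0)
        assert tr.shape == (70,)
        assert np.allclose(tr, 1000.0)

    def test_simultaneous_spikes_add_linearly(self):
        t0 = 2.0  # exactly a frame time at 7 fps? use frame 14 time = 2.0 s
        tr = spikes_to_fluorescence([t0, t0, t0], 10.0, 200.0, 1.8, 1000.0, 0.0)
        peak_frame = int(np.ceil(t0 * 7.0 - 1e-9))
        assert tr[peak_frame] - 1000.0 == pytest.approx(3 * 200.0, rel=1e-12)

    def test_transient_decays_with_tau(self):
        tr = spikes_to_fluorescence([0.0], 5.0, 100.0, 1.0, 500.0, 0.0, frame_rate=10)
        d = tr - 500.0
        assert d[5] / d[0] == pytest.approx(np.exp(-0.5), rel=1e-9)

    def test_calcium_tracks_spiking_across_a_direction_battery(self, tuned_cell):
        """Normalized per-stimulus calcium responses vs spike counts."""
        pooled_c, pooled_s = [], []
        for seed in (0, 1, 2):
            p = build_protocol("orientation", 300.0, seed=50 + seed)
            st = simulate_spikes(tuned_cell, p, 60 + seed)
            f0 = 1000.0
            tr = spikes_to_fluorescence(st, p.duration_s, 0.2 * f0, 1.8, f0,
                                        0.01 * f0, seed=70 + seed)
            table = traces.trial_responses(
                traces.compute_dff(tr, p, 7.0), p)
            on, off = p.trials["onset"].to_numpy(), p.trials["offset"].to_numpy()
            counts = np.searchsorted(st, off) - np.searchsorted(st, on)
            cm = table.groupby("stimulus_id")["response"].mean()
            sm = pd.Series(counts, index=p.trials["stimulus_id"]).groupby(level=0).mean()
            pooled_c.append((cm / cm.max()).to_numpy())
            pooled_s.append((sm / sm.max()).to_numpy())
        r, _ = stats.calcium_spike_correlation(np.concatenate(pooled_c),
                                               np.concatenate(pooled_s))
        assert r >= 0.95


class TestMovie:
    def test_single_cell_disk_reproduces_its_trace(self):
        trace = np.array([[1.0, 2.0, 3.5, 0.5]])
        frames, roi = syngen.render_movie(trace, [True], (40, 40), 5, seed=2,
                                          background=0.0)
        assert frames.shape == (4, 40, 40)
        got = traces.extract_roi_traces(frames, roi)[0]
        assert np.allclose(got, trace[0], atol=1e-6)

    def test_frame_count_matches_duration(self):
        frames, _ = syngen.render_movie(np.zeros((2, 21)), [True, False],
                                        (50, 50), 4, seed=3)
        assert frames.shape[0] == 21

    def test_impossible_packing_raises(self):
        with pytest.raises(RuntimeError):
            syngen.place_cells(50, (30, 30), 10, seed=0)


class TestEphysSession:
    def test_same_seed_reproduces_session(self, small_population):
        p = build_protocol("ephys_contrast", 200.0, seed=8)
        a = syngen.simulate_ephys_session(small_population, p, 99)
        b = syngen.simulate_ephys_session(small_population, p, 99)
        for uid in a[0]:
            assert np.array_equal(a[0][uid], b[0][uid])
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_channel_depths_follow_spacing(self, small_population):
        p = build_protocol("ephys_contrast", 200.0, seed=8)
        _, units, channels = syngen.simulate_ephys_session(
            small_population, p, 1, n_channels=16, channel_spacing_um=50.0)
        assert np.array_equal(channels["depth_from_tip_um"],
                              np.arange(16) * 50.0)
        assert units["channel_index"].between(0, 15).all()

    def test_laser_gain_scales_expected_trial_rates(self, tuned_cell):
        g = 0.8
        cell = syngen.GroundTruthCell(**{**tuned_cell.__dict__, "laser_gain": g})
        p = build_protocol("ephys_contrast", 200.0, seed=9)
        rates = syngen.expected_rates(cell, p)
        t = p.trials
        for (c, d), grp in t.groupby(["contrast", "direction"]):
            r_on = rates[grp.index[grp["laser_on"]]].mean()
            r_off = rates[grp.index[~grp["laser_on"]]].mean()
            assert r_on == pytest.approx(g * r_off, rel=1e-12)


class TestSessionContainer:
    def test_round_trip(self, tmp_path, small_population, tuned_cell):
        p = build_protocol("orientation", 60.0, seed=1)
        tr = np.random.default_rng(0).normal(1000, 10, (3, 420))
        syngen.write_session(
            tmp_path / "s.h5", seed=5, config_yaml="a: 1",
            ground_truth=small_population,
            calcium=dict(orientation=dict(traces=tr, cell_ids=[0, 1, 2],
                                          protocol=p)),
            ephys=dict(ephys_contrast=dict(
                spikes={0: np.array([0.5, 1.0])},
                units=pd.DataFrame(dict(unit_id=[0], channel_index=[3],
                                        laser_gain=[0.9])),
                protocol=build_protocol("ephys_contrast", 200.0, seed=2))))
        s = syngen.load_session(tmp_path / "s.h5")
        assert s["seed"] == 5
        pd.testing.assert_frame_equal(s["ground_truth"], small_population)
        assert np.allclose(s["calcium"]["orientation"]["traces"], tr)
        pd.testing.assert_frame_equal(
            s["calcium"]["orientation"]["protocol"].trials, p.trials)
        assert np.allclose(s["ephys"]["ephys_contrast"]["spikes"][0], [0.5, 1.0])
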