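"""Generator ground truth: Markov behavior, tap responses, calcium trials,
and planted-cell movies."""

import numpy as np
import pytest
from scipy import stats as sps

from zfsleep import LightSchedule, SimConfig
from zfsleep import synthetic as syn
from zfsleep.config import CalciumConfig, GroupSpec, MovieConfig, TapConfig
from zfsleep.sleep import extract_bouts, score_sleep


def _single_group_config(p_ws, p_sw, n_larvae=1, seed=0, **kw):
    group = GroupSpec(
        label="g",
        p_wake_to_sleep={"day": p_ws, "night": p_ws},
        p_sleep_to_wake={"day": p_sw, "night": p_sw},
        **kw,
    )
    return SimConfig(n_larvae=n_larvae, groups=[group], seed=seed)


class TestActivityTraces:
    def test_absorbing_wake_state_gives_zero_sleep(self, schedule):
        cfg = _single_group_config(p_ws=0.0, p_sw=0.5, n_larvae=3)
        for trace in syn.gen_activity_traces(cfg, schedule, initial_state="wake"):
            assert not score_sleep(trace).any()

    def test_absorbing_sleep_state_gives_single_spanning_bout(self, schedule):
        cfg = _single_group_config(p_ws=0.5, p_sw=0.0)
        (trace,) = syn.gen_activity_traces(cfg, schedule, initial_state="sleep")
        assert np.all(trace.values == 0.0)
        bouts = extract_bouts(score_sleep(trace))
        assert bouts.count == 1
        assert bouts.total_sleep == trace.n_minutes

    def test_stationary_sleep_fraction_matches_closed_form(self):
        # pi_sleep = p_ws / (p_ws + p_sw) for the two-state chain
        p_ws, p_sw = 0.06, 0.14
        cfg = _single_group_config(p_ws, p_sw, seed=3)
        schedule = LightSchedule(n_days=70)
        n_min = 100_000
        (trace,) = syn.gen_activity_traces(cfg, schedule, n_minutes=n_min)
        pi = p_ws / (p_ws + p_sw)
        observed = score_sleep(trace).mean()
        # SE of the mean of a two-state chain, inflated by autocorrelation
        rho = 1.0 - p_ws - p_sw
        se = np.sqrt(pi * (1 - pi) / n_min * (1 + rho) / (1 - rho))
        assert abs(observed - pi) < 3 * se

    def test_bout_lengths_geometric(self):
        # sleep bout length ~ Geometric(p_sw), mean 1/p_sw
        p_sw = 0.2
        cfg = _single_group_config(0.1, p_sw, seed=11)
        schedule = LightSchedule(n_days=140)
        (trace,) = syn.gen_activity_traces(cfg, schedule, n_minutes=190_000)
        lengths = extract_bouts(score_sleep(trace)).lengths
        assert lengths.size >= 10_000
        kmax = 25
        observed = np.bincount(np.minimum(lengths, kmax), minlength=kmax + 1)[1:]
        k = np.arange(1, kmax + 1)
        pmf = (1 - p_sw) ** (k - 1) * p_sw
        pmf[-1] = (1 - p_sw) ** (kmax - 1)  # tail lumped into last bin
        chi2, p = sps.chisquare(observed, pmf * lengths.size)
        assert p > 0.01

    def test_heat_shock_multiplier_increases_sleep_transition(self, schedule):
        cfg = _single_group_config(0.01, 0.25, n_larvae=24, seed=5, hs_p_ws_mult=30.0)
        cfg.heat_shock.start_min = 300
        traces = syn.gen_activity_traces(cfg, schedule, initial_state="wake")
        post = np.mean([score_sleep(t)[300:420].mean() for t in traces])
        pre = np.mean([score_sleep(t)[120:300].mean() for t in traces])
        assert post > pre + 0.1

    def test_fixed_seed_is_byte_identical(self, small_config, schedule, tmp_path):
        a = syn.gen_activity_traces(small_config, schedule)
        b = syn.gen_activity_traces(small_config, schedule)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.values, tb.values)
        syn.write_activity_csv(a, tmp_path / "a.csv")
        syn.write_activity_csv(b, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_adding_larvae_never_perturbs_existing_streams(self, schedule):
        small = _single_group_config(0.05, 0.2, n_larvae=2, seed=9)
        big = _single_group_config(0.05, 0.2, n_larvae=5, seed=9)
        a = syn.gen_activity_traces(small, schedule)
        b = syn.gen_activity_traces(big, schedule)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.values, tb.values)

    def test_rejects_nonpositive_duration(self, small_config, schedule):
        with pytest.raises(ValueError):
            syn.gen_activity_traces(small_config, schedule, n_minutes=0)

    def test_activity_csv_round_trip(self, small_config, schedule, tmp_path):
        traces = syn.gen_activity_traces(small_config, schedule)
        syn.write_activity_csv(traces, tmp_path / "act.csv")
        back = syn.read_activity_csv(tmp_path / "act.csv")
        assert len(back) == len(traces)
        for ta, tb in zip(traces, back):
            assert ta.larva_id == tb.larva_id and ta.group == tb.group
            np.testing.assert_allclose(ta.values, tb.values)


class TestTapDataset:
    def test_paper_design_gives_420_trials_per_larva(self):
        cfg = SimConfig(n_larvae=2, groups=[GroupSpec("wt")])
        df = syn.gen_tap_dataset(cfg)
        assert len(cfg.tap.powers) == 14
        assert cfg.tap.trials_per_power == 30
        assert (df.groupby("larva").size() == 420).all()

    def test_flat_zero_curve_and_no_background_never_responds(self):
        cfg = SimConfig(n_larvae=3, groups=[GroupSpec("wt")])
        cfg.tap = TapConfig(bottom=0.0, top=0.0, background_move_prob=0.0)
        df = syn.gen_tap_dataset(cfg)
        assert not df["responded"].any()
        assert not df["pre_moved"].any()

    def test_response_fraction_at_etp50_is_half_maximal(self):
        cfg = SimConfig(n_larvae=40, groups=[GroupSpec("wt")])
        cfg.tap = TapConfig(
            powers=[6.2], trials_per_power=50, bottom=0.0, top=1.0,
            etp50=6.2, hill=2.0, background_move_prob=0.0,
        )
        df = syn.gen_tap_dataset(cfg)
        frac = df["responded"].mean()
        n = len(df)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_top_power_response_approaches_or_combination(self):
        # P(respond) -> top + bg * (1 - top) at saturating power
        cfg = SimConfig(n_larvae=60, groups=[GroupSpec("wt")], seed=2)
        cfg.tap = TapConfig(
            powers=[36.31], trials_per_power=30, bottom=0.0, top=0.9,
            etp50=2.0, hill=3.0, background_move_prob=0.1,
        )
        df = syn.gen_tap_dataset(cfg)
        psi = 0.9 / (1 + 10 ** ((np.log10(2.0) - np.log10(36.31)) * 3.0))
        expected = psi + 0.1 * (1 - psi)
        n = len(df)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(df["responded"].mean() - expected) < 3 * se

    def test_rejects_nonpositive_power(self):
        cfg = SimConfig(n_larvae=1, groups=[GroupSpec("wt")])
        with pytest.raises(ValueError):
            cfg.tap = TapConfig(powers=[0.0, 1.0])


class TestTrialRecordings:
    def test_zero_noise_zero_amplitude_trace_is_flat_at_baseline(self):
        cfg = SimConfig(n_larvae=1)
        cfg.calcium = CalciumConfig(on_amplitude=0.0, off_amplitude=0.0, noise_sd=0.0)
        rec = syn.gen_trial_recordings(cfg, 3, "subjective_day")
        assert np.all(rec.traces == cfg.calcium.day_baseline)

    def test_night_baseline_contrast_is_exact_at_zero_noise(self):
        cfg = SimConfig(n_larvae=1)
        cfg.calcium = CalciumConfig(
            day_baseline=100.0, night_baseline=75.0,
            on_amplitude=0.0, off_amplitude=0.0, noise_sd=0.0,
        )
        day = syn.gen_trial_recordings(cfg, 2, "subjective_day")
        night = syn.gen_trial_recordings(cfg, 2, "subjective_night")
        assert day.traces.mean() == 100.0
        assert night.traces.mean() == 75.0

    def test_on_window_mean_equals_configured_amplitude(self):
        # direct evaluation of the evoked kernel over the 32-37 s window
        cfg = SimConfig(n_larvae=1)
        cfg.calcium = CalciumConfig(on_amplitude=40.0, off_amplitude=25.0, noise_sd=0.0)
        rec = syn.gen_trial_recordings(cfg, 1, "subjective_day")
        trial = rec.traces[0]
        intrinsic = trial[5:26].mean()
        assert trial[32:38].mean() - intrinsic == pytest.approx(40.0, abs=1e-12)
        assert trial[93:99].mean() - intrinsic == pytest.approx(25.0, abs=1e-12)

    def test_suppression_mode_decays_to_night_level(self):
        cfg = SimConfig(n_larvae=1)
        cfg.calcium = CalciumConfig(
            on_amplitude=0.0, off_amplitude=0.0, noise_sd=0.0,
            day_baseline=100.0, suppression_level=70.0, suppression_tau_trials=1.0,
        )
        rec = syn.gen_trial_recordings(cfg, 15, reachr_suppression=True)
        assert np.all(rec.traces[:5] == 100.0)
        assert rec.traces[-1].mean() == pytest.approx(70.0, rel=1e-3)


class TestMovie:
    def test_zero_cells_is_pure_background(self):
        cfg = SimConfig(n_larvae=1)
        cfg.movie = MovieConfig(noise_sd=0.0)
        stack, truth = syn.gen_movie(cfg, 0, frame_shape=(32, 32), n_frames=20)
        assert np.all(stack == cfg.movie.background_level)
        assert len(truth.masks) == 0

    def test_single_bright_static_cell_at_planted_centroid(self):
        cfg = SimConfig(n_larvae=1)
        cfg.movie = MovieConfig(noise_sd=0.0, spike_rate=1.0, cell_amplitude=100.0)
        stack, truth = syn.gen_movie(cfg, 1, frame_shape=(32, 32), n_frames=30)
        from skimage import measure

        for frame in stack:
            signal = frame - cfg.movie.background_level
            labels = measure.label(signal > 0.5 * signal.max())
            regions = measure.regionprops(labels)
            assert len(regions) == 1
            assert np.hypot(*(np.array(regions[0].centroid) - truth.centroids[0])) < 1.0

    def test_variance_map_peaks_at_planted_centroids(self):
        # brute-force per-pixel temporal variance of the generated stack
        cfg = SimConfig(n_larvae=1, seed=4)
        stack, truth = syn.gen_movie(cfg, 20, frame_shape=(64, 64), n_frames=200)
        var_map = stack.var(axis=0)
        from scipy import ndimage

        peaks = var_map == ndimage.maximum_filter(var_map, size=5)
        peak_coords = np.argwhere(peaks & (var_map > var_map.mean() + 3 * var_map.std()))
        for c in truth.centroids:
            d = np.hypot(*(peak_coords - c).T)
            assert d.min() <= 1.0

    def test_too_many_cells_raises(self):
        cfg = SimConfig(n_larvae=1)
        with pytest.raises(ValueError):
            syn.gen_movie(cfg, 500, frame_shape=(32, 32), n_frames=5)
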