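import numpy as np
import pandas as pd
import pytest

from edamic.downstream import (
    DutyCycleModel,
    SurvivalTable,
    TipPair,
    continuous_frames_per_event,
    detect_flicker,
    drp1_tip_ratio,
    excess_mortality,
    fit_decay,
    fold_reduction,
    image_quality,
    nucleus_death_ratio,
    recover_death_times,
    survival_curve,
    tmre_track_classify,
)
from edamic.synthsample.toxicity import ToxicityCohort


class TestDutyCycle:
    def test_186_frames(self):
        assert continuous_frames_per_event(DutyCycleModel(3.1, 20.0, 1.0)) == 186

    def test_192_frames(self):
        assert continuous_frames_per_event(DutyCycleModel(3.2, 20.0, 1.0)) == 192

    def test_nine_fold(self):
        model = DutyCycleModel(3.1, 20.0, 1.0)
        assert fold_reduction(model, 20) == pytest.approx(9.3)
        assert round(fold_reduction(model, 20)) == 9

    def test_ten_fold(self):
        model = DutyCycleModel(3.2, 20.0, 1.0)
        assert fold_reduction(model, 20) == pytest.approx(9.6)
        assert round(fold_reduction(model, 20)) == 10

    def test_zero_triggered_errors(self):
        with pytest.raises(ValueError):
            fold_reduction(DutyCycleModel(3.1, 20.0, 1.0), 0)

    @pytest.mark.parametrize("rate", [0.5, 1.0, 2.0, 5.0])
    def test_fold_reduction_frame_rate_invariant(self, rate):
        model = DutyCycleModel(3.1, 20.0, rate)
        triggered = model.event_duration * model.frame_rate
        assert fold_reduction(model, triggered) == pytest.approx(
            3.1 * 60 / 20.0, rel=1e-2)


class TestSurvival:
    def _table(self, death_times, duration=1000.0, replicate=0):
        return SurvivalTable.from_death_times(death_times, "fluorescence",
                                              duration, replicate)

    def test_no_deaths_flat_one(self):
        table = self._table([np.inf] * 10)
        mean, sd = survival_curve(table, [0, 100, 500])
        np.testing.assert_allclose(mean, 1.0)

    def test_single_replicate_zero_sd(self):
        table = self._table([50.0, np.inf, 200.0])
        _, sd = survival_curve(table, [0, 100, 300])
        np.testing.assert_allclose(sd, 0.0)

    def test_curves_non_increasing(self):
        table = self._table([10, 50, 100, 400, np.inf, np.inf])
        mean, _ = survival_curve(table, np.linspace(0, 800, 30))
        assert all(b <= a + 1e-12 for a, b in zip(mean, mean[1:]))

    def test_monte_carlo_within_3se(self):
        cohort = ToxicityCohort(500, "fluorescence", duration=36000.0, seed=1)
        table = self._table(cohort.death_times(), duration=36000.0)
        grid = np.linspace(0, 3000, 10)
        mean, _ = survival_curve(table, grid)
        p = cohort.per_frame_death_prob
        expected = np.exp(-p * grid)
        se = np.sqrt(expected * (1 - expected) / 500 + 1e-12)
        assert np.all(np.abs(mean - expected) <= 3 * se + 0.01)

    def test_duplicate_cells_rejected(self):
        df = pd.DataFrame({"cell_id": [1, 1], "condition": ["dark"] * 2,
                           "replicate": [0, 0], "time": [1.0, 2.0],
                           "dead": [False, True]})
        with pytest.raises(ValueError):
            SurvivalTable(df)


class TestFitDecay:
    def test_noiseless_recovery(self):
        t = np.linspace(0, 500, 60)
        fit = fit_decay(t, np.exp(-t / 100.0))
        assert fit.rate == pytest.approx(0.01, rel=1e-6)
        assert fit.half_life == pytest.approx(np.log(2) * 100, rel=1e-6)

    def test_half_life_69_31(self):
        t = np.linspace(0, 400, 50)
        fit = fit_decay(t, np.exp(-t / 100.0))
        assert fit.half_life == pytest.approx(69.3147, abs=1e-3)

    def test_identical_curves_excess_one(self):
        t = np.linspace(0, 400, 50)
        fit = fit_decay(t, np.exp(-t / 100.0))
        assert excess_mortality(fit, fit, 50.0) == pytest.approx(1.0)

    def test_non_decaying_flagged(self):
        with pytest.warns(UserWarning):
            fit = fit_decay([0, 1, 2], [1.0, 1.0, 1.0])
        assert fit.clipped

    def test_excess_mortality_100x_at_defaults(self):
        fits = {}
        for cond in ("fluorescence", "phase"):
            cohort = ToxicityCohort(800, cond, duration=2.0e6, seed=3)
            times = cohort.death_times()
            table = SurvivalTable.from_death_times(times, cond, 2.0e6)
            grid = np.linspace(0, 3000, 40)
            mean, _ = survival_curve(table, grid)
            fits[cond] = fit_decay(grid, mean, condition=cond)
        t_half = fits["fluorescence"].half_life
        assert excess_mortality(fits["fluorescence"], fits["phase"],
                                t_half) >= 100.0


class TestNucleusDeathRatio:
    def _nuclei(self, dead_flags, shape=(128, 128), radius=8.0):
        cohort = ToxicityCohort(len(dead_flags), "dark", seed=5)
        centers, radius = cohort.nucleus_layout(shape, radius)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        hoechst = np.zeros(shape)
        sytox = np.zeros(shape)
        for (cx, cy), dead in zip(centers, dead_flags):
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
            hoechst[mask] = 1.0
            if dead:
                sytox[mask] = 1.0
        return sytox, hoechst

    def test_zero_sytox_all_alive(self):
        sytox, hoechst = self._nuclei([False] * 4)
        df = nucleus_death_ratio(sytox, hoechst)
        assert len(df) == 4
        assert not df["dead"].any()
        np.testing.assert_allclose(df["ratio"], 0.0, atol=1e-9)

    def test_equal_intensity_ratio_one_dead(self):
        sytox, hoechst = self._nuclei([True] * 4)
        df = nucleus_death_ratio(sytox, hoechst)
        assert df["dead"].all()
        np.testing.assert_allclose(df["ratio"], 1.0, atol=0.05)

    def test_mixed_population(self):
        sytox, hoechst = self._nuclei([True, False, True, False])
        df = nucleus_death_ratio(sytox, hoechst)
        assert int(df["dead"].sum()) == 2

    def test_empty_frame_warns(self):
        with pytest.warns(UserWarning, match="no nuclei"):
            df = nucleus_death_ratio(np.zeros((64, 64)), np.zeros((64, 64)))
        assert df.empty

    def test_cohort_death_time_recovery_within_one_interval(self):
        # frames recorded every 250 s, as in the toxicity protocol
        cohort = ToxicityCohort(9, "fluorescence", duration=3000.0,
                                hazard_coeff=2e-4 / 3500, seed=12)
        sample_times = np.arange(0, 3000.0, 250.0)
        hoechst, sytox = cohort.render_nucleus_frames(sample_times,
                                                      shape=(128, 128),
                                                      radius=8.0)
        recovered = recover_death_times(hoechst, sytox, sample_times)
        truth = cohort.death_times()
        centers, _ = cohort.nucleus_layout((128, 128), 8.0)
        for _, row in recovered.iterrows():
            d = np.hypot(centers[:, 0] - row["x"], centers[:, 1] - row["y"])
            true_t = truth[int(np.argmin(d))]
            if np.isnan(row["death_time"]):
                assert not (true_t <= sample_times[-1])
            else:
                # recovered at the first sampling point after the true death
                assert 0 <= row["death_time"] - true_t <= 250.0


class TestImageQuality:
    def test_snr_definitional(self, rng):
        mito = np.full(100, 50.0)
        bg = rng.normal(0, 5.0, 20000)
        q = image_quality(mito, bg)
        assert q.snr == pytest.approx(50.0 / bg.std(), rel=1e-9)
        assert q.snr == pytest.approx(10.0, rel=0.05)

    def test_equal_regions_zero_contrast(self, rng):
        vals = rng.normal(10, 1, 5000)
        q = image_quality(vals, vals)
        assert q.contrast == pytest.approx(0.0, abs=1e-12)
        assert q.intensity_ratio == pytest.approx(1.0)

    def test_zero_variance_background_errors(self):
        with pytest.raises(ValueError):
            image_quality([1.0, 2.0], [5.0, 5.0])

    def test_snr_halves_when_noise_doubles(self, small_sample, small_config):
        from dataclasses import replace
        from edamic.synthsample import render_fluorescence_frame, rasterize_tube
        state = small_sample[0].states[0]
        shape = (small_config.height, small_config.width)
        from scipy.ndimage import binary_dilation
        mito_mask = np.zeros(shape, bool)
        for tube in state.tubes:
            mito_mask |= rasterize_tube(shape, tube)
        # background well away from structures (avoid PSF bleed at edges)
        far_bg = ~binary_dilation(mito_mask, iterations=6)
        snrs = []
        for factor in (1.0, 2.0):
            cfg = replace(small_config, noise_sd=0.05 * factor)
            rng = np.random.default_rng(0)
            frame = render_fluorescence_frame(state, "mito_fluo", cfg, rng=rng)
            bg = frame[far_bg]
            q = image_quality(frame[mito_mask], bg)
            snrs.append(q.snr)
        assert snrs[0] / snrs[1] == pytest.approx(2.0, rel=0.10)


class TestDrp1:
    def test_equal_tips_ratio_one(self):
        frame = np.full((32, 32), 100.0)
        frame[10:13, 10:13] += 50.0
        frame[10:13, 20:23] += 50.0
        pair = TipPair((11, 11), (21, 11), camera_offset=100.0)
        assert drp1_tip_ratio(frame, pair) == pytest.approx(1.0)

    def test_two_to_one(self):
        frame = np.full((32, 32), 100.0)
        frame[10:13, 10:13] += 20.0   # sum above offset: 180
        frame[10:13, 20:23] += 10.0   # 90
        pair = TipPair((11, 11), (21, 11), camera_offset=100.0)
        assert drp1_tip_ratio(frame, pair) == pytest.approx(2.0)

    def test_swap_invariance_and_ge_one(self, rng):
        frame = rng.uniform(100, 300, (32, 32))
        a = drp1_tip_ratio(frame, TipPair((8, 8), (20, 20), 100.0))
        b = drp1_tip_ratio(frame, TipPair((20, 20), (8, 8), 100.0))
        assert a == b and a >= 1.0

    def test_zero_lower_is_infinite(self):
        frame = np.full((32, 32), 100.0)
        frame[10:13, 10:13] += 50.0
        pair = TipPair((11, 11), (21, 11), camera_offset=100.0)
        with pytest.warns(UserWarning):
            assert drp1_tip_ratio(frame, pair) == np.inf

    def test_overlapping_rois_rejected(self):
        with pytest.raises(ValueError):
            TipPair((10, 10), (11, 11))

    def test_simulated_symmetric_split_ratio(self, division_sample,
                                             division_config):
        from dataclasses import replace
        from edamic.synthsample import render_fluorescence_frame
        sample, events = division_sample
        ev = [e for e in events if e.event_class == "division"][0]
        cfg = replace(division_config, noise_sd=0.0)
        t = ev.t_end + 2
        state = sample.states[t]
        frame = 100.0 + 1000.0 * render_fluorescence_frame(state, "drp1_fluo",
                                                           cfg)
        assert len(state.drp1_puncta) == 2
        (xa, ya, _), (xb, yb, _) = state.drp1_puncta
        pair = TipPair((xa, ya), (xb, yb), camera_offset=100.0 + 1000 * 0.02)
        ratio = drp1_tip_ratio(frame, pair)
        assert 1.0 <= ratio <= 1.5


def synthetic_tmre_movie(n_frames=50, shape=(64, 64), flicker=None):
    """Three well-separated drifting blobs; optional intensity dropout."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    centers = [(12.0, 12.0), (44.0, 14.0), (30.0, 48.0)]
    frames = np.zeros((n_frames,) + shape)
    for t in range(n_frames):
        for i, (cx, cy) in enumerate(centers):
            amp = 1.0
            if flicker and i == flicker["track"] and \
                    flicker["start"] <= t <= flicker["end"]:
                amp = flicker.get("amp", 0.1)
            dx = 2.0 * np.sin(0.1 * t + i)
            mask = (xx - cx - dx) ** 2 + (yy - cy) ** 2 <= 16.0
            frames[t][mask] = amp
    return frames + 0.02


class TestTmre:
    def test_track_count_and_stability(self):
        movie = synthetic_tmre_movie()
        tracks = tmre_track_classify(movie, (12, 12), 25, pixel_size=0.1)
        long_tracks = [tr for tr in tracks if len(tr.frames) >= 45]
        assert len(long_tracks) == 3

    def test_contact_classification_by_distance(self):
        movie = synthetic_tmre_movie()
        tracks = tmre_track_classify(movie, (12.0, 12.0), 25, pixel_size=0.1)
        by_pos = {tuple(np.round(tr.centroids[0])): tr
                  for tr in tracks if len(tr.frames) >= 45}
        flags = {k: tr.contact_positive for k, tr in by_pos.items()}
        near = [v for k, v in flags.items() if np.hypot(k[0] - 12, k[1] - 12) < 8]
        far = [v for k, v in flags.items() if np.hypot(k[0] - 12, k[1] - 12) > 20]
        assert all(near) and not any(far)

    def test_track_30px_away_is_negative(self):
        movie = synthetic_tmre_movie()
        # 30 px at 0.1 um/px = 3 um > 1.5 um
        tracks = tmre_track_classify(movie, (44.0 - 30.0, 14.0), 25,
                                     pixel_size=0.1)
        tr = [t_ for t_ in tracks
              if len(t_.frames) >= 45 and abs(t_.centroids[0][1] - 14) < 6
              and t_.centroids[0][0] > 35]
        assert tr and not tr[0].contact_positive

    def test_flicker_recovered_within_one_frame(self):
        flicker = {"track": 2, "start": 30, "end": 32, "amp": 0.3}
        movie = synthetic_tmre_movie(n_frames=60, flicker=flicker)
        tracks = tmre_track_classify(movie, (30, 48), 10, pixel_size=0.1)
        tr = max(tracks, key=lambda t_: len(t_.frames))
        target = [t_ for t_ in tracks if len(t_.frames) >= 55
                  and t_.centroids[0][1] > 40]
        series = np.asarray(target[0].mean_intensity)
        spans = detect_flicker(series, n_sd=3.0, baseline_window=20)
        assert len(spans) == 1
        start, end = spans[0]
        assert abs(start - 30) <= 1 and abs(end - 32) <= 1

    def test_empty_movie_errors(self):
        with pytest.raises(ValueError):
            tmre_track_classify(np.zeros((4, 4)), (0, 0), 0)
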