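import numpy as np
import pytest
from scipy.ndimage import label as cc_label

from edamic.synthsample import (
    EndOfAcquisition,
    ExposureSpec,
    SimConfig,
    VirtualMicroscope,
    apply_exposure,
    correlative_spec,
    rasterize_tube,
    render_fluorescence_frame,
    render_phase_frame,
    schedule_events,
    simulate_sample,
    surveillance_spec,
    tube_sphere_boundary_distance,
)
from edamic.synthsample.types import CellSample, SampleState


class TestSimConfig:
    def test_defaults_valid(self):
        cfg = SimConfig()
        assert cfg.n_frames == 600

    @pytest.mark.parametrize("field,value", [
        ("height", 0), ("frame_rate", -1.0), ("duration", 0.0),
        ("pixel_size", -0.1), ("contact_duration", 0.0),
    ])
    def test_rejects_nonpositive(self, field, value):
        with pytest.raises(ValueError):
            SimConfig(**{field: value})

    def test_event_must_span_one_frame(self):
        with pytest.raises(ValueError):
            SimConfig(contact_duration=0.5, frame_rate=1.0)

    def test_roundtrip_and_unknown_keys(self):
        cfg = SimConfig(seed=5)
        assert SimConfig.from_dict(cfg.to_dict()) == cfg
        with pytest.raises(ValueError, match="unknown"):
            SimConfig.from_dict({"bogus": 1})


class TestScheduleEvents:
    def test_zero_rate_gives_no_contacts(self):
        cfg = SimConfig(contact_rate=0.0, division_rate=0.0, duration=600)
        assert schedule_events(cfg, 1) == []

    def test_mean_interval_matches_rate(self):
        # rate 1/3.1 per min over a long movie: mean gap ~ 186 s
        cfg = SimConfig(contact_rate=1 / 3.1, duration=3.1 * 60 * 400,
                        n_mito=2, n_spheres=2)
        gaps = []
        for seed in range(5):
            evs = schedule_events(cfg, seed)
            starts = np.array([e.t_start for e in evs if e.event_class == "contact"])
            gaps.extend(np.diff(starts))
        assert abs(np.mean(gaps) - 186.0) < 10.0

    def test_poisson_count_within_3_se(self):
        # rate 2/min, 60 min -> mean 120, SE over 200 seeds = sqrt(120/200)
        cfg = SimConfig(contact_rate=2.0, duration=3600.0)
        counts = [len(schedule_events(cfg, s)) for s in range(200)]
        se = np.sqrt(120.0 / 200)
        assert abs(np.mean(counts) - 120.0) < 3 * se

    def test_events_inside_movie(self):
        cfg = SimConfig(duration=300, contact_rate=3.0, division_rate=2.0)
        for ev in schedule_events(cfg, 7):
            assert 0 <= ev.t_start <= ev.t_end < cfg.n_frames

    def test_deterministic(self):
        cfg = SimConfig(contact_rate=2.0, division_rate=1.0, duration=600)
        assert schedule_events(cfg, 3) == schedule_events(cfg, 3)

    def test_too_short_movie_empty(self):
        cfg = SimConfig(duration=5.0, contact_duration=20.0, contact_rate=50.0)
        assert schedule_events(cfg, 0) == []


class TestSimulateSample:
    def test_determinism(self, small_config, small_sample):
        sample, events = small_sample
        sample2, events2 = simulate_sample(small_config)
        assert events == events2
        for s1, s2 in zip(sample.states, sample2.states):
            for t1, t2 in zip(s1.tubes, s2.tubes):
                np.testing.assert_array_equal(t1.points, t2.points)

    def test_different_seeds_differ(self, small_config):
        from dataclasses import replace
        s1, _ = simulate_sample(small_config)
        s2, _ = simulate_sample(replace(small_config, seed=small_config.seed + 1))
        assert not np.allclose(s1.states[0].tubes[0].points,
                               s2.states[0].tubes[0].points)

    def test_contact_touching_for_at_least_three_frames(self, small_sample):
        sample, events = small_sample
        contacts = [e for e in events if e.event_class == "contact"]
        assert contacts, "fixture should realize at least one contact"
        for ev in contacts:
            dists = [tube_sphere_boundary_distance(sample.states[t])
                     for t in range(ev.t_start, ev.t_end + 1)]
            touching = [d <= 1e-6 for d in dists]
            # no visible separation for at least three consecutive frames
            run = best = 0
            for flag in touching:
                run = run + 1 if flag else 0
                best = max(best, run)
            assert best >= 3

    def test_no_touching_outside_events(self, small_sample):
        sample, events = small_sample
        active = set()
        for ev in events:
            if ev.polarity == "positive" and ev.event_class == "contact":
                active.update(range(ev.t_start - 4, ev.t_end + 2))
        for t in range(0, len(sample.states), 7):
            if t not in active:
                assert tube_sphere_boundary_distance(sample.states[t]) > 0.2

    def test_division_splits_component(self, division_sample):
        sample, events = division_sample
        divisions = [e for e in events if e.event_class == "division"]
        assert divisions, "fixture should realize at least one division"
        ev = divisions[0]
        before = sample.states[ev.t_end]
        after = sample.states[ev.t_end + 1]
        assert len(after.tubes) == len(before.tubes) + 1

        def tube_dist(tube):
            return np.min(np.hypot(tube.points[:, 0] - ev.x,
                                   tube.points[:, 1] - ev.y))

        def mask_of(tubes):
            mask = np.zeros((64, 64), bool)
            for tube in tubes:
                mask |= rasterize_tube((64, 64), tube)
            return mask

        # the affected tube alone: one component before, two daughters after
        parent = min(before.tubes, key=tube_dist)
        daughters = sorted(after.tubes, key=tube_dist)[:2]
        assert cc_label(mask_of([parent]))[1] == 1
        assert cc_label(mask_of(daughters))[1] == 2

    def test_ruffles_persist(self, small_sample):
        sample, _ = small_sample
        first, last = sample.states[0], sample.states[-1]
        assert len(first.ruffles) == len(last.ruffles) == 1
        np.testing.assert_array_equal(first.ruffles[0].points,
                                      last.ruffles[0].points)

    def test_ruffles_pinch_and_recover(self, small_sample):
        sample, _ = small_sample
        factors = [st.ruffles[0].constriction_factor for st in sample.states]
        assert min(factors) < 0.5 < max(factors)  # cycles, never separates

    def test_overcrowded_field_rejected(self):
        with pytest.raises(ValueError, match="fits"):
            simulate_sample(SimConfig(height=32, width=32, n_mito=50,
                                      n_spheres=50, duration=10))


class TestRenderPhase:
    def test_no_halo_no_noise_max_is_background(self, small_sample, small_config):
        from dataclasses import replace
        cfg = replace(small_config, halo_gain=0.0, noise_sd=0.0)
        frame = render_phase_frame(small_sample[0].states[0], cfg)
        assert frame.max() <= 1.0 + 1e-9
        assert frame.min() < 1.0  # organelles absorb

    def test_noiseless_render_deterministic(self, small_sample, small_config):
        from dataclasses import replace
        cfg = replace(small_config, noise_sd=0.0)
        state = small_sample[0].states[3]
        np.testing.assert_array_equal(render_phase_frame(state, cfg),
                                      render_phase_frame(state, cfg))

    def test_contrast_monotone_in_absorption(self, small_sample, small_config):
        from dataclasses import replace
        state = small_sample[0].states[0]
        shape = (small_config.height, small_config.width)
        organelles = np.zeros(shape, bool)
        for tube in state.tubes:
            organelles |= rasterize_tube(shape, tube)
        contrasts = []
        for absorption in [0.1, 0.2, 0.3, 0.4, 0.5]:
            cfg = replace(small_config, absorption=absorption,
                          noise_sd=0.0, halo_gain=0.0)
            frame = render_phase_frame(state, cfg)
            bg = frame[~organelles].mean()
            contrasts.append(abs(frame[organelles].mean() - bg) / bg)
        assert all(b > a for a, b in zip(contrasts, contrasts[1:]))

    def test_frames_nonnegative_finite(self, small_sample, small_config):
        frame = render_phase_frame(small_sample[0].states[0], small_config)
        assert np.isfinite(frame).all() and (frame >= 0).all()


class TestRenderFluorescence:
    def test_unknown_channel_errors(self, small_sample, small_config):
        with pytest.raises(ValueError):
            render_fluorescence_frame(small_sample[0].states[0], "phase",
                                      small_config)
        with pytest.raises(ValueError):
            render_fluorescence_frame(small_sample[0].states[0], "nope",
                                      small_config)

    def test_zero_pool_is_noise_floor(self, small_sample, small_config):
        from dataclasses import replace
        cfg = replace(small_config, noise_sd=0.0)
        frame = render_fluorescence_frame(small_sample[0].states[0],
                                          "mito_fluo", cfg, pool=0.0)
        assert frame.max() <= 0.02 + 1e-9

    def test_drp1_two_maxima_after_division(self, division_sample,
                                            division_config):
        from dataclasses import replace
        from skimage.feature import peak_local_max
        sample, events = division_sample
        ev = [e for e in events if e.event_class == "division"][0]
        cfg = replace(division_config, noise_sd=0.0)
        frame = render_fluorescence_frame(sample.states[ev.t_end + 2],
                                          "drp1_fluo", cfg)
        peaks = peak_local_max(frame, min_distance=2, threshold_abs=0.1)
        near = [(r, c) for r, c in peaks
                if np.hypot(c - ev.x, r - ev.y) <= 10]
        assert len(near) == 2

    def test_tmre_dropout_durations_one_to_three_seconds(self):
        cfg = SimConfig(height=64, width=64, duration=1200, n_mito=3,
                        n_spheres=0, contact_rate=0.0, n_ruffles=0, seed=2)
        sample, _ = simulate_sample(cfg)
        durations = []
        current = {}
        for t, state in enumerate(sample.states):
            for i, tube in enumerate(state.tubes):
                dark = tube.tmre_dark_span is not None
                if dark and i not in current:
                    current[i] = t
                elif not dark and i in current:
                    durations.append(t - current.pop(i))
        assert durations, "expected some flicker events"
        assert all(1.0 <= d / cfg.frame_rate <= 3.0 + 1e-9 for d in durations)


class TestExposure:
    def test_negative_exposure_errors(self):
        with pytest.raises(ValueError):
            ExposureSpec("surveillance", ("phase",), exposure_time=-1.0)

    def test_modality_channel_invariants(self):
        with pytest.raises(ValueError):
            ExposureSpec("surveillance", ("phase", "mito_fluo"))
        with pytest.raises(ValueError):
            ExposureSpec("correlative", ("phase",))

    def test_zero_hazard_immortal(self, rng):
        sample = CellSample(states=[SampleState([], [], [])], frame_rate=1.0,
                            pixel_size=0.1)
        for _ in range(1000):
            apply_exposure(sample, correlative_spec(["mito_fluo"]),
                           hazard_coeff=0.0, rng=rng)
        assert sample.alive

    def test_monte_carlo_half_life_matches_closed_form(self):
        # constant per-frame fluorescence hazard h: S(t) ~= exp(-h t), so
        # the mean lifetime estimates 1/h and half-life = ln2 x mean
        from edamic.synthsample.toxicity import ToxicityCohort
        cohort = ToxicityCohort(500, "fluorescence", duration=36000.0,
                                seed=4)
        p = cohort.per_frame_death_prob
        times = cohort.death_times()
        expected_half = np.log(2) / p  # frames == seconds at 1 Hz
        observed_half = np.log(2) * np.mean(times[np.isfinite(times)])
        assert abs(observed_half - expected_half) / expected_half < 0.10

    def test_phase_mortality_100x_below_fluorescence(self):
        from edamic.synthsample.toxicity import ToxicityCohort
        frames = 300  # identical frame counts
        mort = {}
        for cond in ("fluorescence", "phase"):
            cohort = ToxicityCohort(1, cond, seed=0)
            p = cohort.per_frame_death_prob
            mort[cond] = 1.0 - (1.0 - p) ** frames
        assert mort["phase"] <= mort["fluorescence"] / 100.0

    def test_bleaching_only_on_fluorescence(self, rng):
        sample = CellSample(states=[SampleState([], [], [])], frame_rate=1.0,
                            pixel_size=0.1)
        apply_exposure(sample, surveillance_spec(), bleach_rate=0.01, rng=rng)
        assert sample.fluorophore_pool["mito_fluo"] == 1.0
        apply_exposure(sample, correlative_spec(["mito_fluo"]),
                       bleach_rate=0.01, rng=rng)
        assert sample.fluorophore_pool["mito_fluo"] == pytest.approx(0.99)

    def test_dose_monotone_and_ledger_replay(self, rng):
        sample = CellSample(states=[SampleState([], [], [])], frame_rate=1.0,
                            pixel_size=0.1)
        for i in range(50):
            spec = (surveillance_spec() if i % 2 else
                    correlative_spec(["mito_fluo", "ld_fluo"]))
            apply_exposure(sample, spec, rng=rng)
        assert sample.accumulated_dose == pytest.approx(sum(sample.dose_ledger))
        assert all(d >= 0 for d in sample.dose_ledger)


class TestVirtualMicroscope:
    def test_surveillance_one_frame(self, small_sample, small_config):
        sample, _ = simulate_sample(small_config)
        scope = VirtualMicroscope(sample, small_config)
        frames = scope.acquire(0, surveillance_spec())
        assert set(frames) == {"phase"}

    def test_correlative_three_frames_dose_two_channels(self, small_config):
        sample, _ = simulate_sample(small_config)
        scope = VirtualMicroscope(sample, small_config)
        spec = correlative_spec(["mito_fluo", "ld_fluo"])
        frames = scope.acquire(0, spec)
        assert set(frames) == {"phase", "mito_fluo", "ld_fluo"}
        per_channel = spec.irradiance * spec.exposure_time
        expected = per_channel * (2 + small_config.phase_dose_factor)
        assert sample.accumulated_dose == pytest.approx(expected)

    def test_surveillance_never_bleaches(self, small_config):
        sample, _ = simulate_sample(small_config)
        scope = VirtualMicroscope(sample, small_config)
        for t in range(100):
            scope.acquire(t, surveillance_spec())
        assert all(v == 1.0 for v in sample.fluorophore_pool.values())

    def test_end_of_acquisition(self, small_config):
        sample, _ = simulate_sample(small_config)
        scope = VirtualMicroscope(sample, small_config)
        with pytest.raises(EndOfAcquisition):
            scope.acquire(sample.n_frames, surveillance_spec())

    def test_acquire_deterministic_per_frame(self, small_config):
        s1, _ = simulate_sample(small_config)
        s2, _ = simulate_sample(small_config)
        f1 = VirtualMicroscope(s1, small_config).acquire(3, surveillance_spec())
        f2 = VirtualMicroscope(s2, small_config).acquire(3, surveillance_spec())
        np.testing.assert_array_equal(f1["phase"], f2["phase"])
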