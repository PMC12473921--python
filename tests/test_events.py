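import numpy as np
import pytest

from lumbargait import (
    GaitEvent,
    Roi,
    TuningError,
    ValidationError,
    assign_sides,
    detect_events,
    find_rois,
    preprocess_segment,
    tune_filter_parameters,
)

FS = 128.0


class TestPreprocessSegment:
    def test_constant_segment_maps_to_zero(self):
        y = preprocess_segment(np.full(1200, 9.81), FS)
        assert np.max(np.abs(y)) < 1e-6

    def test_segment_shorter_than_frame_rejected(self):
        from lumbargait import ParameterError

        with pytest.raises(ParameterError):
            preprocess_segment(np.zeros(500), FS)

    def test_one_lobe_pair_per_step_on_steady_gait(self, sim_clean):
        # the cascade must reduce each step to one positive and one
        # negative lobe, i.e. about two sign runs per step period
        cfg, rec, truth = sim_clean
        a, b = truth.walk_intervals[3]
        events = [
            t
            for t in np.concatenate([truth.hs_times, truth.to_times])
            if a <= t <= b
        ]
        lo, hi = min(events) - 0.25, max(events) + 0.25  # the stepping span
        seg = rec.acc_ap[int(lo * rec.fs) : int(hi * rec.fs)]
        f = preprocess_segment(seg, rec.fs)
        rois = find_rois(f)
        polarities = [r.polarity for r in rois]
        # strict alternation by construction
        assert all(p != q for p, q in zip(polarities, polarities[1:]))
        n_steps = cfg.n_steps_per_pass
        assert 2 * (n_steps - 2) <= len(rois) <= 2 * n_steps + 1

    def test_output_invariant_to_constant_offset(self, sim_clean):
        # the band-pass removes DC, so detection cannot depend on a bias
        cfg, rec, truth = sim_clean
        a, b = truth.walk_intervals[0]
        seg = rec.acc_ap[int(a * rec.fs) : int(b * rec.fs)]
        f0 = preprocess_segment(seg, rec.fs)
        f1 = preprocess_segment(seg + 9.81, rec.fs)
        np.testing.assert_allclose(f0, f1, atol=1e-8)


class TestFindRois:
    def test_shifted_sine_interior_runs(self):
        # sin(2 pi (t + 1/4)) over three periods: 7 sign runs, the two
        # boundary-touching ones discarded leaves 5, alternating polarity
        t = np.arange(0.0, 3.0, 1e-3)
        f = np.sin(2 * np.pi * (t + 0.25))
        rois = find_rois(f)
        assert len(rois) == 5
        assert [r.polarity for r in rois] == [
            "negative", "positive", "negative", "positive", "negative",
        ]

    def test_strictly_positive_signal_has_no_interior_runs(self):
        assert find_rois(np.ones(100)) == []

    def test_matches_brute_force_sign_run_oracle(self):
        rng = np.random.default_rng(4)
        # smooth random signal with plenty of zero crossings
        x = np.convolve(rng.normal(size=500), np.ones(25) / 25, mode="same")
        rois = find_rois(x)
        # elementwise oracle: zeros attach to the following sample's sign
        signs = np.sign(x).astype(int)
        for i in range(len(signs) - 2, -1, -1):
            if signs[i] == 0:
                signs[i] = signs[i + 1]
        for i in range(len(signs) - 1):
            if signs[i + 1] == 0:
                signs[i + 1] = signs[i]
        runs = []
        start = 0
        for i in range(1, len(signs) + 1):
            if i == len(signs) or signs[i] != signs[start]:
                runs.append((start, i, signs[start]))
                start = i
        expected = [
            Roi(a, b, "positive" if s > 0 else "negative")
            for a, b, s in runs[1:-1]
        ]
        assert rois == expected

    def test_exact_zeros_attach_to_following_run(self):
        f = np.array([1.0, 1.0, 0.0, 0.0, -1.0, -1.0, 1.0, 1.0, -1.0])
        rois = find_rois(f)
        # zeros at 2,3 belong to the negative run [2, 6)
        assert rois[0] == Roi(2, 6, "negative")


class TestDetectEvents:
    def test_argmax_argmin_within_rois(self):
        raw = np.array([0, 1, 3, 1, 0, -1, -4, -1, 0, 2, 5, 2.0])
        rois = [Roi(0, 5, "positive"), Roi(5, 9, "negative"), Roi(9, 12, "positive")]
        events = detect_events(raw, rois, fs=1.0, t0=0.0)
        assert [(e.time, e.kind) for e in events] == [
            (2.0, "heel_strike"),
            (6.0, "toe_off"),
            (10.0, "heel_strike"),
        ]

    def test_no_rois_no_events(self):
        assert detect_events(np.zeros(10), [], fs=1.0) == []

    def test_flat_roi_ties_take_earliest_sample(self):
        raw = np.array([2.0, 2.0, 2.0, 2.0, -1.0, -1.0, -1.0, 3.0, 2.0])
        rois = [Roi(0, 4, "positive"), Roi(4, 7, "negative"), Roi(7, 9, "positive")]
        events = detect_events(raw, rois, fs=1.0)
        assert events[0].time == 0.0
        assert events[1].time == 4.0

    def test_trims_to_start_and_end_with_heel_strike(self):
        raw = np.array([-2.0, -1.0, 1.0, 3.0, 1.0, -1.0, -4.0, -1.0])
        rois = [Roi(0, 2, "negative"), Roi(2, 5, "positive"), Roi(5, 8, "negative")]
        events = detect_events(raw, rois, fs=1.0)
        assert [e.kind for e in events] == ["heel_strike"]
        assert events[0].time == 3.0

    def test_timing_recovery_on_simulated_walk(self, sim_default, pipeline_default):
        # >= 95% of interior ground-truth events matched within 3 samples
        from lumbargait import interior_truth_times, match_events

        cfg, rec, truth = sim_default
        res = pipeline_default
        det_hs = [e.time for e in res.events if e.kind == "heel_strike"]
        det_to = [e.time for e in res.events if e.kind == "toe_off"]
        total = matched = 0
        errors = []
        for truth_times, det in [(truth.hs_times, det_hs), (truth.to_times, det_to)]:
            interior = interior_truth_times(truth_times, res.segments, rec.fs, cfg.gct)
            m = match_events(interior, det, rec.fs, tol_samples=3.0)
            total += m.n_truth
            matched += m.n_matched
            errors.extend(m.errors_samples)
        assert total > 150
        assert matched / total >= 0.95
        assert np.median(errors) <= 2.0

    def test_detected_stride_time_matches_simulated_period(self, sim_default, pipeline_default):
        cfg, _, _ = sim_default
        res = pipeline_default
        assert res.summary.gct_s == pytest.approx(cfg.gct, rel=0.01)


class TestAssignSides:
    def test_alternation_rule(self):
        events = [
            GaitEvent(0.0, "heel_strike"),
            GaitEvent(0.1, "toe_off"),
            GaitEvent(0.5, "heel_strike"),
            GaitEvent(0.6, "toe_off"),
            GaitEvent(1.0, "heel_strike"),
        ]
        sides = [e.side for e in assign_sides(events, "right")]
        assert sides == ["right", "left", "left", "right", "right"]

    def test_empty_list(self):
        assert assign_sides([], "right") == []

    def test_non_alternating_kinds_rejected(self):
        events = [
            GaitEvent(0.0, "heel_strike"),
            GaitEvent(0.5, "heel_strike"),
        ]
        with pytest.raises(ValidationError):
            assign_sides(events, "right")

    def test_first_side_choice_does_not_move_summary(self, sim_default):
        from lumbargait import RunConfig, run_pipeline

        _, rec, _ = sim_default
        left = run_pipeline(rec, RunConfig(first_side="left")).summary
        right = run_pipeline(rec, RunConfig(first_side="right")).summary
        assert left == right


class TestTuneFilterParameters:
    def test_grid_of_only_defaults_returns_defaults(self, sim_default):
        _, rec, truth = sim_default
        a, b = truth.walk_intervals[1]
        seg = rec.acc_ap[int(a * rec.fs) : int(b * rec.fs)]
        assert tune_filter_parameters(seg, rec.fs, [(50, 801)]) == (50, 801)

    def test_winner_has_lowest_interval_cv(self, sim_default):
        from lumbargait import detect_events as de, find_rois as fr, preprocess_segment as pp

        _, rec, truth = sim_default
        a, b = truth.walk_intervals[1]
        seg = rec.acc_ap[int(a * rec.fs) : int(b * rec.fs)]
        grid = [(2, 801), (50, 801)]
        best = tune_filter_parameters(seg, rec.fs, grid)
        cvs = {}
        for polyorder, frame in grid:
            f = pp(seg, rec.fs, sg_polyorder=polyorder, sg_frame=frame)
            hs = [e.time for e in de(seg, fr(f), rec.fs) if e.kind == "heel_strike"]
            iv = np.diff(hs)
            cvs[(polyorder, frame)] = np.std(iv) / np.mean(iv)
        assert cvs[best] == min(cvs.values())

    def test_undetectable_segment_raises_tuning_error(self):
        # a flat segment produces no zero crossings, hence no heel-strikes
        with pytest.raises(TuningError):
            tune_filter_parameters(np.zeros(1000), FS, [(50, 801)])
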