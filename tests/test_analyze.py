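"""Trace analysis: angle conversion, segmentation, TD and sub-step detection."""

from __future__ import annotations

import numpy as np
import pytest

from fosubstep.analyze import (
    DegenerateTraceError,
    DetectionParams,
    analyze_trace,
    intensity_to_angle,
    match_events,
    measured_truth_tds,
    normalize_intensity,
    segment_power_strokes,
    smooth_angle,
    summarize_dataset,
    td_percent_histogram,
)
from fosubstep.models import eval_td_occurrence
from fosubstep.simulate import (
    IntensityTrace,
    KineticConfig,
    OpticsConfig,
    SynthaseStepModel,
    sample_rotor_trajectory,
    trajectory_to_intensity,
)

FS = 100_000.0
WINDOW_MAX = DetectionParams().td_angle_max_deg


class TestAngleConversion:
    def test_arcsine_round_trip_identity(self):
        theta = np.linspace(0.0, 90.0, 5001)
        back = intensity_to_angle(np.sin(np.deg2rad(theta)) ** 2)
        assert np.max(np.abs(back - theta)) < 1e-9

    @pytest.mark.parametrize("x, expected", [(0.0, 0.0), (1.0, 90.0), (0.5, 45.0)])
    def test_known_points(self, x, expected):
        assert intensity_to_angle(np.array([x]))[0] == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            intensity_to_angle(np.array([-0.01]))
        with pytest.raises(ValueError):
            intensity_to_angle(np.array([1.01]))


class TestNormalization:
    def test_constant_trace_is_degenerate(self):
        trace = IntensityTrace(np.full(10_000, 500.0), FS, ph=7.0)
        with pytest.raises(DegenerateTraceError):
            normalize_intensity(trace)

    def test_noise_only_trace_is_degenerate(self, rng):
        trace = IntensityTrace(500.0 + rng.normal(0, 15.0, 50_000), FS, ph=7.0)
        with pytest.raises(DegenerateTraceError):
            normalize_intensity(trace)

    def test_recovers_generating_optics(self, quiet_record):
        _, (i_lo, i_hi) = normalize_intensity(quiet_record["trace"])
        optics = quiet_record["optics"]
        span = optics.i_max - optics.i_min
        assert abs(i_lo - optics.i_min) <= 0.01 * span
        assert abs(i_hi - optics.i_max) <= 0.01 * span

    def test_output_clipped_to_unit_interval(self, noisy_cohort):
        norm, _ = normalize_intensity(noisy_cohort[0]["trace"])
        assert norm.min() >= 0.0 and norm.max() <= 1.0


class TestSegmentation:
    def test_monotone_sweep_is_one_segment(self):
        # a dwell at 0 deg followed by a single rise to 90
        angle = np.concatenate([np.zeros(80), np.linspace(0, 90, 100), np.full(20, 90.0)])
        segs = segment_power_strokes(smooth_angle(angle, 5), FS, angle_raw=angle)
        assert len(segs) == 1

    def test_flat_low_angles_give_no_segments(self, rng):
        angle = np.abs(rng.normal(0.0, 2.0, 30_000))
        segs = segment_power_strokes(smooth_angle(angle, 5), FS, angle_raw=angle)
        assert segs == []

    def test_recovers_simulated_stroke_count(self, noisy_cohort):
        for rec in noisy_cohort:
            n_meas = sum(1 for s in rec["traj"].strokes if s.measured)
            assert len(rec["segments"]) >= 0.93 * n_meas
            assert len(rec["segments"]) <= n_meas + 2


class TestDetection:
    def test_noise_free_sensitivity_and_fdr(self, quiet_record):
        truth60 = measured_truth_tds(quiet_record["traj"], WINDOW_MAX, min_duration_us=60.0)
        truth_all = measured_truth_tds(quiet_record["traj"], WINDOW_MAX, min_duration_us=0.0)
        events = quiet_record["events"]
        sens = len(match_events(truth60, events)) / len(truth60)
        fdr = 1.0 - len(match_events(truth_all, events)) / len(events)
        assert sens >= 0.95
        assert fdr <= 0.05

    def test_default_noise_sensitivity_and_fdr_pooled(self, noisy_cohort):
        n60 = hit60 = ndet = matched = 0
        for rec in noisy_cohort:
            truth60 = measured_truth_tds(rec["traj"], WINDOW_MAX, min_duration_us=60.0)
            truth_all = measured_truth_tds(rec["traj"], WINDOW_MAX, min_duration_us=0.0)
            n60 += len(truth60)
            hit60 += len(match_events(truth60, rec["events"]))
            ndet += len(rec["events"])
            matched += len(match_events(truth_all, rec["events"]))
        assert n60 > 1000
        assert hit60 / n60 >= 0.95
        assert 1.0 - matched / ndet <= 0.05

    def test_monotone_stroke_has_no_events(self, wt_kinetics):
        kin = KineticConfig(
            td_probability_model=type(wt_kinetics.td_probability_model)(0.0, 6.4, 6.75),
            synthase_model=wt_kinetics.synthase_model,
        )
        traj = sample_rotor_trajectory(kin, ph=7.0, duration=1.0, seed=4)
        trace = trajectory_to_intensity(traj, OpticsConfig(noise_sd=0.0), seed=4)
        _, events, _ = analyze_trace(trace)
        assert events == []

    def test_eleven_degree_backstep_measured(self, wt_kinetics):
        # every TD carries an 11-degree synthase-direction step exactly
        kin = KineticConfig(
            td_probability_model=wt_kinetics.td_probability_model,
            synthase_model=SynthaseStepModel(pka1=6.5, p1=0.0, pka2=7.7, p2=0.0),
            step_extent_mean_deg=11.0,
            step_extent_sd_deg=0.0,
            step_extent_min_deg=6.0,
        )
        traj = sample_rotor_trajectory(kin, ph=5.5, duration=3.0, seed=6)
        trace = trajectory_to_intensity(traj, OpticsConfig(noise_sd=0.0), seed=6)
        _, events, _ = analyze_trace(trace)
        truth = measured_truth_tds(traj, WINDOW_MAX, min_duration_us=30.0)
        pairs = match_events(truth, events)
        assert len(pairs) >= 0.9 * len(truth)
        flagged = [d for _, d in pairs if d.has_synthase_step]
        assert len(flagged) >= 0.9 * len(pairs)
        extents = np.array([d.cw_extent_deg for d in flagged])
        assert extents.mean() == pytest.approx(11.0, abs=0.5)

    def test_detected_duration_unbiased(self, noisy_cohort):
        diffs = []
        for rec in noisy_cohort:
            truth = measured_truth_tds(rec["traj"], WINDOW_MAX, min_duration_us=30.0)
            for t, d in match_events(truth, rec["events"]):
                diffs.append(d.duration_us - t.duration_us)
        diffs = np.asarray(diffs)
        assert diffs.size > 1500
        assert abs(diffs.mean()) <= 5.0  # half a sample at 100 kHz

    def test_mean_detected_spacing(self, noisy_cohort):
        spacings = [s for rec in noisy_cohort for s in rec["summary"].td_spacings_deg]
        assert len(spacings) >= 1000
        assert np.mean(spacings) == pytest.approx(36.0, abs=1.0)

    def test_event_invariants(self, noisy_cohort):
        params = DetectionParams()
        for rec in noisy_cohort:
            for ev in rec["events"]:
                assert ev.duration_us >= params.min_dwell_us
                assert ev.cw_extent_deg >= 0.0
                if ev.has_synthase_step:
                    assert ev.cw_extent_deg >= params.step_threshold_deg
                assert 0.0 < ev.onset_angle_deg < 90.0
                assert ev.oscillation_count >= 0


class TestSummaries:
    def test_percent_limits(self, noisy_cohort):
        import dataclasses

        segments = noisy_cohort[0]["segments"]
        assert summarize_dataset(segments, []).percent_with_td == 0.0
        events = noisy_cohort[0]["events"]
        covered = sorted({e.segment_index for e in events})
        only_covered = [segments[i] for i in covered]
        reindexed = [
            dataclasses.replace(e, segment_index=covered.index(e.segment_index))
            for e in events
        ]
        assert summarize_dataset(only_covered, reindexed).percent_with_td == 100.0

    def test_occurrence_tracks_generating_curve(self, wt_kinetics, default_optics):
        # single efficiency class, so the dataset percent follows the curve;
        # the oracle accounts for TDs shorter than the 30-us detection floor
        # (the generator's windowed occurrence itself equals the curve)
        kin = KineticConfig(
            td_probability_model=wt_kinetics.td_probability_model,
            synthase_model=wt_kinetics.synthase_model,
            efficiency_multipliers=(1.0, 1.0, 1.0),
        )
        percents, strokes = [], 0
        for seed in (2, 8, 15):
            traj = sample_rotor_trajectory(kin, ph=6.0, duration=5.0, seed=seed)
            trace = trajectory_to_intensity(traj, default_optics, seed=seed + 50)
            _, _, summary = analyze_trace(trace)
            percents.append(summary.percent_with_td * summary.n_power_strokes)
            strokes += summary.n_power_strokes
        observed = sum(percents) / strokes
        model = wt_kinetics.td_probability_model
        t6 = eval_td_occurrence(model, 6.0)
        p = t6 / model.t_saturating
        q1 = 2 * p * (1 - p) / (1 - (1 - p) ** 2)  # one in-window TD
        q2 = p * p / (1 - (1 - p) ** 2)            # both in-window sites
        floor = 1.0 - np.exp(-30.0 / 150.0)        # TD below detection floor
        expected = t6 * (1.0 - q1 * floor - q2 * floor**2)
        assert observed == pytest.approx(expected, abs=3.0)

    def test_histogram_binning(self):
        from fosubstep.analyze import DatasetSummary

        def _summary(p):
            return DatasetSummary(n_power_strokes=100, percent_with_td=p)

        counts, edges = td_percent_histogram([_summary(0.0)])
        assert counts[0] == 1 and counts.sum() == 1
        counts, _ = td_percent_histogram([_summary(5), _summary(15), _summary(25)])
        assert list(counts[:3]) == [1, 1, 1]
        counts, _ = td_percent_histogram([_summary(100.0)])
        assert counts[-1] == 1  # top bin is closed
        assert len(edges) == 11
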