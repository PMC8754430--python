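"""Intensity-trace analysis: angles, power strokes, transient dwells, sub-steps.

The measurement chain inverts the optics and segments the time series:

1. `normalize_intensity` calibrates the polarizer minimum/maximum from
   robust quantiles of the trace and maps intensities to [0, 1];
2. `intensity_to_angle` applies the arcsine-square-root transform,
   theta = (180/pi) * arcsin(sqrt(I_norm)), onto [0, 90] degrees;
3. `segment_power_strokes` finds catalytic dwells (sustained low-angle
   epochs) and carves out the 0-to-90-degree sweep that follows each;
4. `detect_transient_dwells` finds epochs inside a sweep where CCW
   progress stalls or reverses, measures their duration, onset angle and
   maximal clockwise (synthase-direction) excursion, and classifies
   back-steps;
5. `summarize_dataset` reduces one data set to the per-record statistics
   the titrations are built from (percent of strokes with TDs, spacings,
   durations, step extents).

Sub-sample timing conventions: onset/offset edges are refined against a
band around the stall plateau so that event durations and onset angles
are unbiased on average at 10-us sampling (the half-sample phase of a
stall edge relative to the grid is marginalized by construction). These
estimators are exercised against simulator ground truth in the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .simulate import IntensityTrace, AnnotatedTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateTraceError",
    "DetectionParams",
    "PowerStrokeSegment",
    "TransientDwellEvent",
    "DatasetSummary",
    "normalize_intensity",
    "intensity_to_angle",
    "smooth_angle",
    "segment_power_strokes",
    "detect_transient_dwells",
    "analyze_trace",
    "summarize_dataset",
    "td_percent_histogram",
    "match_events",
    "measured_truth_tds",
]


class DegenerateTraceError(ValueError):
    """Raised when a trace has no usable dynamic range (no rotation signal)."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the segmentation and TD detector.

    Defaults assume 100 kHz sampling. ``smooth_window`` (samples) is the
    centered moving mean applied before velocity estimation: 5 samples =
    50 us, below the TD duration but above single-sample noise.
    ``velocity_frac`` sets the stall threshold as a fraction of the median
    power-stroke velocity of the trace, adapting to nanorod drag.
    ``step_threshold_deg`` classifies a TD as containing a
    synthase-direction step; 5 degrees sits below the smallest generated
    back-step (6 degrees) and above angle noise. ``band_halfwidth_deg``
    is the plateau band used for sub-sample edge refinement.
    """

    smooth_window: int = 5
    dwell_angle_max_deg: float = 5.0
    dwell_min_ms: float = 0.5
    dwell_merge_ms: float = 0.1
    segment_end_angle_deg: float = 85.0
    segment_end_smooth_deg: float = 80.0
    max_segment_ms: float = 2.0
    min_dwell_us: float = 30.0
    velocity_frac: float = 0.2
    step_threshold_deg: float = 5.0
    td_angle_min_deg: float = 15.0
    td_angle_max_deg: float = 76.0
    merge_gap_us: float = 40.0
    band_halfwidth_deg: float = 3.5
    quantile_low: float = 1.0
    quantile_high: float = 99.0


@dataclass
class PowerStrokeSegment:
    """One 0-to-90-degree sweep following a catalytic dwell (sample indices)."""

    start: int
    end: int
    dwell_start: int
    dwell_end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("segment start must precede end")


@dataclass
class TransientDwellEvent:
    """One detected transient dwell within a power-stroke segment."""

    segment_index: int
    onset_time_s: float
    onset_angle_deg: float
    duration_us: float
    cw_extent_deg: float
    has_synthase_step: bool
    oscillation_count: int = 0

    def __post_init__(self):
        if self.duration_us <= 0:
            raise ValueError("duration must be positive")
        if self.cw_extent_deg < 0:
            raise ValueError("cw_extent must be >= 0")
        if self.has_synthase_step and self.cw_extent_deg <= 0:
            raise ValueError("synthase step implies positive CW extent")


@dataclass
class DatasetSummary:
    """Per-data-set statistics feeding the pH titrations."""

    n_power_strokes: int
    percent_with_td: float
    td_spacings_deg: list[float] = field(default_factory=list)
    td_durations_us: list[float] = field(default_factory=list)
    percent_td_with_step: float = float("nan")
    step_extents_deg: list[float] = field(default_factory=list)
    n_tds: int = 0

    def __post_init__(self):
        if not 0.0 <= self.percent_with_td <= 100.0:
            raise ValueError("percent_with_td must lie in [0, 100]")


# ---------------------------------------------------------------------------
# intensity -> angle
# ---------------------------------------------------------------------------

def normalize_intensity(
    trace: IntensityTrace,
    quantile_low: float = 1.0,
    quantile_high: float = 99.0,
    refine: bool = True,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Map intensities onto [0, 1] with robust calibration of the optics.

    Rough bounds come from the 1st/99th percentiles; because the arcsine
    transform has unbounded leverage at its ends, the polarizer minimum
    and maximum are then refined to the *centers* of the extreme intensity
    clusters rather than noise-tail quantiles: ``i_min`` as the median of
    the low-intensity band (dominated by the catalytic dwell the polarizer
    was nulled on) and ``i_max`` as a high quantile of the noise-smoothed
    trace (the slow sin^2 turnover near 90 degrees). Values outside the
    calibrated range are clipped. Raises `DegenerateTraceError` when the
    dynamic range is indistinguishable from the noise floor (no rotating
    nanorod in view).
    """
    x = trace.intensity
    lo0, hi0 = np.percentile(x, [quantile_low, quantile_high])
    rng0 = hi0 - lo0
    # sample-to-sample MAD estimate of the noise floor
    noise = 1.4826 * float(np.median(np.abs(np.diff(x)))) / np.sqrt(2.0)
    if rng0 <= 0 or rng0 < 5.0 * noise:
        raise DegenerateTraceError(
            f"intensity range {rng0:.3g} below noise floor {noise:.3g}"
        )
    if refine:
        i_lo = float(np.median(x[x <= lo0 + 0.15 * rng0]))
        i_hi = float(np.percentile(smooth_angle(x, 5), 99.8))
    else:
        i_lo, i_hi = float(lo0), float(hi0)
    if i_hi <= i_lo:
        raise DegenerateTraceError("calibration collapsed: i_max <= i_min")
    norm = np.clip((x - i_lo) / (i_hi - i_lo), 0.0, 1.0)
    return norm, (i_lo, i_hi)


def intensity_to_angle(normalized: np.ndarray) -> np.ndarray:
    """Arcsine-square-root transform onto degrees in [0, 90].

    theta = (180/pi) * arcsin(sqrt(I_norm)); inputs must already be
    clipped to [0, 1].
    """
    x = np.asarray(normalized, dtype=float)
    if x.size and (np.nanmin(x) < 0.0 or np.nanmax(x) > 1.0):
        raise ValueError("normalized intensities must lie in [0, 1]; clip first")
    return np.degrees(np.arcsin(np.sqrt(x)))


def smooth_angle(angle: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving mean with edge-shrinking windows."""
    if window <= 1:
        return np.asarray(angle, float)
    kernel = np.ones(window) / window
    sm = np.convolve(angle, kernel, mode="same")
    # fix the shrunken edges explicitly
    half = window // 2
    n = len(angle)
    for i in range(min(half, n)):
        sm[i] = np.mean(angle[: i + half + 1])
        sm[n - 1 - i] = np.mean(angle[n - 1 - i - half :])
    return sm


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


def segment_power_strokes(
    angle_smooth: np.ndarray,
    sampling_rate: float,
    params: DetectionParams = DetectionParams(),
    angle_raw: np.ndarray | None = None,
) -> list[PowerStrokeSegment]:
    """Carve the measured 0-to-90-degree sweeps out of an angle series.

    Catalytic dwells are sustained epochs below ``dwell_angle_max_deg``
    lasting at least ``dwell_min_ms`` (a dwell truncated by the start of
    the record also qualifies). Each segment runs from the dwell exit to
    the first attainment of ``segment_end_angle_deg``; sweeps that never
    get there (stalled or truncated strokes) are discarded. The endpoint
    is found on the raw angle when given: at typical stroke velocities the
    rotor crosses the sin^2 reflection at 90 degrees within a couple of
    samples, so the smoothed series never reaches the top.
    """
    th = np.asarray(angle_smooth, float)
    th_raw = th if angle_raw is None else np.asarray(angle_raw, float)
    min_samples = max(1, int(round(params.dwell_min_ms * 1e-3 * sampling_rate)))
    merge_gap = max(1, int(round(params.dwell_merge_ms * 1e-3 * sampling_rate)))
    # low-angle runs; brief noise spikes (arcsine leverage at 0 deg) are bridged
    raw_runs = _runs(th < params.dwell_angle_max_deg)
    dwell_runs: list[list[int]] = []
    for s, e in raw_runs:
        if dwell_runs and s - dwell_runs[-1][1] <= merge_gap:
            dwell_runs[-1][1] = e
        else:
            dwell_runs.append([s, e])
    dwell_runs = [(s, e) for s, e in dwell_runs if (e - s + 1) >= min_samples or s == 0]
    if not dwell_runs:
        logger.warning("no qualifying catalytic dwell found; returning no segments")
        return []
    segments: list[PowerStrokeSegment] = []
    n = th.size
    max_len = int(round(params.max_segment_ms * 1e-3 * sampling_rate))
    for i, (ds, de) in enumerate(dwell_runs):
        start = de + 1
        if start >= n - 1:
            break
        stop_search = dwell_runs[i + 1][0] if i + 1 < len(dwell_runs) else n
        # the raw series catches the brief sin^2 crossing at 90 degrees; the
        # smoothed criterion backs it up when no raw sample lands on top
        window = slice(start, stop_search)
        above = np.flatnonzero(
            (th_raw[window] >= params.segment_end_angle_deg)
            | (th[window] >= params.segment_end_smooth_deg)
        )
        if above.size:
            end = start + int(above[0])
        else:
            # last resort: the reflected descent past 90 degrees. Once the
            # smoothed angle has exceeded any reachable TD site (>77 deg)
            # and then dropped by >10 deg, the sweep topped out at its
            # running maximum. CW back-steps never fire this (sites <= 72).
            seg_th = th[window]
            run_max = np.maximum.accumulate(seg_th)
            drop = np.flatnonzero((run_max >= 77.0) & (run_max - seg_th > 10.0))
            if drop.size == 0:
                continue
            end = start + int(np.argmax(seg_th[: drop[0] + 1]))
        if end - start > max_len:  # stalled / inhibited stroke
            continue
        segments.append(PowerStrokeSegment(start=start, end=end, dwell_start=ds, dwell_end=de))
    return segments


# ---------------------------------------------------------------------------
# transient-dwell detection
# ---------------------------------------------------------------------------

def _median_stroke_velocity(
    th_raw: np.ndarray, th: np.ndarray, segments: list[PowerStrokeSegment]
) -> float:
    """Median climb velocity (deg/sample) over segment interiors, 10-80 deg.

    Estimated from raw sample-to-sample increments with the stalled
    population excluded, so short climb legs between transient dwells do
    not drag the estimate down through smoothing edge effects.
    """
    chunks = []
    for seg in segments:
        sl = slice(seg.start, seg.end + 1)
        d = np.diff(th_raw[sl])
        mid = (th[sl] > 10.0) & (th[sl] < 80.0)
        chunks.append(d[mid[:-1]])
    pooled = np.concatenate(chunks) if chunks else np.array([])
    if pooled.size == 0:
        return float("nan")
    cut = max(1.0, 0.25 * float(np.percentile(pooled, 95)))
    climbing = pooled[pooled > cut]
    if climbing.size == 0:
        return float("nan")
    return float(np.median(climbing))


def detect_transient_dwells(
    angle_raw: np.ndarray,
    angle_smooth: np.ndarray,
    sampling_rate: float,
    segment: PowerStrokeSegment,
    segment_index: int = 0,
    params: DetectionParams = DetectionParams(),
    median_velocity: float | None = None,
) -> list[TransientDwellEvent]:
    """Detect transient dwells within one power-stroke segment.

    A TD is an epoch inside the (5, 85)-degree window where the smoothed
    angular velocity drops to ``velocity_frac`` of the median stroke
    velocity or reverses, lasting at least ``min_dwell_us``. Onset angle
    and duration are refined to sub-sample precision against the stall
    plateau; ``cw_extent_deg`` is the maximal clockwise excursion from the
    onset angle, and events reaching ``step_threshold_deg`` are flagged as
    synthase-direction steps. Stall epochs separated by less than
    ``merge_gap_us`` merge into a single event with its oscillation count
    incremented.
    """
    th_s = np.asarray(angle_smooth, float)
    th_r = np.asarray(angle_raw, float)
    dt = 1.0 / sampling_rate
    v = np.gradient(th_s)
    if median_velocity is None:
        median_velocity = _median_stroke_velocity(th_r, th_s, [segment])
    if not np.isfinite(median_velocity) or median_velocity <= 0:
        return []
    v_thr = params.velocity_frac * median_velocity

    sl = slice(segment.start, segment.end + 1)
    local_th = th_s[sl]
    stall = (
        (v[sl] <= v_thr)
        & (local_th > params.td_angle_min_deg)
        & (local_th < params.td_angle_max_deg)
    )
    runs = [(s + segment.start, e + segment.start) for s, e in _runs(stall) if e - s + 1 >= 2]
    if not runs:
        return []

    # merge runs separated by less than the oscillation gap
    gap = max(1, int(round(params.merge_gap_us * 1e-6 * sampling_rate)))
    merged: list[list[int]] = [[runs[0][0], runs[0][1], 0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= gap:
            merged[-1][1] = e
            merged[-1][2] += 1
        else:
            merged.append([s, e, 0])

    events: list[TransientDwellEvent] = []
    for s, e, n_merged in merged:
        ev = _refine_event(
            th_r, s, e, n_merged, dt, median_velocity, segment, segment_index, params
        )
        if ev is not None and ev.duration_us >= params.min_dwell_us:
            events.append(ev)
    return events


def _refine_event(
    th_r: np.ndarray,
    s: int,
    e: int,
    n_merged: int,
    dt: float,
    v_med: float,
    segment: PowerStrokeSegment,
    segment_index: int,
    params: DetectionParams,
) -> TransientDwellEvent | None:
    """Sub-sample refinement of one stall epoch against its plateau band."""
    band = params.band_halfwidth_deg
    # plateau level from the run interior (robust to smeared edges)
    interior = th_r[s + 1 : e] if e - s >= 4 else th_r[s : e + 1]
    level = float(np.median(interior))

    lo = max(segment.start, s - 6)
    hi = min(segment.end, e + 6)
    center = (s + e) // 2

    if n_merged > 0:
        # oscillating event: keep the coarse velocity-run extent
        onset_angle = float(np.max(th_r[max(segment.start, s - 2) : s + 2]))
        floor = float(np.percentile(th_r[s : e + 1], 10))
        extent = max(onset_angle - floor, 0.0)
        duration = (e - s + 1) * dt
        t_onset = s * dt
    else:
        # Entry edge. A synthase-direction back-step arrives at the plateau
        # by an abrupt CW drop from the climb, so the last sample above the
        # plateau band before mid-stall marks the jump; a plain stall is
        # entered from below and starts where the trace settles into the
        # band. Half-sample offsets marginalize the grid phase.
        above_pre = np.flatnonzero(th_r[lo : center + 1] > level + band)
        stepped = above_pre.size > 0
        if stepped:
            j = lo + int(above_pre[-1])
            t_onset = (j + 0.5) * dt
            first_in = j + 1
        else:
            out_pre = np.flatnonzero(np.abs(th_r[lo : center + 1] - level) > band)
            first_in = lo + int(out_pre[-1]) + 1 if out_pre.size else lo
            t_onset = first_in * dt
        # Exit edge: CCW resumption climbs out through the band top.
        above_post = np.flatnonzero(th_r[center : hi + 1] > level + band)
        last_idx = center + int(above_post[0]) - 1 if above_post.size else e
        # second pass: plateau level from the refined stall span only, so
        # climb samples caught in the velocity run cannot bias it
        if last_idx >= first_in:
            level = float(np.median(th_r[first_in : last_idx + 1]))
        if stepped:
            onset_angle = float(th_r[j] + 0.5 * v_med)
            extent = max(onset_angle - level, 0.0)
        else:
            onset_angle = level
            extent = 0.0
        duration = last_idx * dt - t_onset

    if duration <= 0:
        return None
    return TransientDwellEvent(
        segment_index=segment_index,
        onset_time_s=t_onset,
        onset_angle_deg=onset_angle,
        duration_us=duration * 1e6,
        cw_extent_deg=extent,
        has_synthase_step=extent >= params.step_threshold_deg,
        oscillation_count=n_merged,
    )


# ---------------------------------------------------------------------------
# dataset-level reduction
# ---------------------------------------------------------------------------

def analyze_trace(
    trace: IntensityTrace,
    params: DetectionParams = DetectionParams(),
) -> tuple[list[PowerStrokeSegment], list[TransientDwellEvent], "DatasetSummary"]:
    """Run the full chain on one trace: angles, segments, TDs, summary."""
    norm, _ = normalize_intensity(trace, params.quantile_low, params.quantile_high)
    th_raw = intensity_to_angle(norm)
    th_sm = smooth_angle(th_raw, params.smooth_window)
    segments = segment_power_strokes(th_sm, trace.sampling_rate, params, angle_raw=th_raw)
    v_med = _median_stroke_velocity(th_raw, th_sm, segments)
    events: list[TransientDwellEvent] = []
    for i, seg in enumerate(segments):
        events.extend(
            detect_transient_dwells(
                th_raw, th_sm, trace.sampling_rate, seg,
                segment_index=i, params=params, median_velocity=v_med,
            )
        )
    return segments, events, summarize_dataset(segments, events)


def summarize_dataset(
    segments: list[PowerStrokeSegment],
    events: list[TransientDwellEvent],
) -> DatasetSummary:
    """Reduce one data set of power strokes to its summary statistics.

    ``percent_with_td`` counts segments containing at least one TD;
    spacings are successive onset-angle differences within a stroke;
    durations and step extents are pooled over all events.
    """
    if not segments:
        raise ValueError("need at least one power-stroke segment")
    by_seg: dict[int, list[TransientDwellEvent]] = {}
    for ev in events:
        by_seg.setdefault(ev.segment_index, []).append(ev)
    n_with = sum(1 for evs in by_seg.values() if evs)
    spacings: list[float] = []
    for evs in by_seg.values():
        evs_sorted = sorted(evs, key=lambda ev: ev.onset_time_s)
        onsets = [ev.onset_angle_deg for ev in evs_sorted]
        spacings.extend(float(b - a) for a, b in zip(onsets, onsets[1:]))
    n_tds = len(events)
    n_step = sum(1 for ev in events if ev.has_synthase_step)
    return DatasetSummary(
        n_power_strokes=len(segments),
        percent_with_td=100.0 * n_with / len(segments),
        td_spacings_deg=spacings,
        td_durations_us=[ev.duration_us for ev in events],
        percent_td_with_step=(100.0 * n_step / n_tds) if n_tds else float("nan"),
        step_extents_deg=[ev.cw_extent_deg for ev in events if ev.has_synthase_step],
        n_tds=n_tds,
    )


def td_percent_histogram(
    summaries: list[DatasetSummary], bin_width: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-data-set TD percentages in 10-point bins over [0, 100].

    Bins are half-open [lo, hi) except the last, which is closed so that
    100% lands in the top bin (numpy's convention).
    """
    if not summaries:
        raise ValueError("need at least one summary")
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram([s.percent_with_td for s in summaries], bins=edges)
    return counts, edges


# ---------------------------------------------------------------------------
# ground-truth comparison helpers
# ---------------------------------------------------------------------------

def measured_truth_tds(
    traj: AnnotatedTrajectory,
    max_angle_deg: float = 85.0,
    min_duration_us: float = 0.0,
):
    """Ground-truth TDs that fall inside the measured 0-90 degree window.

    Only strokes aligned with the polarizer minimum are measured (one per
    revolution), and candidate sites beyond the window (108 degrees) are
    excluded by construction of the assay.
    """
    measured = {s.index for s in traj.strokes if s.measured}
    return [
        td
        for td in traj.tds
        if td.stroke_index in measured
        and td.site_angle_deg <= max_angle_deg
        and td.duration_us >= min_duration_us
    ]


def match_events(
    truth: list,
    detected: list[TransientDwellEvent],
    time_tol_s: float = 2e-4,
) -> list[tuple]:
    """Greedy one-to-one pairing of truth and detected TDs by onset time."""
    pairs = []
    used: set[int] = set()
    for td in sorted(truth, key=lambda x: x.t_on):
        best, best_d = None, time_tol_s
        for i, ev in enumerate(detected):
            if i in used:
                continue
            d = abs(ev.onset_time_s - td.t_on)
            if d <= best_d:
                best, best_d = i, d
        if best is not None:
            used.add(best)
            pairs.append((td, detected[best]))
    return pairs
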