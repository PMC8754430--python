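#!/usr/bin/env python
"""Detect transient dwells and synthase-direction sub-steps in the example trace.

Reads results/traces/example_trace.tsv (written by 01_simulate_traces.py),
runs the full measurement chain (quantile calibration, arcsine-sqrt angle
conversion, power-stroke segmentation, stall detection), and writes the
detected events plus a one-row summary. With the ground-truth file present
it also reports detection sensitivity against the simulated labels.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fosubstep.analyze import (
    DetectionParams,
    analyze_trace,
    match_events,
    measured_truth_tds,
)
from fosubstep.io import load_trace, load_trajectory, save_events

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    trace_file = OUT / "traces" / "example_trace.tsv"
    if not trace_file.exists():
        raise SystemExit("run analysis/01_simulate_traces.py first")
    trace = load_trace(trace_file)
    params = DetectionParams()
    segments, events, summary = analyze_trace(trace, params)

    save_events(events, OUT / "detected_events.json")
    pd.DataFrame({
        "onset_angle_deg": [e.onset_angle_deg for e in events],
        "onset_time_s": [e.onset_time_s for e in events],
        "duration_us": [e.duration_us for e in events],
        "cw_extent_deg": [e.cw_extent_deg for e in events],
        "has_synthase_step": [e.has_synthase_step for e in events],
    }).to_csv(OUT / "detected_events.csv", index=False)

    print(f"segments (power strokes analyzed): {len(segments)}")
    print(f"transient dwells detected:         {summary.n_tds}")
    print(f"percent of strokes with a TD:      {summary.percent_with_td:.1f}%")
    print(f"percent of TDs with a CW step:     {summary.percent_td_with_step:.1f}%")
    if summary.td_spacings_deg:
        print(f"mean TD spacing:                   {np.mean(summary.td_spacings_deg):.1f} deg")
    print(f"mean TD duration (>=30 us floor):  {np.mean(summary.td_durations_us):.0f} us")
    if summary.step_extents_deg:
        print(f"mean CW step extent:               {np.mean(summary.step_extents_deg):.1f} deg")

    truth_file = OUT / "traces" / "example_ground_truth.json"
    if truth_file.exists():
        traj = load_trajectory(truth_file)
        truth = measured_truth_tds(traj, params.td_angle_max_deg, min_duration_us=60.0)
        hits = len(match_events(truth, events))
        print(f"sensitivity vs ground truth (TDs >= 60 us): {hits}/{len(truth)}"
              f" = {100*hits/len(truth):.1f}%")


if __name__ == "__main__":
    main()
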