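# Methods

This note documents the models, the synthetic-data generator, the
numerical choices in the detector and the fits, and the limitations a user
should know before trusting numbers on real data.

## The rotation assay being emulated

A gold nanorod attached to the c10-ring of a nanodisc-embedded F1FO
reports rotor angle through polarized scattering: with the polarizer
nulled on one catalytic dwell, intensity follows
I(θ) = i_min + (i_max − i_min)·sin²(θ) and rises to its maximum 90° into
the following 120° CCW power stroke. Sampling is 100 kHz by default
(200 kHz in parts of the original experiments). Because sin² has a 180°
period, only the stroke that starts at the nulled dwell maps cleanly onto
0–90°; the other two strokes of each revolution appear as reflected
excursions and are not analyzed. Angles are degrees, CCW positive, 0° at
the catalytic dwell of the measured stroke.

## Synthetic trajectories

Trajectories are piecewise-linear in time (piecewise-constant angular
velocity); the analysis uses only positions and durations, so no attempt
is made to model acceleration profiles or viscous drag.

* **Catalytic dwells**: gamma-distributed, mean 2 ms, shape 8. The shape
  makes dwells narrowly distributed around the mean (CV ≈ 0.35, multiple
  sequential sub-steps), so essentially none fall below the 0.5 ms
  segmentation threshold; no downstream quantity depends on this
  distribution.
* **Power strokes**: 120° CCW at constant velocity; durations gamma with
  mean 200 µs, shape 25 (CV 20%), representing stroke-to-stroke drag
  variation.
* **Transient dwells**: candidate sites every 36° (36°, 72°, 108°; one
  c-subunit of a c10 ring). A stroke carries TDs with probability
  T(pH)/100 from the occurrence curve, scaled by the molecule's
  efficiency-class multiplier and clamped to [0, 1]. Given a TD-carrying
  stroke, each site is occupied with probability T(pH)/T_sat (T_sat =
  Tmin·10^(K₂−K₁), the low-pH saturation), conditioned on at least one
  occupied site inside the 0–90° measurement window. The conditioning
  choice makes the *windowed* occurrence equal T(pH) exactly — the
  quantity the titration is built from — while the site at 108° remains
  independent (generated but invisible, matching the windowed analysis).
  At low pH this yields 2–3 TDs per TD-carrying stroke. TD durations are
  exponential with mean 150 µs: the source reports only a mean, and the
  memoryless stall is the minimal assumption.
* **Synthase-direction steps**: with probability TS(pH) = 100 − TN(pH)
  from the two-pKa model, a TD contains an instantaneous CW displacement
  at onset, a stall at the displaced angle for the remaining duration,
  then CCW resumption. Extents are truncated-normal (mean 12°, sd 3°,
  resampled below 6°; mean of the truncated law 12.17°). A log-normal
  family with matched mean/sd is provided as the right-skewed alternative
  without any claim of fidelity. A configurable fraction of stepped TDs
  (default 0) instead executes 2–3 CW/CCW oscillation cycles, emulating
  Brownian-ratchet-like behavior; the detector merges these into one
  event.
* **Efficiency classes**: each molecule draws one of three classes
  (weights ⅓ each) with relative TD-formation strengths 1.0 : 1.5 : 2.2
  (low : medium : high), fixed across all of the molecule's data sets.
  Multipliers are normalized to unit weighted mean so the across-class
  average occurrence equals T(pH); without the normalization the fitted
  Tmin would be inflated by the mean multiplier and the published
  parameter set could not be recovered from simulated cohorts.
* **Optics**: i_min 100, i_max 1000 a.u., additive Gaussian detector
  noise sd 15 (≈1.7% of the dynamic range, ≈1° of angle noise per raw
  sample mid-range). Shot noise is not modeled (no photon-count
  calibration to anchor it).

What the generator does **not** emulate: drift, photobleaching,
ATP-binding dwells and ADP inhibition, multi-nanorod artifacts,
pH-dependent drag, or any correlation between step extent and pH. Passing
tests therefore demonstrate that the analysis chain is correct under the
stated statistical model, not that it is robust to every instrumental
pathology of real recordings.

## Trace analysis

**Calibration.** The arcsine transform has unbounded leverage at its
endpoints, so i_min/i_max must be the *centers* of the extreme intensity
clusters, not tail quantiles: i_min is the median of the low-intensity
band (dominated by the nulled catalytic dwell) and i_max a high quantile
(99.8%) of the noise-smoothed trace (the slow sin² turnover near 90°).
A trace whose 1–99% range is within 5× the sample-to-sample noise floor
is rejected as degenerate. Normalized intensities are clipped to [0, 1]
before θ = (180/π)·arcsin(√I).

**Segmentation.** Catalytic dwells are runs of smoothed angle below 5°
lasting ≥0.5 ms (sub-0.1 ms noise gaps bridged; a dwell truncated by the
record start qualifies). A segment runs from dwell exit to the first
attainment of 90°, detected on the raw angle (≥85°) with a smoothed
backup (≥80°) and, as a last resort, the reflected descent past the peak.
Segments longer than 2 ms are discarded as stalled/inhibited strokes;
this also rejects the rare spurious segment seeded by a TD on an
unmeasured stroke whose back-stepped stall reflects to <5° apparent angle
and mimics a catalytic dwell.

**Stall detection.** Angles are smoothed with a centered 5-sample moving
mean (50 µs at 100 kHz — below the TD duration, above single-sample
noise). The stall threshold is 20% of the median climb velocity,
estimated from raw sample-to-sample increments with the stalled
population excluded; a relative threshold adapts to nanorod drag. A TD is
a run of sub-threshold (or negative) velocity inside the 15–76° window
lasting ≥30 µs; runs separated by <40 µs merge into one event with its
oscillation count incremented. The window is deliberately narrower than
the nominal (5°, 90°): below ~15° the arcsine noise amplification near
the polarizer null produces spurious stalls, and above ~76° the smoothed
sin² peak does; generated sites lie at 36° and 72°, and back-stepped
plateaus reach below 15° only for the ≈0.1% largest extents.

**Sub-sample edge refinement.** Event edges are refined against a band of
±3.5° around the stall plateau (median of the refined stall span, so
climb samples cannot bias it). A back-step arrives at the plateau by an
abrupt CW drop, so the last sample above the band before mid-stall marks
the jump; the onset angle is that sample plus half a sample of climb,
which marginalizes the grid phase and makes onset, extent and duration
estimators unbiased on average (verified against ground truth to ≲0.2°
and ≲2 µs at default noise). cw_extent is the maximal CW excursion from
onset (onset minus plateau level), not net displacement. A TD is
classified as containing a synthase-direction step when cw_extent ≥ 5° —
below the 6° truncation of generated extents, above angle noise.

**Known censoring.** TDs shorter than the 30 µs floor (three samples) are
invisible, which (i) raises the mean detected duration to ≈180 µs — the
exponential mean is recovered as mean−floor by memorylessness — and (ii)
lowers detected occurrence by 5–15% relative (pH-dependent, since the
per-stroke TD count falls with pH). Closed-loop tests compare fitted
parameters against the floor-censored oracle rather than the raw preset;
on real data the same censoring is a property of the instrument, and the
published parameters already embed it. Step classification similarly
censors a few percent of the smallest extents, lifting the apparent TN by
a few points.

## pH models and fits

Occurrence is fitted in log₁₀ space with parameters (log₁₀Tmin, K₁, Δ),
K₂ = K₁ + Δ ≥ K₁; a fit at the Δ = 0 boundary (pH-independent data) is
flagged. Apparent pKas come from the tangent at the inflection
pH* = (K₁+K₂)/2 intersected with the two plateaus; the construction is
symmetric about pH*, has the closed form |slope| = (b−a)/(2+a+b) with
b = 1/a = 10^(Δ/2), and reproduces the tabulated pKas to ≈0.1 pH units.
(The published pKa offsets from K₁/K₂ vary between 0.65 and 0.9 pH units
across genotypes; no single tangent rule reproduces all of them exactly,
so the tabulated values are also carried verbatim in the presets.)

TN(pH) is fitted in percent space with parameters (pKa₁, gap, P₁, f),
pKa₂ = pKa₁ + gap and P₂ = f·(100 − P₁), which enforces pKa₁ < pKa₂ and
P₁ + P₂ ≤ 100 throughout. Percents are used everywhere outside the
Henderson–Hasselbalch terms. The TN minimum lies strictly between the
two pKas only when neither route dominates — the weight ratio must stay
below (1+10^gap)²/(4·10^gap) — and the property test asserts exactly that
regime.

The efficiency histogram (10-point bins over [0, 100], last bin closed)
is decomposed by least squares on bin counts at bin centers — the figure
procedure, not a likelihood on raw values — into a sum of three
Gaussians, multi-started from the 25/50/75th percentiles of the binned
mass (±1 bin). Because three classes are a structural hypothesis, three
components are always fitted except in one degenerate case: when a single
Gaussian already fits within Poisson counting noise (reduced χ² ≤ 2) the
decomposition is unidentifiable and the fit collapses to one component,
reporting the others with zero weight. With 10-point bins the
decomposition resolves class means reliably only when the within-class
spread is a few points (as binomial sampling over ~300 strokes produces);
at spreads comparable to the bin width the recovered outer means are
biased toward the middle by overlap, and mean *ratios* are trustworthy to
~15%, not better. Components with sd below a quarter bin width flag the
fit as at the resolution limit.

## Energetics

All energies are kBT at 298 K. U = ½κθ² with κ = 12.6 kBT·rad⁻² (the
measured rotor spring constant; θ in radians, conversion explicit at the
call boundary). The screened Coulomb term uses the constant
e²/(4πε₀) = 561 kBT·Å at 298 K (checked against CODATA values to 0.5% in
the tests) and returns magnitudes; directionality is carried by the
charge signs. The pKa-gap term is ln(10)·ΔpKa per proton. Ledgers round
each component to one decimal before summation — the convention such
budgets are quoted in — and report the raw sum alongside. Temperature is
fixed; the constant is exposed for documentation, not fitted.

## Problem sizes and determinism

The reproduction script (`scripts/acceptance.py`) runs the trace targets
at ~20 molecules × 2 s per record (≈6000 power strokes, ≈10³–2·10³
detected events per statistic) and the Monte-Carlo fit recoveries at 50
replicates — a deliberate reduction from the hundreds of molecules of the
full study, sized so each statistic's standard error is well inside its
tolerance. All randomness derives from numpy `SeedSequence`s spawned from
the single `--seed`; identical seeds give bit-identical traces and
byte-identical pipeline reports (wall-clock timings are excluded from the
serialized report).

## Limitations

* The detector's defaults (smoothing window, velocity fraction, stall
  window, band half-width) are declared choices validated on the
  generator; the original study's exact stall criterion is not public,
  and real data may need retuning, particularly at other sampling rates.
* Calibration assumes the record contains many dwell samples near the
  polarizer null and multiple 90° crossings; very short or stalled
  records will mis-normalize.
* The generator's efficiency classes are a discrete stand-in for what is
  physically a continuous elastic mismatch; only the three-class summary
  statistics are meaningful.
* Oscillating (Brownian-ratchet-like) TDs are detected and counted once,
  but their duration/extent estimators are coarser than for simple
  stepped TDs (no sub-sample refinement).
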