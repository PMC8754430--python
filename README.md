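# fosubstep

Single-molecule analysis of FO-driven sub-steps in the *E. coli* F1FO ATP
synthase — and a synthetic-data generator that emulates the gold-nanorod
rotation assay so the whole chain is testable against known ground truth.

## The scientific problem

F1FO ATP synthase couples two rotary motors. During ATP hydrolysis the F1
motor drives 120° counter-clockwise (CCW) power strokes of the c10-ring
between millisecond catalytic dwells. The membrane-embedded FO motor can
fight back: at ~36° intervals (one c-subunit) the stator subunit-a arrests
the rotor in a **transient dwell (TD)** of ~150 µs, and within most TDs the
c-ring rotates ~11° **clockwise** — the ATP-synthesis direction — against
the F1 torque, powered by proton transfer through the two half-channels of
subunit-a. The pH dependence of these events reports the apparent pKa
values of the proton input (low pKa, must be protonated) and output (high
pKa, must be unprotonated) channels.

The experimental observable is the intensity of polarized light scattered
from a gold nanorod on the rotating c-ring, sampled at 100–200 kHz, with
the polarizer nulled on one catalytic dwell so a power stroke sweeps the
intensity through a sin² law over the first 90° of rotation.

This package implements, as importable library code plus numbered analysis
drivers:

1. **Simulation** (`fosubstep.simulate`) — annotated rotor trajectories
   (dwells, strokes, TDs, CW back-steps, per-molecule low/medium/high
   TD-formation efficiency classes) rendered through sin² optics with
   detector noise.
2. **Trace analysis** (`fosubstep.analyze`) — intensity normalization, the
   arcsine-square-root angle transform θ = (180/π)·arcsin(√I), power-stroke
   segmentation, stall/back-step detection with sub-sample edge refinement,
   and per-data-set summaries.
3. **pH models** (`fosubstep.models`) — the Dixon-style occurrence curve

       log₁₀ T(pH) = log₁₀ Tmin + log₁₀(1 + 10^(K₂−pH)) − log₁₀(1 + 10^(K₁−pH)),

   with apparent pKas read off by intersecting the tangent at the
   inflection with the two plateaus; the two-pKa occupancy model for TDs
   without a synthase-direction step, TN(pH) = P₁·X₁(pKa₁) + P₂·Y₂(pKa₂)
   with TS = 100 − TN; and a three-Gaussian decomposition of the
   per-data-set efficiency histogram.
4. **Energetics** (`fosubstep.energetics`) — U = ½κθ² torsional energy,
   the screened Coulomb term U = |q₁q₂|·561/(ε·r) kBT·Å, the pKa-gap free
   energy ln(10)·ΔpKa, and a rounded energy ledger.
5. **Pipeline and CLI** (`fosubstep.pipeline`, `fosubstep.cli`) — the whole
   chain from simulated cohorts to fitted titration parameters, plus the
   `fosubstep` command-line tool.

Genotype presets (WT and subunit-a half-channel mutants aN214L, aQ252L,
aE219L, aH245L, aE196L) ship with the published titration parameters as
generating truth.

## Worked example

Simulate a 2-s WT record at pH 5.5 and analyze it:

```bash
$ fosubstep simulate --ph 5.5 --duration 2 --seed 7 --out demo_sim
wrote demo_sim/trace.tsv (200000 samples, 280 measured power strokes, 1063 TDs in ground truth)

$ fosubstep analyze demo_sim/trace.tsv --out demo_ana
{
 "n_segments": 264,
 "n_tds": 173,
 "percent_with_td": 44.3,
 "percent_td_with_step": 61.8,
 "mean_td_duration_us": 187.3,
 "mean_td_spacing_deg": 35.9,
 "mean_step_extent_deg": 12.6
}
```

Reading the numbers: 264 of the 280 polarizer-aligned power strokes were
segmented; 44% carried at least one transient dwell (the WT occurrence
curve predicts 46% at pH 5.5 before the 30-µs detection floor); detected
TDs sit ~36° apart (successive c-subunits); 62% contain a clockwise
synthase-direction step of mean ~12°; and the mean detected duration of
187 µs corresponds to an exponential dwell of mean ≈ 157 µs once the 30-µs
floor is subtracted (memoryless excess). The 1063 ground-truth TDs span
all three strokes per revolution — only one stroke per revolution is
measured, and only sites inside the 0–90° window are analyzable.

The numbered drivers under `analysis/` run the study end to end at a small
scale and write tables under `results/`:

```bash
python analysis/01_simulate_traces.py    # cohort + example trace
python analysis/02_detect_substeps.py    # TD/sub-step detection vs ground truth
python analysis/03_fit_ph_models.py      # occurrence + synthase-step titrations
python analysis/04_energy_ledger.py      # closed-form energy bookkeeping
```

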