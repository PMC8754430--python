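"""Synthetic rotor trajectories and detector traces for the rotation assay.

The generator emulates the single-molecule experiment: an F1-ATPase drives
120-degree counter-clockwise (CCW) power strokes of the c10-ring between
millisecond catalytic dwells; within a stroke, the stator can arrest the
rotor at 36-degree intervals (one c-subunit) in transient dwells (TDs) of
~150 us; during a TD the FO motor may drive a clockwise (CW,
synthase-direction) back-step of ~12 degrees before CCW rotation resumes.
A gold nanorod reports the rotor angle through sin^2-law polarized
scattering sampled at 100-200 kHz with additive Gaussian detector noise.

TD statistics are tied to the pH models:

* a power stroke carries TDs with probability T(pH)/100 (Dixon-curve
  occurrence) scaled by the molecule's efficiency-class multiplier;
* given a TD-carrying stroke, each 36-degree site is occupied with
  probability T(pH)/T_saturating, conditioned on at least one occupied
  site inside the measured 0-90 degree window, so strokes with TDs
  typically show two to three of them and the windowed occurrence equals
  the Dixon curve (before detection-floor censoring);
* a TD contains a synthase-direction step with probability TS(pH)/100
  from the two-pKa occupancy model.

Efficiency multipliers are normalized to unit weighted mean, so the
across-class average TD occurrence equals T(pH) exactly and titrations
built from simulated data close the loop on the generating parameters.

Angles are degrees, CCW positive, with the catalytic dwell of the first
(measured) stroke at 0. Trajectories are piecewise-linear in time
(piecewise-constant angular velocity); synthase back-steps are
represented as effectively instantaneous CW displacements followed by a
stall for the remaining TD duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Sequence

import numpy as np
from scipy.stats import truncnorm

from .models import PHCurveModel, SynthaseStepModel, eval_td_occurrence, eval_ts
from .presets import get_preset

__all__ = [
    "KineticConfig",
    "OpticsConfig",
    "IntensityTrace",
    "AnnotatedTrajectory",
    "CatalyticDwell",
    "PowerStroke",
    "TransientDwellTruth",
    "ExperimentRecord",
    "sample_step_extent",
    "sample_rotor_trajectory",
    "trajectory_to_intensity",
    "generate_experiment",
]

_JUMP_DT = 1e-9  # seconds; width of the "instantaneous" CW displacement
EFFICIENCY_LABELS = ("low", "medium", "high")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticConfig:
    """Kinetic ground truth of the simulated motor.

    Durations are means of the generating distributions: power strokes and
    catalytic dwells are gamma-distributed (shape parameters below), TD
    durations are exponential (memoryless stall). ``td_spacing_deg`` is 36
    for a c10 ring. ``efficiency_class_weights``/``efficiency_multipliers``
    define the per-molecule low/medium/high TD-formation classes; the
    multipliers are interpreted as relative class means and internally
    normalized to unit weighted mean (see module docstring).
    """

    td_probability_model: PHCurveModel
    synthase_model: SynthaseStepModel
    power_stroke_duration_mean_us: float = 200.0
    power_stroke_shape: float = 25.0
    catalytic_dwell_duration_mean_ms: float = 2.0
    catalytic_dwell_shape: float = 8.0
    td_duration_mean_us: float = 150.0
    td_spacing_deg: float = 36.0
    step_extent_mean_deg: float = 12.0
    step_extent_sd_deg: float = 3.0
    step_extent_min_deg: float = 6.0
    step_extent_family: str = "truncnorm"
    efficiency_class_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    efficiency_multipliers: tuple[float, float, float] = (1.0, 1.5, 2.2)
    oscillation_fraction: float = 0.0
    oscillation_cycles: tuple[int, int] = (2, 3)

    def __post_init__(self):
        for name in (
            "power_stroke_duration_mean_us",
            "catalytic_dwell_duration_mean_ms",
            "td_duration_mean_us",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.td_spacing_deg <= 120:
            raise ValueError("td_spacing_deg must lie in (0, 120]")
        if not self.step_extent_min_deg < self.step_extent_mean_deg:
            raise ValueError("step_extent_min_deg must be < step_extent_mean_deg")
        if self.step_extent_sd_deg < 0:
            raise ValueError("step_extent_sd_deg must be >= 0")
        w = np.asarray(self.efficiency_class_weights, float)
        m = np.asarray(self.efficiency_multipliers, float)
        if w.shape != (3,) or m.shape != (3,):
            raise ValueError("efficiency classes come in threes")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("efficiency_class_weights must be >= 0 and sum to 1")
        if (m <= 0).any():
            raise ValueError("efficiency_multipliers must be positive")
        if not 0.0 <= self.oscillation_fraction <= 1.0:
            raise ValueError("oscillation_fraction must lie in [0, 1]")
        if self.step_extent_family not in ("truncnorm", "lognormal"):
            raise ValueError("step_extent_family must be 'truncnorm' or 'lognormal'")

    @classmethod
    def from_preset(cls, genotype: str = "WT", **overrides) -> "KineticConfig":
        preset = get_preset(genotype)
        kwargs = {
            "td_probability_model": preset.td_model,
            "synthase_model": preset.synthase_model,
        }
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def normalized_multipliers(self) -> np.ndarray:
        """Multipliers rescaled so the weighted class mean is 1."""
        w = np.asarray(self.efficiency_class_weights, float)
        m = np.asarray(self.efficiency_multipliers, float)
        return m / float(w @ m)

    @property
    def site_angles(self) -> np.ndarray:
        """Candidate TD positions within a stroke (36, 72, 108 by default)."""
        n = int(np.floor(120.0 / self.td_spacing_deg + 1e-9))
        sites = self.td_spacing_deg * np.arange(1, n + 1)
        return sites[sites < 120.0 - 1e-9]


@dataclass(frozen=True)
class OpticsConfig:
    """sin^2-law polarization optics and detector sampling.

    ``i_min``/``i_max`` are the scattered intensities (arbitrary units) at
    the polarizer minimum (catalytic dwell, 0 degrees) and at 90 degrees.
    ``noise_sd`` is additive Gaussian detector noise per sample; the
    default is ~1.7% of the dynamic range, which puts mid-range angular
    noise near one degree per raw sample.
    """

    i_min: float = 100.0
    i_max: float = 1000.0
    noise_sd: float = 15.0
    sampling_rate: float = 100_000.0
    polarizer_offset_deg: float = 0.0

    def __post_init__(self):
        if not self.i_max > self.i_min >= 0:
            raise ValueError("requires i_max > i_min >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CatalyticDwell:
    t_on: float
    t_off: float
    angle_deg: float

    def __post_init__(self):
        if not self.t_off > self.t_on:
            raise ValueError("dwell requires t_off > t_on")


@dataclass
class PowerStroke:
    index: int
    t_on: float
    t_off: float
    base_angle_deg: float
    measured: bool
    duration_us: float

    def __post_init__(self):
        if not self.t_off > self.t_on:
            raise ValueError("stroke requires t_off > t_on")


@dataclass
class TransientDwellTruth:
    """Ground-truth label for one simulated TD."""

    stroke_index: int
    t_on: float
    t_off: float
    site_angle_deg: float       # within-stroke angle: multiple of the spacing
    angle_abs_deg: float        # absolute rotor angle at TD onset
    duration_us: float
    has_synthase_step: bool
    extent_deg: float
    oscillations: int = 0

    def __post_init__(self):
        if not self.t_off > self.t_on:
            raise ValueError("TD requires t_off > t_on")
        if self.extent_deg < 0:
            raise ValueError("extent_deg must be >= 0")


@dataclass
class AnnotatedTrajectory:
    """Piecewise-linear rotor angle vs time with ground-truth event labels."""

    time_bp: np.ndarray
    angle_bp: np.ndarray
    dwells: list[CatalyticDwell]
    strokes: list[PowerStroke]
    tds: list[TransientDwellTruth]
    duration: float
    ph: float
    seed: int | None
    efficiency_multiplier: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.time_bp, float)
        if t.ndim != 1 or t.size < 2 or not (np.diff(t) > 0).all():
            raise ValueError("time_bp must be strictly increasing")
        if len(self.angle_bp) != t.size:
            raise ValueError("angle_bp must match time_bp")

    def angle_at(self, times: np.ndarray) -> np.ndarray:
        """Rotor angle (degrees, unbounded CCW) at arbitrary times."""
        return np.interp(times, self.time_bp, self.angle_bp)


@dataclass
class IntensityTrace:
    """Uniformly sampled detector intensities with acquisition metadata."""

    intensity: np.ndarray
    sampling_rate: float
    ph: float
    genotype: str = "WT"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, float)
        if self.intensity.ndim != 1:
            raise ValueError("intensity must be one-dimensional")
        if not np.isfinite(self.intensity).all():
            raise ValueError("intensities must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.intensity.size) / self.sampling_rate


@dataclass
class ExperimentRecord:
    """One 5-s data set: a trace, its ground truth, and molecule metadata."""

    molecule_id: int
    dataset_id: int
    ph: float
    efficiency_class: str
    efficiency_multiplier: float
    trace: IntensityTrace
    trajectory: AnnotatedTrajectory


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_step_extent(
    mean: float,
    sd: float,
    minimum: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    size: int | None = None,
    family: str = "truncnorm",
):
    """Draw CW synthase-step extents (degrees), truncated below ``minimum``.

    The default family is a normal(mean, sd) with draws below ``minimum``
    rejected (truncated normal). A ``lognormal`` family with the same mean
    and sd (rejection below ``minimum``) is provided for the right-skewed
    alternative; neither claims fidelity beyond the reported mean/sd.
    """
    if not minimum < mean:
        raise ValueError("requires minimum < mean")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    scalar = size is None
    n = 1 if scalar else int(size)
    if sd == 0:
        out = np.full(n, float(mean))
    elif family == "truncnorm":
        a = (minimum - mean) / sd
        out = truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    elif family == "lognormal":
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        sigma = np.sqrt(sigma2)
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.lognormal(mu, sigma, size=2 * (n - filled))
            draw = draw[draw >= minimum]
            take = min(draw.size, n - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
    else:
        raise ValueError(f"unknown family {family!r}")
    return float(out[0]) if scalar else out


def sample_rotor_trajectory(
    kinetics: KineticConfig,
    ph: float,
    duration: float,
    seed: int | None = None,
    efficiency_multiplier: float = 1.0,
    rng: np.random.Generator | None = None,
) -> AnnotatedTrajectory:
    """Simulate one record of rotor motion with ground-truth labels.

    Alternating catalytic dwells (at 0, 120, 240, ... degrees) and CCW
    power strokes; candidate TD sites every ``td_spacing_deg`` within each
    stroke. ``efficiency_multiplier`` is the molecule's (normalized) class
    multiplier applied to the per-stroke TD probability.
    """
    if not np.isfinite(ph) or not 3.0 <= ph <= 11.0:
        raise ValueError(f"pH must be finite and within [3, 11], got {ph}")
    if not duration > 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    model = kinetics.td_probability_model
    t_ph = float(eval_td_occurrence(model, ph)) if model.tmin > 0 else 0.0
    t_sat = model.t_saturating
    p_stroke = float(np.clip(t_ph / 100.0 * efficiency_multiplier, 0.0, 1.0))
    p_site = float(np.clip(t_ph / t_sat, 0.0, 1.0)) if t_sat > 0 else 0.0
    ts_prob = float(eval_ts(kinetics.synthase_model, ph)) / 100.0
    sites = kinetics.site_angles
    dwell_scale = kinetics.catalytic_dwell_duration_mean_ms * 1e-3 / kinetics.catalytic_dwell_shape
    stroke_scale = kinetics.power_stroke_duration_mean_us * 1e-6 / kinetics.power_stroke_shape

    tb = [0.0]
    ab = [0.0]
    dwells: list[CatalyticDwell] = []
    strokes: list[PowerStroke] = []
    tds: list[TransientDwellTruth] = []

    t = 0.0
    base = 0.0
    k = 0
    while t < duration:
        # catalytic dwell (rotor parked at base)
        d = rng.gamma(kinetics.catalytic_dwell_shape, dwell_scale)
        dwells.append(CatalyticDwell(t, t + d, base))
        t += d
        tb.append(t)
        ab.append(base)
        if t >= duration:
            break

        # 120-degree CCW power stroke, piecewise-constant velocity
        stroke_t_on = t
        v = 120.0 / rng.gamma(kinetics.power_stroke_shape, stroke_scale)  # deg/s
        pos = base
        occupied = np.zeros(sites.size, dtype=bool)
        in_window = sites < 90.0
        if sites.size and rng.random() < p_stroke and p_site > 0:
            # conditioned on at least one site inside the measured 0-90
            # window, so the windowed occurrence equals the Dixon curve;
            # out-of-window sites stay independent
            while not occupied[in_window].any():
                occupied = rng.random(sites.size) < p_site
        for i in np.flatnonzero(occupied):
            target = base + sites[i]
            t += (target - pos) / v
            pos = target
            tb.append(t)
            ab.append(pos)
            td_t_on = t
            # floor at 10 ns so breakpoint times stay strictly increasing
            # around the instantaneous back-step segments
            dur_td = max(rng.exponential(kinetics.td_duration_mean_us * 1e-6), 1e-8)
            has_step = rng.random() < ts_prob
            extent = 0.0
            oscillations = 0
            if has_step:
                extent = sample_step_extent(
                    kinetics.step_extent_mean_deg,
                    kinetics.step_extent_sd_deg,
                    kinetics.step_extent_min_deg,
                    rng=rng,
                    family=kinetics.step_extent_family,
                )
                if rng.random() < kinetics.oscillation_fraction:
                    lo_c, hi_c = kinetics.oscillation_cycles
                    oscillations = int(rng.integers(lo_c, hi_c + 1))
                    # CW/CCW cycles within the TD; last visit stays CW
                    n_seg = 2 * oscillations - 1
                    seg = dur_td / n_seg
                    tt = t
                    level_lo, level_hi = pos - extent, pos
                    for s_i in range(n_seg):
                        level = level_lo if s_i % 2 == 0 else level_hi
                        tb.append(tt + _JUMP_DT)
                        ab.append(level)
                        tt += seg
                        tb.append(tt)
                        ab.append(level)
                    pos = level_lo
                else:
                    tb.append(t + _JUMP_DT)
                    ab.append(pos - extent)
                    tb.append(t + dur_td)
                    ab.append(pos - extent)
                    pos = pos - extent
            else:
                tb.append(t + dur_td)
                ab.append(pos)
            t += dur_td
            tds.append(
                TransientDwellTruth(
                    stroke_index=k,
                    t_on=td_t_on,
                    t_off=t,
                    site_angle_deg=float(sites[i]),
                    angle_abs_deg=float(base + sites[i]),
                    duration_us=dur_td * 1e6,
                    has_synthase_step=has_step,
                    extent_deg=float(extent),
                    oscillations=oscillations,
                )
            )
        # finish the stroke
        t += (base + 120.0 - pos) / v
        pos = base + 120.0
        tb.append(t)
        ab.append(pos)
        strokes.append(
            PowerStroke(
                index=k,
                t_on=stroke_t_on,
                t_off=t,
                base_angle_deg=base,
                measured=(k % 3 == 0),
                duration_us=(t - stroke_t_on) * 1e6,
            )
        )
        base = pos
        k += 1

    # clip the breakpoint series at the requested duration
    tb_arr = np.asarray(tb)
    ab_arr = np.asarray(ab)
    if tb_arr[-1] > duration:
        end_angle = float(np.interp(duration, tb_arr, ab_arr))
        keep = tb_arr < duration
        tb_arr = np.append(tb_arr[keep], duration)
        ab_arr = np.append(ab_arr[keep], end_angle)
    return AnnotatedTrajectory(
        time_bp=tb_arr,
        angle_bp=ab_arr,
        dwells=[d for d in dwells if d.t_off <= duration],
        strokes=[s for s in strokes if s.t_off <= duration],
        tds=[e for e in tds if e.t_off <= duration],
        duration=duration,
        ph=ph,
        seed=seed,
        efficiency_multiplier=efficiency_multiplier,
    )


def trajectory_to_intensity(
    traj: AnnotatedTrajectory,
    optics: OpticsConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    genotype: str = "WT",
) -> IntensityTrace:
    """Render a trajectory through the sin^2-law optics onto the detector grid.

    I(t) = i_min + (i_max - i_min) * sin^2(theta(t) - polarizer_offset)
    plus additive Gaussian noise of ``noise_sd``.
    """
    if len(traj.strokes) < 1:
        raise ValueError("trajectory must cover at least one power stroke")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(traj.duration * optics.sampling_rate))
    times = np.arange(n) / optics.sampling_rate
    angle = traj.angle_at(times)
    clean = optics.i_min + (optics.i_max - optics.i_min) * np.sin(
        np.deg2rad(angle - optics.polarizer_offset_deg)
    ) ** 2
    noisy = clean if optics.noise_sd == 0 else clean + rng.normal(0.0, optics.noise_sd, n)
    return IntensityTrace(
        intensity=noisy,
        sampling_rate=optics.sampling_rate,
        ph=traj.ph,
        genotype=genotype,
        meta={
            "optics": asdict(optics),
            "seed": seed,
            "efficiency_multiplier": traj.efficiency_multiplier,
        },
    )


def generate_experiment(
    kinetics: KineticConfig,
    optics: OpticsConfig,
    n_molecules: int,
    ph_grid: Sequence[float],
    master_seed: int,
    datasets_per_molecule: int = 10,
    duration: float = 5.0,
    genotype: str = "WT",
) -> Iterator[ExperimentRecord]:
    """Yield (trace, ground truth) records for a cohort of molecules.

    Each molecule is assigned one efficiency class (from the configured
    weights) held fixed across all of its data sets and pH values;
    ``datasets_per_molecule`` records of ``duration`` seconds are produced
    per molecule per pH. Fully reproducible from ``master_seed``. Records
    are yielded lazily so large experiments never hold every trace in
    memory at once.
    """
    if n_molecules <= 0 or datasets_per_molecule <= 0:
        raise ValueError("counts must be positive")
    ph_grid = list(ph_grid)
    if not ph_grid:
        raise ValueError("pH grid must be non-empty")

    class_rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), 0]))
    classes = class_rng.choice(3, size=n_molecules, p=kinetics.efficiency_class_weights)
    multipliers = kinetics.normalized_multipliers
    order = np.argsort(kinetics.efficiency_multipliers)
    rank = {int(order[r]): r for r in range(3)}  # class index -> low/med/high rank

    for i_ph, ph in enumerate(ph_grid):
        for mol in range(n_molecules):
            for ds in range(datasets_per_molecule):
                ss = np.random.SeedSequence([int(master_seed), 1, i_ph, mol, ds])
                rng = np.random.default_rng(ss)
                traj = sample_rotor_trajectory(
                    kinetics,
                    ph=ph,
                    duration=duration,
                    efficiency_multiplier=float(multipliers[classes[mol]]),
                    rng=rng,
                )
                trace = trajectory_to_intensity(traj, optics, rng=rng, genotype=genotype)
                trace.meta["molecule_id"] = mol
                trace.meta["dataset_id"] = ds
                trace.meta["efficiency_class"] = EFFICIENCY_LABELS[rank[int(classes[mol])]]
                yield ExperimentRecord(
                    molecule_id=mol,
                    dataset_id=ds,
                    ph=ph,
                    efficiency_class=EFFICIENCY_LABELS[rank[int(classes[mol])]],
                    efficiency_multiplier=float(multipliers[classes[mol]]),
                    trace=trace,
                    trajectory=traj,
                )
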