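"""End-to-end pipeline: simulate -> analyze -> titrate -> fit -> report.

`run_pipeline` sequences the whole analysis the way the experiment was
reduced: generate (or load) intensity traces over a pH grid, detect
transient dwells and synthase-direction steps in each data set, aggregate
the percent of power strokes with TDs and the percent of TDs lacking a
step versus pH, fit the Dixon occurrence curve and the two-pKa step model,
extract apparent pKas, and decompose the per-data-set efficiency
histogram into three Gaussians. The report is deterministic given the
configuration and master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analyze import (
    DatasetSummary,
    DetectionParams,
    analyze_trace,
    td_percent_histogram,
)
from .models import (
    extract_pkas,
    fit_synthase_model,
    fit_td_occurrence,
    fit_three_gaussians,
)
from .simulate import KineticConfig, OpticsConfig, generate_experiment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    genotype: str = "WT"
    ph_grid: tuple[float, ...] = (5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0)
    n_molecules: int = 6
    datasets_per_molecule: int = 2
    duration_s: float = 1.0
    master_seed: int = 0
    kinetics_overrides: dict = field(default_factory=dict)
    optics: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    fit_mixture: bool = False

    def __post_init__(self):
        if not self.ph_grid:
            raise ValueError("pH grid must be non-empty")
        if self.n_molecules <= 0 or self.datasets_per_molecule <= 0:
            raise ValueError("counts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "ph_grid" in doc:
            doc["ph_grid"] = tuple(float(x) for x in doc["ph_grid"])
        return cls(**doc)

    def build_kinetics(self) -> KineticConfig:
        return KineticConfig.from_preset(self.genotype, **self.kinetics_overrides)

    def build_optics(self) -> OpticsConfig:
        return OpticsConfig(**self.optics)

    def build_detection(self) -> DetectionParams:
        return DetectionParams(**self.detection)

    def hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Aggregated results of one pipeline run (JSON-serializable)."""

    config_hash: str
    version: str
    genotype: str
    master_seed: int
    per_ph: list[dict]
    td_curve_fit: dict | None
    pkas: dict | None
    synthase_fit: dict | None
    mixtures: dict
    pooled: dict
    flags: list[str]
    timings_s: dict

    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("timings_s", None)  # wall-clock is the one non-reproducible field
        return json.dumps(doc, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_json())
        return path


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run simulation, analysis and model fitting per the configuration."""
    kinetics = config.build_kinetics()
    optics = config.build_optics()
    detection = config.build_detection()
    flags: list[str] = []
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    summaries_by_ph: dict[float, list[DatasetSummary]] = {ph: [] for ph in config.ph_grid}
    records = generate_experiment(
        kinetics,
        optics,
        n_molecules=config.n_molecules,
        ph_grid=config.ph_grid,
        master_seed=config.master_seed,
        datasets_per_molecule=config.datasets_per_molecule,
        duration=config.duration_s,
        genotype=config.genotype,
    )
    n_records = 0
    for rec in records:
        try:
            _, _, summary = analyze_trace(rec.trace, detection)
        except ValueError as exc:
            flags.append(f"analyze[pH {rec.ph}, mol {rec.molecule_id}, ds {rec.dataset_id}]: {exc}")
            continue
        summaries_by_ph[rec.ph].append(summary)
        n_records += 1
    timings["simulate_and_analyze"] = time.perf_counter() - t0
    logger.info("analyzed %d records across %d pH values", n_records, len(config.ph_grid))

    per_ph = []
    for ph in config.ph_grid:
        ss = summaries_by_ph[ph]
        n_tds = int(sum(s.n_tds for s in ss))
        n_steps = int(
            sum(round(s.percent_td_with_step * s.n_tds / 100.0) for s in ss if s.n_tds)
        )
        durations = [d for s in ss for d in s.td_durations_us]
        spacings = [d for s in ss for d in s.td_spacings_deg]
        extents = [e for s in ss for e in s.step_extents_deg]
        per_ph.append(
            {
                "ph": ph,
                "n_datasets": len(ss),
                "n_power_strokes": int(sum(s.n_power_strokes for s in ss)),
                "mean_percent_with_td": float(np.mean([s.percent_with_td for s in ss])) if ss else float("nan"),
                "n_tds": n_tds,
                "percent_td_with_step": 100.0 * n_steps / n_tds if n_tds else float("nan"),
                "tn_percent": 100.0 * (1.0 - n_steps / n_tds) if n_tds else float("nan"),
                "mean_td_duration_us": float(np.mean(durations)) if durations else float("nan"),
                "mean_td_spacing_deg": float(np.mean(spacings)) if spacings else float("nan"),
                "mean_step_extent_deg": float(np.mean(extents)) if extents else float("nan"),
            }
        )

    # Dixon occurrence fit over the pH grid
    t0 = time.perf_counter()
    td_fit_doc = None
    pkas_doc = None
    ph_arr = [row["ph"] for row in per_ph if np.isfinite(row["mean_percent_with_td"])]
    t_arr = [row["mean_percent_with_td"] for row in per_ph if np.isfinite(row["mean_percent_with_td"])]
    if len(ph_arr) >= 5 and max(t_arr) > 0:
        fit = fit_td_occurrence(ph_arr, t_arr)
        model = fit.params
        td_fit_doc = {
            "tmin": model.tmin,
            "k1": model.k1,
            "k2": model.k2,
            "stderr": fit.stderr,
            "rms_residual_log10": fit.residual,
            "flagged": fit.flagged,
            "message": fit.message,
        }
        if fit.flagged:
            flags.append(f"fit_td_occurrence: {fit.message}")
        else:
            pka1, pka2 = extract_pkas(model)
            pkas_doc = {"pka1": pka1, "pka2": pka2}
    else:
        flags.append("fit_td_occurrence: skipped (needs >=5 pH points with TDs)")

    # two-pKa synthase-step fit on TN(pH)
    syn_doc = None
    ph_tn = [row["ph"] for row in per_ph if np.isfinite(row["tn_percent"])]
    tn = [row["tn_percent"] for row in per_ph if np.isfinite(row["tn_percent"])]
    if len(ph_tn) >= 5:
        sfit = fit_synthase_model(ph_tn, tn)
        sm = sfit.params
        syn_doc = {
            "pka1": sm.pka1,
            "p1": sm.p1,
            "pka2": sm.pka2,
            "p2": sm.p2,
            "stderr": sfit.stderr,
            "rms_residual_percent": sfit.residual,
            "flagged": sfit.flagged,
            "message": sfit.message,
        }
        if sfit.flagged:
            flags.append(f"fit_synthase_model: {sfit.message}")
    else:
        flags.append("fit_synthase_model: skipped (needs >=5 pH points with TDs)")

    # efficiency-class mixture per pH (needs many datasets per pH)
    mixtures = {}
    if config.fit_mixture:
        for ph in config.ph_grid:
            ss = summaries_by_ph[ph]
            if len(ss) < 12:
                continue
            counts, _ = td_percent_histogram(ss)
            try:
                mfit = fit_three_gaussians(counts)
            except ValueError as exc:
                flags.append(f"fit_three_gaussians[pH {ph}]: {exc}")
                continue
            mix = mfit.params
            mixtures[str(ph)] = {
                "weights": list(mix.weights),
                "means": list(mix.means),
                "sds": list(mix.sds),
                "flagged": mix.flagged,
            }
    timings["fits"] = time.perf_counter() - t0

    all_summaries = [s for ss in summaries_by_ph.values() for s in ss]
    durations = [d for s in all_summaries for d in s.td_durations_us]
    spacings = [d for s in all_summaries for d in s.td_spacings_deg]
    extents = [e for s in all_summaries for e in s.step_extents_deg]
    pooled = {
        "n_records": n_records,
        "n_power_strokes": int(sum(s.n_power_strokes for s in all_summaries)),
        "n_tds": int(sum(s.n_tds for s in all_summaries)),
        "mean_td_duration_us": float(np.mean(durations)) if durations else float("nan"),
        "mean_td_spacing_deg": float(np.mean(spacings)) if spacings else float("nan"),
        "mean_step_extent_deg": float(np.mean(extents)) if extents else float("nan"),
    }

    return RunReport(
        config_hash=config.hash(),
        version=__version__,
        genotype=config.genotype,
        master_seed=config.master_seed,
        per_ph=per_ph,
        td_curve_fit=td_fit_doc,
        pkas=pkas_doc,
        synthase_fit=syn_doc,
        mixtures=mixtures,
        pooled=pooled,
        flags=flags,
        timings_s={k: round(v, 3) for k, v in timings.items()},
    )
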