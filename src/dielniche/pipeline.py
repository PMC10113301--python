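"""End-to-end orchestration of the two analysis tracks.

The hummingbird track builds the trophic (M1) and diel (M2) matrices from
visit events and tests their mean Pianka overlap against the RA3 and ROSARIO
nulls.  The plant track standardizes nectar measurements, fits per-species
secretion curves, assembles the availability matrix (M3), runs the ROSARIO
test on it, classifies plant pairs (co-flowering / pollinator sharing), and
runs the Wilcoxon group comparisons and the anther-height x nectar-schedule
Mantel test.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .group_stats import build_distance_matrices, classify_pairs, mantel_test, wilcoxon_group_test
from .interactions import build_diel_matrix, build_trophic_matrix, deduplicate_visits
from .nectar import (
    DEFAULT_HOUR_GRID,
    build_availability_matrix,
    fit_nectar_curve,
    predict_hourly_production,
    standardize_nectar,
)
from .nullmodels import null_model_test
from .overlap import mean_overlap

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and knobs for one full analysis run."""

    visits_path: str
    nectar_path: str
    abundance_path: str
    traits_path: str
    output_dir: str = "dielniche_out"
    n_reps: int = 10_000
    seed: int = 0
    min_gap_s: float = 20.0
    hour_grid: str = "12"  # '12' (bin left edges 06..17) or '13' (06..18)
    use_observed_concentration: bool = False
    rosario_wrap: bool = True
    distance_metric: str = "per_flower"  # or 'availability'
    mantel_permutations: int = 10_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _hours(config: PipelineConfig) -> tuple:
    if config.hour_grid == "12":
        return DEFAULT_HOUR_GRID
    if config.hour_grid == "13":
        return tuple(range(6, 19))
    raise ValueError("hour_grid must be '12' or '13'")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run both analysis tracks; write results under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- hummingbird track -------------------------------------------
    visits = io.read_visits(config.visits_path)
    logger.info("stage visits: %d raw events", len(visits))
    dedup = deduplicate_visits(visits, min_gap_s=config.min_gap_s)
    m1 = build_trophic_matrix(dedup)
    m2_full = build_diel_matrix(dedup, "full_day")
    m2_morning = build_diel_matrix(dedup, "morning")
    io.write_matrix(m1, out / "m1_trophic.csv", {"matrix_id": "M1"})
    io.write_matrix(m2_full, out / "m2_full_day.csv", {"matrix_id": "M2"})
    io.write_matrix(m2_morning, out / "m2_morning.csv", {"matrix_id": "M2-morning"})

    overlaps = {
        "m1": mean_overlap(m1, "M1"),
        "m2_full_day": mean_overlap(m2_full, "M2"),
        "m2_morning": mean_overlap(m2_morning, "M2-morning"),
    }
    null_tests = {
        "trophic_ra3": null_model_test(m1, "ra3", config.n_reps, seed=config.seed),
        "diel_full_rosario": null_model_test(
            m2_full, "rosario", config.n_reps, seed=config.seed + 1, wrap=config.rosario_wrap
        ),
        "diel_morning_rosario": null_model_test(
            m2_morning, "rosario", config.n_reps, seed=config.seed + 2, wrap=config.rosario_wrap
        ),
    }

    # --- plant track -------------------------------------------------
    nectar = standardize_nectar(
        io.read_nectar(config.nectar_path),
        use_observed_concentration=config.use_observed_concentration,
    )
    curves = {
        plant: fit_nectar_curve(grp) for plant, grp in nectar.groupby("plant", sort=True)
    }
    pd.DataFrame(
        [(c.plant, c.b0, c.b1, c.b2, c.deviance, c.n) for c in curves.values()],
        columns=["plant", "b0", "b1", "b2", "deviance", "n"],
    ).to_csv(out / "nectar_curves.csv", index=False)

    abundance = io.read_abundance(config.abundance_path)
    flower_totals = abundance.groupby("plant")["flowers"].sum().to_dict()
    phenology = (
        abundance[abundance["flowers"] > 0].groupby("plant")["month"].agg(set).to_dict()
    )
    hours = _hours(config)
    m3 = build_availability_matrix(curves, flower_totals, hours)
    io.write_matrix(m3, out / "m3_availability.csv", {"matrix_id": "M3"})
    overlaps["m3"] = mean_overlap(m3, "M3")
    null_tests["plant_rosario"] = null_model_test(
        m3, "rosario", config.n_reps, seed=config.seed + 3, wrap=config.rosario_wrap
    )

    pairs = classify_pairs(m1.reindex(columns=m3.index, fill_value=0), phenology, overlaps["m3"])
    pairs.to_csv(out / "plant_pairs.csv", index=False)
    group_tests = {
        "co_flowered": wilcoxon_group_test(pairs, "co_flowered"),
        "shared_pollinator": wilcoxon_group_test(pairs, "shared_pollinator"),
    }

    anther = io.read_traits(config.traits_path)
    if config.distance_metric == "availability":
        schedule = m3
    else:
        schedule = pd.DataFrame(
            {p: predict_hourly_production(c, hours) for p, c in curves.items()}
        ).T.rename_axis(index="plant")
    d_anther, d_nectar = build_distance_matrices(anther, schedule)
    mantel = mantel_test(d_anther, d_nectar, config.mantel_permutations, seed=config.seed + 4)

    # --- summaries ---------------------------------------------------
    summary = {
        "overlap_means": {k: v.mean_value for k, v in overlaps.items()},
        "null_tests": {k: v.summary() for k, v in null_tests.items()},
        "group_tests": {k: dataclasses.asdict(v) for k, v in group_tests.items()},
        "mantel": dataclasses.asdict(mantel),
        "n_pairs": len(pairs),
        "n_co_flowered": int(pairs["co_flowered"].sum()),
        "n_shared_pollinator": int(pairs["shared_pollinator"].sum()),
    }
    manifest = {
        "dielniche_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "counts": {"raw_events": len(visits), "independent_visits": len(dedup)},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)

    return {
        "m1": m1,
        "m2_full_day": m2_full,
        "m2_morning": m2_morning,
        "m3": m3,
        "overlaps": overlaps,
        "null_tests": null_tests,
        "pairs": pairs,
        "group_tests": group_tests,
        "mantel": mantel,
        "summary": summary,
        "manifest": manifest,
    }
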