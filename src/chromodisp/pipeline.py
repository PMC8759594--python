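"""End-to-end orchestration: simulate -> measure -> classify -> stats.

A run is configured by :class:`RunConfig`, executes its stage chain into one
output directory, and writes a manifest (config echo, software version,
seeds) sufficient to reproduce every deterministic artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import CategoryCutoffs, summarize_condition
from .io import write_measurements_csv, write_scene
from .morphometry import PipelineConfig, ProjectedImage, skeleton_dot_length_pipeline
from .stats import mann_whitney_u
from .synthetic import SyntheticSceneParams, generate_fish_scene

__all__ = ["RunConfig", "run_experiment"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a simulate/measure/classify/stats run."""

    output_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "measure", "classify", "stats")
    spreads_um: tuple[float, ...] = (0.2, 0.6, 1.2, 2.4)
    foci_per_condition: int = 30
    pixel_size_um: float = 0.1
    probe_class: str = "heterochromatin"
    cutoffs: CategoryCutoffs | None = None
    threshold_method: str = "isodata"
    dilate_iterations: int = 3

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cutoffs is not None:
            d["cutoffs"] = dataclasses.asdict(self.cutoffs)
        d["software_version"] = __version__
        return d


def _condition_scenes(config: RunConfig, spread: float, index: int):
    """Enough single-focus scenes for one spread condition."""
    per_scene = 2  # 2 nuclei x 1 focus
    n_scenes = int(np.ceil(config.foci_per_condition / per_scene))
    for s in range(n_scenes):
        yield generate_fish_scene(
            SyntheticSceneParams(
                pixel_size_um=config.pixel_size_um,
                n_nuclei=2,
                foci_per_nucleus=1,
                focus_spread_um=spread,
                seed=int(np.random.SeedSequence([config.seed, index, s]).generate_state(1)[0] % (2**31)),
            )
        )


def run_experiment(config: RunConfig) -> dict:
    """Execute the configured stage chain; returns the run manifest."""
    valid = {"simulate", "measure", "classify", "stats"}
    unknown = set(config.stages) - valid
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {sorted(valid)}")
    if config.probe_class not in ("heterochromatin", "euchromatin", "whole_chromosome"):
        raise ValueError(f"invalid probe_class {config.probe_class!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cutoffs = config.cutoffs or (
        CategoryCutoffs.heterochromatin()
        if config.probe_class == "heterochromatin"
        else CategoryCutoffs.euchromatin()
    )
    manifest = config.to_manifest()
    manifest["artifacts"] = []

    lengths_by_condition: dict[str, list[float]] = {}
    for i, spread in enumerate(config.spreads_um):
        cond = f"spread_{spread:g}um"
        lengths: list[float] = []
        for s, scene in enumerate(_condition_scenes(config, spread, i)):
            if "simulate" in config.stages:
                paths = write_scene(scene, out / "scenes", f"{cond}_scene{s}")
                manifest["artifacts"].append(str(paths["image"].relative_to(out)))
            if "measure" in config.stages:
                image = ProjectedImage(scene.image, scene.pixel_size_um, "fish")
                measurements = skeleton_dot_length_pipeline(
                    image,
                    PipelineConfig(
                        threshold_method=config.threshold_method,
                        dilate_iterations=config.dilate_iterations,
                    ),
                )
                lengths.extend(m.skeleton_dot_length_um for m in measurements)
        if "measure" in config.stages:
            lengths_by_condition[cond] = lengths[: config.foci_per_condition]

    if "measure" in config.stages:
        rows = [
            {"condition": cond, "skeleton_dot_length_um": l}
            for cond, ls in lengths_by_condition.items()
            for l in ls
        ]
        pd.DataFrame(rows).to_csv(out / "measurements.csv", index=False)
        manifest["artifacts"].append("measurements.csv")

    if "classify" in config.stages and lengths_by_condition:
        summary_rows = []
        for cond, ls in lengths_by_condition.items():
            s = summarize_condition(ls, cutoffs, condition=cond)
            row = {
                "condition": cond,
                "n_foci": s.n_foci,
                "mean_length_um": s.mean_length_um,
                "sem_length_um": s.sem_length_um,
            }
            row.update({f"pct_{k}": v for k, v in s.category_percentages.items()})
            summary_rows.append(row)
        pd.DataFrame(summary_rows).to_csv(out / "condition_summary.csv", index=False)
        manifest["artifacts"].append("condition_summary.csv")

    if "stats" in config.stages and len(lengths_by_condition) >= 2:
        conds = list(lengths_by_condition)
        stat_rows = []
        for a, b in zip(conds, conds[1:]):
            res = mann_whitney_u(lengths_by_condition[a], lengths_by_condition[b])
            stat_rows.append(
                {"condition_a": a, "condition_b": b, "U": res.statistic,
                 "p_value": res.p_value, "stars": res.stars,
                 "method": res.method_detail}
            )
        pd.DataFrame(stat_rows).to_csv(out / "stats.csv", index=False)
        manifest["artifacts"].append("stats.csv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
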