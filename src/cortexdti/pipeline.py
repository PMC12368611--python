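"""End-to-end orchestration: phantom -> tensor fit -> surface metrics,
and cohort -> group stats -> trajectories, from one validated config.

Every run writes its resolved configuration and a provenance record
(package/library versions, seeds, exclusion counts) next to the outputs, so
a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .cohort_sim import (
    DEFAULT_RHO,
    TrajectorySpec,
    average_hemispheres,
    simulate_cohort,
    whole_cortex_reference_specs,
)
from .core import (
    FA_EXCLUDE_THRESHOLD,
    MD_EXCLUDE_THRESHOLD,
    PRACTICAL_MARGINS,
    default_scheme,
)
from .dti_fit import fit_tensor, tensor_scalars
from .group_stats import hemisphere_test, lobe_anova, sex_test
from .io import save_dwi, save_nifti, save_surfaces
from .phantom import make_shell_phantom, make_slab_phantom, synthesize_dwi
from .surface_metrics import build_vertex_table, summarize_regions
from .trajectory import fit_all_families

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_end_to_end", "load_config"]


class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    geometry: str = "slab"               # slab | shell
    thickness_mm: float = 3.0
    extent_mm: float = 30.0              # slab only
    inner_radius_mm: float = 40.0        # shell only
    subdivisions: int = 3                # shell only
    voxel_mm: float = 1.5
    tilt_deg: float = 0.0                # slab only
    s0: float = 1000.0
    snr: float | None = None
    seed: int = 0


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_subjects: int = 190
    seed: int = 0
    age_mode: str = "uniform"            # uniform | paper_hist
    rho: float = DEFAULT_RHO
    # optional explicit specs: {"region,metric": {family, params, noise_sd}}
    specs: dict[str, dict] | None = None


class ThresholdConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    md_max: float = MD_EXCLUDE_THRESHOLD
    fa_max: float = FA_EXCLUDE_THRESHOLD
    margins: dict[str, float] = Field(
        default_factory=lambda: dict(PRACTICAL_MARGINS))


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    phantom: bool = True
    fit: bool = True
    surface: bool = True
    cohort: bool = True
    stats: bool = True
    trajectories: bool = True


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected by name."""

    model_config = ConfigDict(extra="forbid")
    out_dir: str = "cortexdti_run"
    stages: StageToggles = Field(default_factory=StageToggles)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def _cohort_specs(cfg: CohortConfig) -> dict:
    if cfg.specs is None:
        return whole_cortex_reference_specs(rho=cfg.rho)
    specs = {}
    for key, body in cfg.specs.items():
        region, metric = (s.strip() for s in key.split(","))
        specs[(region, metric)] = TrajectorySpec(
            family=body["family"], params=tuple(body["params"]),
            noise_sd=float(body["noise_sd"]),
            rho=float(body.get("rho", cfg.rho)))
    return specs


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns a provenance record (also written to ``provenance.json``).
    Stage outputs are deterministic given identical config and seeds.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)

    provenance: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seeds": {"phantom": config.phantom.seed,
                  "cohort": config.cohort.seed},
        "stages_run": [],
        "counts": {},
    }

    surfaces = tv = dwi = None
    if config.stages.phantom:
        pc = config.phantom
        if pc.geometry == "slab":
            surfaces, tv = make_slab_phantom(
                pc.thickness_mm, pc.extent_mm, pc.voxel_mm, pc.tilt_deg)
        elif pc.geometry == "shell":
            surfaces, tv = make_shell_phantom(
                pc.inner_radius_mm, pc.thickness_mm, pc.voxel_mm,
                pc.subdivisions)
        else:
            raise ValueError(f"unknown phantom geometry: {pc.geometry!r}")
        dwi = synthesize_dwi(tv, default_scheme(), s0=pc.s0, snr=pc.snr,
                             seed=pc.seed)
        save_dwi(out / "phantom", dwi)
        save_surfaces(out / "phantom" / "surfaces", surfaces)
        provenance["stages_run"].append("phantom")
        provenance["counts"]["masked_voxels"] = int(tv.mask.sum())

    maps = eigen = None
    if config.stages.fit:
        if dwi is None:
            raise RuntimeError("fit stage requires the phantom stage")
        fitted = fit_tensor(dwi)
        maps, eigen = tensor_scalars(fitted)
        dti_dir = out / "dti"
        dti_dir.mkdir(exist_ok=True)
        for name, vol in maps.items():
            save_nifti(dti_dir / f"{name}.nii", vol.values, vol.affine)
        save_nifti(dti_dir / "e1.nii", eigen.e1, eigen.affine)
        provenance["stages_run"].append("fit")
        provenance["counts"]["clamped_voxels"] = getattr(
            fitted, "n_clamped", 0)

    if config.stages.surface:
        if maps is None or surfaces is None:
            raise RuntimeError("surface stage requires phantom and fit")
        table = build_vertex_table(surfaces, maps, eigen)
        summary = summarize_regions(table, subject="phantom")
        surf_dir = out / "surface"
        surf_dir.mkdir(exist_ok=True)
        table.to_csv(surf_dir / "vertex_metrics.csv", index=False)
        summary.to_csv(surf_dir / "region_summary.csv", index=False)
        provenance["stages_run"].append("surface")
        provenance["counts"]["excluded_vertices"] = int(
            (~table["included"]).sum())

    cohort = None
    if config.stages.cohort:
        specs = _cohort_specs(config.cohort)
        cohort = simulate_cohort(specs, n=config.cohort.n_subjects,
                                 seed=config.cohort.seed,
                                 age_mode=config.cohort.age_mode)
        cdir = out / "cohort"
        cdir.mkdir(exist_ok=True)
        cohort.to_csv(cdir / "cohort.csv", index=False)
        provenance["stages_run"].append("cohort")
        provenance["counts"]["cohort_rows"] = int(len(cohort))

    if config.stages.stats:
        if cohort is None:
            raise RuntimeError("stats stage requires the cohort stage")
        results = []
        metrics = sorted(cohort["metric"].unique())
        regions = sorted(cohort["region"].unique())
        for metric in metrics:
            for region in regions:
                results.append(hemisphere_test(cohort, metric, region))
                results.append(sex_test(cohort, metric, region))
            lobes_present = set(cohort["region"].unique())
            if {"frontal", "temporal", "insula", "parietal",
                    "occipital"} <= lobes_present:
                omni, pairs = lobe_anova(cohort, metric)
                results.append(omni)
                results.extend(pairs)
        stats_df = pd.DataFrame([asdict(r) for r in results])
        sdir = out / "stats"
        sdir.mkdir(exist_ok=True)
        stats_df.to_csv(sdir / "comparisons.csv", index=False)
        with open(sdir / "summary.json", "w") as fh:
            json.dump({
                "n_comparisons": len(results),
                "n_significant": int(stats_df["significant"].sum()),
            }, fh, indent=2)
        provenance["stages_run"].append("stats")

    if config.stages.trajectories:
        if cohort is None:
            raise RuntimeError("trajectories stage requires the cohort stage")
        averaged = average_hemispheres(cohort)
        rows = []
        for (region, metric), grp in averaged.groupby(["region", "metric"]):
            fits = fit_all_families(grp["age"].to_numpy(),
                                    grp["value"].to_numpy())
            for f in fits:
                lm = f.landmarks()
                rows.append({
                    "region": region, "metric": metric, "family": f.family,
                    "k": f.k, "rss": f.rss, "aic": f.aic,
                    "selected": f.selected,
                    "params": json.dumps(list(f.params)),
                    "value_at_5": lm["value_at_start"],
                    "value_at_74": lm["value_at_end"],
                    "extrema": json.dumps(lm["extrema"]),
                })
        tdir = out / "trajectories"
        tdir.mkdir(exist_ok=True)
        pd.DataFrame(rows).to_csv(tdir / "fits.csv", index=False)
        selected = [r for r in rows if r["selected"]]
        with open(tdir / "selected_models.json", "w") as fh:
            json.dump(selected, fh, indent=2)
        provenance["stages_run"].append("trajectories")

    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    return provenance
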