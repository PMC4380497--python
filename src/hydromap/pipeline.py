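"""End-to-end study orchestration: cohort -> acquisition -> water maps ->
classification -> ROI tables -> group statistics, as one reproducible run.

A master seed spawns per-subject, per-scan sub-seeds through hashed seed
sequences, so adding a subject or a scan never perturbs the noise stream of
any other; identical config + seed gives an identical summary JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import spawn_seed
from .mr_forward import default_protocol, simulate_protocol
from .phantom import (CohortSpec, TissueParams, cohort_manifest, make_cohort,
                      make_fields, realize_phantom)
from .roi_analysis import build_synthetic_atlas, roi_water_table
from .tissue_histogram import global_tissue_water
from .water_mapping import ALL_STEPS, map_water

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full configuration of a simulated study run."""

    shape: tuple = (64, 64, 64)
    voxel_size_mm: float = 3.0
    cohort: dict = field(default_factory=dict)    # CohortSpec overrides
    noise_sd: float = 0.02                        # relative magnitude noise (SNR 50)
    field_amplitude: float = 0.15
    field_smoothness_mm: float = 60.0
    steps: tuple = ALL_STEPS
    roi_threshold: float = 0.75
    min_tissue_fraction: float = 0.07
    covariates: tuple = ()
    m_comparisons: int | None = None
    groups: tuple = ("hd", "control")
    timepoints: tuple = (1, 2)
    seed: int = 1
    outdir: str | None = None
    write_volumes: bool = False

    def __post_init__(self):
        if not 0 < self.roi_threshold <= 1:
            raise ValueError("roi_threshold must lie in (0, 1]")
        if not 0 <= self.min_tissue_fraction < 1:
            raise ValueError("min_tissue_fraction must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("shape", "steps", "groups", "timepoints", "covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(seed=spawn_seed(self.seed, "cohort"), **self.cohort)


def process_subject(entry, config: RunConfig, atlas=None):
    """Phantom -> acquisition -> water map -> classification for one entry.

    Returns (record dict for ROI tabulation, class stats, chain result,
    phantom)."""
    phantom = realize_phantom(entry, config.shape,
                              voxel_size_mm=config.voxel_size_mm)
    fields = make_fields(config.shape, config.field_amplitude,
                         config.field_smoothness_mm,
                         seed=spawn_seed(config.seed, "fields", entry.subject_id),
                         voxel_size_mm=config.voxel_size_mm,
                         brain_mask=phantom.brain_mask)
    acq = simulate_protocol(phantom, fields,
                            default_protocol(config.noise_sd),
                            seed=entry.noise_seed)
    res = map_water(acq, phantom.ventricle_mask, phantom.brain_mask,
                    steps=config.steps, voxel_size_mm=config.voxel_size_mm)
    stats = global_tissue_water(
        res.water_map, res.t1_hat, phantom.prob_maps,
        seed=spawn_seed(config.seed, "segment", entry.subject_id,
                        entry.timepoint),
        valid_mask=res.valid_mask)
    record = {"subject": entry.subject_id, "group": entry.group,
              "timepoint": entry.timepoint, "water_map": res.water_map,
              "tissue_masks": {"wm": phantom.tissue_mask("wm"),
                               "gm": phantom.tissue_mask("gm")},
              "valid_mask": res.valid_mask}
    return record, stats, res, phantom


def run_full_study(config: RunConfig) -> dict:
    """Execute the whole study; returns the machine-readable summary.

    Writes (when ``config.outdir`` is set): cohort manifest TSV, per-subject
    class statistics TSV, ROI statistics TSV, effects TSV, correlations TSV,
    summary JSON and optionally all NIfTI intermediates.
    """
    from .group_stats import correlation_table, effects_table, wilcoxon_ranksum

    t_start = time.time()
    spec = config.cohort_spec()
    entries = [e for e in make_cohort(spec)
               if e.group in config.groups and e.timepoint in config.timepoints]
    if not entries:
        raise ValueError("cohort selection is empty")

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    atlas = None
    roi_records = []
    class_rows = []
    for entry in entries:
        t0 = time.time()
        stage = f"{entry.subject_id}/t{entry.timepoint}"
        try:
            record, stats, res, phantom = process_subject(entry, config)
        except Exception as err:
            raise RuntimeError(f"stage water-mapping failed for {stage}: {err}"
                               ) from err
        if atlas is None:
            atlas = build_synthetic_atlas(phantom)
        roi_records.append(record)
        d = stats.as_dict()
        class_rows.append({"subject": entry.subject_id, "group": entry.group,
                           "timepoint": entry.timepoint,
                           "wm_mean_water": d["wm"]["mean_water"],
                           "gm_mean_water": d["gm"]["mean_water"],
                           "wm_mean_t1": d["wm"]["mean_t1"],
                           "gm_mean_t1": d["gm"]["mean_t1"],
                           "vintage_months": entry.vintage_months,
                           "weight_change_kg": entry.weight_change_kg})
        if outdir and config.write_volumes:
            from ._utils import save_nifti
            vol_dir = outdir / "volumes" / f"{entry.subject_id}_t{entry.timepoint}"
            vol_dir.mkdir(parents=True, exist_ok=True)
            save_nifti(res.water_map, vol_dir / "water.nii.gz",
                       config.voxel_size_mm)
            save_nifti(res.t1_hat, vol_dir / "t1.nii.gz", config.voxel_size_mm)
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    class_df = pd.DataFrame(class_rows)
    roi_df = roi_water_table(roi_records, atlas, config.roi_threshold,
                             config.min_tissue_fraction)

    summary = {"seed": config.seed, "n_entries": len(entries),
               "groups": list(config.groups),
               "global": {}, "wilcoxon": {}}
    t1_df = class_df[class_df["timepoint"] == config.timepoints[0]]
    for g in config.groups:
        gdf = t1_df[t1_df["group"] == g]
        summary["global"][g] = {
            "wm_mean_water": round(float(gdf["wm_mean_water"].mean()), 6),
            "wm_sd_water": round(float(gdf["wm_mean_water"].std(ddof=1)), 6),
            "gm_mean_water": round(float(gdf["gm_mean_water"].mean()), 6),
            "gm_sd_water": round(float(gdf["gm_mean_water"].std(ddof=1)), 6),
            "n": int(len(gdf))}

    effects_df = corr_df = None
    if set(config.groups) == {"hd", "control"}:
        for tissue in ("wm", "gm"):
            x = t1_df.loc[t1_df["group"] == "hd", f"{tissue}_mean_water"]
            y = t1_df.loc[t1_df["group"] == "control", f"{tissue}_mean_water"]
            u, p = wilcoxon_ranksum(x, y)
            summary["wilcoxon"][tissue] = {"U": u, "p": round(p, 8)}
        if len(config.timepoints) == 2:
            effects_df = effects_table(roi_df, covariates=config.covariates,
                                       m_comparisons=config.m_comparisons)
        hd_t1 = class_df[(class_df["group"] == "hd")
                         & (class_df["timepoint"] == config.timepoints[0])]
        parietal = roi_df[(roi_df["roi"] == "parietal")
                          & (roi_df["timepoint"] == config.timepoints[0])
                          & (roi_df["group"] == "hd")]
        par_wm = parietal[parietal["tissue"] == "wm"][["subject", "mean_water"]]
        merged = hd_t1.merge(par_wm.rename(
            columns={"mean_water": "parietal_wm_water"}), on="subject",
            how="left")
        if len(merged) >= 3:
            corr_df = correlation_table(
                merged, ["parietal_wm_water", "wm_mean_water"],
                ["vintage_months", "weight_change_kg"])

    if outdir:
        cohort_manifest(entries).to_csv(outdir / "manifest.tsv", sep="\t",
                                        index=False)
        class_df.to_csv(outdir / "class_stats.tsv", sep="\t", index=False)
        roi_df.to_csv(outdir / "roi_stats.tsv", sep="\t", index=False)
        if effects_df is not None:
            effects_df.to_csv(outdir / "effects.tsv", sep="\t", index=False)
        if corr_df is not None:
            corr_df.to_csv(outdir / "correlations.tsv", sep="\t", index=False)

    summary["runtime_s"] = round(time.time() - t_start, 1)
    if effects_df is not None and not effects_df.empty:
        grp = effects_df[effects_df["effect"] == "group"]
        summary["n_group_effects_significant"] = int((grp["p"] < 0.05).sum())
    if outdir:
        stable = {k: v for k, v in summary.items() if k != "runtime_s"}
        (outdir / "summary.json").write_text(
            json.dumps(stable, indent=1, sort_keys=True))
    return summary
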