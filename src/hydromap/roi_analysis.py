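"""Probabilistic-atlas ROI masking and regional water-content tables.

ROIs are probability volumes thresholded at 75% (inclusive).  Each ROI mask
is intersected with the subject-specific WM and GM masks, and a per-tissue
row is emitted only when that tissue makes up more than 7% of the ROI — the
rule that lets mixed structures (e.g. an angular gyrus with ~50% GM and
~49% WM) report both a WM and a GM value.

The shipped atlas is synthetic: geometric lobe-like sectors, a mid-plane
"corpus callosum" slab and a periventricular shell, with the same file
contract (probability NIfTIs + TSV index) as real probabilistic atlases, so
the masking rules are exercised without any download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from ._utils import load_nifti, save_nifti
from .phantom import DigitalPhantom, lobe_sector_masks

log = logging.getLogger(__name__)

ROI_PROB_THRESHOLD = 0.75
MIN_TISSUE_FRACTION = 0.07


@dataclass
class AtlasROI:
    name: str
    prob: np.ndarray                       # probability volume in [0, 1]
    composition: dict = field(default_factory=dict)   # nominal WM/GM fraction

    def __post_init__(self):
        p = np.asarray(self.prob)
        if p.min() < 0 or p.max() > 1:
            raise ValueError(f"ROI {self.name!r}: probabilities outside [0, 1]")


def roi_mask(roi: AtlasROI, threshold: float = ROI_PROB_THRESHOLD) -> np.ndarray:
    """Voxels with ROI probability >= threshold (inclusive boundary)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    m = np.asarray(roi.prob) >= threshold
    if not m.any():
        log.warning("ROI %s empty at threshold %.2f; skipped", roi.name, threshold)
    return m


def split_by_tissue(mask: np.ndarray, tissue_masks: dict,
                    min_fraction: float = MIN_TISSUE_FRACTION) -> dict:
    """Intersect an ROI mask with subject tissue masks.

    Returns {tissue: mask} only for tissues whose voxel fraction within the
    ROI exceeds ``min_fraction`` (strict >)."""
    n_roi = int(mask.sum())
    out = {}
    for tissue, tmask in tissue_masks.items():
        if tmask.shape != mask.shape:
            raise ValueError("tissue mask grid does not match ROI mask grid")
        joint = mask & np.asarray(tmask, bool)
        frac = joint.sum() / n_roi if n_roi else 0.0
        if frac > min_fraction:
            out[tissue] = joint
        else:
            log.info("tissue %s below %.0f%% of ROI (%.1f%%); row not emitted",
                     tissue, 100 * min_fraction, 100 * frac)
    return out


def build_synthetic_atlas(phantom: DigitalPhantom, boundary_fwhm_vox: float = 1.5
                          ) -> list[AtlasROI]:
    """Geometric probabilistic atlas on the phantom grid.

    Four lobe sectors, a mid-plane corpus-callosum-like slab and a
    periventricular shell; binary regions are blurred to give probabilistic
    boundaries like a real atlas.
    """
    brain = phantom.brain_mask
    shape = phantom.shape
    regions = {}
    for name, sector in lobe_sector_masks(shape).items():
        regions[name] = sector & brain
    c = shape[2] // 2
    slab = np.zeros(shape, bool)
    slab[:, :, max(0, c - 2): c + 2] = True
    regions["corpus_callosum"] = slab & (phantom.labels == 1)
    regions["periventricular"] = (binary_dilation(phantom.ventricle_mask,
                                                  iterations=3)
                                  & ~phantom.ventricle_mask & brain)
    rois = []
    for name, m in regions.items():
        prob = gaussian_filter(m.astype(float), boundary_fwhm_vox / 2.3548)
        prob = np.clip(np.where(m, np.maximum(prob, 0.9), prob), 0.0, 1.0)
        comp = {}
        n = m.sum()
        if n:
            comp = {"wm": float((phantom.labels[m] == 1).mean()),
                    "gm": float((phantom.labels[m] == 2).mean())}
        rois.append(AtlasROI(name=name, prob=prob, composition=comp))
    return rois


def roi_water_table(subject_maps, atlas: list[AtlasROI],
                    threshold: float = ROI_PROB_THRESHOLD,
                    min_fraction: float = MIN_TISSUE_FRACTION) -> pd.DataFrame:
    """Tabulate per-ROI, per-tissue water content over a cohort.

    ``subject_maps`` yields dicts with keys: subject, group, timepoint,
    water_map, tissue_masks ({"wm": mask, "gm": mask}), and optionally
    valid_mask.  Rows: subject, group, timepoint, roi, tissue, mean_water,
    sd_water, n_voxels.
    """
    rows = []
    for rec in subject_maps:
        water = rec["water_map"]
        valid = rec.get("valid_mask")
        for roi in atlas:
            m = roi_mask(roi, threshold)
            if not m.any():
                continue
            for tissue, joint in split_by_tissue(
                    m, rec["tissue_masks"], min_fraction).items():
                sel = joint if valid is None else joint & valid
                if not sel.any():
                    log.info("ROI %s/%s empty after validity masking", roi.name,
                             tissue)
                    continue
                vals = water[sel]
                rows.append({
                    "subject": rec["subject"], "group": rec["group"],
                    "timepoint": rec["timepoint"], "roi": roi.name,
                    "tissue": tissue,
                    "mean_water": float(vals.mean()),
                    "sd_water": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "n_voxels": int(vals.size)})
    df = pd.DataFrame(rows, columns=["subject", "group", "timepoint", "roi",
                                     "tissue", "mean_water", "sd_water",
                                     "n_voxels"])
    return df.sort_values(["subject", "timepoint", "roi", "tissue"],
                          kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# on-disk interface (same contract as real probabilistic atlas directories)

def write_atlas(atlas: list[AtlasROI], outdir, voxel_size_mm=3.0) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for roi in atlas:
        f = f"{roi.name}.nii.gz"
        save_nifti(roi.prob, outdir / f, voxel_size_mm)
        rows.append({"name": roi.name, "file": f,
                     "wm_fraction": roi.composition.get("wm", float("nan")),
                     "gm_fraction": roi.composition.get("gm", float("nan"))})
    index = outdir / "atlas_index.tsv"
    pd.DataFrame(rows).to_csv(index, sep="\t", index=False)
    return index


def read_atlas(atlas_dir) -> list[AtlasROI]:
    atlas_dir = Path(atlas_dir)
    index = pd.read_csv(atlas_dir / "atlas_index.tsv", sep="\t")
    rois = []
    for _, row in index.iterrows():
        prob, _ = load_nifti(atlas_dir / row["file"])
        comp = {"wm": row.get("wm_fraction", float("nan")),
                "gm": row.get("gm_fraction", float("nan"))}
        rois.append(AtlasROI(name=row["name"], prob=np.asarray(prob, float),
                             composition=comp))
    return rois
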