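"""Digital brain phantoms and synthetic cohorts with known ground truth.

The phantom is a nested-ellipsoid head: a white-matter (WM) core, a
gray-matter (GM) shell, a cerebrospinal-fluid (CSF) rim and two interior
ellipsoidal ventricles.  Each voxel carries ground-truth water content
(percent of pure water molarity), T1 and T2*, so every downstream estimator
can be checked against exact truth.  Cohorts emulate a two-group
(hemodialysis vs control), two-timepoint study with configurable group
offsets, between-subject variation and clinical covariates (dialysis
vintage, intradialytic weight change) correlated with regional water.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._utils import rng_from, save_nifti, spawn_seed

BACKGROUND, WM, GM, CSF = 0, 1, 2, 3
TISSUES = ("wm", "gm", "csf")
LABEL_OF = {"wm": WM, "gm": GM, "csf": CSF}

#: default ground-truth water content (% of pure water) for a healthy adult
#: control at 3 T; CSF is the normalization reference and is 100 by definition.
DEFAULT_WATER = {"wm": 71.46, "gm": 82.93, "csf": 100.0}
#: 3 T literature relaxation times (ms); override via TissueParams for other
#: field strengths or pathologies.
DEFAULT_T1 = {"wm": 900.0, "gm": 1400.0, "csf": 4000.0}
DEFAULT_T2STAR = {"wm": 50.0, "gm": 60.0, "csf": 200.0}


@dataclass(frozen=True)
class TissueParams:
    """Per-class ground-truth water content and relaxation times."""

    water_pct: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WATER))
    t1_ms: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_T1))
    t2star_ms: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_T2STAR))

    def __post_init__(self):
        for t in TISSUES:
            w = self.water_pct[t]
            if not 0.0 < w <= 100.0:
                raise ValueError(f"water_pct[{t}]={w} outside (0, 100]")
            if self.t1_ms[t] <= 0 or self.t2star_ms[t] <= 0:
                raise ValueError(f"non-positive relaxation time for {t}")
        if self.water_pct["csf"] != 100.0:
            raise ValueError("CSF water content must be exactly 100%")
        if not self.water_pct["wm"] < self.water_pct["gm"] < self.water_pct["csf"]:
            raise ValueError("expected WM < GM < CSF water content")

    def with_water(self, water_pct: Mapping[str, float]) -> "TissueParams":
        return replace(self, water_pct=dict(water_pct))


@dataclass
class DigitalPhantom:
    """Label/probability volumes plus ground-truth parameter maps."""

    labels: np.ndarray              # int volume: 0 bg, 1 WM, 2 GM, 3 CSF
    prob_maps: dict                 # tissue -> probability volume in [0, 1]
    truth_water: np.ndarray         # % of pure water, 0 outside brain
    truth_t1: np.ndarray            # ms
    truth_t2star: np.ndarray        # ms
    ventricle_mask: np.ndarray      # bool, subset of CSF
    voxel_size_mm: tuple

    @property
    def shape(self):
        return self.labels.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return self.labels == LABEL_OF[tissue]


@dataclass
class FieldMaps:
    """Multiplicative transmit (B1+) and receive (B1-) field maps, mean 1."""

    b1t: np.ndarray
    b1r: np.ndarray


@dataclass(frozen=True)
class CohortSpec:
    """Two-group, two-timepoint study design with known truth.

    Group offsets, between-subject SDs and the covariate structure default to
    the hemodialysis-study conditions the generator emulates: HD white matter
    +1.43 and gray matter +1.49 percentage points of water over controls,
    control between-subject SDs 1.06 (WM) and 1.00 (GM), dialysis vintage
    correlated +0.69 and intradialytic weight change -0.74 with a per-subject
    parietal water deviation.
    """

    n_per_group: int = 10
    group_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"wm": 1.43, "gm": 1.49, "csf": 0.0})
    between_subject_sd: Mapping[str, float] = field(
        default_factory=lambda: {"wm": 1.06, "gm": 1.00, "csf": 0.0})
    parietal_mean: float = 0.0
    parietal_sd: float = 0.8
    vintage_corr: float = 0.69
    weight_change_corr: float = -0.74
    vintage_mean_months: float = 44.5
    vintage_sd_months: float = 20.0
    weight_change_mean_kg: float = -1.5
    weight_change_sd_kg: float = 0.8
    time_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"wm": 0.0, "gm": 0.0, "csf": 0.0})
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for t in TISSUES:
            if self.between_subject_sd.get(t, 0.0) < 0:
                raise ValueError("between-subject SDs must be >= 0")
        for r in (self.vintage_corr, self.weight_change_corr):
            if not -1.0 <= r <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")
        if self.group_offsets.get("csf", 0.0) != 0.0 or \
                self.between_subject_sd.get("csf", 0.0) != 0.0:
            raise ValueError("CSF is the normalization reference; its water "
                             "content admits no offset or variation")


@dataclass
class CohortEntry:
    """One subject at one timepoint."""

    subject_id: str
    group: str                      # "hd" | "control"
    timepoint: int                  # 1 | 2
    water_pct: dict                 # subject's per-tissue truth water
    parietal_offset: float          # extra water added in the parietal sector
    vintage_months: float           # NaN for controls
    weight_change_kg: float         # NaN for controls
    anatomy_seed: int
    noise_seed: int


def _normalized_radius(shape, semi_axes_vox, center=None, offset_vox=(0.0, 0.0, 0.0)):
    c = (np.asarray(shape) - 1) / 2.0 if center is None else np.asarray(center)
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    rho2 = sum(((g - ci - oi) / ai) ** 2
               for g, ci, oi, ai in zip(grids, c, offset_vox, semi_axes_vox))
    return np.sqrt(rho2)


def make_phantom(shape, tissue_params: TissueParams | None = None, seed: int = 0,
                 voxel_size_mm=3.0, texture_sd: Mapping[str, float] | None = None,
                 ) -> DigitalPhantom:
    """Build a nested-ellipsoid brain phantom.

    Geometry: brain = outer ellipsoid with semi-axes 0.44/0.46/0.42 of the
    grid; the outer 8% radial band is CSF, the next band down to 70% of the
    radius is GM, the core is WM; two interior ellipsoids are CSF ventricles.
    ``texture_sd`` adds optional within-class Gaussian water texture (percent
    points, per tissue); the default is a pure-class phantom so estimators
    have exact truth.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 32 for s in shape):
        raise ValueError(f"shape {shape} too small to contain all tissue "
                         "shells; need >= 32 voxels per axis")
    params = tissue_params or TissueParams()
    semi = np.array([0.44, 0.46, 0.42]) * np.asarray(shape)

    rho = _normalized_radius(shape, semi)
    labels = np.zeros(shape, dtype=np.int16)
    labels[rho <= 1.0] = CSF
    labels[rho <= 0.92] = GM
    labels[rho <= 0.70] = WM

    ventricle_mask = np.zeros(shape, dtype=bool)
    for sign in (-1.0, 1.0):
        off = np.array([sign * 0.14 * semi[0], 0.0, 0.04 * semi[2]])
        rv = _normalized_radius(shape, semi * np.array([0.10, 0.30, 0.13]),
                                offset_vox=off)
        ventricle_mask |= rv <= 1.0
    labels[ventricle_mask] = CSF

    brain = labels > 0
    n_brain = int(brain.sum())
    for t in TISSUES:
        if (labels == LABEL_OF[t]).sum() < 0.01 * n_brain:
            raise ValueError(f"tissue {t} occupies < 1% of brain voxels at "
                             f"shape {shape}")

    prob_maps = {t: (labels == LABEL_OF[t]).astype(float) for t in TISSUES}

    truth_water = np.zeros(shape)
    truth_t1 = np.zeros(shape)
    truth_t2star = np.zeros(shape)
    rng = rng_from(seed, "texture")
    for t in TISSUES:
        m = labels == LABEL_OF[t]
        truth_water[m] = params.water_pct[t]
        truth_t1[m] = params.t1_ms[t]
        truth_t2star[m] = params.t2star_ms[t]
        sd = (texture_sd or {}).get(t, 0.0)
        if sd > 0 and t != "csf":    # CSF stays exactly 100
            truth_water[m] += rng.normal(0.0, sd, size=int(m.sum()))
    np.clip(truth_water, 0.0, 110.0, out=truth_water)

    vs = tuple(np.broadcast_to(np.asarray(voxel_size_mm, float), (3,)))
    return DigitalPhantom(labels=labels, prob_maps=prob_maps,
                          truth_water=truth_water, truth_t1=truth_t1,
                          truth_t2star=truth_t2star,
                          ventricle_mask=ventricle_mask, voxel_size_mm=vs)


def lobe_sector_masks(shape) -> dict:
    """Crude lobe-like sectors by anterior/posterior x superior/inferior
    quadrant (geometric stand-ins for atlas lobes, not anatomy)."""
    shape = tuple(int(s) for s in shape)
    c = (np.asarray(shape) - 1) / 2.0
    _, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    ant, sup = y >= c[1], z >= c[2]
    full = np.ones(shape, dtype=bool)
    return {
        "frontal": (ant & sup) & full,
        "parietal": (~ant & sup) & full,
        "temporal": (ant & ~sup) & full,
        "occipital": (~ant & ~sup) & full,
    }


def apply_regional_offset(phantom: DigitalPhantom, sector: str, offset_pct: float
                          ) -> DigitalPhantom:
    """Add a water offset inside one lobe sector (WM and GM only; CSF is the
    reference and never moves)."""
    if offset_pct == 0.0:
        return phantom
    sec = lobe_sector_masks(phantom.shape)[sector]
    m = sec & ((phantom.labels == WM) | (phantom.labels == GM))
    water = phantom.truth_water.copy()
    water[m] += offset_pct
    return replace(phantom, truth_water=water)


def make_fields(shape, amplitude: float = 0.15, smoothness_mm: float = 60.0,
                seed: int = 0, voxel_size_mm=3.0, brain_mask=None) -> FieldMaps:
    """Smooth multiplicative B1+ / B1- fields with mean 1 and bounded range.

    Each field is Gaussian-filtered white noise (correlation length
    ``smoothness_mm``), centred to mean 1 over the brain (or whole volume)
    and scaled so the maximum deviation from 1 equals ``amplitude``.
    """
    if not 0.0 <= amplitude < 0.5:
        raise ValueError(f"amplitude must lie in [0, 0.5), got {amplitude}")
    shape = tuple(int(s) for s in shape)
    mask = np.ones(shape, bool) if brain_mask is None else np.asarray(brain_mask, bool)

    def one_field(sub: str) -> np.ndarray:
        if amplitude == 0.0:
            return np.ones(shape)
        rng = rng_from(seed, sub)
        noise = rng.standard_normal(shape)
        from scipy.ndimage import gaussian_filter
        vs = np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))
        u = gaussian_filter(noise, smoothness_mm / vs)
        u = u - u[mask].mean()
        peak = np.abs(u).max()
        if peak == 0.0:
            return np.ones(shape)
        u /= peak                     # zero mean over mask preserved
        return 1.0 + amplitude * u

    return FieldMaps(b1t=one_field("b1t"), b1r=one_field("b1r"))


def make_cohort(spec: CohortSpec, control_params: TissueParams | None = None
                ) -> list[CohortEntry]:
    """Draw a two-group, two-timepoint cohort with known per-subject truth.

    HD subjects' tissue water = control values + group offsets + a subject
    random effect; each HD subject also gets a parietal water deviation to
    which dialysis vintage and intradialytic weight change are correlated
    (Gaussian construction: cov = r * z_parietal + sqrt(1-r^2) * noise).
    """
    base = (control_params or TissueParams()).water_pct
    rng = rng_from(spec.seed, "cohort")
    entries: list[CohortEntry] = []
    for group in ("hd", "control"):
        is_hd = group == "hd"
        for i in range(spec.n_per_group):
            sid = f"{group}{i + 1:02d}"
            water = {}
            for t in TISSUES:
                w = base[t]
                if is_hd:
                    w += spec.group_offsets.get(t, 0.0)
                sd = spec.between_subject_sd.get(t, 0.0)
                if sd > 0:
                    w += rng.normal(0.0, sd)
                water[t] = w
            water["csf"] = 100.0

            z_par = rng.standard_normal()
            parietal = spec.parietal_mean + spec.parietal_sd * z_par if is_hd else 0.0
            if is_hd:
                zv = spec.vintage_corr * z_par + \
                    np.sqrt(1 - spec.vintage_corr**2) * rng.standard_normal()
                zw = spec.weight_change_corr * z_par + \
                    np.sqrt(1 - spec.weight_change_corr**2) * rng.standard_normal()
                vintage = max(1.0, spec.vintage_mean_months
                              + spec.vintage_sd_months * zv)
                weight = spec.weight_change_mean_kg + spec.weight_change_sd_kg * zw
            else:
                vintage = weight = float("nan")

            for tp in (1, 2):
                w_tp = {t: water[t] + (spec.time_offsets.get(t, 0.0) if tp == 2 else 0.0)
                        for t in TISSUES}
                w_tp["csf"] = 100.0
                entries.append(CohortEntry(
                    subject_id=sid, group=group, timepoint=tp,
                    water_pct=w_tp, parietal_offset=parietal,
                    vintage_months=vintage, weight_change_kg=weight,
                    anatomy_seed=spawn_seed(spec.seed, "anatomy", group, i),
                    noise_seed=spawn_seed(spec.seed, "noise", group, i, tp),
                ))
    return entries


def realize_phantom(entry: CohortEntry, shape=(64, 64, 64),
                    base_params: TissueParams | None = None,
                    voxel_size_mm=3.0, texture_sd=None) -> DigitalPhantom:
    """Materialize the phantom for one cohort entry."""
    params = (base_params or TissueParams()).with_water(entry.water_pct)
    ph = make_phantom(shape, params, seed=entry.anatomy_seed,
                      voxel_size_mm=voxel_size_mm, texture_sd=texture_sd)
    return apply_regional_offset(ph, "parietal", entry.parietal_offset)


# ---------------------------------------------------------------------------
# on-disk interface

def cohort_manifest(entries: list[CohortEntry]) -> pd.DataFrame:
    rows = [{
        "subject": e.subject_id, "group": e.group, "timepoint": e.timepoint,
        "vintage_months": e.vintage_months,
        "weight_change_kg": e.weight_change_kg,
        "parietal_offset": e.parietal_offset,
        "water_wm": e.water_pct["wm"], "water_gm": e.water_pct["gm"],
        "anatomy_seed": e.anatomy_seed, "noise_seed": e.noise_seed,
    } for e in entries]
    return pd.DataFrame(rows)


def write_phantom(phantom: DigitalPhantom, outdir) -> dict:
    """Write all phantom volumes as NIfTI-1; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vs = phantom.voxel_size_mm
    paths = {}
    items = {"labels": (phantom.labels, np.int16),
             "truth_water": (phantom.truth_water, None),
             "truth_t1": (phantom.truth_t1, None),
             "truth_t2star": (phantom.truth_t2star, None),
             "ventricle_mask": (phantom.ventricle_mask, np.uint8)}
    for t, p in phantom.prob_maps.items():
        items[f"prob_{t}"] = (p, None)
    for name, (vol, dt) in items.items():
        path = outdir / f"{name}.nii.gz"
        save_nifti(vol, path, voxel_size_mm=vs, dtype=dt)
        paths[name] = str(path)
    return paths


def write_cohort(entries: list[CohortEntry], spec: CohortSpec, outdir,
                 shape=(64, 64, 64), voxel_size_mm=3.0) -> Path:
    """Write phantoms for all entries, a manifest TSV and the config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = cohort_manifest(entries)
    dirs = []
    for e in entries:
        d = outdir / f"{e.subject_id}_t{e.timepoint}"
        write_phantom(realize_phantom(e, shape, voxel_size_mm=voxel_size_mm), d)
        dirs.append(str(d))
    manifest["phantom_dir"] = dirs
    mpath = outdir / "manifest.tsv"
    manifest.to_csv(mpath, sep="\t", index=False)
    cfg = {k: (dict(v) if isinstance(v, Mapping) else v)
           for k, v in vars(spec).items()}
    cfg.update(shape=list(shape), voxel_size_mm=voxel_size_mm)
    (outdir / "cohort_config.yaml").write_text(yaml.safe_dump(cfg))
    return mpath
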