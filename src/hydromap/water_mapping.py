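"""Invert a simulated acquisition into quantitative water content maps.

The correction chain mirrors the acquisition physics step by step:

i)   compensation of transmit (B1+) and receive (B1-) field inhomogeneity,
ii)  compensation of T2* decay (log-linear multi-echo fit, extrapolation of
     the PD scan to TE = 0),
iii) correction of the T1-saturation effect (per-voxel T1 from the ratio of
     the PD scan to the TR 500 / FA 90 companion scan, then division by the
     spoiled-GRE saturation factor),
iv)  correction of residual nonuniformity (homomorphic bias estimation), and
v)   normalization to the ventricular CSF signal, expressing the result as a
     percentage of pure water molarity.

All estimators are vectorized over brain voxels; voxels where a fit is
impossible are flagged and excluded downstream rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion

from ._utils import masked_gaussian_smooth
from .mr_forward import StudyAcquisition, saturation_factor

ALL_STEPS = ("b1_transmit", "t2star", "t1_saturation", "residual_bias",
             "csf_normalization")


@dataclass
class CorrectionChainResult:
    """All intermediate and final maps of one correction-chain run."""

    b1t_hat: np.ndarray
    b1r_hat: np.ndarray
    t2star_hat: np.ndarray
    s0_hat: np.ndarray
    t1_hat: np.ndarray
    pd_corrected: np.ndarray
    bias_hat: np.ndarray
    water_map: np.ndarray
    applied_steps: list
    valid_mask: np.ndarray
    csf_mask_eroded: np.ndarray
    flags: dict = field(default_factory=dict)

    def qc_summary(self) -> dict:
        return {
            "applied_steps": list(self.applied_steps),
            "n_valid": int(self.valid_mask.sum()),
            "n_csf_reference": int(self.csf_mask_eroded.sum()),
            "flag_counts": {k: int(np.sum(v)) for k, v in self.flags.items()},
            "b1t_range": [float(self.b1t_hat.min()), float(self.b1t_hat.max())],
            "water_brain_mean": float(self.water_map[self.valid_mask].mean())
            if self.valid_mask.any() else float("nan"),
        }


# ---------------------------------------------------------------------------
# step i — transmit field

def estimate_b1t(b1_series, angles_deg=None, mask=None, smooth_fwhm_mm=24.0,
                 voxel_size_mm=3.0, grid=(0.3, 1.7, 0.001), chunk=8192):
    """Per-voxel transmit-efficiency b from the multi-flip-angle series.

    Fits S(a) = A * sin(b * a_nominal), A > 0, by least squares over a dense
    grid of b with parabolic refinement of the minimum.  The map is then
    smoothed with a wide Gaussian kernel (B1 is physically smooth); pass
    ``smooth_fwhm_mm=0`` for the raw fit.

    ``b1_series`` is a list of (fa_deg, volume) pairs or, with
    ``angles_deg`` given, a list of volumes.
    """
    if angles_deg is None:
        angles_deg = [fa for fa, _ in b1_series]
        vols = [v for _, v in b1_series]
    else:
        vols = list(b1_series)
    if len(vols) < 3:
        raise ValueError("B1+ estimation requires at least 3 flip angles")
    shape = vols[0].shape
    if mask is None:
        mask = np.ones(shape, bool)
    S = np.stack([v[mask] for v in vols], axis=1)   # (N, K)
    alpha = np.deg2rad(np.asarray(angles_deg, float))

    lo, hi, step = grid
    bgrid = np.linspace(lo, hi, int(round((hi - lo) / step)) + 1)
    sinmat = np.sin(bgrid[:, None] * alpha[None, :])     # (B, K)
    norm2 = (sinmat ** 2).sum(axis=1)                    # (B,)

    n = S.shape[0]
    b_hat = np.ones(n)
    dead = np.zeros(n, bool)
    ss = (S ** 2).sum(axis=1)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        cross = S[sl] @ sinmat.T                         # (c, B)
        proj = np.where(cross > 0, cross ** 2 / norm2[None, :], 0.0)
        ssr = ss[sl, None] - proj
        idx = np.argmin(ssr, axis=1)
        # parabolic refinement of the discrete minimum
        i0 = np.clip(idx, 1, len(bgrid) - 2)
        rows = np.arange(ssr.shape[0])
        s_m, s_0, s_p = ssr[rows, i0 - 1], ssr[rows, i0], ssr[rows, i0 + 1]
        denom = s_m - 2 * s_0 + s_p
        shift = np.where(np.abs(denom) > 1e-300,
                         0.5 * (s_m - s_p) / np.where(denom == 0, 1, denom), 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        b_hat[sl] = bgrid[i0] + shift * step
        dead[sl] = ss[sl] <= 0
    b_hat[dead] = 1.0

    b1t = np.ones(shape)
    b1t[mask] = b_hat
    flags = np.zeros(shape, bool)
    flags[mask] = dead
    if smooth_fwhm_mm > 0:
        b1t = np.where(mask, masked_gaussian_smooth(
            b1t, mask, smooth_fwhm_mm, voxel_size_mm), 1.0)
    return b1t, flags


# ---------------------------------------------------------------------------
# step ii — T2* relaxometry

def estimate_t2star(multiecho, te_ms, mask=None, max_t2star_ms=2000.0,
                    default_t2star_ms=50.0, min_echoes=3):
    """Per-voxel log-linear fit of ln S against TE.

    t2star = -1/slope, s0 = exp(intercept).  Voxels with a non-positive
    sample in the series are fitted on their positive prefix if it holds at
    least ``min_echoes`` echoes, otherwise flagged and set to the default.
    Non-negative slopes (no decay) yield the ``max_t2star_ms`` cap.
    """
    te = np.asarray(te_ms, float)
    if len(multiecho) != len(te):
        raise ValueError("echo count does not match TE list")
    if len(te) < min_echoes:
        raise ValueError(f"need at least {min_echoes} echoes")
    shape = multiecho[0].shape
    if mask is None:
        mask = np.ones(shape, bool)
    S = np.stack([v[mask] for v in multiecho], axis=1)   # (N, E)
    n, E = S.shape
    pos = S > 0
    # length of the positive prefix per voxel
    prefix = np.where(pos.all(axis=1), E, pos.argmin(axis=1))

    t2s = np.full(n, default_t2star_ms)
    s0 = np.zeros(n)
    flagged = prefix < min_echoes

    for L in range(min_echoes, E + 1):
        sel = prefix == L
        if not sel.any():
            continue
        x = te[:L]
        # regress on ln(S_k / S_0): the first-echo reference cancels any
        # global gain exactly, making the slope scale-invariant.  Weights
        # proportional to S^2 are the Gauss-Markov choice for log-transformed
        # additive noise; expressed as (S_k/S_0)^2 they are gain-invariant too.
        rel = S[sel, :L] / S[sel, :1]
        y = np.log(rel)
        w = rel ** 2
        wsum = w.sum(axis=1)
        xw = (w * x).sum(axis=1) / wsum
        yw = (w * y).sum(axis=1) / wsum
        dx = x[None, :] - xw[:, None]
        slope = (w * dx * (y - yw[:, None])).sum(axis=1) \
            / (w * dx ** 2).sum(axis=1)
        inter = yw - slope * xw + np.log(S[sel, 0])
        vals = np.where(slope < 0, -1.0 / np.where(slope == 0, -1, slope),
                        max_t2star_ms)
        t2s[sel] = np.minimum(vals, max_t2star_ms)
        s0[sel] = np.exp(inter)
        # non-decaying series carry no T2* information: capped and flagged
        flagged[sel] |= slope >= 0
    s0[flagged] = np.where(S[flagged, 0] > 0,
                           S[flagged, 0] * np.exp(te[0] / default_t2star_ms), 0.0)

    def full(v, fill):
        out = np.full(shape, fill, dtype=float)
        out[mask] = v
        return out

    flags = np.zeros(shape, bool)
    flags[mask] = flagged
    return full(t2s, default_t2star_ms), full(s0, 0.0), flags


# ---------------------------------------------------------------------------
# step iii — T1 from the two-scan ratio

def t1_signal_ratio(t1_ms, b1t=1.0, tr_pd=1800.0, fa_pd=40.0,
                    tr_t1=500.0, fa_t1=90.0):
    """Model ratio of the PD scan to the T1-weighting scan (T2* and receive
    terms cancel because both scans share TE)."""
    return (saturation_factor(t1_ms, fa_pd, tr_pd, b1t)
            / saturation_factor(t1_ms, fa_t1, tr_t1, b1t))


def estimate_t1(pd_scan, t1_scan, b1t_hat, mask=None, tr_pd=1800.0,
                fa_pd=40.0, tr_t1=500.0, fa_t1=90.0,
                bracket=(100.0, 6000.0), tol_ms=0.1):
    """Per-voxel T1 by bracketed bisection on the two-scan signal ratio.

    The ratio R(T1) is strictly increasing on the bracket (asserted at run
    time); observed ratios outside the attainable range are clamped to the
    bracket end and flagged.
    """
    shape = pd_scan.shape
    if mask is None:
        mask = np.ones(shape, bool)
    lo0, hi0 = bracket

    # monotonicity check over the observed b1t range
    bmin, bmax = float(np.min(b1t_hat[mask])), float(np.max(b1t_hat[mask]))
    tgrid = np.geomspace(lo0, hi0, 64)
    for b in (bmin, bmax):
        r = t1_signal_ratio(tgrid, b, tr_pd, fa_pd, tr_t1, fa_t1)
        if not np.all(np.diff(r) > 0):
            raise RuntimeError("signal ratio is not monotone in T1 on the "
                               f"bracket for b1t={b:.3f}")

    denom = t1_scan[mask]
    bad_denom = denom <= 0
    ratio = np.where(bad_denom, 1.0, pd_scan[mask] / np.where(bad_denom, 1.0, denom))
    b = b1t_hat[mask]

    r_lo = t1_signal_ratio(lo0, b, tr_pd, fa_pd, tr_t1, fa_t1)
    r_hi = t1_signal_ratio(hi0, b, tr_pd, fa_pd, tr_t1, fa_t1)
    below = ratio <= r_lo
    above = ratio >= r_hi
    clamped = below | above | bad_denom

    lo = np.full(ratio.shape, lo0)
    hi = np.full(ratio.shape, hi0)
    n_iter = int(np.ceil(np.log2((hi0 - lo0) / tol_ms)))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        r_mid = t1_signal_ratio(mid, b, tr_pd, fa_pd, tr_t1, fa_t1)
        go_up = ratio > r_mid
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
    t1 = 0.5 * (lo + hi)
    t1[below] = lo0
    t1[above] = hi0

    out = np.zeros(shape)
    out[mask] = t1
    flags = np.zeros(shape, bool)
    flags[mask] = clamped
    return out, flags


# ---------------------------------------------------------------------------
# step i (receive part)

def estimate_receive_field(recv_array, recv_body, mask=None,
                           smooth_fwhm_mm=15.0, voxel_size_mm=3.0):
    """Receive sensitivity as the smoothed array-coil / body-coil ratio,
    mean-normalized to 1 over the mask."""
    shape = recv_array.shape
    if mask is None:
        mask = np.ones(shape, bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    body = recv_body[mask]
    floor = 0.05 * np.median(body[body > 0]) if np.any(body > 0) else 0.0
    ok = body > floor
    ratio = np.ones(mask.sum())
    ratio[ok] = recv_array[mask][ok] / body[ok]
    vol = np.ones(shape)
    vol[mask] = ratio
    sm_mask = mask.copy()
    sm_mask[mask] = ok
    b1r = np.where(mask, masked_gaussian_smooth(
        vol, sm_mask, smooth_fwhm_mm, voxel_size_mm), 1.0)
    b1r[mask & ~np.isfinite(b1r)] = 1.0
    b1r[mask] /= b1r[mask].mean()
    flags = np.zeros(shape, bool)
    flags[mask] = ~ok
    return b1r, flags


# ---------------------------------------------------------------------------
# steps i–iii applied to the PD scan

def correct_pd(pd_scan, t2star_hat, t1_hat, b1t_hat, b1r_hat, mask=None,
               te_ms=5.2, tr_ms=1800.0, fa_deg=40.0, apply_b1=True,
               apply_t2star=True, apply_t1=True):
    """Divide out receive sensitivity, T2* decay and T1 saturation:

        pd_corrected = pd * exp(TE / T2*)
                       / [ b1r * sin(b1t*a) (1-E1) / (1 - cos(b1t*a) E1) ]

    In the noiseless limit the result is proportional to true water content.
    Near-zero denominators are excluded via the returned validity mask.
    """
    shape = pd_scan.shape
    if mask is None:
        mask = np.ones(shape, bool)
    b1t_eff = b1t_hat if apply_b1 else np.ones(shape)
    b1r_eff = b1r_hat if apply_b1 else np.ones(shape)
    alpha = np.deg2rad(fa_deg) * b1t_eff
    denom = b1r_eff * np.sin(alpha)
    if apply_t1:
        e1 = np.exp(-tr_ms / np.clip(t1_hat, 1.0, None))
        denom = denom * (1 - e1) / (1 - np.cos(alpha) * e1)
    num = pd_scan.copy()
    if apply_t2star:
        num = num * np.exp(te_ms / np.clip(t2star_hat, 1.0, None))

    scale = np.median(np.abs(denom[mask])) if mask.any() else 1.0
    valid = mask & (np.abs(denom) > 1e-6 * scale)
    out = np.zeros(shape)
    out[valid] = num[valid] / denom[valid]
    return out, valid


# ---------------------------------------------------------------------------
# step iv — residual nonuniformity

def _kmeans_1d(values, k=3, max_iter=100):
    """Deterministic 1-D k-means (quantile init, Lloyd updates)."""
    qs = np.quantile(values, (np.arange(k) + 0.5) / k)
    centers = np.asarray(qs, float)
    assign = np.zeros(values.shape, dtype=np.int8)
    for _ in range(max_iter):
        d = np.abs(values[:, None] - centers[None, :])
        new = d.argmin(axis=1).astype(np.int8)
        if np.array_equal(new, assign) and _ > 0:
            break
        assign = new
        for j in range(k):
            sel = assign == j
            if sel.any():
                centers[j] = values[sel].mean()
    return assign, centers


def remove_residual_bias(vol, mask, fwhm_mm=60.0, voxel_size_mm=3.0,
                         n_classes=3, max_iterations=3, tol_log=1e-5):
    """Estimate and divide out smooth residual nonuniformity.

    Homomorphic estimation on the anatomy-removed residual: log intensities
    inside the mask are decomposed into ``n_classes`` piecewise-constant
    levels (1-D k-means, class medians); the residual log map is smoothed
    with a very wide Gaussian kernel (FWHM >= 60 mm, far broader than
    anatomical detail) and exponentiated to give the bias field, which is
    divided out while preserving the brain mean.  Removing the class levels
    first keeps the step an identity (to within a fraction of a percent) on
    bias-free input instead of flattening genuine tissue contrast.

    Two refinements keep that identity tight: voxels whose residual is a
    robust outlier of the class decomposition (mostly partial-volume voxels
    between classes) are excluded from the smoothing support, and the
    estimate is iterated so the smoothing kernel's attenuation of genuinely
    smooth bias is recovered.
    """
    mask = np.asarray(mask, bool) & (np.asarray(vol) > 0)
    if not mask.any():
        raise ValueError("empty brain mask")
    # normalize by the brain mean before the log so the estimate is exactly
    # invariant under a global gain
    work = vol[mask] / vol[mask].mean()
    bias_log_total = np.zeros(mask.sum())
    for _ in range(max_iterations):
        logv = np.log(work / work.mean())
        assign, _ = _kmeans_1d(logv, k=n_classes)
        levels = np.array([np.median(logv[assign == j]) if (assign == j).any()
                           else 0.0 for j in range(n_classes)])
        resid_m = logv - levels[assign]
        # robust support: drop residual outliers (partial-volume voxels)
        mad = np.median(np.abs(resid_m - np.median(resid_m)))
        support_m = np.abs(resid_m) <= max(3.0 * 1.4826 * mad, 1e-12)
        if support_m.sum() < 0.1 * resid_m.size:
            support_m = np.ones_like(support_m)
        resid = np.zeros_like(vol, dtype=float)
        resid[mask] = np.where(support_m, resid_m, 0.0)
        support = np.zeros_like(mask)
        support[mask] = support_m
        step_log = masked_gaussian_smooth(resid, support, fwhm_mm,
                                          voxel_size_mm)[mask]
        step_log = np.nan_to_num(step_log, nan=0.0)
        bias_log_total += step_log
        work = work / np.exp(step_log)
        if np.max(np.abs(step_log)) < tol_log:
            break
    bias = np.ones_like(vol, dtype=float)
    bias[mask] = np.exp(bias_log_total)
    bias[mask] /= bias[mask].mean()
    out = vol.copy().astype(float)
    out[mask] = vol[mask] / bias[mask]
    out[mask] *= vol[mask].mean() / out[mask].mean()
    return out, bias


# ---------------------------------------------------------------------------
# step v — CSF normalization

def normalize_to_csf(pd_corrected, ventricle_mask, min_voxels=20,
                     erode_iterations=1):
    """Scale the corrected map so the eroded ventricular-CSF mean is 100%.

    Erosion guards against partial-volume voxels on the ventricle border.
    Returns (water_map, eroded_mask).
    """
    vent = np.asarray(ventricle_mask, bool)
    eroded = binary_erosion(vent, iterations=erode_iterations) \
        if erode_iterations > 0 else vent
    n = int(eroded.sum())
    if n < min_voxels:
        raise ValueError(
            f"ventricle_mask too small after erosion ({n} voxels, need >= "
            f"{min_voxels}); supply a larger ventricular CSF mask")
    ref = pd_corrected[eroded].mean()
    if ref <= 0:
        raise ValueError("non-positive mean signal in ventricle_mask")
    return 100.0 * pd_corrected / ref, eroded


# ---------------------------------------------------------------------------
# the full chain

def _pooled_reference_relaxometry(acq, region_mask, b1t_hat, t1_hat,
                                  t2star_hat, bracket=(100.0, 6000.0)):
    """Replace per-voxel T1/T2* inside the CSF reference region by pooled
    region fits from the region-mean signals.

    The ventricular reference is one homogeneous compartment; per-voxel
    relaxometry noise there feeds nonlinearly into the global calibration
    factor and biases every tissue value, whereas a single fit on the
    region-mean signals is nearly noise-free.  Operating on ratios of means
    keeps the step exactly gain-invariant.
    """
    from scipy.optimize import brentq

    prot = acq.protocol
    ratio = acq.pd_scan[region_mask].mean() / acq.t1_scan[region_mask].mean()
    b1t_ref = float(b1t_hat[region_mask].mean())

    def f(t1):
        return t1_signal_ratio(t1, b1t_ref, prot["pd"].tr_ms,
                               prot["pd"].fa_deg, prot["t1"].tr_ms,
                               prot["t1"].fa_deg) - ratio

    lo, hi = bracket
    if f(lo) * f(hi) < 0:
        t1_ref = brentq(f, lo, hi, xtol=0.01)
    else:
        t1_ref = hi if ratio > 0 else lo
    t1_hat = t1_hat.copy()
    t1_hat[region_mask] = t1_ref

    te = np.asarray(acq.multiecho_te_ms, float)
    means = np.array([v[region_mask].mean() for v in acq.multiecho])
    if np.all(means > 0):
        y = np.log(means / means[0])
        xm = te.mean()
        slope = ((te - xm) * (y - y.mean())).sum() / ((te - xm) ** 2).sum()
        t2s_ref = min(-1.0 / slope, 2000.0) if slope < 0 else 2000.0
        t2star_hat = t2star_hat.copy()
        t2star_hat[region_mask] = t2s_ref
    return t1_hat, t2star_hat


def map_water(acq: StudyAcquisition, ventricle_mask, brain_mask,
              steps=ALL_STEPS, b1t_smooth_fwhm_mm=24.0,
              b1r_smooth_fwhm_mm=15.0, bias_fwhm_mm=60.0,
              voxel_size_mm=None, pool_reference_relaxometry=True
              ) -> CorrectionChainResult:
    """Run the correction chain i-v in order on one acquisition.

    ``steps`` may omit correction steps for ablation studies; parameter maps
    are estimated regardless so intermediates stay inspectable.
    """
    steps = list(steps)
    unknown = set(steps) - set(ALL_STEPS)
    if unknown:
        raise ValueError(f"unknown correction steps: {sorted(unknown)}")
    vs = voxel_size_mm if voxel_size_mm is not None else acq.voxel_size_mm[0]
    brain = np.asarray(brain_mask, bool)
    prot = acq.protocol

    flags = {}
    b1t_hat, flags["b1t"] = estimate_b1t(
        acq.b1_series, mask=brain, smooth_fwhm_mm=b1t_smooth_fwhm_mm,
        voxel_size_mm=vs)
    t2star_hat, s0_hat, flags["t2star"] = estimate_t2star(
        acq.multiecho, acq.multiecho_te_ms, mask=brain)
    t1_hat, flags["t1"] = estimate_t1(
        acq.pd_scan, acq.t1_scan, b1t_hat, mask=brain,
        tr_pd=prot["pd"].tr_ms, fa_pd=prot["pd"].fa_deg,
        tr_t1=prot["t1"].tr_ms, fa_t1=prot["t1"].fa_deg)
    b1r_hat, flags["b1r"] = estimate_receive_field(
        acq.recv_array, acq.recv_body, mask=brain,
        smooth_fwhm_mm=b1r_smooth_fwhm_mm, voxel_size_mm=vs)

    if pool_reference_relaxometry and "csf_normalization" in steps:
        region = binary_erosion(np.asarray(ventricle_mask, bool))
        if region.sum() >= 20:
            t1_hat, t2star_hat = _pooled_reference_relaxometry(
                acq, region, b1t_hat, t1_hat, t2star_hat)

    applied = []
    apply_b1 = "b1_transmit" in steps
    apply_t2s = "t2star" in steps
    apply_t1s = "t1_saturation" in steps
    pd_corr, valid = correct_pd(
        acq.pd_scan, t2star_hat, t1_hat, b1t_hat, b1r_hat, mask=brain,
        te_ms=prot["pd"].te_ms[0], tr_ms=prot["pd"].tr_ms,
        fa_deg=prot["pd"].fa_deg, apply_b1=apply_b1,
        apply_t2star=apply_t2s, apply_t1=apply_t1s)
    for name, on in (("b1_transmit", apply_b1), ("t2star", apply_t2s),
                     ("t1_saturation", apply_t1s)):
        if on:
            applied.append(name)

    bias_hat = np.ones_like(pd_corr)
    work = pd_corr
    if "residual_bias" in steps:
        work, bias_hat = remove_residual_bias(
            pd_corr, valid, fwhm_mm=bias_fwhm_mm, voxel_size_mm=vs)
        applied.append("residual_bias")

    csf_eroded = np.asarray(ventricle_mask, bool)
    water = work
    if "csf_normalization" in steps:
        water, csf_eroded = normalize_to_csf(work, ventricle_mask)
        applied.append("csf_normalization")

    flags["invalid"] = ~valid & brain
    return CorrectionChainResult(
        b1t_hat=b1t_hat, b1r_hat=b1r_hat, t2star_hat=t2star_hat,
        s0_hat=s0_hat, t1_hat=t1_hat, pd_corrected=pd_corr,
        bias_hat=bias_hat, water_map=water, applied_steps=applied,
        valid_mask=valid, csf_mask_eroded=csf_eroded, flags=flags)
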