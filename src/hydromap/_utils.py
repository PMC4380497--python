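"""Shared numerical helpers: seeding, smoothing, NIfTI I/O."""

from __future__ import annotations

import numpy as np
import nibabel as nib
from scipy.ndimage import gaussian_filter

#: conversion between full width at half maximum and Gaussian sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def spawn_seed(*keys) -> int:
    """Deterministic child seed from a master seed plus context keys.

    Hashing the key tuple through a ``SeedSequence`` means adding a subject
    or a scan never perturbs the noise stream of any other one.
    """
    ints = [int(k) if not isinstance(k, str) else _str_key(k) for k in keys]
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2**31))


def _str_key(s: str) -> int:
    return int.from_bytes(s.encode()[:8].ljust(8, b"\0"), "little") % (2**31)


def rng_from(*keys) -> np.random.Generator:
    return np.random.default_rng(spawn_seed(*keys))


def fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    return fwhm_mm / FWHM_PER_SIGMA / vs


def masked_gaussian_smooth(vol, mask, fwhm_mm, voxel_size_mm):
    """Gaussian smoothing restricted to ``mask`` (normalized convolution).

    Voxels outside the mask neither contribute to nor receive signal, which
    avoids the edge darkening plain filtering produces on masked maps.
    """
    if fwhm_mm <= 0:
        return np.asarray(vol, dtype=float).copy()
    mask = np.asarray(mask, bool)
    sigma = fwhm_to_sigma_vox(fwhm_mm, voxel_size_mm)
    w = mask.astype(float)
    num = gaussian_filter(np.where(mask, vol, 0.0), sigma)
    den = gaussian_filter(w, sigma)
    out = np.zeros_like(num)
    inside = mask & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    return out


def ras_affine(voxel_size_mm) -> np.ndarray:
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    aff = np.diag([vs[0], vs[1], vs[2], 1.0])
    return aff


def save_nifti(vol, path, voxel_size_mm=1.0, dtype=None):
    data = np.asarray(vol)
    if dtype is not None:
        data = data.astype(dtype)
    elif data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, ras_affine(voxel_size_mm))
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine
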