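"""Partial-volume suppression and bivariate (water, T1) tissue classification.

Partial-volume voxels are suppressed by keeping only voxels whose tissue
probability equals one.  WM and GM statistics are then obtained from a
two-component full-covariance Gaussian mixture fitted to the voxelwise
(water content, T1) pairs — a model-based discriminant analysis of the
bivariate histogram.  Classes are relabelled by ascending mean water content
so class 1 is always WM and class 2 GM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from ._utils import spawn_seed


@dataclass
class BivariateHistogram:
    water_edges: np.ndarray
    t1_edges: np.ndarray
    counts: np.ndarray
    n_voxels: int


@dataclass
class TissueClassStats:
    """Per-class summary of the fitted mixture (row order: ascending water)."""

    mean_water: np.ndarray
    sd_water: np.ndarray
    mean_t1: np.ndarray
    sd_t1: np.ndarray
    weight: np.ndarray
    voxel_count: np.ndarray
    labels_: np.ndarray = None          # hard assignment of the input voxels

    @property
    def n_components(self) -> int:
        return len(self.mean_water)

    def as_dict(self, names=("wm", "gm")) -> dict:
        out = {}
        for i, name in enumerate(names[: self.n_components]):
            out[name] = {"mean_water": float(self.mean_water[i]),
                         "sd_water": float(self.sd_water[i]),
                         "mean_t1": float(self.mean_t1[i]),
                         "sd_t1": float(self.sd_t1[i]),
                         "weight": float(self.weight[i]),
                         "n_voxels": int(self.voxel_count[i])}
        return out


def pure_tissue_mask(prob_maps: dict, tol: float = 1e-9) -> np.ndarray:
    """Voxels whose WM, GM or CSF probability equals one (within ``tol``);
    every voxel with any class probability below one is suppressed."""
    stack = np.stack([np.asarray(p) for p in prob_maps.values()])
    return (stack >= 1.0 - tol).any(axis=0)


def bivariate_histogram(water, t1, water_bins=60, t1_bins=60,
                        water_range=(60.0, 105.0), t1_range=(300.0, 4500.0)
                        ) -> BivariateHistogram:
    counts, we, te = np.histogram2d(np.ravel(water), np.ravel(t1),
                                    bins=(water_bins, t1_bins),
                                    range=(water_range, t1_range))
    return BivariateHistogram(water_edges=we, t1_edges=te,
                              counts=counts.astype(int),
                              n_voxels=int(counts.sum()))


def fit_bivariate_gmm(water_values, t1_values, k: int = 2, seed: int = 0,
                      n_init: int = 5, max_iter: int = 300) -> TissueClassStats:
    """EM fit of a k-component full-covariance Gaussian mixture to the
    voxelwise (water, T1) pairs.

    T1 is rescaled internally so both coordinates have comparable spread;
    reported statistics are on the original scales.
    """
    w = np.ravel(np.asarray(water_values, float))
    t = np.ravel(np.asarray(t1_values, float))
    if w.shape != t.shape:
        raise ValueError("water and T1 arrays differ in length")
    if w.size < 100:
        raise ValueError(f"need >= 100 pure voxels to fit the mixture, "
                         f"got {w.size}")
    t1_scale = 10.0                    # ms per water percent, display-like
    X = np.column_stack([w, t / t1_scale])
    gmm = GaussianMixture(n_components=k, covariance_type="full",
                          n_init=n_init, max_iter=max_iter,
                          random_state=spawn_seed(seed, "gmm"),
                          reg_covar=1e-6)
    gmm.fit(X)
    if not gmm.converged_:
        raise RuntimeError(
            f"mixture EM did not converge in {max_iter} iterations "
            f"(lower bound {gmm.lower_bound_:.4g}); increase max_iter or "
            "check the input distribution")
    order = np.argsort(gmm.means_[:, 0])
    hard = gmm.predict(X)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    hard = relabel[hard]
    means = gmm.means_[order]
    covs = gmm.covariances_[order]
    return TissueClassStats(
        mean_water=means[:, 0],
        sd_water=np.sqrt(covs[:, 0, 0]),
        mean_t1=means[:, 1] * t1_scale,
        sd_t1=np.sqrt(covs[:, 1, 1]) * t1_scale,
        weight=gmm.weights_[order],
        voxel_count=np.bincount(hard, minlength=k),
        labels_=hard)


def global_tissue_water(water_map, t1_map, prob_maps, seed: int = 0,
                        k: int = 2, include_csf: bool = False,
                        valid_mask=None) -> TissueClassStats:
    """Pure-voxel selection followed by the bivariate mixture fit.

    CSF is excluded by default: it is the normalization reference, and the
    global WM/GM statistics concern parenchyma.  Pass ``include_csf=True``
    with ``k=3`` to classify all three classes.
    """
    if include_csf:
        sel = pure_tissue_mask(prob_maps)
    else:
        sel = pure_tissue_mask({t: prob_maps[t] for t in ("wm", "gm")
                                if t in prob_maps})
    if valid_mask is not None:
        sel = sel & np.asarray(valid_mask, bool)
    if not sel.any():
        raise ValueError("no pure voxels: every voxel has a tissue "
                         "probability below one")
    return fit_bivariate_gmm(water_map[sel], t1_map[sel], k=k, seed=seed)
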