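"""Whole-volume searchlight decoding and group cluster-level inference.

A sphere (default radius 5 voxels) is centered on every gray-matter voxel;
the mean-centered t-patterns of the in-mask sphere voxels are decoded with
the same PCA + LDA + leave-one-run-out machinery as the ROI analysis, and
accuracy minus chance (1/3) is written back to the seed voxel.  Group
inference smooths the per-subject maps (FWHM 1 mm), computes a voxelwise
one-sample t against zero, forms clusters at p < 0.001 (one-sided), and
assigns cluster-level family-wise-error p-values from a sign-flip
permutation null of the maximum cluster size.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .glm import FWHM_TO_SIGMA, ContrastMap
from .io import StudyConfig, Volume3D
from .mvpa import CHANCE_LEVEL, _condition_rank, cv_predictions

_PERM_STREAM = 31


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer offsets (dx, dy, dz) of the Euclidean lattice ball
    dx^2 + dy^2 + dz^2 <= radius^2."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(radius)
    grid = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(grid, grid, grid, indexing="ij")
    keep = dx ** 2 + dy ** 2 + dz ** 2 <= radius ** 2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def run_searchlight(contrast_maps: list[ContrastMap], gray_mask: Volume3D,
                    config: StudyConfig) -> Volume3D:
    """Per-subject accuracy map: (accuracy - 1/3) at every gray seed voxel,
    NaN outside the mask and at seeds whose sphere holds < 2 usable voxels."""
    shape = gray_mask.data.shape
    maps = sorted(contrast_maps,
                  key=lambda m: (m.run_index, _condition_rank(m.condition)))
    for m in maps:
        if m.t.data.shape != shape:
            raise ValueError("contrast map grid does not match the gray mask")
    data = np.stack([m.t.data for m in maps])          # (n_samples, x, y, z)
    labels = np.array([m.condition for m in maps])
    runs = np.array([m.run_index for m in maps])

    usable = gray_mask.data > 0
    for m in maps:
        usable &= ~m.degenerate
    flat_ok = usable.ravel()
    data_flat = data.reshape(len(maps), -1)

    offsets = sphere_offsets(config.searchlight_radius)
    out = np.full(shape, np.nan)
    seeds = np.argwhere(gray_mask.data > 0)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    with warnings.catch_warnings():
        # clipped spheres with fewer voxels than components pad by design
        warnings.filterwarnings("ignore",
                                message=".*padded with zero-variance.*")
        for seed in seeds:
            vox = seed + offsets
            inside = np.all((vox >= 0) & (vox < shape), axis=1)
            vox = vox[inside]
            flat = vox @ strides
            flat = flat[flat_ok[flat]]
            if flat.size < 2:
                continue
            X = data_flat[:, flat]
            X = X - X.mean(axis=1, keepdims=True)  # mean-centered patterns
            records = cv_predictions(X, labels, runs,
                                     n_components=config.n_components,
                                     pca_within_fold=config.pca_within_fold,
                                     ridge=config.ridge)
            accuracy = sum(t == p for _, t, p in records) / len(records)
            out[tuple(seed)] = accuracy - CHANCE_LEVEL
    return Volume3D(out, gray_mask.affine)


# ---------------------------------------------------------------------------
# Group cluster inference
# ---------------------------------------------------------------------------


def connectivity_structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def label_clusters(binary: np.ndarray, connectivity: int = 6):
    """Connected components of a binary volume (face connectivity default)."""
    labeled, n = ndimage.label(binary, structure=connectivity_structure(connectivity))
    return labeled, n


def _smooth_nan_aware(vol: Volume3D, fwhm_mm: float) -> Volume3D:
    """Gaussian smoothing that renormalises for NaN voxels (outside mask)."""
    if fwhm_mm == 0:
        return vol
    sigma = tuple(fwhm_mm * FWHM_TO_SIGMA / vol.voxel_sizes_mm)
    valid = np.isfinite(vol.data)
    filled = np.where(valid, vol.data, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma, mode="reflect")
    den = ndimage.gaussian_filter(valid.astype(float), sigma=sigma, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(valid, num / den, np.nan)
    return Volume3D(out, vol.affine)


def _sign_flip_t(D: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for every row of ``signs`` (n_perm, S) given data D (S, V).

    Sign flips leave per-voxel sums of squares unchanged, so the permuted
    variance follows from the permuted mean alone.
    """
    s = D.shape[0]
    ss = (D ** 2).sum(axis=0)
    m = signs @ D / s
    var = (ss[None, :] - s * m ** 2) / (s - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(var > 0, m / np.sqrt(var / s), 0.0)
    return t


def group_cluster_inference(accuracy_maps: list[Volume3D],
                            config: StudyConfig,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[Volume3D, pd.DataFrame]:
    """Cluster-level FWE inference on subject accuracy-minus-chance maps.

    Each map is smoothed (FWHM 1 mm), a one-sample t vs 0 is computed per
    voxel, clusters are formed at the one-sided p < 0.001 threshold with
    face connectivity, and the FWE-corrected p of each cluster is
    p = (1 + #{null max size >= observed}) / (1 + n_perm) under random
    sign-flips of the subject maps.
    """
    n_sub = len(accuracy_maps)
    if n_sub < 5:
        raise ValueError("group inference needs at least 5 subjects")
    shape = accuracy_maps[0].data.shape
    affine = accuracy_maps[0].affine
    for m in accuracy_maps:
        if m.data.shape != shape:
            raise ValueError("accuracy maps are not on a common grid")
    if config.n_permutations < 100:
        warnings.warn("fewer than 100 permutations; FWE p-values are coarse")
    if rng is None:
        rng = np.random.default_rng([config.seed, _PERM_STREAM])

    smoothed = [_smooth_nan_aware(m, config.searchlight_smooth_fwhm_mm)
                for m in accuracy_maps]
    stack = np.stack([m.data for m in smoothed])       # (S, x, y, z)
    valid = np.all(np.isfinite(stack), axis=0)
    D = stack[:, valid]                                # (S, V)

    dof = n_sub - 1
    t_thr = stats.t.ppf(1.0 - config.cluster_forming_p, dof)
    t_flat = _sign_flip_t(D, np.ones((1, n_sub)))[0]
    t_map = np.zeros(shape)
    t_map[valid] = t_flat

    supra = np.zeros(shape, dtype=bool)
    supra[valid] = t_flat > t_thr
    labeled, n_clusters = label_clusters(supra, config.connectivity)

    signs = rng.integers(0, 2, size=(config.n_permutations, n_sub)) * 2 - 1
    t_perm = _sign_flip_t(D, signs.astype(float))
    null_max = np.zeros(config.n_permutations, dtype=int)
    perm_supra = np.zeros(shape, dtype=bool)
    for i in range(config.n_permutations):
        perm_supra[:] = False
        perm_supra[valid] = t_perm[i] > t_thr
        lab, k = label_clusters(perm_supra, config.connectivity)
        if k:
            null_max[i] = np.bincount(lab.ravel())[1:].max()

    rows = []
    for cid in range(1, n_clusters + 1):
        in_cluster = labeled == cid
        size = int(in_cluster.sum())
        peak_flat = np.argmax(np.where(in_cluster, t_map, -np.inf))
        peak_idx = np.unravel_index(peak_flat, shape)
        world = affine @ np.array([*peak_idx, 1.0])
        p_fwe = (1 + int((null_max >= size).sum())) / (1 + config.n_permutations)
        rows.append({"cluster_id": cid, "size_voxels": size,
                     "peak_t": float(t_map[peak_idx]),
                     "peak_x_mm": world[0], "peak_y_mm": world[1],
                     "peak_z_mm": world[2], "p_fwe": p_fwe})
    table = pd.DataFrame(rows, columns=["cluster_id", "size_voxels", "peak_t",
                                        "peak_x_mm", "peak_y_mm", "peak_z_mm",
                                        "p_fwe"])
    if len(table):
        table = table.sort_values("size_voxels", ascending=False,
                                  ignore_index=True)
    return Volume3D(t_map, affine), table
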