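"""fMRI quality metrics: TSNR maps, tissue metrics, smoothing, cluster inference.

TSNR is the voxelwise temporal mean divided by the temporal standard deviation
(n-1 denominator); zero-variance voxels are marked invalid and excluded from
every downstream statistic. Paired condition contrasts use a voxelwise paired
t with clusters formed at voxel p < 0.001 (one-sided per contrast direction,
18-connectivity) and cluster-level FWE p from sign-flip permutations — exactly
enumerable at five subjects (2⁵ = 32 flips, minimum attainable p = 1/32).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .recording import VolumeSeries

__all__ = [
    "TSNRImage", "ClusterResult", "tsnr_map", "compartment_metrics",
    "gaussian_smooth", "paired_group_contrast",
]


@dataclass
class TSNRImage:
    """Voxelwise temporal SNR with a validity mask (temporal sd > 0)."""
    values: np.ndarray
    affine: np.ndarray
    valid_mask: np.ndarray
    run_id: str | None = None
    condition_tag: str | None = None


@dataclass
class ClusterResult:
    """Supra-threshold clusters of a paired contrast with permutation FWE p."""
    t_map: np.ndarray
    threshold_t: float
    clusters: pd.DataFrame            # size, peak_t, peak coords (mm), p_fwe
    n_permutations: int
    direction: str = "x_gt_y"


def tsnr_map(vs: VolumeSeries, run_id: str | None = None,
             condition_tag: str | None = None) -> TSNRImage:
    """Temporal mean / temporal (n-1) standard deviation per voxel."""
    mean = vs.data.mean(axis=3)
    sd = vs.data.std(axis=3, ddof=1)
    valid = sd > 0
    values = np.zeros_like(mean)
    values[valid] = mean[valid] / sd[valid]
    if vs.mask is not None:
        valid = valid & vs.mask
    return TSNRImage(values=values, affine=vs.affine, valid_mask=valid,
                     run_id=run_id, condition_tag=condition_tag)


def compartment_metrics(tsnr: TSNRImage, masks: dict[str, np.ndarray],
                        ) -> pd.DataFrame:
    """Mean and median TSNR per tissue compartment plus the GM/WM ratio."""
    keys = [k for k in ("gm", "wm", "csf") if k in masks]
    for a, b in itertools.combinations(keys, 2):
        if np.any(masks[a] & masks[b]):
            raise ValueError(f"tissue masks overlap: {a}/{b}")
    rows = {}
    for tissue in keys:
        sel = masks[tissue] & tsnr.valid_mask
        if not sel.any():
            warnings.warn(f"empty mask for {tissue}", stacklevel=2)
            rows[tissue] = {"mean": np.nan, "median": np.nan, "n_voxels": 0}
            continue
        v = tsnr.values[sel]
        rows[tissue] = {"mean": float(v.mean()), "median": float(np.median(v)),
                        "n_voxels": int(sel.sum())}
    df = pd.DataFrame(rows).T
    if "gm" in rows and "wm" in rows and rows["wm"]["mean"]:
        df.attrs["gm_wm_ratio"] = rows["gm"]["mean"] / rows["wm"]["mean"]
    return df


def gaussian_smooth(vol: np.ndarray, fwhm_mm: float = 8.0,
                    voxel_mm=(3.0, 3.0, 3.0)) -> np.ndarray:
    """Separable Gaussian smoothing with edge renormalization.

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis, converted to voxel units.
    Near the volume edge the truncated kernel is renormalized (data and a
    ones-volume are filtered with zero padding and divided), so a constant
    volume stays constant.
    """
    vol = np.asarray(vol, float)
    sigma = np.asarray(fwhm_mm, float) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = np.atleast_1d(sigma) / np.asarray(voxel_mm, float)
    if sigma_vox.size == 1:
        sigma_vox = np.repeat(sigma_vox, 3)
    num = ndimage.gaussian_filter(vol, sigma_vox, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(np.ones_like(vol), sigma_vox,
                                  mode="constant", cval=0.0)
    return num / den


def _cluster_sizes(above: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Connected components under 18-connectivity; returns (labels, sizes)."""
    structure = ndimage.generate_binary_structure(3, 2)  # faces + edges
    labeled, n = ndimage.label(above, structure=structure)
    if n == 0:
        return labeled, np.array([], int)
    sizes = ndimage.sum_labels(above, labeled, index=np.arange(1, n + 1))
    return labeled, sizes.astype(int)


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """One-sample t of subject differences, stacked on axis 0."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def paired_group_contrast(tsnr_x: list[TSNRImage], tsnr_y: list[TSNRImage],
                          mask: np.ndarray | None = None,
                          voxel_p: float = 0.001, n_perm: int | None = None,
                          seed: int = 0) -> dict[str, ClusterResult]:
    """Paired voxelwise contrast between two conditions with cluster FWE.

    ``tsnr_x[i]`` and ``tsnr_y[i]`` are the two conditions of subject ``i``.
    Both contrast directions are evaluated (one-sided voxel p < ``voxel_p``
    each). Cluster-level FWE p is the proportion of sign-flip permutations
    whose maximum cluster size reaches the observed cluster's size; with
    n <= 12 subjects all 2^n flips are enumerated exactly, which makes the
    p-values deterministic and invariant to subject order.
    """
    if len(tsnr_x) != len(tsnr_y):
        raise ValueError("each subject needs both conditions")
    n = len(tsnr_x)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    diffs = np.stack([a.values - b.values for a, b in zip(tsnr_x, tsnr_y)])
    valid = np.logical_and.reduce([a.valid_mask & b.valid_mask
                                   for a, b in zip(tsnr_x, tsnr_y)])
    if mask is not None:
        valid = valid & mask
    diffs = diffs * valid[None]

    df = n - 1
    t_crit = sps.t.isf(voxel_p, df)
    affine = tsnr_x[0].affine

    if n_perm is None and n <= 12:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        m = n_perm or 1000
        signs = rng.choice([1.0, -1.0], size=(m, n))
        signs[0] = 1.0  # include the identity
    n_total = signs.shape[0]

    # max cluster size distribution per direction under sign flips
    max_sizes = {"pos": np.zeros(n_total, int), "neg": np.zeros(n_total, int)}
    t_obs = None
    for k, s in enumerate(signs):
        t = _paired_t(s[:, None, None, None] * diffs)
        t = np.where(valid, t, 0.0)
        if k == 0 and np.all(s == 1.0):
            t_obs = t
        for key, above in (("pos", t > t_crit), ("neg", -t > t_crit)):
            _, sizes = _cluster_sizes(above)
            max_sizes[key][k] = sizes.max() if sizes.size else 0
    if t_obs is None:
        t_obs = np.where(valid, _paired_t(diffs), 0.0)

    out = {}
    for direction, sign, key in (("x_gt_y", 1.0, "pos"), ("y_gt_x", -1.0, "neg")):
        tmap = sign * t_obs
        labeled, sizes = _cluster_sizes(tmap > t_crit)
        rows = []
        for ci, size in enumerate(sizes, start=1):
            in_cluster = labeled == ci
            peak_flat = np.argmax(np.where(in_cluster, tmap, -np.inf))
            peak_idx = np.unravel_index(peak_flat, tmap.shape)
            peak_mm = (affine @ np.array([*peak_idx, 1.0]))[:3]
            p_fwe = np.count_nonzero(max_sizes[key] >= size) / n_total
            rows.append({"size_voxels": int(size),
                         "peak_t": float(tmap[peak_idx]),
                         "peak_x_mm": peak_mm[0], "peak_y_mm": peak_mm[1],
                         "peak_z_mm": peak_mm[2], "p_fwe": p_fwe})
        clusters = pd.DataFrame(
            rows, columns=["size_voxels", "peak_t", "peak_x_mm", "peak_y_mm",
                           "peak_z_mm", "p_fwe"]
        ).sort_values("size_voxels", ascending=False, ignore_index=True) \
            if rows else pd.DataFrame(
                columns=["size_voxels", "peak_t", "peak_x_mm", "peak_y_mm",
                         "peak_z_mm", "p_fwe"])
        out[direction] = ClusterResult(
            t_map=tmap, threshold_t=float(t_crit), clusters=clusters,
            n_permutations=n_total, direction=direction)
    return out
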