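"""Fuzzy c-means clustering of the pseudo-colored thermogram and ROI extraction.

Fuzzy c-means (FCM) assigns every pixel a graded membership in each of k
clusters (memberships sum to one), which suits the smooth temperature
gradients of thermograms better than hard k-means.  The cluster whose pixels
are on average hottest in the source image is taken as the region of interest;
optional exclusion bands remove the axillae (top of the torso bounding box)
and the sternal midline before nonlinear features are computed on the
resulting binary image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import ThermalImage

__all__ = [
    "FCMConfig",
    "SegmentationResult",
    "fcm_cluster",
    "select_hot_cluster",
    "exclude_regions",
    "refine_roi",
    "binarize_roi",
    "segment_image",
]


@dataclass(frozen=True)
class FCMConfig:
    """Fuzzy c-means settings: k clusters, fuzziness exponent m > 1."""

    k: int = 4
    m: float = 2.0
    max_iter: int = 300
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzziness exponent m must be > 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class SegmentationResult:
    cluster_map: np.ndarray          # (H, W) int labels
    memberships: np.ndarray          # (H, W, k), rows sum to 1 on the mask
    centers: np.ndarray              # (k, n_features)
    objective_history: list[float]
    converged: bool
    mask: np.ndarray                 # foreground mask the clustering ran on
    roi_mask: np.ndarray | None = None
    binary_image: np.ndarray | None = None
    hot_cluster: int | None = None


def _init_centers(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding: spread initial centers over the data."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(((X[:, None, :] - np.asarray(centers)[None]) ** 2).sum(-1), axis=1)
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers.append(X[rng.choice(n, p=probs)])
    return np.asarray(centers, dtype=float)


def fcm_cluster(features: np.ndarray, cfg: FCMConfig = FCMConfig(),
                mask: np.ndarray | None = None) -> SegmentationResult:
    """Cluster per-pixel feature vectors with canonical fuzzy c-means.

    Parameters
    ----------
    features : (H, W, F) or (H, W) array
        Per-pixel feature vectors, e.g. the (hue, saturation, intensity)
        triple of the pseudo-colored image.
    cfg : FCMConfig
    mask : optional binary (H, W) array restricting clustering to foreground.

    Alternates the membership update
    u_ij = 1 / sum_l (d_ij / d_lj)^(2/(m-1)) with the membership-weighted
    center update c_i = sum_j u_ij^m x_j / sum_j u_ij^m until the largest
    center shift drops below ``tol``.  The weighted objective
    J = sum_ij u_ij^m d_ij^2 is recorded every iteration and is non-increasing.
    """
    F = np.asarray(features, dtype=float)
    if F.ndim == 2:
        F = F[..., None]
    h, w, nf = F.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    X = F[mask]  # (n, nf)
    n = X.shape[0]
    uniq = np.unique(X, axis=0)
    if uniq.shape[0] < cfg.k:
        raise ValueError(f"need at least k={cfg.k} distinct pixels, found {uniq.shape[0]}")

    rng = np.random.default_rng(cfg.seed)
    centers = _init_centers(uniq, cfg.k, rng)
    expo = 2.0 / (cfg.m - 1.0)
    history: list[float] = []
    converged = False
    U = None
    for _ in range(cfg.max_iter):
        d2 = ((X[:, None, :] - centers[None]) ** 2).sum(-1)  # (n, k)
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-expo / 2.0)
        U = inv / inv.sum(axis=1, keepdims=True)
        Um = U ** cfg.m
        history.append(float((Um * d2).sum()))
        new_centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn("FCM did not converge within max_iter", RuntimeWarning)

    # final memberships for the final centers
    d2 = np.maximum(((X[:, None, :] - centers[None]) ** 2).sum(-1), 1e-300)
    inv = d2 ** (-expo / 2.0)
    U = inv / inv.sum(axis=1, keepdims=True)

    memberships = np.zeros((h, w, cfg.k))
    memberships[mask] = U
    cluster_map = np.full((h, w), -1, dtype=int)
    cluster_map[mask] = np.argmax(U, axis=1)
    return SegmentationResult(
        cluster_map=cluster_map, memberships=memberships, centers=centers,
        objective_history=history, converged=converged, mask=mask,
    )


def select_hot_cluster(res: SegmentationResult, img: ThermalImage) -> np.ndarray:
    """ROI = pixels of the cluster with the highest mean source intensity.

    Ties (constant foreground) go to the larger cluster, with a warning.
    """
    px = np.asarray(img.pixels, dtype=float)
    k = res.centers.shape[0]
    means = np.full(k, -np.inf)
    sizes = np.zeros(k, dtype=int)
    for c in range(k):
        sel = res.cluster_map == c
        sizes[c] = sel.sum()
        if sizes[c]:
            means[c] = px[sel].mean()
    best = np.flatnonzero(np.isclose(means, means.max()))
    if best.size > 1:
        warnings.warn("tie in cluster mean intensity; choosing the larger cluster", RuntimeWarning)
        best = best[np.argsort(sizes[best])[::-1]]
    hot = int(best[0])
    res.hot_cluster = hot
    res.roi_mask = res.cluster_map == hot
    return res.roi_mask


def exclude_regions(roi_mask: np.ndarray, axilla_frac: float = 0.0,
                    sternum_frac: float = 0.0, keep_largest_per_side: bool = True,
                    torso_mask: np.ndarray | None = None) -> np.ndarray:
    """Remove axillary and sternal bands from the ROI mask.

    ``axilla_frac`` drops the top fraction of the torso bounding box (armpit
    hot spots); ``sternum_frac`` drops a central vertical band of that width
    (sternal midline).  Afterwards only the largest connected component on
    each side of the midline is kept (small speckle is discarded).
    Both fractions zero and ``keep_largest_per_side`` disabled is the identity.
    """
    roi = np.asarray(roi_mask, dtype=bool).copy()
    if not roi.any():
        raise ValueError("empty ROI mask")
    ref = np.asarray(torso_mask, dtype=bool) if torso_mask is not None else roi
    rr, cc = np.nonzero(ref)
    top, bottom = rr.min(), rr.max()
    left, right = cc.min(), cc.max()

    if axilla_frac > 0:
        cut = top + int(round(axilla_frac * (bottom - top + 1)))
        roi[:cut, :] = False
    mid = (left + right) / 2.0
    if sternum_frac > 0:
        half = sternum_frac * (right - left + 1) / 2.0
        cols = np.arange(roi.shape[1])
        roi[:, np.abs(cols - mid) <= half] = False
    if not roi.any():
        raise ValueError("exclusion removed the entire ROI")

    if keep_largest_per_side:
        out = np.zeros_like(roi)
        cols = np.arange(roi.shape[1])[None, :]
        for side in (cols <= mid, cols > mid):
            part = roi & np.broadcast_to(side, roi.shape)
            lab, nlab = ndimage.label(part)
            if nlab:
                sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
                out |= lab == (1 + int(np.argmax(sizes)))
        roi = out
    if not roi.any():
        raise ValueError("exclusion removed the entire ROI")
    return roi


def refine_roi(img: ThermalImage, roi_mask: np.ndarray,
               dilate_iter: int = 8) -> np.ndarray:
    """Coarse-to-fine boundary refinement of the hottest-region mask.

    Clustering runs on a smoothed image, which blurs the lesion outline; this
    step recovers it by re-thresholding the *raw* pixels (Otsu over a dilated
    neighbourhood of the coarse ROI), keeping the largest connected component
    and filling holes.  Falls back to the coarse mask if the refined region
    collapses (e.g. the neighbourhood has no bimodal intensity structure).
    """
    from .preprocess import ThermalImage as _TI
    from .preprocess import otsu_threshold

    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI mask")
    px = np.asarray(img.pixels, dtype=float)
    dil = ndimage.binary_dilation(roi, iterations=dilate_iter)
    vals = px[dil]
    if vals.max() == vals.min():
        return roi
    t = otsu_threshold(_TI(vals[:, None], bit_depth="float", id="roi-neighbourhood"))
    ref = (px > t) & dil
    lab, n = ndimage.label(ref)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab, dtype=float), lab,
                                   index=np.arange(1, n + 1))
        ref = lab == (1 + int(np.argmax(sizes)))
    ref = ndimage.binary_fill_holes(ref)
    if ref.sum() < 0.25 * roi.sum():
        warnings.warn("refined ROI collapsed; keeping the coarse cluster mask", RuntimeWarning)
        return roi
    return ref


def binarize_roi(img: ThermalImage, roi_mask: np.ndarray) -> np.ndarray:
    """Binary image: 1 inside the ROI, 0 elsewhere (input to nonlinear features)."""
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != img.shape:
        raise ValueError("ROI mask shape does not match image")
    if not roi.any():
        raise ValueError("empty ROI")
    return roi.astype(np.uint8)


def segment_image(img: ThermalImage, cfg: FCMConfig = FCMConfig(),
                  axilla_frac: float = 0.0, sternum_frac: float = 0.0,
                  smooth_sigma: float = 4.0, consolidate: bool = True,
                  refine: bool = True) -> SegmentationResult:
    """Full segmentation stage: threshold, pseudo-color, FCM, hottest-region ROI.

    Clustering runs on a Gaussian-smoothed copy of the image (``smooth_sigma``
    pixels) so that fine internal lesion texture does not split the hot region
    across clusters; all downstream features are still taken from the raw
    pixels through the resulting mask.  ``consolidate`` closes small gaps and
    fills holes in the hottest-cluster mask, yielding a solid lesion region.
    """
    from scipy.ndimage import gaussian_filter

    from .preprocess import foreground_mask, pseudo_color_hsi

    src = img
    if smooth_sigma > 0:
        src = ThermalImage(gaussian_filter(np.asarray(img.pixels, dtype=float), smooth_sigma),
                           bit_depth="float", id=img.id)
    mask = foreground_mask(src)
    pc = pseudo_color_hsi(src, mask)
    res = fcm_cluster(pc.stack(), cfg, mask=mask)
    roi = select_hot_cluster(res, src)
    if consolidate:
        roi = ndimage.binary_fill_holes(
            ndimage.binary_closing(roi, structure=np.ones((3, 3)), iterations=2))
        res.roi_mask = roi
    if axilla_frac > 0 or sternum_frac > 0:
        roi = exclude_regions(roi, axilla_frac, sternum_frac, torso_mask=mask)
        res.roi_mask = roi
    if refine:
        roi = refine_roi(img, roi)
        res.roi_mask = roi
    res.binary_image = binarize_roi(img, roi)
    return res
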