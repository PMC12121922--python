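"""Gray-level co-occurrence texture descriptors of the segmented ROI.

The GLCM is the normalized joint histogram of gray-level pairs at a fixed
pixel offset; 21 scalar descriptors (Haralick's originals plus the
Soh/Tsatsoulis cluster statistics and Clausi's normalized inverse-difference
measures) summarise contrast, uniformity and correlation of the lesion
texture.  Descriptors can also be computed on wavelet sub-bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from skimage.feature import graycomatrix

__all__ = [
    "GLCMConfig",
    "TEXTURE_FEATURE_NAMES",
    "quantize_roi",
    "compute_glcm",
    "texture_descriptors",
    "roi_texture_features",
    "dwt_texture",
]

TEXTURE_FEATURE_NAMES = (
    "autocorrelation", "contrast", "correlation", "cluster_prominence",
    "cluster_shade", "dissimilarity", "energy", "entropy", "homogeneity",
    "maximum_probability", "variance", "sum_average", "sum_variance",
    "sum_entropy", "difference_variance", "difference_entropy",
    "imc1", "imc2", "inn", "idn", "idm",
)


@dataclass(frozen=True)
class GLCMConfig:
    """Quantization depth, pixel offsets and directions for the co-occurrence matrix."""

    levels: int = 16
    distances: tuple[int, ...] = (1,)
    angles: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1")


def quantize_roi(img: np.ndarray, roi_mask: np.ndarray | None, levels: int) -> np.ndarray:
    """Equal-width quantization of ROI gray levels into 1..levels; background = 0.

    The sentinel 0 lets non-rectangular ROIs pass through the rectangular pair
    counter: pairs touching the background are discarded afterwards.
    """
    px = np.asarray(img, dtype=float)
    if roi_mask is None:
        roi_mask = np.ones(px.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    vals = px[roi_mask]
    lo, hi = vals.min(), vals.max()
    q = np.zeros(px.shape, dtype=np.int32)
    if hi > lo:
        bins = np.clip(((px - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    else:
        bins = np.zeros(px.shape, dtype=int)
    q[roi_mask] = bins[roi_mask] + 1
    return q


def compute_glcm(img_roi: np.ndarray, cfg: GLCMConfig = GLCMConfig(),
                 roi_mask: np.ndarray | None = None) -> np.ndarray:
    """Normalized co-occurrence matrices, shape (levels, levels, n_dist, n_angle).

    Each slice sums to 1; with ``symmetric`` both pair orders are counted.
    Raises if the ROI admits no pixel pair at any requested offset.
    """
    q = quantize_roi(img_roi, roi_mask, cfg.levels)
    raw = graycomatrix(
        q.astype(np.uint8) if cfg.levels < 255 else q.astype(np.uint16),
        distances=list(cfg.distances), angles=list(cfg.angles),
        levels=cfg.levels + 1, symmetric=cfg.symmetric, normed=False,
    ).astype(float)
    # drop sentinel background row/column, renormalize each (distance, angle) slice
    P = raw[1:, 1:, :, :]
    sums = P.sum(axis=(0, 1))
    if np.any(sums == 0):
        raise ValueError("ROI thinner than the requested offset in every direction")
    if cfg.normalize:
        P = P / sums[None, None, :, :]
    return P


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def texture_descriptors(P: np.ndarray, average_angles: bool = True) -> dict[str, float]:
    """The 21 scalar texture descriptors of one or several normalized GLCMs.

    ``P`` is (L, L) or (L, L, n_dist, n_angle); in the latter case descriptors
    are computed per slice and averaged.  Degenerate matrices (zero marginal
    variance, e.g. a constant ROI) report correlation 1 and information
    measures 0, the perfectly-predictable limit.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim == 2:
        return _descriptors_single(P)
    slices = [P[:, :, d, a] for d in range(P.shape[2]) for a in range(P.shape[3])]
    per = [_descriptors_single(s) for s in slices]
    if not average_angles:
        return per  # type: ignore[return-value]
    return {k: float(np.mean([d[k] for d in per])) for k in TEXTURE_FEATURE_NAMES}


def _descriptors_single(P: np.ndarray) -> dict[str, float]:
    L = P.shape[0]
    i = np.arange(L, dtype=float)[:, None]
    j = np.arange(L, dtype=float)[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((np.arange(L) * px).sum())
    mu_y = float((np.arange(L) * py).sum())
    var_x = float(((np.arange(L) - mu_x) ** 2 * px).sum())
    var_y = float(((np.arange(L) - mu_y) ** 2 * py).sum())
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)

    diff = np.abs(i - j)
    ssum = i + j

    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ssum.astype(int)).ravel(), P.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, (diff.astype(int)).ravel(), P.ravel())
    ks = np.arange(2 * L - 1, dtype=float)
    kd = np.arange(L, dtype=float)

    out: dict[str, float] = {}
    out["autocorrelation"] = float((i * j * P).sum())
    out["contrast"] = float(((i - j) ** 2 * P).sum())
    if sd_x > 0 and sd_y > 0:
        out["correlation"] = float(((i - mu_x) * (j - mu_y) * P).sum() / (sd_x * sd_y))
    else:
        out["correlation"] = 1.0
    out["cluster_prominence"] = float(((ssum - mu_x - mu_y) ** 4 * P).sum())
    out["cluster_shade"] = float(((ssum - mu_x - mu_y) ** 3 * P).sum())
    out["dissimilarity"] = float((diff * P).sum())
    out["energy"] = float((P ** 2).sum())
    out["entropy"] = _entropy(P)
    out["homogeneity"] = float((P / (1.0 + diff)).sum())
    out["maximum_probability"] = float(P.max())
    out["variance"] = float(((i - mu_x) ** 2 * P).sum())
    sum_avg = float((ks * p_sum).sum())
    out["sum_average"] = sum_avg
    out["sum_variance"] = float(((ks - sum_avg) ** 2 * p_sum).sum())
    out["sum_entropy"] = _entropy(p_sum)
    diff_avg = float((kd * p_diff).sum())
    out["difference_variance"] = float(((kd - diff_avg) ** 2 * p_diff).sum())
    out["difference_entropy"] = _entropy(p_diff)

    # information measures of correlation
    hxy = out["entropy"]
    hx, hy = _entropy(px), _entropy(py)
    pxy = px[:, None] * py[None, :]
    nz = (P > 0) & (pxy > 0)
    hxy1 = float(-(P[nz] * np.log(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log(pxy[nz2])).sum())
    denom = max(hx, hy)
    out["imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    out["inn"] = float((P / (1.0 + diff ** 2 / L ** 2)).sum())   # inverse difference moment normalized
    out["idn"] = float((P / (1.0 + diff / L)).sum())             # inverse difference normalized
    out["idm"] = float((P / (1.0 + (i - j) ** 2)).sum())         # classic inverse difference moment
    return out


def roi_texture_features(img: np.ndarray, roi_mask: np.ndarray | None = None,
                         cfg: GLCMConfig = GLCMConfig()) -> dict[str, float]:
    """21 angle-averaged descriptors of the ROI gray levels."""
    P = compute_glcm(img, cfg, roi_mask=roi_mask)
    return texture_descriptors(P)


def dwt_texture(img: np.ndarray, roi_mask: np.ndarray | None = None,
                wavelet: str = "db4", level: int = 1,
                cfg: GLCMConfig = GLCMConfig(), include_details: bool = False):
    """Descriptors on wavelet sub-bands of the ROI bounding box.

    ``level=0`` is the identity (plain ROI descriptors).  The 2-D transform is
    applied to the ROI bounding box (background filled with the ROI mean so the
    transform sees no artificial step); descriptors are computed on the
    approximation band, optionally also on each detail band.
    Returns a dict for the approximation band, or a dict of dicts keyed
    ``approx``/``horiz``/``vert``/``diag`` when ``include_details`` is set.
    """
    if level == 0:
        return roi_texture_features(img, roi_mask, cfg)
    px = np.asarray(img, dtype=float)
    if roi_mask is None:
        roi_mask = np.ones(px.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    rr, cc = np.nonzero(roi_mask)
    box = px[rr.min():rr.max() + 1, cc.min():cc.max() + 1].copy()
    boxmask = roi_mask[rr.min():rr.max() + 1, cc.min():cc.max() + 1]
    if min(box.shape) < 2 ** level:
        raise ValueError("ROI bounding box smaller than 2^level in one dimension")
    box[~boxmask] = px[roi_mask].mean()

    # periodization keeps a constant region exactly constant at the boundary
    coeffs = pywt.wavedec2(box, wavelet=wavelet, level=level, mode="periodization")
    approx = coeffs[0]
    out_a = roi_texture_features(approx, None, cfg)
    if not include_details:
        return out_a
    ch, cv, cd = coeffs[1]
    return {
        "approx": out_a,
        "horiz": roi_texture_features(ch, None, cfg),
        "vert": roi_texture_features(cv, None, cfg),
        "diag": roi_texture_features(cd, None, cfg),
    }
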