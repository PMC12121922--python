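"""Chaotic (nonlinear) indices of the segmented lesion.

Four complexity invariants characterise the lesion beyond second-order
texture: the box-counting fractal dimension of the binary ROI shape, and —
on the ROI gray levels serialized to a 1-D sequence and reconstructed in a
time-delay embedding — the largest Lyapunov exponent (Jacobian method), the
Kolmogorov–Sinai entropy estimated in the sample-entropy form
-ln(C_{m+1}/C_m), and the Grassberger–Procaccia correlation dimension.
Malignant lesions, with their irregular boundaries and disordered internal
heat pattern, score higher on all four.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "EmbeddingConfig",
    "image_to_series",
    "box_counting_fd",
    "delay_from_mutual_information",
    "dim_from_false_neighbors",
    "embed",
    "lle_jacobian",
    "ks_entropy",
    "correlation_sum",
    "correlation_dimension",
    "roi_chaos_features",
    "CHAOS_FEATURE_NAMES",
]

CHAOS_FEATURE_NAMES = ("fd", "lle", "kse", "cd")


@dataclass(frozen=True)
class EmbeddingConfig:
    """Time-delay embedding settings.

    ``dim``/``delay`` of ``None`` mean automatic choice: the delay at the
    first minimum of the auto mutual information, and the smallest dimension
    with under 5 % false nearest neighbours (capped at ``max_dim``).
    ``theiler`` of ``None`` defaults to dim * delay.
    """

    dim: int | None = None
    delay: int | None = None
    series_order: str = "row_major"
    theiler: int | None = None
    max_dim: int = 10

    def __post_init__(self) -> None:
        if self.dim is not None and self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.delay is not None and self.delay < 1:
            raise ValueError("delay must be >= 1")
        if self.theiler is not None and self.theiler < 0:
            raise ValueError("theiler must be >= 0")


# ---------------------------------------------------------------------------
# serialization and embedding
# ---------------------------------------------------------------------------

def image_to_series(img: np.ndarray, roi_mask: np.ndarray | None = None,
                    order: str = "row_major") -> np.ndarray:
    """Serialize ROI pixels to a 1-D sequence in a deterministic scan order.

    ``row_major`` and ``column_major`` are raster scans; ``hilbert`` follows a
    Hilbert space-filling curve, which preserves 2-D locality in the 1-D
    sequence.  Length equals the ROI pixel count.
    """
    px = np.asarray(img, dtype=float)
    if roi_mask is None:
        roi_mask = np.ones(px.shape, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    if order == "row_major":
        return px[roi_mask]
    if order == "column_major":
        return px.T[roi_mask.T]
    if order == "hilbert":
        side = 1 << int(np.ceil(np.log2(max(px.shape))))
        d = _hilbert_index(side, *np.nonzero(roi_mask))
        idx = np.argsort(d, kind="stable")
        return px[roi_mask][idx]
    raise ValueError(f"unknown scan order {order!r}")


def _hilbert_index(side: int, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Distance along the Hilbert curve of order log2(side) for (row, col) points."""
    x = cols.astype(np.int64).copy()
    y = rows.astype(np.int64).copy()
    d = np.zeros_like(x)
    s = side // 2
    while s > 0:
        rx = ((x & s) > 0).astype(np.int64)
        ry = ((y & s) > 0).astype(np.int64)
        d += s * s * ((3 * rx) ^ ry)
        # rotate/reflect quadrant
        swap = ry == 0
        flip = swap & (rx == 1)
        x[flip] = s - 1 - x[flip]
        y[flip] = s - 1 - y[flip]
        xs, ys = x[swap].copy(), y[swap].copy()
        x[swap], y[swap] = ys, xs
        s //= 2
    return d


def embed(series: np.ndarray, dim: int, delay: int) -> np.ndarray:
    """Delay-coordinate matrix of shape (N - (dim-1)*delay, dim)."""
    x = np.asarray(series, dtype=float).ravel()
    n = x.size - (dim - 1) * delay
    if n < 1:
        raise ValueError("series too short for this embedding")
    return np.stack([x[i * delay:i * delay + n] for i in range(dim)], axis=1)


def delay_from_mutual_information(series: np.ndarray, max_lag: int | None = None,
                                  bins: int = 16) -> int:
    """First local minimum of the auto mutual information (lag in samples)."""
    x = np.asarray(series, dtype=float).ravel()
    if x.std() == 0:
        return 1
    max_lag = max_lag or max(2, min(50, x.size // 10))
    mis = []
    for lag in range(1, max_lag + 1):
        h, _, _ = np.histogram2d(x[:-lag], x[lag:], bins=bins)
        p = h / h.sum()
        px_, py_ = p.sum(1), p.sum(0)
        nz = p > 0
        mis.append(float((p[nz] * np.log(p[nz] / (px_[:, None] * py_[None, :])[nz])).sum()))
    first_min = None
    for i in range(1, len(mis) - 1):
        if mis[i] < mis[i - 1] and mis[i] <= mis[i + 1]:
            first_min = i + 1
            break
    # a strongly chaotic map loses memory almost immediately and its MI curve
    # decays into a noise floor whose wiggles are not real minima; the
    # autocorrelation 1/e time guards against picking one of those
    ac_lag = max_lag
    x0 = x - x.mean()
    denom = float(x0 @ x0)
    for lag in range(1, max_lag + 1):
        if denom == 0 or (x0[:-lag] @ x0[lag:]) / denom < np.exp(-1.0):
            ac_lag = lag
            break
    return max(1, min(first_min or max_lag, ac_lag))


def dim_from_false_neighbors(series: np.ndarray, delay: int, max_dim: int = 10,
                             frac: float = 0.05, rtol: float = 15.0,
                             atol: float = 2.0, theiler: int | None = None) -> int:
    """Smallest embedding dimension with under ``frac`` false nearest neighbours."""
    x = np.asarray(series, dtype=float).ravel()
    sd = x.std()
    if sd == 0:
        return 1
    for d in range(1, max_dim):
        Y = embed(x, d, delay)
        nxt = x[d * delay:]
        n = min(Y.shape[0], nxt.size)
        Y = Y[:n]
        W = theiler if theiler is not None else d * delay
        nn_idx, nn_dist = _nearest_neighbor(Y, W)
        ok = nn_dist > 0
        if not ok.any():
            return d
        extra = np.abs(nxt[:n][ok] - nxt[:n][nn_idx[ok]])
        false = (extra / nn_dist[ok] > rtol) | (np.sqrt(nn_dist[ok] ** 2 + extra ** 2) / sd > atol)
        if false.mean() < frac:
            return d
    return max_dim


def _nearest_neighbor(Y: np.ndarray, theiler: int) -> tuple[np.ndarray, np.ndarray]:
    """Temporally-excluded nearest neighbour of every embedded point."""
    tree = cKDTree(Y)
    k = min(Y.shape[0], 2 * theiler + 4)
    dist, idx = tree.query(Y, k=k)
    n = Y.shape[0]
    t = np.arange(n)[:, None]
    valid = np.abs(idx - t) > theiler
    # first valid neighbour per row; rows with none fall back to the farthest
    first = np.argmax(valid, axis=1)
    has = valid.any(axis=1)
    first[~has] = k - 1
    return idx[np.arange(n), first], dist[np.arange(n), first]


# ---------------------------------------------------------------------------
# box-counting fractal dimension
# ---------------------------------------------------------------------------

def box_counting_fd(binary_image: np.ndarray,
                    box_sizes: "list[int] | None" = None) -> float:
    """Box-counting dimension of a planar binary set.

    Crops to the bounding box, anchors the grid at its corner, counts occupied
    boxes N(s) for each size s, and returns the least-squares slope of
    log N(s) against log(1/s).  Default sizes are powers of two from 2 up to
    min(height, width)/4 of the bounding box.
    """
    pts = np.argwhere(np.asarray(binary_image) != 0)
    if pts.size == 0:
        raise ValueError("empty set")
    pts = pts - pts.min(axis=0)
    h, w = pts.max(axis=0) + 1
    if box_sizes is None:
        smax = max(max(h, w) // 2, 1)  # larger bbox extent, so small/1-D sets still span scales
        box_sizes = [s for s in (2 ** np.arange(1, 16)) if s <= smax]
    if len(box_sizes) < 3:
        raise ValueError("need at least 3 box sizes; set is too small")
    counts = []
    for s in box_sizes:
        boxes = pts // s
        counts.append(len(np.unique(boxes[:, 0].astype(np.int64) * (w // s + 2) + boxes[:, 1])))
    counts = np.asarray(counts, dtype=float)
    if np.all(counts == counts[0]) and counts[0] == 1:
        raise ValueError("scale range too narrow: one occupied box at every scale")
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(box_sizes, dtype=float)), np.log(counts), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# largest Lyapunov exponent (Jacobian / Eckmann–Ruelle method)
# ---------------------------------------------------------------------------

def lle_jacobian(series: np.ndarray, emb: EmbeddingConfig = EmbeddingConfig(),
                 n_neighbors: int | None = None, max_steps: int = 2000,
                 min_length: int = 500, rank_rtol: float = 0.05) -> float:
    """Largest Lyapunov exponent in nats per sample (Jacobian method).

    Reconstructs the attractor by time-delay embedding and fits, at each orbit
    point, a local linear map by least squares over its nearest neighbours
    (Theiler-excluded).  The fit is performed in the local tangent frame: the
    singular-value decomposition of the neighbour displacements gives the
    directions the data actually explores (singular values above
    ``rank_rtol`` of the leading one), which keeps the map well-posed when the
    attractor is a thin curve inside the embedding space.  The leading growth
    vector is propagated through the chain of local maps with
    re-orthonormalization at every step (the one-column QR product); the
    exponent is the mean log growth.  A constant (zero-variance) series is
    degenerate and reports 0.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < min_length:
        raise ValueError(f"series must have at least {min_length} samples")
    if x.std() == 0:
        warnings.warn("constant series: Lyapunov exponent undefined, reporting 0", RuntimeWarning)
        return 0.0
    tau = emb.delay or delay_from_mutual_information(x)
    m = emb.dim or dim_from_false_neighbors(x, tau, emb.max_dim)
    W = emb.theiler if emb.theiler is not None else m * tau
    Y = embed(x, m, tau)
    M = Y.shape[0]
    if M - 1 <= 10 * m:
        raise ValueError("too few embedded points for the requested dimension")
    k = n_neighbors or max(2 * m + 4, 10)

    T = min(M - 1, max_steps)
    tree = cKDTree(Y[:-1])
    kq = min(M - 1, k + 2 * W + 2)
    _, idxs = tree.query(Y[:T + 1], k=kq)

    neigh: list[np.ndarray] = []
    bases: list[np.ndarray | None] = []
    for t in range(T + 1):
        cand = idxs[t]
        cand = cand[np.abs(cand - t) > W][:k]
        neigh.append(cand)
        if cand.size >= 2:
            _, s, Vt = np.linalg.svd(Y[cand] - Y[t], full_matrices=False)
            q = max(1, int((s > rank_rtol * s[0]).sum())) if s[0] > 0 else 1
            bases.append(Vt[:q].T)
        else:
            bases.append(None)

    v: np.ndarray | None = None
    total, steps = 0.0, 0
    for t in range(T):
        cand = neigh[t]
        if cand.size < 2 or bases[t] is None or bases[t + 1] is None:
            v = None
            continue
        B = (Y[cand] - Y[t]) @ bases[t]
        C = (Y[cand + 1] - Y[t + 1]) @ bases[t + 1]
        Mq, *_ = np.linalg.lstsq(B, C, rcond=None)  # local map, frame t -> t+1
        if v is None or v.shape[0] != Mq.shape[0]:
            v = np.full(Mq.shape[0], 1.0 / np.sqrt(Mq.shape[0]))
        w = Mq.T @ v
        norm = float(np.linalg.norm(w))
        if norm <= 0:
            v = None
            continue
        total += np.log(norm)
        steps += 1
        v = w / norm
    if steps == 0:
        raise ValueError("too few neighbors: could not fit any local map")
    return total / steps


# ---------------------------------------------------------------------------
# Kolmogorov–Sinai entropy (sample-entropy estimator)
# ---------------------------------------------------------------------------

def ks_entropy(series: np.ndarray, m: int = 2, r: float | None = None,
               max_points: int = 3000) -> float:
    """KS entropy estimate -ln(C_{m+1}(r) / C_m(r)) (sample-entropy form).

    Template similarity uses the Chebyshev distance with tolerance ``r``
    (default 0.2 x series SD); self-matches are excluded.  Series longer than
    ``max_points`` are truncated (the estimator is length-stable).
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < m + 3:
        raise ValueError("series too short for the requested template length")
    if x.size > max_points:
        x = x[:max_points]
    if r is None:
        r = 0.2 * x.std()
    if r < 0:
        raise ValueError("tolerance r must be non-negative")
    n = x.size - m  # both template lengths use the same N - m starting points
    b = _template_matches(x, m, r, n)
    a = _template_matches(x, m + 1, r, n)
    if b == 0 or a == 0:
        raise ValueError("no matches; increase r")
    return float(-np.log(a / b))


def _template_matches(x: np.ndarray, m: int, r: float, n: int) -> int:
    """Ordered pairs i<j (of ``n`` starting points) of m-templates within Chebyshev r."""
    if n < 2:
        return 0
    Y = embed(x, m, 1)[:n]
    D = cdist(Y, Y, metric="chebyshev")
    iu = np.triu_indices(n, k=1)
    return int((D[iu] <= r).sum())


# ---------------------------------------------------------------------------
# correlation dimension (Grassberger–Procaccia)
# ---------------------------------------------------------------------------

def correlation_sum(points: np.ndarray, radii: np.ndarray,
                    theiler: int = 0) -> np.ndarray:
    """C(r) = fraction of (Theiler-excluded) point pairs closer than r."""
    P = np.asarray(points, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    n = P.shape[0]
    D = cdist(P, P)
    i, j = np.triu_indices(n, k=1)
    keep = (j - i) > theiler
    d = D[i[keep], j[keep]]
    if d.size == 0:
        raise ValueError("no admissible pairs (Theiler window too large)")
    radii = np.asarray(radii, dtype=float)
    return np.array([(d < r).mean() for r in radii])


def correlation_dimension(data: np.ndarray, emb: EmbeddingConfig = EmbeddingConfig(),
                          radii: np.ndarray | None = None,
                          max_points: int = 1200,
                          scaling_percentiles: tuple[float, float] = (0.5, 10.0),
                          min_r2: float = 0.98) -> float:
    """Correlation dimension: slope of log C(r) versus log r.

    ``data`` may be a scalar series (delay-embedded per ``emb``) or an (n, d)
    point set used as-is.  Default radii are log-spaced between the 0.5th and
    10th percentile of pairwise distances — the small-radius regime where the
    correlation sum scales as a clean power law before boundary saturation
    bends it.  A fit with R^2 below ``min_r2`` triggers a warning.
    """
    X = np.asarray(data, dtype=float)
    theiler = 0
    if X.ndim == 1:
        if X.std() == 0:
            warnings.warn("constant series: correlation dimension 0", RuntimeWarning)
            return 0.0
        tau = emb.delay or delay_from_mutual_information(X)
        m = emb.dim or dim_from_false_neighbors(X, tau, emb.max_dim)
        X = embed(X, m, tau)
        theiler = emb.theiler if emb.theiler is not None else m * tau
    if X.shape[0] < 200:
        raise ValueError("need at least 200 embedded points")
    if X.shape[0] > max_points:
        stride = int(np.ceil(X.shape[0] / max_points))
        X = X[::stride]
        theiler = max(theiler // stride, 0)

    D = cdist(X, X)
    i, j = np.triu_indices(X.shape[0], k=1)
    keep = (j - i) > theiler
    d = D[i[keep], j[keep]]
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("empty scaling region: all pairwise distances are zero")
    if radii is None:
        lo, hi = np.percentile(d, scaling_percentiles)
        if not hi > lo > 0:
            raise ValueError("empty scaling region")
        radii = np.geomspace(lo, hi, 10)
    C = np.array([(d < r).mean() for r in radii])
    ok = C > 0
    if ok.sum() < 3:
        raise ValueError("empty scaling region: correlation sum vanishes")
    lr, lc = np.log(np.asarray(radii)[ok]), np.log(C[ok])
    slope, intercept = np.polyfit(lr, lc, 1)
    resid = lc - (slope * lr + intercept)
    ss_tot = ((lc - lc.mean()) ** 2).sum()
    if ss_tot > 0 and 1.0 - (resid ** 2).sum() / ss_tot < min_r2:
        warnings.warn("correlation-sum fit is not cleanly linear (R^2 below threshold)",
                      RuntimeWarning)
    return float(slope)


# ---------------------------------------------------------------------------
# per-image feature wrapper
# ---------------------------------------------------------------------------

def roi_chaos_features(img: np.ndarray, roi_mask: np.ndarray,
                       binary_image: np.ndarray | None = None,
                       emb: EmbeddingConfig = EmbeddingConfig(),
                       fd_on: str = "boundary") -> dict[str, float]:
    """The four chaotic indices of one segmented image.

    The fractal dimension is computed on the binary ROI: by default on its
    boundary curve (``fd_on="boundary"``), whose dimension ranges over [1, 2)
    and rises with lesion-outline irregularity — the scale on which reported
    lesion FD values live; ``fd_on="filled"`` measures the full
    boundary-plus-interior set instead.  The Lyapunov exponent, KS entropy and
    correlation dimension are computed on the serialized gray-level sequence
    of the ROI.
    """
    from scipy.ndimage import binary_erosion

    if binary_image is None:
        binary_image = np.asarray(roi_mask, dtype=np.uint8)
    if fd_on == "boundary":
        solid = np.asarray(binary_image, dtype=bool)
        binary_image = solid & ~binary_erosion(solid)
    elif fd_on != "filled":
        raise ValueError(f"fd_on must be 'boundary' or 'filled', got {fd_on!r}")
    series = image_to_series(img, roi_mask, order=emb.series_order)
    out = {"fd": box_counting_fd(binary_image)}
    # cohort ROIs can fall below the canonical series-length floor after
    # conservative segmentation; the estimator degrades gracefully there
    out["lle"] = lle_jacobian(series, emb, max_steps=600, min_length=64)
    sd = series.std()
    try:
        out["kse"] = ks_entropy(series, m=2, r=0.2 * sd if sd > 0 else None)
    except ValueError:
        out["kse"] = float(-np.log(1.0 / series.size))  # saturated: no m+1 matches
    try:
        out["cd"] = correlation_dimension(series, emb, max_points=600)
    except ValueError:
        out["cd"] = 0.0
    return out
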