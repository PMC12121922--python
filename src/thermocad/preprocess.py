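"""Thermogram ingestion, Otsu foreground thresholding and HSI pseudo-coloring.

A thermogram is a grayscale map of emitted heat; the torso is much warmer than
the background, so a single global threshold separates foreground from
background.  Pseudo-coloring maps gray level to hue (blue = cool, red = hot)
in the hue/saturation/intensity colour space, which is both the conventional
clinical rendering and the feature space later handed to fuzzy clustering.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ThermalImage",
    "PseudoColorImage",
    "load_image",
    "save_image",
    "otsu_threshold",
    "foreground_mask",
    "pseudo_color_hsi",
]


@dataclass(frozen=True)
class ThermalImage:
    """A 2-D intensity matrix (gray levels or temperature units) plus metadata."""

    pixels: np.ndarray
    bit_depth: int | str = 8  # 8, 16 or "float"
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("thermal image must be a 2-D matrix")
        if not np.all(np.isfinite(px.astype(float))):
            raise ValueError("thermal image contains non-finite values")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class PseudoColorImage:
    """Hue/saturation/intensity planes, each the source shape with values in [0, 1]."""

    hue: np.ndarray
    saturation: np.ndarray
    intensity: np.ndarray

    def stack(self) -> np.ndarray:
        """(H, W, 3) array of the three channels, clustering feature order (h, s, i)."""
        return np.dstack([self.hue, self.saturation, self.intensity])


def load_image(path: str | os.PathLike, id: str | None = None) -> ThermalImage:
    """Read a PNG/TIFF image or a plain-text/CSV thermal matrix."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".csv", ".txt"):
        px = np.loadtxt(path, delimiter="," if ext == ".csv" else None)
        depth: int | str = "float"
    else:
        px = iio.imread(path)
        if px.ndim == 3:  # flatten an RGB export to luminance
            px = px[..., :3].mean(axis=2)
        depth = 16 if px.dtype == np.uint16 else 8
    return ThermalImage(pixels=px, bit_depth=depth, id=id or os.path.basename(path))


def save_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an array as PNG/TIFF (bool/float arrays are scaled to 8-bit)."""
    arr = np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype.kind == "f":
        arr = np.clip(arr * 255, 0, 255).astype(np.uint8)
    iio.imwrite(os.fspath(path), arr)


def _histogram(px: np.ndarray, bit_depth) -> tuple[np.ndarray, np.ndarray]:
    # 256 bins for 8-bit data, 1024 for deeper/float data
    if bit_depth == 8:
        edges = np.arange(257)
        counts, _ = np.histogram(px, bins=edges)
        centers = np.arange(256, dtype=float)
    else:
        nbins = 1024
        lo, hi = float(px.min()), float(px.max())
        counts, edges = np.histogram(px, bins=nbins, range=(lo, hi))
        centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def otsu_threshold(img: ThermalImage) -> float:
    """Gray level maximizing between-class variance of the intensity histogram.

    Pixels strictly above the returned threshold are foreground.  The scan is
    exhaustive over histogram bins; ties are broken toward the smallest
    threshold.  Raises on a constant image (degenerate histogram).
    """
    px = np.asarray(img.pixels, dtype=float)
    if px.max() == px.min():
        raise ValueError("degenerate histogram: image is constant")
    counts, centers = _histogram(px, img.bit_depth)
    total = counts.sum()
    p = counts / total
    omega = np.cumsum(p)                     # class-0 probability up to bin t
    mu = np.cumsum(p * centers)              # first moment up to bin t
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    # argmax returns the first (smallest) maximizer, i.e. the tie-break we want
    return float(centers[int(np.argmax(sigma_b))])


def foreground_mask(img: ThermalImage, threshold: float | None = None) -> np.ndarray:
    """Binary mask of pixels strictly above the (Otsu) threshold."""
    if threshold is None:
        threshold = otsu_threshold(img)
    return np.asarray(img.pixels, dtype=float) > threshold


def pseudo_color_hsi(img: ThermalImage, mask: np.ndarray,
                     background_hue: float = 5 / 6) -> PseudoColorImage:
    """Map gray level to an HSI rendering: blue (cool) through red (hot).

    Intensity is the min–max normalized gray level over the mask; hue runs
    linearly from 240° (blue) at the coolest masked pixel to 0° (red) at the
    hottest, stored on a [0, 1] scale; saturation is 1 on the mask.  Background
    pixels receive the reserved ``background_hue`` (default 300°, magenta, a
    hue the foreground ramp never produces) with zero saturation/intensity.
    """
    mask = np.asarray(mask, dtype=bool)
    px = np.asarray(img.pixels, dtype=float)
    if mask.shape != px.shape:
        raise ValueError("mask shape does not match image shape")

    hue = np.full(px.shape, background_hue)
    sat = np.zeros(px.shape)
    inten = np.zeros(px.shape)
    if mask.any():
        fg = px[mask]
        lo, hi = fg.min(), fg.max()
        norm = (fg - lo) / (hi - lo) if hi > lo else np.zeros_like(fg)
        inten[mask] = norm
        # 240 deg -> 0 deg, i.e. hue fraction 2/3 -> 0, monotone decreasing in heat
        hue[mask] = (2.0 / 3.0) * (1.0 - norm)
        sat[mask] = 1.0
    return PseudoColorImage(hue=hue, saturation=sat, intensity=inten)
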