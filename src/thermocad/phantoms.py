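"""Seeded generators for synthetic thermogram phantoms and reference dynamical systems.

Breast thermograms show a warm torso against a cold background, with tumours
appearing as focal hot spots whose boundary irregularity and internal texture
differ between benign and malignant lesions.  The phantom generator emulates
exactly those controllable properties so the whole pipeline — segmentation,
texture and chaotic feature extraction, selection, classification — can be
exercised and validated without access to clinical data.

The module also provides reference series and point sets (logistic map, Henon
map, sine, Sierpinski triangle, ...) whose complexity invariants (Lyapunov
exponent, fractal dimension, correlation dimension) are known in closed form;
they serve as ground-truth oracles for the nonlinear feature estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ThermalImage

__all__ = [
    "PhantomSpec",
    "AttractorSeries",
    "benign_spec",
    "malignant_spec",
    "generate_phantom",
    "generate_series",
    "generate_dataset",
    "planted_feature_table",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic thermogram.

    Attributes
    ----------
    width, height : int
        Image size in pixels (>= 64 each).
    label : str
        ``"benign"`` or ``"malignant"``.
    hotspot_center : tuple[int, int]
        (row, col) of the lesion centre; must lie inside the image together
        with the whole hotspot disk.
    hotspot_radius : float
        Mean lesion radius in pixels.
    boundary_roughness : float
        Amplitude in [0, 1] of the low-order Fourier perturbation of the
        hotspot boundary; larger values give a more irregular (higher fractal
        dimension) lesion outline.
    texture_contrast : float
        Peak-to-background amplitude (gray levels) of the correlated random
        field inside the hotspot.
    texture_corr_len : float
        Correlation length (pixels) of that field; shorter means a busier,
        higher-entropy texture.
    noise_sd : float
        Additive white-noise standard deviation in gray levels.
    seed : int
        Seed for all randomness in this phantom.
    """

    width: int = 128
    height: int = 128
    label: str = "benign"
    hotspot_center: tuple[int, int] = (60, 48)
    hotspot_radius: float = 18.0
    boundary_roughness: float = 0.2
    texture_contrast: float = 12.0
    texture_corr_len: float = 5.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("phantom must be at least 64x64 pixels")
        if not 0.0 <= self.boundary_roughness <= 1.0:
            raise ValueError("boundary_roughness must lie in [0, 1]")
        if self.label not in ("benign", "malignant"):
            raise ValueError(f"unknown label {self.label!r}")
        r, c = self.hotspot_center
        # worst-case boundary excursion is (1 + roughness) * radius
        reach = self.hotspot_radius * (1.0 + self.boundary_roughness)
        if not (reach <= r <= self.height - reach and reach <= c <= self.width - reach):
            raise ValueError("hotspot (including boundary perturbation) must fit inside the image")


@dataclass(frozen=True)
class AttractorSeries:
    """A reference series or planar point set with known complexity.

    ``values`` is a 1-D float array for time series and a 2-D binary array for
    point sets (sierpinski, line, filled_square).
    """

    name: str
    values: np.ndarray
    params: dict = field(default_factory=dict)
    seed: int = 0


# Class-conditional defaults.  Malignant lesions get a strictly rougher
# boundary (higher box-count FD of the lesion outline), shorter texture
# correlation with proportionally stronger pixel noise (higher entropy and
# contrast of the interior heat pattern) — the directions reported for
# malignant thermogram ROIs.
_BENIGN = dict(boundary_roughness=0.18, texture_contrast=12.0, texture_corr_len=5.0,
               noise_sd=1.5)
_MALIGNANT = dict(boundary_roughness=0.55, texture_contrast=22.0, texture_corr_len=2.2,
                  noise_sd=4.0)


def benign_spec(seed: int = 0, **over) -> PhantomSpec:
    """A benign-class phantom spec with per-image jitter drawn from ``seed``."""
    return _jittered_spec("benign", _BENIGN, seed, over)


def malignant_spec(seed: int = 0, **over) -> PhantomSpec:
    """A malignant-class phantom spec with per-image jitter drawn from ``seed``."""
    return _jittered_spec("malignant", _MALIGNANT, seed, over)


def _jittered_spec(label: str, base: dict, seed: int, over: dict) -> PhantomSpec:
    # jitter makes the two classes overlap so that no single feature regime is
    # perfectly separable, mimicking biological variability
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC1A55 if label == "benign" else 0xB10B]))
    params = dict(
        label=label,
        seed=seed,
        hotspot_center=(int(rng.integers(52, 72)), int(rng.integers(44, 58))),
        hotspot_radius=float(rng.uniform(15.0, 21.0)),
        boundary_roughness=float(np.clip(rng.normal(base["boundary_roughness"], 0.07), 0.0, 0.8)),
        texture_contrast=float(max(rng.normal(base["texture_contrast"], 3.0), 2.0)),
        texture_corr_len=float(max(rng.normal(base["texture_corr_len"], 0.8), 1.2)),
        noise_sd=float(max(rng.normal(base["noise_sd"], 0.5), 0.5)),
    )
    params.update(over)
    return PhantomSpec(**params)


def generate_phantom(spec: PhantomSpec) -> ThermalImage:
    """Render one synthetic thermogram.

    The scene is a warm torso ellipse with two slightly warmer breast regions
    on a cold background, plus an elliptical hot spot whose boundary is a
    circle perturbed by seeded low-order Fourier modes scaled by
    ``boundary_roughness`` and whose interior carries a seeded Gaussian random
    field with correlation length ``texture_corr_len``.

    Returns an 8-bit :class:`~thermocad.preprocess.ThermalImage`; deterministic
    for a fixed spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    rows, cols = np.mgrid[0:h, 0:w].astype(float)

    img = np.full((h, w), 30.0)  # cold background

    # torso ellipse
    cy, cx = h * 0.52, w * 0.5
    torso = ((rows - cy) / (h * 0.46)) ** 2 + ((cols - cx) / (w * 0.38)) ** 2 <= 1.0
    img[torso] = 120.0
    # two breast mounds (smooth radial warm gradients)
    for bc in (w * 0.34, w * 0.66):
        d2 = ((rows - h * 0.55) / (h * 0.28)) ** 2 + ((cols - bc) / (w * 0.17)) ** 2
        img += np.where(torso, 25.0 * np.exp(-d2), 0.0)

    # hotspot mask: polar boundary r(theta) = R * (1 + roughness * sum of modes)
    hot = _rough_disk_mask(
        h, w, spec.hotspot_center, spec.hotspot_radius, spec.boundary_roughness, rng
    )

    # internal texture: correlated Gaussian random field, hotter than surroundings
    field_ = _gaussian_random_field(h, w, spec.texture_corr_len, rng)
    img = np.where(hot, 205.0 + spec.texture_contrast * field_, img)

    img += rng.normal(0.0, spec.noise_sd, size=(h, w))
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ThermalImage(pixels=pixels, bit_depth=8, id=f"phantom_{spec.label}_{spec.seed}")


def hotspot_mask(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth binary mask of the planted hotspot (same RNG stream as the image)."""
    rng = np.random.default_rng(spec.seed)
    return _rough_disk_mask(
        spec.height, spec.width, spec.hotspot_center, spec.hotspot_radius,
        spec.boundary_roughness, rng,
    )


def _rough_disk_mask(h, w, center, radius, roughness, rng) -> np.ndarray:
    # multi-scale Fourier perturbation of a circle: a 1/k^0.6 amplitude
    # spectrum puts power at fine angular scales as well as coarse ones, so
    # the boundary's box-counting dimension actually rises with roughness
    # (a low-order-only perturbation stays a smooth dimension-1 curve)
    modes = np.arange(2, 41)
    amp = rng.uniform(-1.0, 1.0, size=modes.size) / modes.astype(float) ** 0.6
    amp *= roughness / (np.abs(amp).sum() + 1e-12)
    phase = rng.uniform(0, 2 * np.pi, size=modes.size)
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = rows - center[0], cols - center[1]
    theta = np.arctan2(dy, dx)
    r_bound = radius * (1.0 + (amp[None, None, :] * np.cos(modes * theta[..., None] + phase)).sum(-1))
    return np.hypot(dy, dx) <= r_bound


def _gaussian_random_field(h, w, corr_len, rng) -> np.ndarray:
    """Unit-variance Gaussian field with Gaussian autocorrelation of scale corr_len."""
    from scipy.ndimage import gaussian_filter

    white = rng.standard_normal((h, w))
    f = gaussian_filter(white, sigma=corr_len, mode="wrap")
    return (f - f.mean()) / (f.std() + 1e-12)


# ---------------------------------------------------------------------------
# reference dynamical systems / fractal sets
# ---------------------------------------------------------------------------

_SERIES_NAMES = (
    "logistic", "henon", "sine", "const", "white_noise",
    "sierpinski", "line", "filled_square",
)


def generate_series(name: str, params: dict | None = None, n: int = 1000,
                    seed: int = 0) -> AttractorSeries:
    """Generate a reference series or binary point set with known invariants.

    Time series (``n >= 500`` required): ``logistic`` iterates
    x_{t+1} = r x_t (1 - x_t) (default r = 4, largest Lyapunov exponent ln 2);
    ``henon`` is the standard (a, b) = (1.4, 0.3) map (x component returned);
    ``sine`` is a pure sinusoid (zero Lyapunov exponent); ``const`` is
    constant; ``white_noise`` is i.i.d. standard normal.

    Binary sets (returned as 2-D arrays, ``n`` ignored): ``sierpinski`` at
    ``depth`` d is the 2^d x 2^d bitwise-AND construction with exactly 3^d
    set pixels and self-similarity dimension log 3 / log 2; ``line`` is a
    one-pixel straight segment (dimension 1); ``filled_square`` a solid block
    (dimension 2).
    """
    params = dict(params or {})
    if name not in _SERIES_NAMES:
        raise ValueError(f"unknown series name {name!r}; choose from {_SERIES_NAMES}")

    if name in ("sierpinski", "line", "filled_square"):
        values = _binary_set(name, params)
        return AttractorSeries(name=name, values=values, params=params, seed=seed)

    if n < 500:
        raise ValueError("time series require n >= 500")
    rng = np.random.default_rng(seed)

    if name == "logistic":
        r = params.setdefault("r", 4.0)
        x = params.setdefault("x0", float(rng.uniform(0.1, 0.9)))
        burn = 100
        out = np.empty(n + burn)
        for t in range(n + burn):
            out[t] = x
            x = r * x * (1.0 - x)
        values = out[burn:]
    elif name == "henon":
        a = params.setdefault("a", 1.4)
        b = params.setdefault("b", 0.3)
        x, y = 0.1, 0.1
        burn = 200
        out = np.empty(n + burn)
        for t in range(n + burn):
            out[t] = x
            x, y = 1.0 - a * x * x + y, b * x
        values = out[burn:]
    elif name == "sine":
        # default period is incommensurate with the sampling so the delay
        # embedding fills the closed orbit densely instead of hitting a
        # finite set of repeated points
        period = params.setdefault("period", 128.0 / np.pi)
        phase = params.setdefault("phase", float(rng.uniform(0, 2 * np.pi)))
        values = np.sin(2 * np.pi * np.arange(n) / period + phase)
    elif name == "const":
        values = np.full(n, params.setdefault("value", 1.0))
    else:  # white_noise
        values = rng.standard_normal(n)

    if not np.all(np.isfinite(values)):
        raise FloatingPointError(f"{name} series diverged")
    return AttractorSeries(name=name, values=values, params=params, seed=seed)


def _binary_set(name: str, params: dict) -> np.ndarray:
    if name == "sierpinski":
        depth = int(params.setdefault("depth", 7))
        size = 2 ** depth
        i, j = np.mgrid[0:size, 0:size]
        return ((i & j) == 0).astype(np.uint8)
    if name == "line":
        length = int(params.setdefault("length", 256))
        img = np.zeros((length, length), dtype=np.uint8)
        img[length // 2, :] = 1
        return img
    # filled_square
    side = int(params.setdefault("side", 128))
    pad = int(params.setdefault("pad", 8))
    img = np.zeros((side + 2 * pad, side + 2 * pad), dtype=np.uint8)
    img[pad:pad + side, pad:pad + side] = 1
    return img


# ---------------------------------------------------------------------------
# dataset-level helpers
# ---------------------------------------------------------------------------

def generate_dataset(n_per_class: int, seed: int = 0) -> tuple[list[ThermalImage], pd.Series, list[PhantomSpec]]:
    """Generate a balanced labelled phantom cohort.

    Returns (images, labels, specs); labels is a pandas Series of
    "benign"/"malignant" indexed by image id.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    images, labels, specs = [], {}, []
    for i in range(n_per_class):
        for make in (benign_spec, malignant_spec):
            spec = make(seed=seed * 100_003 + i)
            img = generate_phantom(spec)
            images.append(img)
            labels[img.id] = spec.label
            specs.append(spec)
    return images, pd.Series(labels, name="label"), specs


def planted_feature_table(n_samples: int = 200, n_informative: int = 3,
                          n_noise: int = 17, effect_size: float = 2.0,
                          seed: int = 0) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Synthetic feature table with known informative columns.

    Informative columns are Gaussian with class means separated by
    ``effect_size`` standard deviations; noise columns are class-independent.
    Returns (table, labels in {0,1}, names of informative columns).
    """
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], [n_samples - n_samples // 2, n_samples // 2])
    rng.shuffle(y)
    info = rng.standard_normal((n_samples, n_informative)) + effect_size * y[:, None]
    noise = rng.standard_normal((n_samples, n_noise))
    names = [f"info_{i}" for i in range(n_informative)] + [f"noise_{i}" for i in range(n_noise)]
    table = pd.DataFrame(np.hstack([info, noise]), columns=names)
    return table, y, names[:n_informative]
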