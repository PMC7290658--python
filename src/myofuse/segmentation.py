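"""Nuclei detection from the DAPI channel.

The stage chain mirrors the classic interactive workflow for counting nuclei
in fluorescence images: rolling-ball background subtraction, automatic global
thresholding (Otsu), binary cleanup (hole filling + morphological opening),
and connected-component particle analysis with an area filter, yielding one
centroid + area record per detected nucleus.

The rolling-ball background is the grayscale morphological opening of the
image by a ball-shaped (spherical-cap) structuring element: the surface traced
by the top of a ball of the given radius rolled under the intensity landscape.
For radii above ``_EXACT_RADIUS_LIMIT`` the background is estimated on a
block-minimum downsampled copy and linearly upsampled (clipped to stay inside
``[0, image]``), which keeps large radii tractable; small radii use the exact
opening.  Touching nuclei are not split (no watershed step) — a documented
limitation.
"""

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError

__all__ = [
    "ImageStack",
    "SegmentationConfig",
    "NucleusSet",
    "ball_structuring_element",
    "rolling_ball_background",
    "rolling_ball_background_subtract",
    "otsu_threshold",
    "clean_mask",
    "find_particles",
    "segment_nuclei",
]

_EXACT_RADIUS_LIMIT = 16
_DOWNSAMPLE_FACTOR = 4


@dataclass(frozen=True)
class ImageStack:
    """Two-channel raster (DAPI nuclear stain + eMHC cytoplasmic stain)."""

    dapi: np.ndarray
    emhc: np.ndarray
    pixel_size_um: float
    bit_depth: int = 8

    def __post_init__(self):
        if self.dapi.shape != self.emhc.shape:
            raise ParameterError("dapi and emhc channels must have the same shape")
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")

    @property
    def shape(self):
        return self.dapi.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in ("dapi", "emhc"):
            raise ParameterError(f"unknown channel {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable knobs of the nuclei-detection chain.

    Defaults: rolling-ball radius 50 px (the conventional default of the
    interactive tool this reimplements), Otsu thresholding, opening by a
    radius-1 disk, hole filling on, minimum particle area 20 px^2 with no
    upper bound, and 8-connectivity for particle analysis.
    """

    rolling_ball_radius_px: float = 50.0
    threshold_method: str = "otsu"
    opening_radius_px: int = 1
    fill_holes: bool = True
    min_area_px: int = 20
    max_area_px: float = math.inf
    connectivity: int = 8

    def __post_init__(self):
        if self.rolling_ball_radius_px <= 0:
            raise ParameterError("rolling_ball_radius_px must be positive")
        if self.threshold_method != "otsu":
            raise ParameterError(f"unsupported threshold method {self.threshold_method!r}")
        if self.opening_radius_px < 0:
            raise ParameterError("opening_radius_px must be >= 0")
        if self.min_area_px < 0:
            raise ParameterError("min_area_px must be >= 0")
        if self.min_area_px > self.max_area_px:
            raise ParameterError("min_area_px must not exceed max_area_px")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class NucleusSet:
    """Detected particles: one row per nucleus (label, centroid x/y, area)."""

    particles: pd.DataFrame  # columns: label, x, y, area_px
    width_px: int
    height_px: int
    pixel_size_um: float

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def centroids(self) -> np.ndarray:
        return self.particles[["x", "y"]].to_numpy(dtype=float).reshape(-1, 2)

    @staticmethod
    def empty(width_px: int, height_px: int, pixel_size_um: float) -> "NucleusSet":
        df = pd.DataFrame({"label": pd.Series(dtype=int), "x": pd.Series(dtype=float),
                           "y": pd.Series(dtype=float), "area_px": pd.Series(dtype=int)})
        return NucleusSet(df, width_px, height_px, pixel_size_um)


# ---------------------------------------------------------------------------
# Rolling-ball background subtraction
# ---------------------------------------------------------------------------

def ball_structuring_element(radius_px: float):
    """Footprint and height profile of the ball structuring element.

    Returns (footprint, heights): footprint is the boolean disk
    ``x^2 + y^2 <= r^2``; heights are ``sqrt(r^2 - x^2 - y^2) - r`` inside the
    footprint (0 at the centre, negative towards the rim), which makes the
    grayscale opening anti-extensive and non-negative on non-negative input.
    """
    if radius_px <= 0:
        raise ParameterError("ball radius must be positive")
    r_int = int(math.floor(radius_px))
    yy, xx = np.mgrid[-r_int:r_int + 1, -r_int:r_int + 1]
    d2 = xx * xx + yy * yy
    footprint = d2 <= radius_px * radius_px
    heights = np.zeros_like(d2, dtype=float)
    heights[footprint] = np.sqrt(radius_px * radius_px - d2[footprint]) - radius_px
    return footprint, heights


def _ball_opening(raster: np.ndarray, radius_px: float) -> np.ndarray:
    footprint, heights = ball_structuring_element(radius_px)
    eroded = ndimage.grey_erosion(raster, footprint=footprint, structure=heights, mode="nearest")
    return ndimage.grey_dilation(eroded, footprint=footprint, structure=heights, mode="nearest")


def rolling_ball_background(raster: np.ndarray, radius_px: float) -> np.ndarray:
    """Rolling-ball background estimate (grayscale opening by a ball).

    Large radii (> 16 px) are computed on a block-minimum downsampled copy and
    linearly upsampled; the result is clipped elementwise into ``[0, raster]``
    so the subtraction below is always non-negative and anti-extensive.
    """
    if radius_px <= 0:
        raise ParameterError("rolling_ball radius_px must be positive")
    img = np.asarray(raster, dtype=float)
    if img.size == 0:
        raise ParameterError("raster must be non-empty")
    if radius_px <= _EXACT_RADIUS_LIMIT:
        bg = _ball_opening(img, radius_px)
    else:
        f = _DOWNSAMPLE_FACTOR
        h, w = img.shape
        ph, pw = (-h) % f, (-w) % f
        padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
        small = padded.reshape(padded.shape[0] // f, f, padded.shape[1] // f, f).min(axis=(1, 3))
        small_bg = _ball_opening(small, radius_px / f)
        bg = ndimage.zoom(small_bg, f, order=1, mode="nearest")[:h, :w]
    return np.clip(bg, 0.0, img)


def rolling_ball_background_subtract(raster: np.ndarray, radius_px: float) -> np.ndarray:
    """Image minus its rolling-ball background; everywhere in [0, raster]."""
    img = np.asarray(raster, dtype=float)
    return img - rolling_ball_background(img, radius_px)


# ---------------------------------------------------------------------------
# Otsu thresholding
# ---------------------------------------------------------------------------

_N_BINS = 256


def otsu_threshold(raster: np.ndarray):
    """Global threshold maximising between-class variance over 256 bins.

    The histogram spans the raster's own value range in 256 equal-width bins
    (16-bit data is binned down, which keeps an exhaustive oracle cheap).  On
    ties the lowest maximising threshold is chosen.  Returns
    ``(threshold_value, mask)`` with ``mask = raster > threshold_value``.

    A constant raster has no separable foreground: the mask is empty and a
    warning is emitted.
    """
    img = np.asarray(raster, dtype=float)
    if img.size == 0:
        raise ParameterError("raster must be non-empty")
    vmin, vmax = float(img.min()), float(img.max())
    if vmin == vmax:
        warnings.warn("constant raster: no foreground separable; returning empty mask")
        return vmax, np.zeros(img.shape, dtype=bool)
    hist, edges = np.histogram(img, bins=_N_BINS, range=(vmin, vmax))
    p = hist.astype(float) / img.size
    omega = np.cumsum(p)                      # class-0 probability up to bin k
    mu = np.cumsum(p * np.arange(_N_BINS))    # class-0 first moment (bin units)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0, posinf=-1.0)
    k = int(np.argmax(sigma_b))               # argmax returns the lowest tie
    threshold = float(edges[k + 1])
    return threshold, img > threshold


# ---------------------------------------------------------------------------
# Binary cleanup and particle analysis
# ---------------------------------------------------------------------------

def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return xx * xx + yy * yy <= radius * radius


def clean_mask(mask: np.ndarray, config: SegmentationConfig = SegmentationConfig()) -> np.ndarray:
    """Fill enclosed holes, then open with a disk of the configured radius."""
    m = np.asarray(mask, dtype=bool)
    if config.fill_holes:
        m = ndimage.binary_fill_holes(m)
    if config.opening_radius_px > 0:
        fp = _disk_footprint(config.opening_radius_px)
        m = ndimage.binary_opening(m, structure=fp)
    return m


def _connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def find_particles(mask: np.ndarray, config: SegmentationConfig = SegmentationConfig(),
                   pixel_size_um: float = 1.0) -> NucleusSet:
    """Connected-component particle analysis with an area filter.

    Components are labelled under the configured connectivity; those with
    areas outside ``[min_area_px, max_area_px]`` are discarded.  Centroids are
    arithmetic means of member-pixel centres, i.e. ``(col + 0.5, row + 0.5)``.
    """
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    labels, n = ndimage.label(m, structure=_connectivity_structure(config.connectivity))
    if n == 0:
        return NucleusSet.empty(w, h, pixel_size_um)
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero((areas >= config.min_area_px) & (areas <= config.max_area_px)) + 1
    if keep.size == 0:
        return NucleusSet.empty(w, h, pixel_size_um)
    coms = ndimage.center_of_mass(m, labels, keep)
    rows = np.array([c[0] for c in coms])
    cols = np.array([c[1] for c in coms])
    df = pd.DataFrame({
        "label": np.arange(1, keep.size + 1, dtype=int),
        "x": cols + 0.5,
        "y": rows + 0.5,
        "area_px": areas[keep - 1].astype(int),
    })
    return NucleusSet(df, w, h, pixel_size_um)


def segment_nuclei(stack: ImageStack, config: SegmentationConfig = SegmentationConfig()) -> NucleusSet:
    """Full detection chain on the DAPI channel.

    rolling-ball subtraction -> Otsu threshold -> binary cleanup -> particle
    analysis; deterministic for fixed input and config.
    """
    dapi = np.asarray(stack.dapi, dtype=float)
    corrected = rolling_ball_background_subtract(dapi, config.rolling_ball_radius_px)
    _, mask = otsu_threshold(corrected)
    mask = clean_mask(mask, config)
    return find_particles(mask, config, pixel_size_um=stack.pixel_size_um)
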