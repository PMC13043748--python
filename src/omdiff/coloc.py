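"""Two-color co-localization (thresholded Pearson) and island morphometry.

Reconstructed super-resolution maps of two membrane species are compared
pixel-by-pixel inside a signal mask: both channels are Gaussian-blurred
(σ = 1 px), a minimal ISODATA threshold on the lower-signal channel removes
extracellular/dark pixels, and the Pearson correlation coefficient (PCC) of
the masked intensities quantifies co-localization (+1 co-localized, −1
mutually exclusive, 0 independent).

Separately, each channel can be segmented into discrete patches ("islands")
by ISODATA thresholding; per island the height (caliper extent along the
principal axis) and width (extent perpendicular to it) are measured and
patches of 50 nm or less are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops

from .errors import MaskError, ParameterError

__all__ = [
    "ChannelPair",
    "PccResult",
    "IslandMeasurement",
    "blur",
    "isodata_threshold",
    "make_analysis_mask",
    "pcc",
    "measure_islands",
    "median_island_size",
    "MIN_ISLAND_SIZE_UM",
]

#: Patches with height <= this (µm) are discarded (the >50 nm size filter).
MIN_ISLAND_SIZE_UM = 0.05


@dataclass
class ChannelPair:
    """Two registered single-channel intensity maps on a common grid."""

    a: np.ndarray
    b: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ParameterError("channels must have identical dimensions")
        if self.a.ndim != 2:
            raise ParameterError("channels must be 2-D")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel size must be positive")


@dataclass
class PccResult:
    pcc: float
    n_mask_pixels: int


@dataclass
class IslandMeasurement:
    """Height/width of one segmented patch (µm); width <= height."""

    island_id: int
    height_um: float
    width_um: float


def blur(channel: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Gaussian blur (reflective boundary) with the standard σ = 1 px default."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ParameterError("expected a 2-D image")
    return ndimage.gaussian_filter(channel, sigma=sigma, mode="reflect")


def isodata_threshold(
    image: np.ndarray, tol: float = 0.5, max_iter: int = 1000
) -> float:
    """ISODATA (iterative intermeans) automatic threshold.

    Starting from the mid-range, iterate T ← (mean below T + mean above T)/2
    until the change is below ``tol`` intensity units (0.5 for 8/16-bit
    data). Raises on a constant image.
    """
    vals = np.asarray(image, dtype=float).ravel()
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ParameterError("constant image: ISODATA threshold undefined")
    t = 0.5 * (lo + hi)
    for _ in range(max_iter):
        below = vals[vals <= t]
        above = vals[vals > t]
        if len(below) == 0 or len(above) == 0:
            break
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def make_analysis_mask(pair: ChannelPair, tol: float = 0.5) -> np.ndarray:
    """Minimal-threshold mask from the lower-signal channel.

    The channel with the lower total intensity (the weaker label) is
    thresholded with the ISODATA criterion; pixels above threshold form the
    analysis mask, excluding extracellular and dark regions whose mutual
    absence of signal would inflate the correlation.
    """
    low = pair.a if pair.a.sum() <= pair.b.sum() else pair.b
    if np.ptp(low) == 0:
        if low.flat[0] > 0:
            # uniformly bright: nothing to exclude
            return np.ones(low.shape, dtype=bool)
        raise MaskError("lower-signal channel is dark; mask undefined")
    mask = low > isodata_threshold(low, tol=tol)
    if not mask.any():
        raise MaskError("analysis mask is empty")
    return mask


def pcc(pair: ChannelPair, mask: np.ndarray | None = None) -> PccResult:
    """Pearson correlation coefficient of the two channels inside the mask.

    PCC = Σ(A_i−Ā)(B_i−B̄) / sqrt(Σ(A_i−Ā)²·Σ(B_i−B̄)²) over masked pixels.
    """
    if mask is None:
        mask = np.ones(pair.a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pair.a.shape:
        raise ParameterError("mask shape must match the channels")
    a = pair.a[mask]
    b = pair.b[mask]
    if a.size < 2:
        raise MaskError("mask must contain at least 2 pixels")
    da = a - a.mean()
    db = b - b.mean()
    va, vb = np.sum(da * da), np.sum(db * db)
    if va == 0 or vb == 0:
        raise MaskError("zero variance inside the mask: PCC undefined")
    r = float(np.sum(da * db) / np.sqrt(va * vb))
    return PccResult(pcc=r, n_mask_pixels=int(a.size))


def _caliper_extents(coords: np.ndarray) -> tuple[float, float]:
    """Extents (px) of pixel footprints along/perpendicular to the principal axis.

    The axis is the leading eigenvector of the pixel-coordinate covariance.
    Each pixel (r, c) contributes its four corners so the measurement spans
    whole pixels rather than center-to-center distances.
    """
    cov = np.cov(coords.T) if len(coords) > 1 else np.eye(2)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    axis = evecs[:, np.argmax(evals)]
    perp = np.array([-axis[1], axis[0]])
    corners = np.concatenate(
        [coords + off for off in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    along = corners @ axis
    across = corners @ perp
    return float(np.ptp(along)), float(np.ptp(across))


def measure_islands(
    image: np.ndarray,
    pixel_size_um: float,
    min_size_um: float = MIN_ISLAND_SIZE_UM,
    tol: float = 0.5,
) -> list[IslandMeasurement]:
    """Segment and measure discrete patches in a single-channel map.

    A non-boolean image is binarized at its ISODATA threshold. Connected
    components (8-connectivity) are measured by axis-aligned calipers:
    height = extent along the component's principal axis, width = extent
    perpendicular to it (both in µm, spanning whole pixels). Components
    with height <= ``min_size_um`` are discarded. An empty result is not an
    error.
    """
    if pixel_size_um <= 0:
        raise ParameterError("pixel size must be positive")
    image = np.asarray(image)
    if image.dtype == bool:
        mask = image
    else:
        mask = image > isodata_threshold(image, tol=tol)
    lab = label(mask, connectivity=2)
    out: list[IslandMeasurement] = []
    for region in regionprops(lab):
        coords = region.coords.astype(float)
        if len(coords) == 1:
            h = w = pixel_size_um
        else:
            h_px, w_px = _caliper_extents(coords)
            h, w = h_px * pixel_size_um, w_px * pixel_size_um
            if w > h:
                h, w = w, h
        if h <= min_size_um:
            continue
        out.append(IslandMeasurement(island_id=region.label, height_um=h, width_um=w))
    return out


def median_island_size(islands: list[IslandMeasurement]) -> dict[str, float]:
    """Median height/width summaries (µm) over a set of islands."""
    if not islands:
        return {"median_height_um": float("nan"), "median_width_um": float("nan"), "n": 0}
    return {
        "median_height_um": float(np.median([i.height_um for i in islands])),
        "median_width_um": float(np.median([i.width_um for i in islands])),
        "n": len(islands),
    }
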