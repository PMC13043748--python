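"""FRAP analysis: regions, drift, double normalization, mobile fraction.

A FRAP experiment photobleaches a defined region (here, typically one pole
of a rod-shaped bacterium) and follows the return of fluorescence as mobile
molecules exchange into the bleached area. Because the initial brightness
and the depth of the bleach vary from cell to cell, the bleached-region
trace B_t is double-normalized: background-subtracted, referenced to its
pre-bleach value, and divided by the similarly normalized whole-cell trace
T_t, which cancels acquisition photobleaching:

    B̂_t = B_t − BG_t,   T̂_t = T_t − BG_t,
    Î_t = (T̂_0 · B̂_t) / (T̂_t · B̂_0).

The end-point statistic is the mobile fraction,

    mobile fraction = (I_end − I_postbleach) / (1 − I_postbleach),

with I_postbleach the first post-bleach Î and I_end the Î at 300 s (the
frame nearest 300 s; the last frame, flagged, if the schedule has none).
Distributions of per-cell mobile fractions are compared with a two-sided
Mann–Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .errors import DriftError, NormalizationError, ParameterError, SegmentationError

__all__ = [
    "FrapSequence",
    "RegionSet",
    "RegionTraces",
    "NormalizedRecoveryCurve",
    "MobileFractionResult",
    "ComparisonResult",
    "identify_regions",
    "correct_drift",
    "extract_traces",
    "double_normalize",
    "mobile_fraction",
    "compare_mobile_fractions",
    "analyze_sequence",
    "I_END_TIME_S",
    "I_END_TOLERANCE_S",
]

#: Nominal time of the end-point frame (s after the bleach).
I_END_TIME_S = 300.0

#: A frame within this window of the nominal end time is accepted as I_end.
I_END_TOLERANCE_S = 30.0


@dataclass
class FrapSequence:
    """Timestamped single-channel FRAP image sequence.

    ``t`` is in seconds relative to the bleach event (pre-bleach <= 0);
    ``phase`` labels each frame 'pre' or 'post'. Timestamps must be strictly
    increasing, with at least one pre- and two post-bleach frames.
    """

    frames: np.ndarray          # (n_frames, ny, nx)
    t: np.ndarray               # (n_frames,), seconds
    phase: np.ndarray           # (n_frames,), 'pre' | 'post'
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if self.frames.ndim != 3:
            raise ParameterError("frames must be a (n, ny, nx) stack")
        n = self.frames.shape[0]
        if not (len(self.t) == len(self.phase) == n):
            raise ParameterError("timestamps/phases must match frame count")
        if np.any(np.diff(self.t) <= 0):
            raise ParameterError("timestamps must be strictly increasing")
        if np.sum(self.phase == "pre") < 1 or np.sum(self.phase == "post") < 2:
            raise ParameterError("need >= 1 pre-bleach and >= 2 post-bleach frames")

    @property
    def pre_indices(self) -> np.ndarray:
        return np.flatnonzero(self.phase == "pre")

    @property
    def post_indices(self) -> np.ndarray:
        return np.flatnonzero(self.phase == "post")

    @property
    def reference_index(self) -> int:
        """Index of the reference pre-bleach frame (the last one)."""
        return int(self.pre_indices[-1])


@dataclass
class RegionSet:
    """Bleach / whole-cell / background masks on the frame grid."""

    bleach: np.ndarray
    cell: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        for name in ("bleach", "cell", "background"):
            m = np.asarray(getattr(self, name), dtype=bool)
            setattr(self, name, m)
            if not m.any():
                raise ParameterError(f"{name} mask is empty")
        if np.any(self.bleach & ~self.cell):
            raise ParameterError("bleach mask must lie inside the cell mask")
        if np.any(self.background & self.cell):
            raise ParameterError("background mask overlaps the cell mask")


@dataclass
class RegionTraces:
    """Per-frame mean intensities of the three regions (arbitrary units)."""

    t: np.ndarray
    phase: np.ndarray
    B: np.ndarray               # bleached-region mean
    T: np.ndarray               # whole-cell mean
    BG: np.ndarray              # background mean


@dataclass
class NormalizedRecoveryCurve:
    """Double-normalized recovery curve with its end-point statistics."""

    t: np.ndarray
    i_hat: np.ndarray           # Î_t, dimensionless; = 1 at the reference frame
    b_hat: np.ndarray           # background-subtracted bleach trace
    t_hat: np.ndarray           # background-subtracted whole-cell trace
    reference_index: int
    i_postbleach: float
    i_end: float
    i_end_time: float
    i_end_extrapolated: bool = False   # True when no frame near 300 s existed


@dataclass
class MobileFractionResult:
    mobile_fraction: float
    immobile_fraction: float
    i_postbleach: float
    i_end: float
    flags: list[str] = field(default_factory=list)


@dataclass
class ComparisonResult:
    """Two-sided Mann–Whitney U comparison of two mobile-fraction samples."""

    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    quartiles_a: tuple[float, float]
    quartiles_b: tuple[float, float]
    outliers_a: np.ndarray      # boolean, Tukey 1.5-IQR fences
    outliers_b: np.ndarray
    significant: bool           # p <= 0.05


def _cell_threshold(seq: FrapSequence) -> tuple[np.ndarray, float]:
    mean_pre = seq.frames[seq.pre_indices].mean(axis=0)
    if np.ptp(mean_pre) == 0:
        raise SegmentationError("cell identification: pre-bleach frame is constant")
    return mean_pre, float(threshold_otsu(mean_pre))


def identify_regions(seq: FrapSequence) -> RegionSet:
    """Automatic cell / bleach / background masks.

    * cell: the above-threshold (Otsu, mean pre-bleach frame) connected
      component being photobleached — the one with the largest summed
      (pre − first-post) difference; the largest component when several
      cells are present and none shows a difference;
    * bleach: pixels inside the cell whose (pre − first-post) difference
      exceeds half the (robust) maximum difference, morphologically closed;
    * background: pixels below threshold in every frame, eroded by 2 px,
      excluding the bounding boxes of all above-threshold components.
    """
    mean_pre, thr = _cell_threshold(seq)
    above = mean_pre > thr
    lab = label(above, connectivity=2)
    if lab.max() == 0:
        raise SegmentationError("cell identification: no above-threshold component")
    first_post = seq.frames[seq.post_indices[0]]
    # smooth before the half-max rule: single-frame differences carry shot
    # noise and particle-count graininess much larger than per-pixel signal
    diff_full = ndimage.gaussian_filter(mean_pre - first_post, sigma=2.0)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    loss = ndimage.sum_labels(diff_full, lab, index=np.arange(1, lab.max() + 1))
    if np.max(loss) > 0:
        cell = lab == (1 + int(np.argmax(loss)))
    else:
        cell = lab == np.argmax(sizes)

    diff = diff_full * cell
    # robust maximum: the literal max of a noisy field overshoots the bleach
    # plateau and would shrink the half-max mask
    dmax = float(np.percentile(diff[cell], 99.5))
    # a genuine bleach skews the in-cell difference strongly positive; pure
    # noise and diffusive redistribution are nearly symmetric about zero
    dmin = abs(min(float(diff[cell].min()), 0.0))
    if dmax <= 0 or dmax < 1.6 * dmin:
        raise SegmentationError(
            "bleach identification: no pre/post intensity difference detected"
        )
    bleach = ndimage.binary_closing((diff > 0.5 * dmax) & cell, structure=disk(2)) & cell
    if not bleach.any():
        raise SegmentationError("bleach identification: empty bleach mask")

    below_all = np.all(seq.frames < thr, axis=0)
    background = ndimage.binary_erosion(below_all, structure=disk(2))
    for region in regionprops(lab):
        r0, c0, r1, c1 = region.bbox
        background[r0:r1, c0:c1] = False
    if not background.any():
        raise SegmentationError("background identification: empty background mask")
    return RegionSet(bleach=bleach, cell=cell, background=background)


def correct_drift(
    seq: FrapSequence,
    max_shift_fraction: float = 0.25,
    exclude: np.ndarray | None = None,
) -> FrapSequence:
    """Integer-pixel xy drift correction against the pre-bleach reference.

    Each frame's above-threshold mask is registered to the reference
    pre-bleach mask by cross-correlation; frames are shifted by the integer
    offset. ``exclude`` masks pixels (typically the bleached region, whose
    disappearance would otherwise bias the registration) out of both masks.
    A shift exceeding ``max_shift_fraction`` of either image dimension
    raises :class:`DriftError` (the cell moved — discard the cell).
    Recovered shifts are stored in ``meta['drift_shifts']``.
    """
    if seq.frames.shape[0] < 2:
        raise ParameterError("drift correction needs >= 2 frames")
    mean_pre, thr = _cell_threshold(seq)
    keep = np.ones(seq.frames.shape[1:], dtype=bool)
    if exclude is not None:
        keep &= ~ndimage.binary_dilation(exclude, iterations=5)
    ref_mask = ((seq.frames[seq.reference_index] > thr) & keep).astype(float)
    ny, nx = ref_mask.shape
    out = np.empty_like(seq.frames)
    shifts = []
    for i, frame in enumerate(seq.frames):
        mask = ((frame > thr) & keep).astype(float)
        if mask.sum() == 0:
            shift = np.zeros(2)
        else:
            shift, _, _ = phase_cross_correlation(
                ref_mask, mask, upsample_factor=1, normalization=None
            )
        shift = np.round(shift).astype(int)
        if abs(shift[0]) > max_shift_fraction * ny or abs(shift[1]) > max_shift_fraction * nx:
            raise DriftError(
                f"frame {i}: shift {tuple(int(s) for s in shift)} exceeds "
                f"{max_shift_fraction:.0%} of the field — cell moved"
            )
        out[i] = ndimage.shift(frame, shift, order=0, mode="nearest")
        shifts.append((int(shift[0]), int(shift[1])))
    meta = dict(seq.meta)
    meta["drift_shifts"] = shifts
    return FrapSequence(frames=out, t=seq.t.copy(), phase=seq.phase.copy(), meta=meta)


def extract_traces(seq: FrapSequence, regions: RegionSet) -> RegionTraces:
    """Per-frame arithmetic mean intensity over each region mask."""
    B = seq.frames[:, regions.bleach].mean(axis=1)
    T = seq.frames[:, regions.cell].mean(axis=1)
    BG = seq.frames[:, regions.background].mean(axis=1)
    return RegionTraces(t=seq.t.copy(), phase=seq.phase.copy(), B=B, T=T, BG=BG)


def double_normalize(
    traces: RegionTraces, reference_index: int | None = None
) -> NormalizedRecoveryCurve:
    """Double-normalized recovery curve Î_t = (T̂_0·B̂_t)/(T̂_t·B̂_0).

    ``reference_index`` defaults to the last pre-bleach frame; Î there is 1
    exactly. Raises :class:`NormalizationError` on non-positive reference
    values or a non-positive whole-cell trace at any frame.
    """
    if reference_index is None:
        pre = np.flatnonzero(traces.phase == "pre")
        if len(pre) == 0:
            raise ParameterError("no pre-bleach frame to use as reference")
        reference_index = int(pre[-1])
    b_hat = traces.B - traces.BG
    t_hat = traces.T - traces.BG
    b0, t0 = b_hat[reference_index], t_hat[reference_index]
    if b0 <= 0 or t0 <= 0:
        raise NormalizationError(
            f"non-positive background-subtracted reference (B̂_0={b0:.4g}, T̂_0={t0:.4g})"
        )
    bad = np.flatnonzero(t_hat <= 0)
    if len(bad):
        raise NormalizationError(
            f"non-positive background-subtracted whole-cell trace at frame {bad[0]}"
        )
    i_hat = (t0 * b_hat) / (t_hat * b0)

    post = np.flatnonzero(traces.phase == "post")
    i_postbleach = float(i_hat[post[0]])
    t_post = traces.t[post]
    nearest = post[int(np.argmin(np.abs(t_post - I_END_TIME_S)))]
    extrapolated = abs(traces.t[nearest] - I_END_TIME_S) > I_END_TOLERANCE_S
    if extrapolated:
        nearest = post[-1]
    return NormalizedRecoveryCurve(
        t=traces.t.copy(),
        i_hat=i_hat,
        b_hat=b_hat,
        t_hat=t_hat,
        reference_index=reference_index,
        i_postbleach=i_postbleach,
        i_end=float(i_hat[nearest]),
        i_end_time=float(traces.t[nearest]),
        i_end_extrapolated=bool(extrapolated),
    )


def mobile_fraction(curve: NormalizedRecoveryCurve) -> MobileFractionResult:
    """Mobile fraction = (I_end − I_postbleach)/(1 − I_postbleach).

    Reported raw (it can fall outside [0, 1] under noise — no clamping);
    outlier handling belongs to the distribution summary.
    """
    if curve.i_postbleach >= 1:
        raise ParameterError(
            f"I_postbleach = {curve.i_postbleach:.4g} >= 1: no photobleaching occurred"
        )
    mf = (curve.i_end - curve.i_postbleach) / (1.0 - curve.i_postbleach)
    flags = []
    if curve.i_end_extrapolated:
        flags.append(f"i_end_taken_at_{curve.i_end_time:.0f}s")
    return MobileFractionResult(
        mobile_fraction=float(mf),
        immobile_fraction=float(1.0 - mf),
        i_postbleach=curve.i_postbleach,
        i_end=curve.i_end,
        flags=flags,
    )


def _tukey_outliers(values: np.ndarray) -> tuple[tuple[float, float], np.ndarray]:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    out = (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)
    return (float(q1), float(q3)), out


def compare_mobile_fractions(
    group_a: Sequence[float], group_b: Sequence[float]
) -> ComparisonResult:
    """Two-sided Mann–Whitney U test between two mobile-fraction samples.

    The exact null distribution is used for combined n <= 20 without ties;
    otherwise the normal approximation with tie correction. Significance is
    judged at P <= 0.05.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    qa, out_a = _tukey_outliers(a)
    qb, out_b = _tukey_outliers(b)
    return ComparisonResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        quartiles_a=qa,
        quartiles_b=qb,
        outliers_a=out_a,
        outliers_b=out_b,
        significant=bool(res.pvalue <= 0.05),
    )


def analyze_sequence(
    seq: FrapSequence,
    regions: RegionSet | None = None,
    *,
    drift_correction: bool = True,
) -> tuple[NormalizedRecoveryCurve, MobileFractionResult]:
    """Full single-cell pipeline: drift → regions → traces → Î_t → mobile fraction.

    Drift registration excludes the (provisionally identified) bleached
    region, whose disappearance after the bleach would bias the alignment.
    """
    if drift_correction:
        exclude = regions.bleach if regions is not None else identify_regions(seq).bleach
        seq = correct_drift(seq, exclude=exclude)
    if regions is None:
        regions = identify_regions(seq)
    traces = extract_traces(seq, regions)
    curve = double_normalize(traces)
    return curve, mobile_fraction(curve)
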