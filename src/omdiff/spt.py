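"""Single-particle-tracking analysis: MSD curves, mobility filters, diffusion fits.

The workflow mirrors quantitative SPT practice for membrane molecules imaged by
TIRF microscopy at 30 or 67 Hz:

1. (optional) a moving 3-frame median time filter on the raw video,
2. per-track time-averaged MSD over all overlapping displacement pairs,
3. removal of surface-immobilized molecules (end-of-trajectory MSD plateau
   must exceed 0.008 µm²),
4. a single-step-photobleach check on the intensity trace (single fluorophore),
5. deterministic classification of each MSD curve as confined or free
   Brownian via a plateau ratio,
6. the lateral diffusion coefficient D_2D from a linear regression of the
   first 4 (confined) or 13 (free) lags, D_2D = slope/4,
7. for confined molecules, the corral (confinement) diameter from the mean
   MSD in the 0.5-0.8 s lag window via MSD_average = (d_confine/2)²/6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "Track",
    "MsdCurve",
    "DiffusionFit",
    "ConfinementEstimate",
    "MIN_TRACK_DURATION_S",
    "IMMOBILE_MSD_THRESHOLD_UM2",
    "CONFINEMENT_WINDOW_S",
    "PLATEAU_RATIO_THRESHOLD",
    "TRACKING_METADATA",
    "median_time_filter",
    "compute_msd",
    "ensemble_msd",
    "end_of_trajectory_msd",
    "filter_immobile",
    "check_single_step_bleach",
    "find_bleach_step",
    "classify_mode",
    "fit_diffusion",
    "confinement_diameter",
]

#: Minimum track duration admitted to MSD analysis (s).
MIN_TRACK_DURATION_S = 0.9

#: End-of-trajectory MSD below which a molecule is considered immobilized
#: on the support surface and discarded (µm²); retention is strict (>).
IMMOBILE_MSD_THRESHOLD_UM2 = 0.008

#: Lag window over which the MSD plateau is averaged for the confinement
#: diameter (closed interval, seconds).
CONFINEMENT_WINDOW_S = (0.5, 0.8)

#: Plateau ratio below which a track is classified as confined.
PLATEAU_RATIO_THRESHOLD = 0.6

#: Acquisition/linking constants of the upstream tracking step (recorded for
#: provenance; detection and linking from raw video are outside this package).
TRACKING_METADATA = {
    "resolution_um_per_px": 0.096,
    "max_displacement_um": 0.4,
    "death_frames": 5,
    "short_trajectory_filter_frames": 12,
    "max_eccentricity": 1.7,
}


@dataclass
class Track:
    """A single-molecule trajectory with uniform frame interval.

    Parameters
    ----------
    t, x, y
        Observation times (s) and lateral positions (µm), equal length.
    intensity
        Optional fluorophore intensity trace, same length as ``t``. For
        simulated bleaching tracks the trailing frames after the single-step
        drop repeat the last localized position at background intensity.
    track_id
        Optional identifier carried through tables.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray | None = None
    track_id: int | str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ParameterError("t, x, y must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        """Frame interval (s); raises if the sampling is non-uniform."""
        diffs = np.diff(self.t)
        if len(diffs) == 0:
            raise ParameterError("track has fewer than 2 observations")
        if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-9):
            raise ParameterError(
                f"track {self.track_id!r} has non-uniform frame interval"
            )
        return float(diffs[0])

    @property
    def duration(self) -> float:
        """Track duration (s), first to last observation."""
        return float(self.t[-1] - self.t[0])


@dataclass
class MsdCurve:
    """Time- (or ensemble-) averaged MSD as a function of lag.

    ``lags[0] = 0`` with ``msd[0] = 0`` by construction. ``n_pairs`` counts
    the displacement pairs (per-track curves) or contributing tracks
    (ensemble curves); ``sem`` is the across-track standard error and is
    None for per-track curves.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


@dataclass
class DiffusionFit:
    """Lateral diffusion coefficient from a linear fit of MSD vs lag."""

    d2d: float                      # µm²/s, slope/4, floored at 0
    intercept: float                # µm² (absorbs the localization-noise offset)
    mode: Literal["confined", "brownian"]
    n_lags: int                     # 4 for confined, 13 for brownian
    degenerate: bool = False        # True when the raw slope was negative


@dataclass
class ConfinementEstimate:
    """Corral diameter from the plateau MSD via MSD_average = (d/2)²/6."""

    msd_average: float              # µm², mean MSD over the lag window
    d_confine: float                # µm, 2·sqrt(6·MSD_average)
    window: tuple[float, float] = CONFINEMENT_WINDOW_S


def median_time_filter(stack: np.ndarray, window: int = 3) -> np.ndarray:
    """Per-pixel running median over time with symmetric shrinking ends.

    At frame ``i`` the window radius is ``min(window//2, i, n-1-i)``, so the
    first and last frames pass through unchanged for ``window=3``.

    Parameters
    ----------
    stack
        Array of shape (n_frames, ...); filtering is along axis 0.
    window
        Odd window length >= 3.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError("window must be odd and >= 3")
    stack = np.asarray(stack)
    n = stack.shape[0]
    if n < 3:
        raise ParameterError("need at least 3 frames")
    out = np.empty_like(stack, dtype=float)
    half = window // 2
    for i in range(n):
        r = min(half, i, n - 1 - i)
        out[i] = np.median(stack[i - r : i + r + 1], axis=0)
    return out


def compute_msd(
    track: Track, *, enforce_duration: bool = True, max_lag: int | None = None
) -> MsdCurve:
    """Time-averaged MSD using all overlapping observation pairs.

    MSD(k·dt) = mean over i of |r(i+k) − r(i)|², k = 1 … n−1 (or ``max_lag``).
    Lag 0 is included with MSD = 0.
    """
    n = len(track)
    if n < 2:
        raise ParameterError("need at least 2 observations for an MSD")
    if enforce_duration and track.duration < MIN_TRACK_DURATION_S - 1e-12:
        raise ParameterError(
            f"track duration {track.duration:.3f} s below the "
            f"{MIN_TRACK_DURATION_S} s admission criterion"
        )
    dt = track.dt
    kmax = n - 1 if max_lag is None else min(max_lag, n - 1)
    msd = np.zeros(kmax + 1)
    counts = np.zeros(kmax + 1, dtype=int)
    counts[0] = n
    x, y = track.x, track.y
    for k in range(1, kmax + 1):
        dx = x[k:] - x[:-k]
        dy = y[k:] - y[:-k]
        msd[k] = np.mean(dx * dx + dy * dy)
        counts[k] = n - k
    lags = np.arange(kmax + 1) * dt
    return MsdCurve(lags=lags, msd=msd, n_pairs=counts)


def ensemble_msd(tracks: Sequence[Track], **msd_kwargs) -> MsdCurve:
    """Unweighted across-track mean of per-track MSD curves.

    Lags at which fewer than half the tracks contribute are dropped; the
    uncertainty is the across-track s.e.m. at each retained lag.
    """
    if len(tracks) < 2:
        raise ParameterError("ensemble MSD needs at least 2 tracks")
    curves = [compute_msd(tr, **msd_kwargs) for tr in tracks]
    dts = np.array([c.dt for c in curves])
    if not np.allclose(dts, dts[0], rtol=1e-6):
        raise ParameterError("tracks have incompatible frame intervals")
    dt = dts[0]
    kmax = max(len(c.msd) for c in curves) - 1
    n_tracks = len(curves)
    values = np.full((n_tracks, kmax + 1), np.nan)
    for i, c in enumerate(curves):
        values[i, : len(c.msd)] = c.msd
    contributing = np.sum(~np.isnan(values), axis=0)
    keep = contributing >= (n_tracks / 2.0)
    if not np.any(keep[1:]):
        raise ParameterError("no common lags across tracks")
    # keep is a prefix by construction (longer tracks cover shorter lags)
    kmax_keep = int(np.max(np.nonzero(keep)[0]))
    values = values[:, : kmax_keep + 1]
    mean = np.nanmean(values, axis=0)
    n_c = contributing[: kmax_keep + 1]
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(values, axis=0, ddof=1)
    sem = np.where(n_c > 1, sd / np.sqrt(n_c), np.nan)
    sem[0] = 0.0
    lags = np.arange(kmax_keep + 1) * dt
    return MsdCurve(lags=lags, msd=mean, n_pairs=n_c, sem=sem)


def end_of_trajectory_msd(curve: MsdCurve) -> float:
    """Asymptotic (end-of-trajectory) MSD: mean over the last quarter of lags."""
    n_lags = len(curve.msd) - 1  # excluding lag 0
    tail = max(1, n_lags // 4)
    return float(np.mean(curve.msd[-tail:]))


def filter_immobile(
    tracks: Sequence[Track],
    threshold: float = IMMOBILE_MSD_THRESHOLD_UM2,
    **msd_kwargs,
) -> tuple[list[Track], list[Track]]:
    """Split tracks into (retained, discarded) by the immobility criterion.

    A track is retained iff its end-of-trajectory MSD (mean over the last
    quarter of lags) strictly exceeds ``threshold`` (µm²). Molecules below
    it are considered immobilized on the support surface.
    """
    retained: list[Track] = []
    discarded: list[Track] = []
    for tr in tracks:
        plateau = end_of_trajectory_msd(compute_msd(tr, **msd_kwargs))
        (retained if plateau > threshold else discarded).append(tr)
    return retained, discarded


def _piecewise_const_sse(prefix: np.ndarray, prefix2: np.ndarray, a: int, b: int) -> float:
    """SSE of the best constant fit to trace[a:b] from prefix sums."""
    n = b - a
    s = prefix[b] - prefix[a]
    s2 = prefix2[b] - prefix2[a]
    return s2 - s * s / n


def find_bleach_step(trace: np.ndarray) -> tuple[int, float, float]:
    """Best single change point of a two-level fit.

    Returns (index of the first post-step frame, pre level, post level).
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    prefix = np.concatenate(([0.0], np.cumsum(trace)))
    prefix2 = np.concatenate(([0.0], np.cumsum(trace**2)))
    best_k, best_sse = 1, np.inf
    for k in range(1, n):
        sse = _piecewise_const_sse(prefix, prefix2, 0, k) + _piecewise_const_sse(
            prefix, prefix2, k, n
        )
        if sse < best_sse:
            best_k, best_sse = k, sse
    pre = float(np.mean(trace[:best_k]))
    post = float(np.mean(trace[best_k:]))
    return best_k, pre, post


def check_single_step_bleach(trace: np.ndarray) -> bool:
    """True iff the intensity trace shows one single-step drop to background.

    Single-fluorophore verification: the best two-level (one change point)
    fit must (i) reduce the residual sum of squares at least 4-fold versus a
    constant fit, (ii) not itself be beaten 4-fold by the best three-level
    (two change point) fit — which rejects double steps — and (iii) be at
    least as good as a straight-line fit — which rejects monotone ramps.
    The step must be downward. Traces that never bleach (no step) fail (i).
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < 6:
        raise ParameterError("bleach check needs a trace of length >= 6")
    prefix = np.concatenate(([0.0], np.cumsum(trace)))
    prefix2 = np.concatenate(([0.0], np.cumsum(trace**2)))
    sse_const = _piecewise_const_sse(prefix, prefix2, 0, n)
    k1, pre, post = find_bleach_step(trace)
    sse_1 = _piecewise_const_sse(prefix, prefix2, 0, k1) + _piecewise_const_sse(
        prefix, prefix2, k1, n
    )
    sse_2 = np.inf
    for a in range(1, n - 1):
        left = _piecewise_const_sse(prefix, prefix2, 0, a)
        for b in range(a + 1, n):
            sse = (
                left
                + _piecewise_const_sse(prefix, prefix2, a, b)
                + _piecewise_const_sse(prefix, prefix2, b, n)
            )
            if sse < sse_2:
                sse_2 = sse
    # straight-line fit
    tt = np.arange(n, dtype=float)
    coef = np.polyfit(tt, trace, 1)
    sse_line = float(np.sum((trace - np.polyval(coef, tt)) ** 2))

    scale = max(float(np.mean(trace**2)), 1e-300)
    eps = 1e-9 * n * scale
    if post >= pre:
        return False
    if sse_const < 4.0 * sse_1:
        return False
    if sse_1 > max(4.0 * sse_2, eps):
        return False
    if sse_1 > sse_line + eps:
        return False
    return True


def _origin_slope(lags: np.ndarray, msd: np.ndarray) -> float:
    """Least-squares slope of a line through the origin."""
    return float(np.sum(msd * lags) / np.sum(lags * lags))


def classify_mode(
    curve: MsdCurve,
    *,
    window: tuple[float, float] = CONFINEMENT_WINDOW_S,
    rho_threshold: float = PLATEAU_RATIO_THRESHOLD,
) -> Literal["confined", "brownian"]:
    """Deterministic confined-vs-free classification via the plateau ratio.

    A line through the origin is fitted to the first 4 nonzero lags; the
    plateau ratio ρ compares the measured late MSD (mean over the lag
    window) with the linear extrapolation at the window's mean lag. Free
    Brownian motion gives ρ ≈ 1; a saturating (corralled) MSD gives ρ well
    below 1. Confined iff ρ < ``rho_threshold``.
    """
    if len(curve.msd) - 1 < 13:
        raise ParameterError("classification requires at least 13 lags")
    lo, hi = window
    in_win = (curve.lags >= lo - 1e-9) & (curve.lags <= hi + 1e-9)
    if not np.any(in_win):
        raise ParameterError(
            f"lag window [{lo}, {hi}] s not covered by the MSD curve "
            f"(max lag {curve.lags[-1]:.3f} s)"
        )
    slope = _origin_slope(curve.lags[1:5], curve.msd[1:5])
    tau_late = float(np.mean(curve.lags[in_win]))
    msd_late = float(np.mean(curve.msd[in_win]))
    if slope <= 0:
        return "confined"
    rho = msd_late / (slope * tau_late)
    return "confined" if rho < rho_threshold else "brownian"


def fit_diffusion(
    curve: MsdCurve, mode: Literal["confined", "brownian"]
) -> DiffusionFit:
    """D_2D from an ordinary least-squares line over the first lags.

    The first 4 (confined) or 13 (free Brownian) nonzero lags are used with
    a free intercept, so a static localization-noise offset (4σ²) does not
    inflate D. D_2D = slope/4; a negative slope is reported as D_2D = 0
    with the degenerate flag set.
    """
    if mode not in ("confined", "brownian"):
        raise ParameterError(f"unknown mode {mode!r}")
    n_lags = 4 if mode == "confined" else 13
    if len(curve.msd) - 1 < n_lags:
        raise ParameterError(
            f"{mode} fit needs {n_lags} lags, curve has {len(curve.msd) - 1}"
        )
    tau = curve.lags[1 : n_lags + 1]
    msd = curve.msd[1 : n_lags + 1]
    slope, intercept = np.polyfit(tau, msd, 1)
    degenerate = slope < 0
    d2d = 0.0 if degenerate else float(slope) / 4.0
    return DiffusionFit(
        d2d=d2d,
        intercept=float(intercept),
        mode=mode,
        n_lags=n_lags,
        degenerate=bool(degenerate),
    )


def confinement_diameter(
    curve: MsdCurve, window: tuple[float, float] = CONFINEMENT_WINDOW_S
) -> ConfinementEstimate:
    """Corral diameter from the plateau MSD.

    MSD_average is the mean MSD over lags in the closed window (default
    0.5-0.8 s); the diameter inverts MSD_average = (d_confine/2)²/6, i.e.
    d_confine = 2·sqrt(6·MSD_average).
    """
    lo, hi = window
    in_win = (curve.lags >= lo - 1e-9) & (curve.lags <= hi + 1e-9)
    if not np.any(in_win):
        raise ParameterError(
            f"lag window [{lo}, {hi}] s not covered by the MSD curve"
        )
    msd_avg = float(np.mean(curve.msd[in_win]))
    d = 2.0 * np.sqrt(6.0 * msd_avg)
    return ConfinementEstimate(msd_average=msd_avg, d_confine=float(d), window=(lo, hi))
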