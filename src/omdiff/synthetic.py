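"""Ground-truth-labeled synthetic data for every analysis stage.

Three forward models, all seeded and reproducible:

* :func:`simulate_track` — 2-D lateral diffusion trajectories: free Brownian
  motion, corral-confined motion (circular disc with specular reflection),
  or immobile molecules; Gaussian localization noise per axis; optional
  memoryless single-step photobleaching with an attached intensity trace.
* :func:`simulate_frap_sequence` — a FRAP experiment on a rod-shaped
  (spherocylindrical) cell carrying mobile and immobile fluorophore
  populations: rectangular bleach event between the pre- and post-bleach
  frames, per-frame acquisition photobleaching, background, Poisson shot
  noise and Gaussian read noise.
* :func:`simulate_patch_maps` — two-channel localization-density maps with
  circular patches whose centers can be anti-correlated (mutually
  exclusive membrane domains) or co-localized.

Defaults reproduce the imaging conditions of the experiments the analysis
stack targets: 30 Hz track sampling, 25 nm localization precision, a
50 × 30 px bleach box, one pre-bleach frame then five post-bleach frames at
1-s intervals followed by 60/120/300 s, and ~0.2 µm patches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .coloc import ChannelPair
from .errors import ParameterError
from .frap import FrapSequence
from .spt import Track

__all__ = [
    "TrajectoryParams",
    "FrapSimParams",
    "PatchMapParams",
    "simulate_track",
    "simulate_frap_sequence",
    "simulate_patch_maps",
    "DEFAULT_FRAP_TIMESTAMPS",
]

#: Acquisition schedule (s relative to the bleach): one pre-bleach frame,
#: five post-bleach frames at 1-s intervals, then 1, 2 and 5 minutes.
DEFAULT_FRAP_TIMESTAMPS = (-1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 60.0, 120.0, 300.0)

# Intensity levels for simulated single-fluorophore traces (arbitrary units).
_TRACE_SIGNAL = 10.0
_TRACE_BACKGROUND = 1.0
_TRACE_NOISE_SD = 0.3
_DEATH_FRAMES = 5


@dataclass
class TrajectoryParams:
    """Parameters of a single simulated trajectory.

    D_um2_s is the true lateral diffusion coefficient (µm²/s);
    corral_diameter_um, when set, confines the molecule to a circular disc
    with specular reflection; loc_noise_sd_um is the per-axis localization
    noise; bleach_mean_frames, when set, draws a geometric (memoryless)
    single-step photobleach lifetime and attaches an intensity trace.
    """

    d_um2_s: float
    dt_s: float = 1.0 / 30.0
    n_frames: int = 45
    loc_noise_sd_um: float = 0.025
    corral_diameter_um: float | None = None
    bleach_mean_frames: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.d_um2_s < 0:
            raise ParameterError("diffusion coefficient must be >= 0")
        if self.dt_s <= 0:
            raise ParameterError("frame interval must be positive")
        if self.n_frames < 2:
            raise ParameterError("need at least 2 frames")
        if self.loc_noise_sd_um < 0:
            raise ParameterError("localization noise must be >= 0")
        if self.corral_diameter_um is not None and self.corral_diameter_um <= 0:
            raise ParameterError("corral diameter must be positive")
        if self.bleach_mean_frames is not None and self.bleach_mean_frames <= 0:
            raise ParameterError("bleach lifetime must be positive")


def _reflect_into_disc(p: np.ndarray, target: np.ndarray, radius: float) -> np.ndarray:
    """Specular reflection of the sub-step segment p→target at the disc wall."""
    for _ in range(64):
        if target @ target <= radius * radius:
            return target
        d = target - p
        a = d @ d
        b = p @ d
        c = p @ p - radius * radius
        disc = max(b * b - a * c, 0.0)
        t_hit = (-b + math.sqrt(disc)) / a
        t_hit = min(max(t_hit, 0.0), 1.0)
        hit = p + t_hit * d
        normal = hit / radius
        rest = target - hit
        rest = rest - 2.0 * (rest @ normal) * normal
        p, target = hit, hit + rest
    # pathological numerical corner: clamp to the wall
    return target / max(np.linalg.norm(target) / radius, 1.0)


def simulate_track(params: TrajectoryParams) -> Track:
    """Simulate one trajectory; identical seeds give identical tracks.

    Observed positions are the true Brownian path plus i.i.d. Gaussian
    localization noise per axis. With a corral, the true path starts uniform
    in the disc and each step is reflected specularly at the wall, so the
    true positions never leave the corral. With bleaching, the track is
    truncated at a geometric lifetime and up to 5 trailing "death" frames at
    the last localized position carry a background-level intensity so the
    single-step drop is present in the attached trace.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    sd_step = math.sqrt(2.0 * params.d_um2_s * params.dt_s)

    if params.corral_diameter_um is None:
        steps = rng.normal(0.0, sd_step, size=(n - 1, 2))
        true = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    else:
        radius = params.corral_diameter_um / 2.0
        while True:
            p0 = rng.uniform(-radius, radius, size=2)
            if p0 @ p0 <= radius * radius:
                break
        steps = rng.normal(0.0, sd_step, size=(n - 1, 2))
        true = np.empty((n, 2))
        true[0] = p0
        for i in range(1, n):
            true[i] = _reflect_into_disc(true[i - 1], true[i - 1] + steps[i - 1], radius)

    noise = rng.normal(0.0, params.loc_noise_sd_um, size=(n, 2)) \
        if params.loc_noise_sd_um > 0 else np.zeros((n, 2))
    obs = true + noise

    intensity = None
    if params.bleach_mean_frames is not None:
        lifetime = int(rng.geometric(min(1.0 / params.bleach_mean_frames, 1.0)))
        n_signal = min(lifetime, n)
        if n_signal < n:
            n_tail = min(_DEATH_FRAMES, n - n_signal)
            obs = np.vstack([obs[:n_signal], np.repeat(obs[n_signal - 1 : n_signal], n_tail, axis=0)])
            true = np.vstack([true[:n_signal], np.repeat(true[n_signal - 1 : n_signal], n_tail, axis=0)])
            n = n_signal + n_tail
        intensity = np.full(n, _TRACE_BACKGROUND)
        intensity[:n_signal] = _TRACE_SIGNAL
        intensity = intensity + rng.normal(0.0, _TRACE_NOISE_SD, size=n)

    t = np.arange(n) * params.dt_s
    if params.d_um2_s == 0:
        mode = "immobile"
    elif params.corral_diameter_um is not None:
        mode = "confined"
    else:
        mode = "free"
    meta = {
        "d_true": params.d_um2_s,
        "corral_diameter_um": params.corral_diameter_um,
        "true_mode": mode,
        "true_positions": true,
        "seed": params.seed,
    }
    return Track(t=t, x=obs[:, 0], y=obs[:, 1], intensity=intensity, meta=meta)


@dataclass
class FrapSimParams:
    """Parameters of a simulated FRAP experiment on a spherocylindrical cell."""

    cell_length_um: float = 3.0
    cell_width_um: float = 1.0
    pixel_size_um: float = 0.0274
    mobile_fraction: float = 0.5
    d_mobile_um2_s: float = 0.02
    n_particles: int = 3000
    bleach_box_px: tuple[int, int] = (50, 30)     # (width along x, height along y)
    bleach_box_origin_px: tuple[int, int] | None = None  # (col, row); default: left pole
    bleach_depth: float = 0.85
    acquisition_bleach_rate: float = 0.995        # per-frame multiplicative decay
    background_level: float = 10.0
    brightness: float = 120.0                     # counts per particle
    read_noise_sd: float = 2.0
    noise: bool = True
    timestamps_s: tuple[float, ...] = DEFAULT_FRAP_TIMESTAMPS
    margin_px: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.cell_length_um <= 0 or self.cell_width_um <= 0:
            raise ParameterError("cell dimensions must be positive")
        if self.cell_width_um > self.cell_length_um:
            raise ParameterError("spherocylinder requires width <= length")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel size must be positive")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ParameterError("mobile fraction must lie in [0, 1]")
        if self.d_mobile_um2_s < 0:
            raise ParameterError("D_mobile must be >= 0")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ParameterError("bleach depth must lie in (0, 1]")
        if not 0.0 < self.acquisition_bleach_rate <= 1.0:
            raise ParameterError("acquisition bleach rate must lie in (0, 1]")
        t = np.asarray(self.timestamps_s)
        if np.any(np.diff(t) <= 0):
            raise ParameterError("timestamps must be strictly increasing")
        if not (np.any(t < 0) and np.sum(t > 0) >= 2):
            raise ParameterError("schedule needs >= 1 pre-bleach and >= 2 post-bleach times")


class _Spherocylinder:
    """2-D spherocylinder (capsule) footprint in µm, origin at its bounding box."""

    def __init__(self, length: float, width: float):
        self.length = length
        self.width = width
        self.radius = width / 2.0
        self.ax0 = np.array([self.radius, self.radius])
        self.ax1 = np.array([length - self.radius, self.radius])

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = self.ax1 - self.ax0
        tt = np.clip(((pts - self.ax0) @ d) / (d @ d), 0.0, 1.0)
        closest = self.ax0 + tt[:, None] * d
        return np.sum((pts - closest) ** 2, axis=1) <= self.radius**2 + 1e-12


def simulate_frap_sequence(params: FrapSimParams) -> tuple[FrapSequence, dict]:
    """Simulate a FRAP image sequence and return it with its ground truth.

    Particles are placed uniformly in the cell; a fraction diffuses with
    D_mobile (reflected at the cell boundary by step resampling), the rest
    is static. At t = 0 each particle inside the bleach box loses its
    fluorescence with probability ``bleach_depth``. Frames are Gaussian-
    smoothed particle-count images scaled by the per-frame acquisition decay
    plus background and (optionally) Poisson shot noise and Gaussian read
    noise. The ground-truth record carries the true masks, mobile fraction
    and D_mobile.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size_um
    cell = _Spherocylinder(params.cell_length_um, params.cell_width_um)
    nx = int(np.ceil(params.cell_length_um / px)) + 2 * params.margin_px
    ny = int(np.ceil(params.cell_width_um / px)) + 2 * params.margin_px
    offset = params.margin_px * px  # cell bounding box origin in image µm coords

    bw, bh = params.bleach_box_px
    if params.bleach_box_origin_px is None:
        # left pole, vertically centred on the cell axis
        col0 = params.margin_px
        row0 = int(round(params.margin_px + cell.radius / px - bh / 2.0))
    else:
        col0, row0 = params.bleach_box_origin_px
    if col0 < 0 or row0 < 0 or col0 + bw > nx or row0 + bh > ny:
        raise ParameterError("bleach box does not fit inside the image")
    box_um = (col0 * px - offset, (col0 + bw) * px - offset,
              row0 * px - offset, (row0 + bh) * px - offset)  # cell-frame µm

    # uniform placement inside the capsule by rejection
    pos = np.empty((params.n_particles, 2))
    filled = 0
    while filled < params.n_particles:
        cand = rng.uniform(
            [0.0, 0.0], [params.cell_length_um, params.cell_width_um],
            size=(2 * (params.n_particles - filled), 2),
        )
        cand = cand[cell.contains(cand)]
        take = min(len(cand), params.n_particles - filled)
        pos[filled : filled + take] = cand[:take]
        filled += take
    mobile = rng.random(params.n_particles) < params.mobile_fraction
    fluorescent = np.ones(params.n_particles, dtype=bool)

    if params.d_mobile_um2_s > 0:
        dt_max = min(0.5, (0.2 * cell.radius) ** 2 / (4.0 * params.d_mobile_um2_s))
    else:
        dt_max = np.inf

    def propagate(duration: float) -> None:
        if duration <= 0 or params.d_mobile_um2_s == 0 or not mobile.any():
            return
        # cap the substep count: fine substeps matter only for wall fidelity,
        # and steps much larger than the cell just resample toward uniform
        n_sub = min(max(1, int(np.ceil(duration / dt_max))), 256)
        sd = math.sqrt(2.0 * params.d_mobile_um2_s * duration / n_sub)
        idx = np.flatnonzero(mobile)
        p = pos[idx]
        for _ in range(n_sub):
            step = rng.normal(0.0, sd, size=p.shape)
            trial = p + step
            bad = ~cell.contains(trial)
            for _retry in range(20):
                if not bad.any():
                    break
                step = rng.normal(0.0, sd, size=(int(bad.sum()), 2))
                trial[bad] = p[bad] + step
                bad[bad] = ~cell.contains(trial[bad])
            trial[bad] = p[bad]  # rare: leave in place this sub-step
            p = trial
        pos[idx] = p

    def render(frame_index: int) -> np.ndarray:
        pts = pos[fluorescent]
        counts, _, _ = np.histogram2d(
            pts[:, 1] + offset, pts[:, 0] + offset,
            bins=(ny, nx), range=((0, ny * px), (0, nx * px)),
        )
        img = ndimage.gaussian_filter(counts * params.brightness, sigma=1.0)
        img = img * params.acquisition_bleach_rate**frame_index + params.background_level
        if params.noise:
            img = rng.poisson(img).astype(float)
            img += rng.normal(0.0, params.read_noise_sd, size=img.shape)
            img = np.clip(img, 0.0, None)
        return img

    times = np.asarray(params.timestamps_s, dtype=float)
    frames = np.empty((len(times), ny, nx))
    current_t = times[0]
    bleached_applied = False
    for i, t_frame in enumerate(times):
        propagate(t_frame - current_t)
        current_t = t_frame
        if not bleached_applied and t_frame > 0:
            # bleach event at t = 0, between the last pre and first post frame
            propagate(0.0)
            x0, x1, y0, y1 = box_um
            in_box = (
                (pos[:, 0] >= x0) & (pos[:, 0] < x1)
                & (pos[:, 1] >= y0) & (pos[:, 1] < y1)
            )
            zapped = in_box & (rng.random(params.n_particles) < params.bleach_depth)
            fluorescent[zapped] = False
            bleached_applied = True
        frames[i] = render(i)

    phase = np.where(times <= 0, "pre", "post").astype(object)

    rows, cols = np.mgrid[0:ny, 0:nx]
    centers = np.column_stack(
        [(cols.ravel() + 0.5) * px - offset, (rows.ravel() + 0.5) * px - offset]
    )
    cell_mask = cell.contains(centers).reshape(ny, nx)
    box_mask = np.zeros((ny, nx), dtype=bool)
    box_mask[row0 : row0 + bh, col0 : col0 + bw] = True
    truth = {
        "cell_mask": cell_mask,
        "bleach_mask": box_mask & cell_mask,
        "bleach_box_px": (col0, row0, bw, bh),
        "mobile_fraction": params.mobile_fraction,
        "d_mobile_um2_s": params.d_mobile_um2_s,
        "bleach_depth": params.bleach_depth,
        "pixel_size_um": px,
        "seed": params.seed,
    }
    seq = FrapSequence(
        frames=frames, t=times, phase=phase,
        meta={"pixel_size_um": px, "seed": params.seed},
    )
    return seq, truth


@dataclass
class PatchMapParams:
    """Parameters of a two-channel localization-density patch map.

    The default configuration emulates the co-localization setting: a
    rectangular cell footprint carrying a uniform membrane signal in both
    channels, modestly brighter circular patches whose centers are
    anti-correlated between channels, and a dark exterior, so that a
    minimal threshold on the dimmer channel selects the cell. Use
    :meth:`for_morphometry` for high-contrast sparse patches on a dark
    background (island-size measurement).
    """

    field_um: float = 2.56
    pixel_size_um: float = 0.01
    n_patches: int = 25
    patch_diameter_um: float = 0.22          # median of a lognormal
    patch_diameter_spread: float = 0.12      # sigma of log-diameter
    anti_correlation: float = -1.0           # [-1, 1]; <0 mutually exclusive
    density_in_per_um2: float = 4500.0       # localization density inside patches
    density_out_per_um2: float = 3000.0      # in-cell density outside patches
    exterior_density_per_um2: float = 20.0
    cell_um: tuple[float, float] | None = (2.2, 1.4)  # None: whole field is "cell"
    precision_um: float = 0.02               # localization precision (render sigma)
    seed: int = 0

    @classmethod
    def for_morphometry(cls, n_patches: int = 120, seed: int = 0) -> "PatchMapParams":
        """High-contrast sparse-patch configuration for island measurement."""
        return cls(
            field_um=5.12,
            n_patches=n_patches,
            anti_correlation=0.0,
            density_in_per_um2=30000.0,
            density_out_per_um2=100.0,
            exterior_density_per_um2=0.0,
            cell_um=None,
            seed=seed,
        )

    def validate(self) -> None:
        if self.field_um <= 0 or self.pixel_size_um <= 0:
            raise ParameterError("field and pixel size must be positive")
        if self.patch_diameter_um >= self.field_um:
            raise ParameterError("patch diameter must be smaller than the field")
        if not -1.0 <= self.anti_correlation <= 1.0:
            raise ParameterError("anti-correlation strength must lie in [-1, 1]")
        if self.precision_um < 0:
            raise ParameterError("localization precision must be >= 0")


def _uniform_in_disc(rng: np.random.Generator, center: np.ndarray, radius: float, n: int) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return center + np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def simulate_patch_maps(params: PatchMapParams) -> tuple[ChannelPair, dict]:
    """Two registered localization-density maps plus ground-truth patches.

    Patch centers in channel B avoid (probability |anti_correlation|, when
    negative) landing inside any channel-A patch; a positive strength
    co-locates B patches on A centers with that probability. Localization
    events are binned on the pixel grid and rendered with a Gaussian of the
    stated localization precision.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    f = params.field_um
    if params.cell_um is None:
        cell_lo = np.array([0.0, 0.0])
        cell_hi = np.array([f, f])
    else:
        cw, ch = params.cell_um
        if cw > f or ch > f:
            raise ParameterError("cell footprint exceeds the field")
        cell_lo = np.array([(f - cw) / 2.0, (f - ch) / 2.0])
        cell_hi = cell_lo + [cw, ch]

    def sample_diameters(n: int) -> np.ndarray:
        return params.patch_diameter_um * np.exp(
            params.patch_diameter_spread * rng.standard_normal(n)
        )

    def place_uniform(radius: float) -> np.ndarray:
        lo = np.maximum(cell_lo, radius)
        hi = np.minimum(cell_hi, f - radius)
        return rng.uniform(lo, hi)

    def place_patch(
        radius: float,
        same_channel: list[tuple[np.ndarray, float]],
        other_centers: np.ndarray | None,
        other_radii: np.ndarray | None,
        reject_prob: float,
    ) -> np.ndarray:
        """Rejection placement: same-channel discs stay disjoint; a disc
        overlapping the other channel's patches is rejected with
        ``reject_prob`` (so strength -1 yields disjoint, truly
        anti-correlated domains). Bounded tries; a crowded field accepts
        the last proposal rather than looping forever."""
        c = place_uniform(radius)
        for _ in range(2000):
            c = place_uniform(radius)
            if any(np.hypot(*(c - pc)) < radius + pr for pc, pr in same_channel):
                continue
            if other_centers is not None and reject_prob > 0:
                overlaps = np.any(
                    np.sum((other_centers - c) ** 2, axis=1)
                    < (other_radii + radius) ** 2
                )
                if overlaps and rng.random() < reject_prob:
                    continue
            return c
        return c

    strength = params.anti_correlation
    diam_a = sample_diameters(params.n_patches)
    placed_a: list[tuple[np.ndarray, float]] = []
    for d in diam_a:
        placed_a.append((place_patch(d / 2.0, placed_a, None, None, 0.0), d / 2.0))
    centers_a = np.array([c for c, _ in placed_a])

    diam_b = sample_diameters(params.n_patches)
    centers_b = np.empty((params.n_patches, 2))
    a_r = diam_a / 2.0
    placed_b: list[tuple[np.ndarray, float]] = []
    for i, d in enumerate(diam_b):
        if strength > 0 and rng.random() < strength:
            centers_b[i] = centers_a[rng.integers(params.n_patches)]
        else:
            centers_b[i] = place_patch(
                d / 2.0, placed_b, centers_a, a_r, max(-strength, 0.0)
            )
        placed_b.append((centers_b[i], d / 2.0))

    area = lambda d: np.pi * (d / 2.0) ** 2  # noqa: E731
    extra = max(params.density_in_per_um2 - params.density_out_per_um2, 0.0)
    cell_area = float(np.prod(cell_hi - cell_lo))

    def channel_events(centers: np.ndarray, diams: np.ndarray) -> np.ndarray:
        chunks = []
        n_base = rng.poisson(params.density_out_per_um2 * cell_area)
        chunks.append(rng.uniform(cell_lo, cell_hi, size=(n_base, 2)))
        if params.exterior_density_per_um2 > 0:
            n_ext = rng.poisson(params.exterior_density_per_um2 * f * f)
            ext = rng.uniform(0.0, f, size=(n_ext, 2))
            outside = ~np.all((ext >= cell_lo) & (ext <= cell_hi), axis=1)
            chunks.append(ext[outside])
        for c, d in zip(centers, diams):
            k = rng.poisson(extra * area(d))
            chunks.append(_uniform_in_disc(rng, c, d / 2.0, k))
        return np.concatenate(chunks)

    n_px = int(round(f / params.pixel_size_um))
    sigma = params.precision_um / params.pixel_size_um

    def render(events: np.ndarray) -> np.ndarray:
        counts, _, _ = np.histogram2d(
            events[:, 1], events[:, 0], bins=n_px, range=((0, f), (0, f))
        )
        return ndimage.gaussian_filter(counts, sigma=sigma) if sigma > 0 else counts

    img_a = render(channel_events(centers_a, diam_a))
    img_b = render(channel_events(centers_b, diam_b))
    truth = {
        "centers_a_um": centers_a,
        "diameters_a_um": diam_a,
        "centers_b_um": centers_b,
        "diameters_b_um": diam_b,
        "cell_um": (tuple(cell_lo), tuple(cell_hi)),
        "seed": params.seed,
    }
    return ChannelPair(a=img_a, b=img_b, pixel_size_um=params.pixel_size_um), truth
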