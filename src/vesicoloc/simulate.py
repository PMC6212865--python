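"""Synthetic dual/tri-channel fluorescence microscopy of endosomal vesicles.

The generator emulates the geometry of membrane-marker imaging of endosomes:
a Rab-family GTPase marker decorates the endosome *surface*, producing a ring
(annulus) in the marker channel, while a lumenal cargo fills the *inside* of
the vesicle, producing a filled disk strictly inside the ring in the cargo
channel.  Because the two signals occupy disjoint sub-structures they never
overlap pixel-wise, which is exactly the situation in which object-based
(per-vesicle) colocalization is the right statistic.

Optionally, punctate particles (e.g. EGFP-tagged immature capsids) are
attached to a subset of cargo-positive vesicles and rendered in a third
channel; attached puncta follow their vesicle's position exactly in
time-lapse mode.

Rendering model
---------------
Objects are rasterized as hard shapes on a 4x-supersampled grid (sub-pixel
centers supported), summed into a photon image, convolved with an isotropic
Gaussian point-spread function, offset by a uniform background, and then
corrupted with Poisson shot noise followed by zero-mean Gaussian read noise
(the standard CCD/sCMOS camera model).  Negative values after read noise are
clipped at zero.

Every simulation returns the rendered :class:`FrameStack` together with a
:class:`GroundTruth` table so downstream detection, colocalization and
tracking stages can be validated without any real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SimulationConfig",
    "FrameStack",
    "GroundTruth",
    "simulate_field",
    "simulate_timelapse",
    "simulate_tracks",
    "MOTION_CLASSES",
]

MOTION_CLASSES = ("directed", "diffusive", "confined")

VESICLE_COLUMNS = [
    "vesicle_id",
    "center_row",
    "center_col",
    "radius",
    "is_cargo_positive",
    "has_punctum",
]
TRACK_COLUMNS = [
    "track_id",
    "object_type",
    "vesicle_id",
    "motion_class",
    "frame",
    "row",
    "col",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic vesicle field or time-lapse.

    Intensities are in photons/pixel above background unless stated
    otherwise; lengths in pixels; times in seconds; the diffusion
    coefficient is in pixels^2/frame.
    """

    image_height: int = 512
    image_width: int = 512
    n_vesicles: int = 50
    coloc_fraction: float = 0.5
    ring_radius_range: tuple[float, float] = (4.0, 7.0)
    ring_thickness: float = 2.0
    marker_amplitude: float = 400.0
    cargo_amplitude: float = 300.0
    punctum_amplitude: float = 2000.0  # integrated photons per punctum
    background_level: float = 100.0
    psf_sigma: float = 1.2
    read_noise_sigma: float = 2.0
    min_separation: float | None = None  # default: 3 x max ring radius
    n_frames: int = 1
    frame_interval: float = 1.0
    motion_mix: Mapping[str, float] = field(
        default_factory=lambda: {"directed": 0.3, "diffusive": 0.5, "confined": 0.2}
    )
    speed: float = 2.0  # px/frame, directed motion
    diffusion_coefficient: float = 1.0  # px^2/frame
    confinement_radius: float = 5.0
    position_noise_sigma: float = 0.0
    punctum_attach_fraction: float = 0.0
    poisson_noise: bool = True
    pixel_size: float | None = None  # microns/pixel, metadata only
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def effective_min_separation(self) -> float:
        if self.min_separation is not None:
            return self.min_separation
        return 3.0 * self.ring_radius_range[1]

    def validate(self) -> None:
        scalars = {
            "image_height": self.image_height,
            "image_width": self.image_width,
            "ring_thickness": self.ring_thickness,
            "marker_amplitude": self.marker_amplitude,
            "cargo_amplitude": self.cargo_amplitude,
            "punctum_amplitude": self.punctum_amplitude,
            "background_level": self.background_level,
            "psf_sigma": self.psf_sigma,
            "read_noise_sigma": self.read_noise_sigma,
            "frame_interval": self.frame_interval,
            "speed": self.speed,
            "diffusion_coefficient": self.diffusion_coefficient,
            "confinement_radius": self.confinement_radius,
            "position_noise_sigma": self.position_noise_sigma,
            "coloc_fraction": self.coloc_fraction,
            "punctum_attach_fraction": self.punctum_attach_fraction,
        }
        for name, value in scalars.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite configuration value: {name}={value!r}")
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_vesicles < 0:
            raise ValueError("n_vesicles must be >= 0")
        if not (0.0 <= self.coloc_fraction <= 1.0):
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if not (0.0 <= self.punctum_attach_fraction <= 1.0):
            raise ValueError("punctum_attach_fraction must lie in [0, 1]")
        rmin, rmax = self.ring_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("ring_radius_range must satisfy 0 < min <= max")
        if not (0 < self.ring_thickness < rmin):
            raise ValueError("ring_thickness must be positive and smaller than the minimum radius")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        unknown = set(self.motion_mix) - set(MOTION_CLASSES)
        if unknown:
            raise ValueError(f"unknown motion classes in motion_mix: {sorted(unknown)}")
        total = sum(self.motion_mix.get(c, 0.0) for c in MOTION_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"motion_mix must sum to 1 (got {total})")


@dataclass
class FrameStack:
    """Time-ordered multi-channel intensity stack.

    ``frames`` has shape ``(n_frames, n_channels, height, width)`` and is
    non-negative.  ``channels`` names the channel axis (subset of
    marker/cargo/punctum).
    """

    frames: np.ndarray
    channels: tuple[str, ...]
    frame_interval: float = 1.0
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 4:
            raise ValueError("frames must be a (T, C, H, W) array")
        if self.frames.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def channel(self, name: str, frame: int = 0) -> np.ndarray:
        return self.frames[frame, self.channels.index(name)]


@dataclass
class GroundTruth:
    """Per-vesicle and per-track truth tables used as the testing oracle."""

    vesicles: pd.DataFrame
    tracks: pd.DataFrame

    def realized_cargo_fraction(self) -> float:
        if len(self.vesicles) == 0:
            return float("nan")
        return float(self.vesicles["is_cargo_positive"].mean())

    def track_positions(self, track_id: int) -> np.ndarray:
        sub = self.tracks[self.tracks["track_id"] == track_id].sort_values("frame")
        return sub[["row", "col"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# rasterization


def _add_radial_shape(
    img: np.ndarray,
    center: tuple[float, float],
    r_in: float,
    r_out: float,
    amplitude: float,
    oversample: int = 4,
) -> None:
    """Add a hard annulus (r_in <= d < r_out) rasterized at ``oversample`` x.

    Pixel (i, j) spans [i-0.5, i+0.5) x [j-0.5, j+0.5); per-pixel coverage is
    the fraction of its subsamples falling inside the shape.
    """
    h, w = img.shape
    r0, c0 = center
    pad = int(math.ceil(r_out)) + 1
    rmin = max(int(math.floor(r0)) - pad, 0)
    rmax = min(int(math.ceil(r0)) + pad, h - 1)
    cmin = max(int(math.floor(c0)) - pad, 0)
    cmax = min(int(math.ceil(c0)) + pad, w - 1)
    if rmax < rmin or cmax < cmin:
        return
    nr = rmax - rmin + 1
    nc = cmax - cmin + 1
    os_ = oversample
    ys = rmin - 0.5 + (np.arange(nr * os_) + 0.5) / os_
    xs = cmin - 0.5 + (np.arange(nc * os_) + 0.5) / os_
    d2 = (ys[:, None] - r0) ** 2 + (xs[None, :] - c0) ** 2
    inside = (d2 >= r_in * r_in) & (d2 < r_out * r_out)
    frac = inside.reshape(nr, os_, nc, os_).mean(axis=(1, 3))
    img[rmin : rmax + 1, cmin : cmax + 1] += amplitude * frac


def _add_point_source(img: np.ndarray, pos: tuple[float, float], photons: float) -> None:
    """Deposit ``photons`` at a sub-pixel position by bilinear spreading."""
    h, w = img.shape
    r, c = pos
    i0 = int(math.floor(r))
    j0 = int(math.floor(c))
    fr = r - i0
    fc = c - j0
    for di, dj, wgt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        i, j = i0 + di, j0 + dj
        if 0 <= i < h and 0 <= j < w:
            img[i, j] += photons * wgt


def render_noiseless_channels(
    config: SimulationConfig,
    vesicles: pd.DataFrame,
    positions: np.ndarray | None = None,
    punctum_positions: np.ndarray | None = None,
    *,
    apply_psf: bool = True,
    add_background: bool = True,
) -> dict[str, np.ndarray]:
    """Render one frame's channels without noise.

    ``positions`` overrides the per-vesicle centers (shape ``(n, 2)``);
    ``punctum_positions`` gives punctum centers for vesicles whose
    ``has_punctum`` flag is set (same row order as those vesicles).
    Exposed separately so the photon-conservation contract of the PSF step
    can be checked directly.
    """
    shape = (config.image_height, config.image_width)
    marker = np.zeros(shape)
    cargo = np.zeros(shape)
    punctum = np.zeros(shape)

    centers = (
        positions
        if positions is not None
        else vesicles[["center_row", "center_col"]].to_numpy(dtype=float)
    )
    punctum_iter = iter(punctum_positions) if punctum_positions is not None else None

    for idx, (_, ves) in enumerate(vesicles.iterrows()):
        r = float(ves["radius"])
        center = (float(centers[idx, 0]), float(centers[idx, 1]))
        _add_radial_shape(marker, center, r - config.ring_thickness, r, config.marker_amplitude)
        if ves["is_cargo_positive"]:
            _add_radial_shape(cargo, center, 0.0, r - config.ring_thickness, config.cargo_amplitude)
        if ves["has_punctum"]:
            if punctum_iter is not None:
                p = next(punctum_iter)
                ppos = (float(p[0]), float(p[1]))
            else:
                ppos = center
            _add_point_source(punctum, ppos, config.punctum_amplitude)

    channels = {"marker": marker, "cargo": cargo}
    if config.punctum_attach_fraction > 0:
        channels["punctum"] = punctum
    if apply_psf:
        channels = {
            name: ndimage.gaussian_filter(ch, config.psf_sigma, mode="constant")
            for name, ch in channels.items()
        }
    if add_background:
        channels = {name: ch + config.background_level for name, ch in channels.items()}
    return channels


def _apply_noise(channel: np.ndarray, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    out = channel
    if config.poisson_noise:
        out = rng.poisson(np.clip(out, 0.0, None)).astype(np.float64)
    if config.read_noise_sigma > 0:
        out = out + rng.normal(0.0, config.read_noise_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# placement and object sampling


def _edge_margin(config: SimulationConfig) -> float:
    # objects stay >= 2 x radius from edges to avoid truncation ambiguity
    return 2.0 * config.ring_radius_range[1]


def _place_centers(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_vesicles
    if n == 0:
        return np.empty((0, 2))
    margin = _edge_margin(config)
    lo_r, hi_r = margin, config.image_height - 1 - margin
    lo_c, hi_c = margin, config.image_width - 1 - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("image too small for the requested vesicle radii and edge margin")
    min_sep2 = config.effective_min_separation ** 2
    centers: list[tuple[float, float]] = []
    budget = 10 * max(n, 1)
    for i in range(n):
        for _ in range(budget):
            cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
            if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_sep2 for r, c in centers):
                centers.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place vesicle {i + 1}/{n} after {budget} attempts: "
                f"min_separation={config.effective_min_separation:.1f} px is too dense "
                f"for a {config.image_height}x{config.image_width} field"
            )
    return np.asarray(centers)


def _sample_vesicles(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    centers = _place_centers(config, rng)
    n = config.n_vesicles
    radii = rng.uniform(*config.ring_radius_range, size=n)
    cargo = rng.random(n) < config.coloc_fraction
    punctum = cargo & (rng.random(n) < config.punctum_attach_fraction)
    return pd.DataFrame(
        {
            "vesicle_id": np.arange(n, dtype=int),
            "center_row": centers[:, 0] if n else np.empty(0),
            "center_col": centers[:, 1] if n else np.empty(0),
            "radius": radii,
            "is_cargo_positive": cargo,
            "has_punctum": punctum,
        }
    )


# ---------------------------------------------------------------------------
# motion models


def simulate_tracks(
    n_tracks: int,
    motion_class: str,
    n_frames: int,
    *,
    speed: float = 2.0,
    diffusion_coefficient: float = 1.0,
    confinement_radius: float = 5.0,
    position_noise_sigma: float = 0.0,
    starts: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Generate trajectories of one motion class; shape ``(n_tracks, n_frames, 2)``.

    directed: constant speed along a random fixed heading.
    diffusive: 2-D random walk, per-axis step variance ``2 D`` (D in px^2/frame),
    i.e. mean squared per-frame displacement ``4 D``.
    confined: random walk reflected radially at ``confinement_radius`` about the
    start point.
    ``position_noise_sigma`` adds i.i.d. Gaussian localization jitter on top of
    the true path.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if motion_class not in MOTION_CLASSES:
        raise ValueError(f"unknown motion class {motion_class!r}")
    if starts is None:
        starts = np.zeros((n_tracks, 2))
    starts = np.asarray(starts, dtype=float)
    t = np.arange(n_frames, dtype=float)

    if motion_class == "directed":
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n_tracks)
        u = np.stack([np.sin(theta), np.cos(theta)], axis=1)  # (n, 2)
        paths = starts[:, None, :] + speed * t[None, :, None] * u[:, None, :]
    else:
        sd = math.sqrt(2.0 * diffusion_coefficient)
        steps = rng.normal(0.0, sd, size=(n_tracks, n_frames - 1, 2))
        if motion_class == "diffusive":
            paths = np.concatenate(
                [starts[:, None, :], starts[:, None, :] + np.cumsum(steps, axis=1)], axis=1
            )
        else:  # confined: step-by-step radial reflection about the start
            paths = np.empty((n_tracks, n_frames, 2))
            paths[:, 0] = starts
            rc = confinement_radius
            for k in range(1, n_frames):
                pos = paths[:, k - 1] + steps[:, k - 1]
                d = pos - starts
                dist = np.hypot(d[:, 0], d[:, 1])
                out = dist > rc
                # reflect the radial overshoot back inside (repeat for big steps)
                iters = 0
                while np.any(out) and iters < 16:
                    scale = (2.0 * rc - dist[out]) / dist[out]
                    d[out] = d[out] * scale[:, None]
                    dist = np.hypot(d[:, 0], d[:, 1])
                    out = dist > rc
                    iters += 1
                paths[:, k] = starts + d
    if position_noise_sigma > 0:
        paths = paths + rng.normal(0.0, position_noise_sigma, size=paths.shape)
    return paths


def _fit_directed_heading(
    start: np.ndarray,
    n_frames: int,
    speed: float,
    bounds: tuple[float, float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a heading whose full constant-velocity path stays in bounds."""
    lo_r, hi_r, lo_c, hi_c = bounds
    travel = speed * (n_frames - 1)
    for _ in range(200):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        end = start + travel * np.array([math.sin(theta), math.cos(theta)])
        if lo_r <= end[0] <= hi_r and lo_c <= end[1] <= hi_c:
            return np.array([math.sin(theta), math.cos(theta)])
    raise RuntimeError(
        f"no directed heading keeps a {travel:.0f} px path inside the field; "
        "increase the image size or lower speed/n_frames"
    )


def _simulate_motion(
    config: SimulationConfig,
    vesicles: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vesicle trajectories; returns (positions (n, T, 2), classes (n,))."""
    n = len(vesicles)
    T = config.n_frames
    margin = _edge_margin(config)
    bounds = (
        margin,
        config.image_height - 1 - margin,
        margin,
        config.image_width - 1 - margin,
    )
    probs = np.array([config.motion_mix.get(c, 0.0) for c in MOTION_CLASSES])
    classes = rng.choice(len(MOTION_CLASSES), size=n, p=probs / probs.sum())
    starts = vesicles[["center_row", "center_col"]].to_numpy(dtype=float)
    positions = np.empty((n, T, 2))
    for i in range(n):
        cls = MOTION_CLASSES[classes[i]]
        if cls == "directed":
            u = _fit_directed_heading(starts[i], T, config.speed, bounds, rng)
            t = np.arange(T, dtype=float)
            path = starts[i][None, :] + config.speed * t[:, None] * u[None, :]
        else:
            path = simulate_tracks(
                1,
                cls,
                T,
                diffusion_coefficient=config.diffusion_coefficient,
                confinement_radius=config.confinement_radius,
                starts=starts[i][None, :],
                rng=rng,
            )[0]
            path[:, 0] = np.clip(path[:, 0], bounds[0], bounds[1])
            path[:, 1] = np.clip(path[:, 1], bounds[2], bounds[3])
        if config.position_noise_sigma > 0:
            path = path + rng.normal(0.0, config.position_noise_sigma, size=path.shape)
        positions[i] = path
    return positions, classes


# ---------------------------------------------------------------------------
# public entry points


def simulate_field(config: SimulationConfig) -> tuple[FrameStack, GroundTruth]:
    """Render a single dual/tri-channel field with ground truth.

    Identical (config, seed) pairs produce bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    vesicles = _sample_vesicles(config, rng)
    channels = render_noiseless_channels(config, vesicles)
    names = tuple(channels)
    noisy = [_apply_noise(channels[name], config, rng) for name in names]
    frames = np.stack(noisy)[None, ...]
    stack = FrameStack(
        frames=frames,
        channels=names,
        frame_interval=config.frame_interval,
        pixel_size=config.pixel_size,
    )
    tracks = pd.DataFrame(columns=TRACK_COLUMNS)
    return stack, GroundTruth(vesicles=vesicles, tracks=tracks)


def simulate_timelapse(config: SimulationConfig) -> tuple[FrameStack, GroundTruth]:
    """Render a time-lapse of moving vesicles (attached puncta ride along).

    Each vesicle is assigned a motion class from ``motion_mix``; the ground
    truth records the class and the per-frame true center of every vesicle
    and punctum track.
    """
    config.validate()
    if config.n_frames < 2:
        raise ValueError("simulate_timelapse requires n_frames >= 2")
    rng = np.random.default_rng(config.seed)
    vesicles = _sample_vesicles(config, rng)
    positions, class_idx = _simulate_motion(config, vesicles, rng)

    frames = []
    names: tuple[str, ...] = ()
    for t in range(config.n_frames):
        channels = render_noiseless_channels(config, vesicles, positions=positions[:, t])
        names = tuple(channels)
        frames.append(np.stack([_apply_noise(channels[n_], config, rng) for n_ in names]))
    stack = FrameStack(
        frames=np.stack(frames),
        channels=names,
        frame_interval=config.frame_interval,
        pixel_size=config.pixel_size,
    )

    rows = []
    n = len(vesicles)
    punctum_tid = n
    for i in range(n):
        cls = MOTION_CLASSES[class_idx[i]]
        for t in range(config.n_frames):
            rows.append((i, "vesicle", i, cls, t, positions[i, t, 0], positions[i, t, 1]))
        if vesicles.loc[i, "has_punctum"]:
            for t in range(config.n_frames):
                rows.append(
                    (punctum_tid, "punctum", i, cls, t, positions[i, t, 0], positions[i, t, 1])
                )
            punctum_tid += 1
    tracks = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return stack, GroundTruth(vesicles=vesicles, tracks=tracks)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
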