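"""Configuration, TIFF/CSV I/O, provenance, and the two composed analyses.

The two end-to-end entry points mirror the two imaging analyses the library
supports:

* :func:`run_rab_coloc` — segment marker-channel (e.g. EGFP-Rab) vesicles,
  call each one cargo-positive or negative against a robust background model,
  report the percent-positive statistic, and compute masked pixel
  colocalization (Pearson, Manders) inside the vesicle mask.
* :func:`run_cotransport` — on a time-lapse, segment cargo vesicles and
  detect puncta per frame, measure the punctum co-transport fraction, link
  vesicles through time, and classify each track's motion from its MSD.

Runs are reproducible: a (config, seed) pair determines every output byte,
and each output directory carries a provenance record (config hash, seed,
package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .coloc import (
    ColocSummary,
    PixelColocResult,
    classify_objects,
    estimate_background,
    percent_positive,
    pixel_coloc,
)
from .detect import DetectionParams, PunctaParams, detect_puncta, detect_vesicles
from .simulate import (
    FrameStack,
    GroundTruth,
    SimulationConfig,
    simulate_field,
    simulate_timelapse,
)
from .track import classify_motion, compute_msd, cotransport_fraction, link_detections

__all__ = [
    "ColocParams",
    "TrackingParams",
    "RunConfig",
    "ResultBundle",
    "read_stack",
    "write_stack",
    "write_ground_truth",
    "ground_truth_label_map",
    "run_rab_coloc",
    "run_cotransport",
]

logger = logging.getLogger("vesicoloc")

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class ColocParams:
    """Object-call and pixel-colocalization settings."""

    k: float = 3.0
    dilation_radius: int = 3
    threshold_mode: str = "background-model"  # otsu | background-model | fixed
    mask_from: str = "marker"  # marker | cargo
    use_ground_truth_mask: bool = False


@dataclass(frozen=True)
class TrackingParams:
    """Linking, MSD and co-transport settings."""

    max_displacement: float = 8.0
    max_gap: int = 1
    min_length: int = 4
    max_lag_fraction: float = 0.25
    cotransport_max_distance: float = 3.0
    cotransport_min_frames: int = 3


@dataclass(frozen=True)
class RunConfig:
    """Full run description: exactly one of an input file or a simulation."""

    outdir: str
    simulation: SimulationConfig | None = None
    input_path: str | None = None
    channels: dict = field(default_factory=lambda: {"marker": 0, "cargo": 1, "punctum": 2})
    frame_interval: float = 1.0
    detection: DetectionParams = field(default_factory=DetectionParams)
    puncta: PunctaParams = field(default_factory=PunctaParams)
    coloc: ColocParams = field(default_factory=ColocParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_path is None):
            raise ValueError("exactly one of 'simulation' or 'input_path' must be given")
        idx = list(self.channels.values())
        if len(idx) != len(set(idx)):
            raise ValueError("channel indices must be distinct")


_SCHEMA_VERSION = 1

_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "detection": DetectionParams,
    "puncta": PunctaParams,
    "coloc": ColocParams,
    "tracking": TrackingParams,
}


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{section}' config section: {sorted(unknown)}")
    if cls is SimulationConfig and "ring_radius_range" in data:
        data = dict(data, ring_radius_range=tuple(data["ring_radius_range"]))
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration; unknown keys are rejected (fail fast)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    schema = raw.pop("schema", None)
    if schema != _SCHEMA_VERSION:
        raise ValueError(f"config schema must be {_SCHEMA_VERSION} (got {schema!r})")
    top_allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES and value is not None:
            kwargs[key] = _build_section(_SECTION_TYPES[key], dict(value), key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the canonical JSON form of the configuration.

    The output directory and log level are excluded: they affect where and
    how verbosely results are written, not what is computed, so two runs of
    the same analysis into different directories share a hash.
    """
    payload = dataclasses.asdict(config)
    payload.pop("outdir", None)
    payload.pop("log_level", None)
    canon = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class ResultBundle:
    """Paths and headline numbers of one completed run."""

    outdir: Path
    summary: ColocSummary
    pixel: PixelColocResult | None = None
    files: dict = field(default_factory=dict)
    warning: str | None = None


# ---------------------------------------------------------------------------
# stack I/O


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a multi-page TIFF, one page per frame per channel
    (channel-fastest page order: marker, cargo, punctum)."""
    t, c, h, w = stack.frames.shape
    pages = stack.frames.reshape(t * c, h, w)
    tifffile.imwrite(str(path), pages, photometric="minisblack")


def read_stack(
    path: str | Path,
    n_channels: int,
    channels: tuple[str, ...] | None = None,
    frame_interval: float = 1.0,
) -> FrameStack:
    """Read a TIFF into a FrameStack, resolving the page axis into (T, C).

    Integer pixel data are preserved losslessly (converted to float64 without
    rounding).  Raises a distinct error for a missing file, an unreadable
    file, and a page count incompatible with ``n_channels``.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input stack not found: {p}")
    try:
        arr = tifffile.imread(str(p))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"could not read TIFF {p}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim == 3:
        pages = arr.shape[0]
        if pages % n_channels != 0:
            raise ValueError(
                f"axis mismatch: {pages} pages cannot be split into {n_channels} channels"
            )
        arr = arr.reshape(pages // n_channels, n_channels, *arr.shape[1:])
    elif arr.ndim == 4:
        if arr.shape[1] != n_channels:
            raise ValueError(
                f"axis mismatch: stack has {arr.shape[1]} channels, config demands {n_channels}"
            )
    else:
        raise ValueError(f"unsupported TIFF dimensionality: {arr.ndim}")
    if channels is None:
        channels = ("marker", "cargo", "punctum")[:n_channels]
    return FrameStack(frames=arr.astype(np.float64), channels=tuple(channels), frame_interval=frame_interval)


def write_ground_truth(gt: GroundTruth, outdir: str | Path) -> dict:
    """Write the simulator truth tables (one row per vesicle / per track-frame)."""
    outdir = Path(outdir)
    files = {}
    vpath = outdir / "ground_truth_vesicles.csv"
    gt.vesicles.to_csv(vpath, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    files["ground_truth_vesicles"] = vpath
    tpath = outdir / "ground_truth_tracks.csv"
    gt.tracks.to_csv(tpath, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    files["ground_truth_tracks"] = tpath
    return files


def ground_truth_label_map(vesicles: pd.DataFrame, shape: tuple[int, int]) -> np.ndarray:
    """Label map of filled true-vesicle disks (label = vesicle_id + 1)."""
    label_map = np.zeros(shape, dtype=np.int32)
    for _, v in vesicles.iterrows():
        r0, c0, rad = float(v["center_row"]), float(v["center_col"]), float(v["radius"])
        rmin = max(int(np.floor(r0 - rad)), 0)
        rmax = min(int(np.ceil(r0 + rad)) + 1, shape[0])
        cmin = max(int(np.floor(c0 - rad)), 0)
        cmax = min(int(np.ceil(c0 + rad)) + 1, shape[1])
        rows, cols = np.ogrid[rmin:rmax, cmin:cmax]
        d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        patch = label_map[rmin:rmax, cmin:cmax]
        patch[d2 <= rad * rad] = int(v["vesicle_id"]) + 1
    return label_map


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _write_provenance(config: RunConfig, outdir: Path, analysis: str) -> Path:
    record = {
        "analysis": analysis,
        "config_sha256": config_hash(config),
        "seed": config.seed if config.seed is not None else (
            config.simulation.seed if config.simulation else None
        ),
        "software": "vesicoloc",
        "version": __version__,
    }
    path = outdir / "provenance.json"
    path.write_text(json.dumps(record, sort_keys=True, indent=2) + "\n")
    return path


def _resolve_stack(config: RunConfig, timelapse: bool) -> tuple[FrameStack, GroundTruth | None]:
    if config.simulation is not None:
        sim = config.simulation
        if config.seed is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
        stack, gt = (simulate_timelapse if timelapse else simulate_field)(sim)
        logger.info("simulated %d frame(s), %d vesicle(s)", stack.n_frames, len(gt.vesicles))
        return stack, gt
    n_channels = len(config.channels)
    stack = read_stack(
        config.input_path, n_channels=n_channels, frame_interval=config.frame_interval
    )
    # map configured channel indices onto names
    names = sorted(config.channels, key=config.channels.get)
    stack.channels = tuple(names)
    logger.info("read %s: %d frame(s), channels %s", config.input_path, stack.n_frames, names)
    return stack, None


# ---------------------------------------------------------------------------
# composed analyses


def run_rab_coloc(config: RunConfig) -> ResultBundle:
    """Marker-mask object colocalization plus masked pixel colocalization."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack, gt = _resolve_stack(config, timelapse=False)
    mask_channel = config.coloc.mask_from
    other = "cargo" if mask_channel == "marker" else "marker"
    marker = stack.channel(mask_channel, 0)
    cargo = stack.channel(other, 0)

    files: dict = {}
    if config.simulation is not None:
        stack_path = outdir / "stack.tif"
        write_stack(stack, stack_path)
        files["stack"] = stack_path
        files.update(write_ground_truth(gt, outdir))

    if config.coloc.use_ground_truth_mask:
        if gt is None:
            raise ValueError("ground-truth mask mode requires a simulation block")
        label_map = ground_truth_label_map(gt.vesicles, marker.shape)
        from .detect import label_map_to_rois

        rois = label_map_to_rois(label_map, marker)
    else:
        rois, label_map = detect_vesicles(marker, config.detection)
    logger.info("detected %d vesicle ROI(s)", len(rois))

    warning = None
    if rois:
        bg_cargo = estimate_background(cargo, label_map, config.coloc.dilation_radius)
        bg_marker = estimate_background(marker, label_map, config.coloc.dilation_radius)
        calls = classify_objects(cargo, rois, bg_cargo, config.coloc.k)
        summary = percent_positive(calls)
        pixel = pixel_coloc(
            marker,
            cargo,
            label_map,
            threshold_mode=config.coloc.threshold_mode,
            bg_a=bg_marker,
            bg_b=bg_cargo,
            k=config.coloc.k,
        )
    else:
        calls = []
        summary = percent_positive(calls)
        pixel = None
        warning = "zero vesicles detected; percentage undefined"
        logger.warning(warning)

    objects = pd.DataFrame(
        {
            "label_id": [r.label_id for r in rois],
            "row": [r.centroid[0] for r in rois],
            "col": [r.centroid[1] for r in rois],
            "area": [r.area for r in rois],
            "mean_marker_intensity": [r.mean_marker_intensity for r in rois],
            "cargo_mean": [c.cargo_mean for c in calls],
            "threshold_used": [c.threshold_used for c in calls],
            "is_positive": [c.is_positive for c in calls],
        }
    )
    objects_path = outdir / "objects.csv"
    _write_csv(objects, objects_path)
    files["objects"] = objects_path

    summary_df = pd.DataFrame(
        [
            {
                "n_objects": summary.n_objects,
                "n_positive": summary.n_positive,
                "percent_positive": summary.percent_positive,
                "percent_undefined": summary.undefined,
                "ci_low": summary.ci_low,
                "ci_high": summary.ci_high,
                "pearson_r": pixel.pearson_r if pixel else float("nan"),
                "m1": pixel.manders_m1 if pixel else float("nan"),
                "m2": pixel.manders_m2 if pixel else float("nan"),
            }
        ]
    )
    summary_path = outdir / "summary.csv"
    _write_csv(summary_df, summary_path)
    files["summary"] = summary_path

    label_path = outdir / "label_map.tif"
    tifffile.imwrite(str(label_path), label_map.astype(np.uint16), photometric="minisblack")
    files["label_map"] = label_path
    files["provenance"] = _write_provenance(config, outdir, "rab-coloc")
    return ResultBundle(outdir=outdir, summary=summary, pixel=pixel, files=files, warning=warning)


def run_cotransport(config: RunConfig) -> ResultBundle:
    """Cargo-mask co-transport fraction plus per-track motion classification."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack, gt = _resolve_stack(config, timelapse=True)
    if stack.n_frames < 2:
        raise ValueError("co-transport analysis requires at least 2 frames")
    if "punctum" not in stack.channels:
        raise ValueError("co-transport analysis requires a punctum channel")

    files: dict = {}
    if config.simulation is not None:
        stack_path = outdir / "stack.tif"
        write_stack(stack, stack_path)
        files["stack"] = stack_path
        files.update(write_ground_truth(gt, outdir))

    rois_per_frame = []
    puncta_per_frame = []
    for f in range(stack.n_frames):
        rois, _ = detect_vesicles(stack.channel("cargo", f), config.detection)
        rois_per_frame.append(rois)
        puncta_per_frame.append(detect_puncta(stack.channel("punctum", f), config.puncta, frame_index=f))
    logger.info(
        "per-frame detections: %s vesicles, %s puncta (frame 0)",
        len(rois_per_frame[0]),
        len(puncta_per_frame[0]),
    )

    summary = cotransport_fraction(
        rois_per_frame,
        puncta_per_frame,
        max_distance=config.tracking.cotransport_max_distance,
        min_frames=config.tracking.cotransport_min_frames,
        link_max_displacement=config.tracking.max_displacement,
        link_max_gap=config.tracking.max_gap,
    )
    warning = "zero vesicles detected; percentage undefined" if summary.undefined else None
    if warning:
        logger.warning(warning)

    centroid_frames = [
        np.array([r.centroid for r in rois], dtype=float).reshape(-1, 2) for rois in rois_per_frame
    ]
    tracks = link_detections(
        centroid_frames,
        max_displacement=config.tracking.max_displacement,
        max_gap=config.tracking.max_gap,
        min_length=max(2, config.tracking.min_length),
    )
    logger.info("linked %d track(s)", len(tracks))

    track_rows = []
    msd_rows = []
    motion_rows = []
    for trk in tracks:
        for frame, row, col in trk.points:
            track_rows.append((trk.track_id, int(frame), row, col))
        if trk.n_points < 4:
            continue
        msd = compute_msd(trk, stack.frame_interval, config.tracking.max_lag_fraction)
        for lag, val, npair in zip(msd.lags, msd.msd, msd.n_pairs):
            msd_rows.append((trk.track_id, lag, val, int(npair)))
        est = classify_motion(msd)
        motion_rows.append(
            (
                trk.track_id,
                est.alpha,
                est.diffusion_coefficient,
                est.velocity,
                est.r_squared,
                est.motion_class,
            )
        )

    tracks_path = outdir / "tracks.csv"
    _write_csv(pd.DataFrame(track_rows, columns=["track_id", "frame", "row", "col"]), tracks_path)
    files["tracks"] = tracks_path
    msd_path = outdir / "msd.csv"
    _write_csv(pd.DataFrame(msd_rows, columns=["track_id", "lag_s", "msd_px2", "n_pairs"]), msd_path)
    files["msd"] = msd_path
    motion_path = outdir / "motion.csv"
    _write_csv(
        pd.DataFrame(
            motion_rows,
            columns=["track_id", "alpha", "diffusion_coefficient", "velocity", "r_squared", "motion_class"],
        ),
        motion_path,
    )
    files["motion"] = motion_path

    summary_df = pd.DataFrame(
        [
            {
                "n_objects": summary.n_objects,
                "n_positive": summary.n_positive,
                "percent_positive": summary.percent_positive,
                "percent_undefined": summary.undefined,
                "ci_low": summary.ci_low,
                "ci_high": summary.ci_high,
                "n_tracks": len(tracks),
                "n_classified": len(motion_rows),
            }
        ]
    )
    summary_path = outdir / "summary.csv"
    _write_csv(summary_df, summary_path)
    files["summary"] = summary_path
    files["provenance"] = _write_provenance(config, outdir, "cotransport")
    return ResultBundle(outdir=outdir, summary=summary, pixel=None, files=files, warning=warning)
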