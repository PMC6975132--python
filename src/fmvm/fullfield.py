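"""Full-field pipeline: detect -> skeletonize -> kymograph -> velocity.

Runs the whole velocimetry chain on every capillary in the field of view and
collects per-capillary velocities plus field statistics, together with the
reference visual RBC-tracking calculation (path length / elapsed time), the
coincidence statistic comparing the two methods, and the measurable-velocity
range set by the frame rate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time

import numpy as np
import pandas as pd

from . import __version__
from .detection import CapillaryBox, detect_framediff, detect_threshold
from .errors import FmvmError, InputError
from .kymograph import (
    VelocityEstimate,
    build_kymograph,
    fit_streaks_auto,
    summarize_velocity,
)
from .skeletonize import extract_path, segment_vessel, thin
from .video import VideoStack

__all__ = [
    "CalibrationInfo",
    "PipelineConfig",
    "CapillaryResult",
    "FailureRecord",
    "FullFieldReport",
    "run_pipeline",
    "vrbct_velocity",
    "coincidence",
    "velocity_limits",
    "write_report",
    "read_report",
]

log = logging.getLogger("fmvm")


@dataclasses.dataclass(frozen=True)
class CalibrationInfo:
    """Spatial/temporal calibration of the acquisition.

    ``optical_resolution_um`` is the diffraction-limited resolution (the
    smallest per-frame displacement that counts as motion); the wavelength is
    informational.
    """

    um_per_px: float
    fps: float = 60.0
    optical_resolution_um: float = 0.18
    wavelength_nm: float = 420.0

    def __post_init__(self) -> None:
        if min(self.um_per_px, self.fps, self.optical_resolution_um,
               self.wavelength_nm) <= 0:
            raise InputError("all calibration values must be positive")


@dataclasses.dataclass
class PipelineConfig:
    """Knobs of the full-field pipeline (all stages)."""

    detector: str = "threshold"  # threshold | framediff | boxes
    boxes: list[CapillaryBox] | None = None
    detect_frame: str | int = "median"  # middle-index frame by default
    box_pad_px: int = 3
    min_frames: int = 60
    min_area_px: int = 50
    min_spur_um: float = 10.0
    segment_projection: str = "min"  # min | median | frame index as int
    dark_quantile: float = 0.2
    min_streak_len_frames: int = 5
    detector_params: dict = dataclasses.field(default_factory=dict)
    seed: int | None = None

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["boxes"] = (
            None if self.boxes is None else [b.to_dict() for b in self.boxes]
        )
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclasses.dataclass
class CapillaryResult:
    """One successfully processed capillary."""

    box: CapillaryBox
    skeleton_length_um: float
    estimate: VelocityEstimate


@dataclasses.dataclass
class FailureRecord:
    """A capillary that could not be processed, with stage and reason."""

    box: CapillaryBox
    stage: str
    reason: str


@dataclasses.dataclass
class FullFieldReport:
    """Per-capillary velocities, failures, and field statistics."""

    results: list[CapillaryResult]
    failures: list[FailureRecord]
    field_mean_mm_s: float | None
    field_variance: float | None
    count: int
    um_per_px: float
    fps: float
    config_hash: str
    seed: int | None
    version: str
    status: str = "ok"


def _select_frame(video: VideoStack, which) -> np.ndarray:
    if which == "median":
        return video.frames[video.n_frames // 2]
    return video.frames[int(which)]


def _projection(frames: np.ndarray, how) -> np.ndarray:
    if how == "min":
        return frames.min(axis=0)
    if how == "median":
        return np.median(frames, axis=0)
    return frames[int(how)]


def run_pipeline(
    video: VideoStack, calib: CalibrationInfo, config: PipelineConfig | None = None
) -> FullFieldReport:
    """Measure the flow velocity of every capillary in the field.

    Boxes come from the configured detector (or are supplied directly); each
    box is independently segmented on the temporal-minimum projection (moving
    RBCs darken the whole tube), thinned, ordered into a path, turned into a
    kymograph and fitted.  Per-capillary failures are recorded with their
    stage and reason, never silently dropped.
    """
    config = config or PipelineConfig()
    if video.n_frames < config.min_frames:
        raise InputError(
            f"video has {video.n_frames} frames < min_frames={config.min_frames}"
        )
    if video.um_per_px != calib.um_per_px or video.fps != calib.fps:
        log.warning("video calibration differs from CalibrationInfo; using video's")

    if config.detector == "boxes":
        if config.boxes is None:
            raise InputError("detector='boxes' requires config.boxes")
        boxes = list(config.boxes)
    elif config.detector == "threshold":
        frame = _select_frame(video, config.detect_frame)
        boxes = detect_threshold(frame, **config.detector_params)
    elif config.detector == "framediff":
        boxes = detect_framediff(video, **config.detector_params)
    else:
        raise InputError(f"unknown detector '{config.detector}'")

    proj = _projection(video.frames, config.segment_projection)
    results: list[CapillaryResult] = []
    failures: list[FailureRecord] = []
    for box in boxes:
        t0 = time.perf_counter()
        stage = "segment"
        try:
            roi_box = box.pad(config.box_pad_px, video.frame_shape)
            roi = proj[roi_box.row_min : roi_box.row_max,
                       roi_box.col_min : roi_box.col_max]
            mask = segment_vessel(
                roi, min_area_px=config.min_area_px,
                roi_offset=(roi_box.row_min, roi_box.col_min),
            )
            stage = "thin"
            skel = thin(mask)
            stage = "extract_path"
            path = extract_path(
                skel, min_spur_um=config.min_spur_um,
                um_per_px=video.um_per_px, roi_offset=mask.roi_offset,
            )
            stage = "kymograph"
            kymo = build_kymograph(video, path)
            stage = "fit_streaks"
            streaks = fit_streaks_auto(
                kymo, dark_quantile=config.dark_quantile,
                min_streak_len_frames=config.min_streak_len_frames,
            )
            est = summarize_velocity(streaks)
            results.append(CapillaryResult(box, path.total_length_um, est))
            log.info(
                "capillary %s: v=%.2f mm/s (%d streaks) in %.2f s",
                box, est.mean_velocity_mm_s, est.n_streaks,
                time.perf_counter() - t0,
            )
        except FmvmError as e:
            failures.append(FailureRecord(box, stage, str(e)))
            log.info("capillary %s failed at %s: %s", box, stage, e)

    velocities = np.array([r.estimate.mean_velocity_mm_s for r in results])
    report = FullFieldReport(
        results=results,
        failures=failures,
        field_mean_mm_s=float(velocities.mean()) if len(velocities) else None,
        field_variance=float(velocities.var()) if len(velocities) else None,
        count=len(results),
        um_per_px=video.um_per_px,
        fps=video.fps,
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        status="ok" if boxes else "warning: no capillaries detected",
    )
    return report


# ---------------------------------------------------------------------------
# reference calculations and statistics
# ---------------------------------------------------------------------------

def vrbct_velocity(path_length_um: float, elapsed_ms: float) -> float:
    """Visual RBC tracking velocity: traced path length / elapsed time.

    um/ms is numerically identical to mm/s.
    """
    if elapsed_ms <= 0:
        raise InputError("elapsed_ms must be positive")
    if path_length_um < 0:
        raise InputError("path_length_um must be non-negative")
    return path_length_um / elapsed_ms


def coincidence(v_a: list[float], v_b: list[float]) -> float:
    """Average pairwise agreement of two velocity lists, in percent.

    Each pair contributes min/max (so the statistic never exceeds 100); the
    mean ratio is scaled to percent and rounded to the nearest integer.
    """
    a = np.asarray(v_a, dtype=float)
    b = np.asarray(v_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise InputError("velocity lists must have equal, nonzero length")
    if (a <= 0).any() or (b <= 0).any():
        raise InputError("coincidence requires strictly positive velocities")
    ratios = np.minimum(a, b) / np.maximum(a, b)
    return float(round(100.0 * ratios.mean()))


def velocity_limits(
    calib: CalibrationInfo, observable_length_um: float
) -> tuple[float, float]:
    """Measurable velocity range [v_min, v_max] in mm/s, set by the frame rate.

    v_min = delta * f: one optical-resolution element per frame is the
    slowest resolvable motion.  v_max = L * f: a cell crossing the whole
    observable vessel length in one frame interval is the fastest.
    """
    if observable_length_um <= 0:
        raise InputError("observable_length_um must be positive")
    v_min = calib.optical_resolution_um * calib.fps / 1000.0
    v_max = observable_length_um * calib.fps / 1000.0
    return v_min, v_max


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------

def _report_to_dict(report: FullFieldReport) -> dict:
    return {
        "results": [
            {
                "box": r.box.to_dict(),
                "skeleton_length_um": r.skeleton_length_um,
                "estimate": dataclasses.asdict(r.estimate),
            }
            for r in report.results
        ],
        "failures": [
            {"box": f.box.to_dict(), "stage": f.stage, "reason": f.reason}
            for f in report.failures
        ],
        "field_mean_mm_s": report.field_mean_mm_s,
        "field_variance": report.field_variance,
        "count": report.count,
        "um_per_px": report.um_per_px,
        "fps": report.fps,
        "config_hash": report.config_hash,
        "seed": report.seed,
        "version": report.version,
        "status": report.status,
    }


def write_report(report: FullFieldReport, path) -> None:
    """Write report.json plus a one-row-per-capillary summary.csv alongside.

    Velocities in the CSV summary are rounded to one decimal in mm/s (the
    conventional reporting precision); the JSON keeps full precision so that
    read_report(write_report(r)) round-trips exactly.
    """
    path = pathlib.Path(path)
    if path.suffix.lower() != ".json":
        path.mkdir(parents=True, exist_ok=True)
        path = path / "report.json"
    path.write_text(json.dumps(_report_to_dict(report), indent=1))
    rows = []
    for r in report.results:
        rows.append(
            {
                "row_min": r.box.row_min, "col_min": r.box.col_min,
                "row_max": r.box.row_max, "col_max": r.box.col_max,
                "length_um": round(r.skeleton_length_um, 1),
                "velocity_mm_s": round(r.estimate.mean_velocity_mm_s, 1),
                "sd_mm_s": round(r.estimate.sd_mm_s, 2),
                "n_streaks": r.estimate.n_streaks,
                "direction": r.estimate.direction,
            }
        )
    pd.DataFrame(
        rows,
        columns=["row_min", "col_min", "row_max", "col_max", "length_um",
                 "velocity_mm_s", "sd_mm_s", "n_streaks", "direction"],
    ).to_csv(path.with_name("summary.csv"), index=False)


def read_report(path) -> FullFieldReport:
    """Load a report.json written by :func:`write_report`."""
    d = json.loads(pathlib.Path(path).read_text())
    results = [
        CapillaryResult(
            box=CapillaryBox.from_dict(r["box"]),
            skeleton_length_um=r["skeleton_length_um"],
            estimate=VelocityEstimate(**r["estimate"]),
        )
        for r in d["results"]
    ]
    failures = [
        FailureRecord(CapillaryBox.from_dict(f["box"]), f["stage"], f["reason"])
        for f in d["failures"]
    ]
    return FullFieldReport(
        results=results,
        failures=failures,
        field_mean_mm_s=d["field_mean_mm_s"],
        field_variance=d["field_variance"],
        count=d["count"],
        um_per_px=d["um_per_px"],
        fps=d["fps"],
        config_hash=d["config_hash"],
        seed=d["seed"],
        version=d["version"],
        status=d["status"],
    )
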