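"""Capillary detection baselines, box I/O and detection-rate metrics.

Two classic detectors are provided — static threshold segmentation of a single
frame and temporal frame differencing — together with a file interface for
boxes produced by an external detector (e.g. a trained object-detection
network), greedy IoU matching against ground truth, and the detection-rate /
false-positive-rate statistics

    Pm_T = 100 * N_detect_true / N_total
    Pm_F = 100 * N_detect_false / N_total

where N_total counts ground-truth capillaries, N_detect_true the detections
matched to a truth box, and N_detect_false the unmatched detections.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import apply_hysteresis_threshold, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing as _closing
from skimage.morphology import disk, remove_small_objects

from .errors import ConfigError, InputError, ParseError
from .video import VideoStack

__all__ = [
    "CapillaryBox",
    "DetectionEval",
    "iou",
    "detect_threshold",
    "detect_framediff",
    "load_boxes",
    "save_boxes",
    "match_detections",
    "detection_rates",
]


@dataclasses.dataclass(frozen=True)
class CapillaryBox:
    """Axis-aligned box in pixel coordinates, half-open ([min, max))."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int
    score: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("row_min", "col_min", "row_max", "col_max"):
            object.__setattr__(self, name, int(getattr(self, name)))
        if self.row_min < 0 or self.col_min < 0:
            raise InputError(f"negative box coordinate: {self}")
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise InputError(f"empty or inverted box: {self}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise InputError(f"box score outside [0, 1]: {self.score}")

    @property
    def area(self) -> int:
        return (self.row_max - self.row_min) * (self.col_max - self.col_min)

    def clip(self, frame_shape: tuple[int, int]) -> "CapillaryBox":
        h, w = frame_shape
        return CapillaryBox(
            max(self.row_min, 0),
            max(self.col_min, 0),
            min(self.row_max, h),
            min(self.col_max, w),
            self.score,
            self.label,
        )

    def pad(self, px: int, frame_shape: tuple[int, int]) -> "CapillaryBox":
        h, w = frame_shape
        return CapillaryBox(
            max(self.row_min - px, 0),
            max(self.col_min - px, 0),
            min(self.row_max + px, h),
            min(self.col_max + px, w),
            self.score,
            self.label,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CapillaryBox":
        return cls(
            d["row_min"], d["col_min"], d["row_max"], d["col_max"],
            d.get("score"), d.get("label", ""),
        )


def iou(a: CapillaryBox, b: CapillaryBox) -> float:
    """Intersection-over-union of two half-open boxes."""
    ri = max(a.row_min, b.row_min)
    ci = max(a.col_min, b.col_min)
    ra = min(a.row_max, b.row_max)
    ca = min(a.col_max, b.col_max)
    inter = max(0, ra - ri) * max(0, ca - ci)
    if inter == 0:
        return 0.0
    return inter / float(a.area + b.area - inter)


@dataclasses.dataclass(frozen=True)
class DetectionEval:
    """Matched/unmatched detection counts against ground truth."""

    n_total: int
    n_detect_true: int
    n_detect_false: int
    iou_threshold: float

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_detect_true, self.n_detect_false) < 0:
            raise InputError("detection counts must be non-negative")
        if self.n_detect_true > self.n_total:
            raise InputError("n_detect_true cannot exceed n_total")


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def _components_to_boxes(mask: np.ndarray, min_area_px: int, tag: str) -> list[CapillaryBox]:
    mask = remove_small_objects(mask, max_size=min_area_px - 1)
    lab = label(mask, connectivity=2)
    boxes = []
    for rp in regionprops(lab):
        r0, c0, r1, c1 = rp.bbox
        boxes.append(CapillaryBox(r0, c0, r1, c1, None, tag))
    boxes.sort(key=lambda b: (b.row_min, b.col_min))
    return boxes


def _robust_sigma(x: np.ndarray) -> float:
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def detect_threshold(
    frame: np.ndarray,
    background_smoothing_px: float = 25.0,
    min_area_px: int = 80,
    morph_radius_px: int = 4,
    denoise_sigma_px: float = 1.5,
) -> list[CapillaryBox]:
    """Detect dark capillary structures in a single frame.

    The frame is background-flattened by subtracting a lightly denoised copy
    from a large-kernel Gaussian smooth of itself (so dark structures become
    positive), thresholded by Otsu with a 4-sigma robust noise floor and
    grown by hysteresis into the fainter vessel band, morphologically closed,
    and connected components of sufficient area are returned as boxes.  The
    noise floor makes a structure-free frame yield no detections and
    reproduces the low-SNR failure mode: a capillary whose contrast sits
    below the sensor noise is missed.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 16:
        raise ConfigError("frame must be a 2-D array of at least 16x16 px")
    if min(frame.shape) < background_smoothing_px:
        raise ConfigError(
            f"frame {frame.shape} smaller than smoothing kernel "
            f"({background_smoothing_px} px)"
        )
    smooth = ndimage.gaussian_filter(frame, background_smoothing_px)
    denoised = (
        ndimage.gaussian_filter(frame, denoise_sigma_px)
        if denoise_sigma_px > 0 else frame
    )
    resid = smooth - denoised  # dark structures -> positive
    if np.ptp(resid) == 0:
        return []
    sig = _robust_sigma(resid)
    floor = 4.0 * sig
    try:
        otsu = float(threshold_otsu(resid))
    except ValueError:
        return []
    # hysteresis: strong seeds (Otsu, noise-floor guarded) grown into the
    # fainter vessel-wall band, which sits between background and RBC levels
    strong = max(otsu, floor)
    weak = max(0.5 * strong, 3.0 * sig)
    mask = apply_hysteresis_threshold(resid, weak, strong)
    if morph_radius_px > 0:
        mask = _closing(mask, disk(morph_radius_px))
    return _components_to_boxes(mask, min_area_px, "threshold")


def detect_framediff(
    video: VideoStack,
    frame_gap: int = 2,
    diff_threshold: float | None = None,
    min_area_px: int = 80,
    accumulate_frames: int | None = None,
    morph_radius_px: int = 4,
) -> list[CapillaryBox]:
    """Detect moving capillaries by accumulated absolute frame differences.

    |I_t - I_{t-gap}| is averaged over ``accumulate_frames`` pairs (all
    available pairs by default).  Static structures — including a capillary
    with stalled flow — produce no response and are missed by design.
    """
    if frame_gap < 1:
        raise ConfigError("frame_gap must be >= 1")
    n = video.n_frames
    if n < frame_gap + 1:
        raise InputError(
            f"need at least frame_gap+1={frame_gap + 1} frames, got {n}"
        )
    n_pairs = n - frame_gap
    if accumulate_frames is not None:
        n_pairs = min(n_pairs, accumulate_frames)
    starts = np.linspace(0, n - frame_gap - 1, n_pairs).astype(int)
    acc = np.zeros(video.frame_shape, dtype=float)
    for t in starts:
        acc += np.abs(video.frames[t + frame_gap].astype(float) - video.frames[t])
    acc /= len(starts)
    if np.ptp(acc) == 0:
        return []
    if diff_threshold is None:
        med = float(np.median(acc))
        diff_threshold = med + 4.0 * max(_robust_sigma(acc), 1e-12)
    mask = acc > diff_threshold
    if morph_radius_px > 0:
        mask = _closing(mask, disk(morph_radius_px))
    return _components_to_boxes(mask, min_area_px, "framediff")


# ---------------------------------------------------------------------------
# box file interface (external detectors)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["row_min", "col_min", "row_max", "col_max", "score", "label"]


def save_boxes(boxes: list[CapillaryBox], path) -> None:
    """Write boxes as CSV (`row_min,col_min,row_max,col_max,score,label`) or JSON."""
    path = pathlib.Path(path)
    records = [b.to_dict() for b in boxes]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=1))
    else:
        df = pd.DataFrame(records, columns=_CSV_COLUMNS)
        df.to_csv(path, index=False)


def load_boxes(path) -> list[CapillaryBox]:
    """Load boxes from the CSV/JSON schema written by :func:`save_boxes`."""
    path = pathlib.Path(path)
    if not path.exists():
        raise InputError(f"box file not found: {path}")
    if path.suffix.lower() == ".json":
        try:
            records = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: invalid JSON ({e})") from e
    else:
        try:
            df = pd.read_csv(path)
        except Exception as e:  # pragma: no cover - pandas-specific messages
            raise ParseError(f"{path}: unreadable CSV ({e})") from e
        missing = [c for c in _CSV_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing required columns {missing}")
        records = df.to_dict("records")
    boxes = []
    for i, rec in enumerate(records):
        try:
            score = rec.get("score")
            if score is None or (isinstance(score, float) and np.isnan(score)):
                score = None
            lab = rec.get("label", "")
            if lab is None or (isinstance(lab, float) and np.isnan(lab)):
                lab = ""
            boxes.append(
                CapillaryBox(
                    int(rec["row_min"]), int(rec["col_min"]),
                    int(rec["row_max"]), int(rec["col_max"]),
                    None if score is None else float(score), str(lab),
                )
            )
        except (KeyError, TypeError, ValueError, InputError) as e:
            raise ParseError(f"{path}: record {i} invalid: {e}") from e
    return boxes


# ---------------------------------------------------------------------------
# matching and rates
# ---------------------------------------------------------------------------

def match_detections(
    predicted: list[CapillaryBox],
    truth: list[CapillaryBox],
    iou_threshold: float = 0.5,
) -> DetectionEval:
    """Greedy one-to-one matching of predictions to truth in descending IoU.

    A prediction whose best available truth overlap reaches ``iou_threshold``
    counts as a true detection; each truth box is matched at most once; the
    remaining predictions are false detections.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ConfigError("iou_threshold must lie in (0, 1)")
    pairs = []
    for i, p in enumerate(predicted):
        for j, t in enumerate(truth):
            v = iou(p, t)
            if v >= iou_threshold:
                pairs.append((v, i, j))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    for v, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
    return DetectionEval(
        n_total=len(truth),
        n_detect_true=len(used_t),
        n_detect_false=len(predicted) - len(used_p),
        iou_threshold=iou_threshold,
    )


def detection_rates(ev: DetectionEval) -> tuple[float, float]:
    """Detection rate and false-positive rate in percent, one decimal.

    Pm_T = 100*n_detect_true/n_total; Pm_F = 100*n_detect_false/n_total.
    Pm_F may exceed 100 when false detections outnumber ground truth.
    """
    if ev.n_total <= 0:
        raise InputError("detection rates undefined for n_total = 0")
    pm_t = round(100.0 * ev.n_detect_true / ev.n_total, 1)
    pm_f = round(100.0 * ev.n_detect_false / ev.n_total, 1)
    return pm_t, pm_f
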