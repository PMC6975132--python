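"""Synthetic microcirculation video generator with exact ground truth.

Emulates violet-illuminated (420 nm) skin capillaroscopy: a bright tissue
background, faintly darkened curved capillary tubes, and strongly absorbing
red blood cells (RBCs) rendered as dark elongated blobs that advance along
the tube centerline at a constant per-capillary velocity.  Because hemoglobin
absorbs strongly in the Soret band, RBCs image darker than the vessel wall,
which images darker than tissue — the polarity every downstream stage relies
on.

The generator is a pure function of its configuration: identical config and
seed give bit-identical videos.  Ground truth (tube masks, boxes, centerline
polylines, velocities) is returned alongside the frames so that detection,
skeletonization and velocimetry can all be scored without real data.

RBC trains are irregular: consecutive center-to-center gaps are jittered
around ``rbc_spacing``.  A perfectly periodic train is temporally aliased
whenever the per-frame displacement is commensurate with the spacing, an
ambiguity no slope estimator can resolve; physiological trains are irregular,
which removes it.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib

import numpy as np
from scipy.interpolate import splev, splprep
from scipy.spatial import cKDTree

from .detection import CapillaryBox
from .errors import ConfigError
from .video import VideoStack

__all__ = [
    "CapillarySpec",
    "SimulationConfig",
    "CapillaryTruth",
    "SimulationTruth",
    "simulate_video",
    "render_truth_boxes",
    "save_truth",
    "load_truth",
]

#: FWHM-to-sigma conversion for the Gaussian RBC profile.
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))
#: Vessel-wall shading as a fraction of rbc_contrast * background: the tube
#: band is visibly but faintly darker than tissue, and scales with the same
#: optical contrast as the cells it carries.
TUBE_SHADE_FRACTION = 0.25
#: Arc step (pixels) of the dense centerline used for rendering and truth.
DENSE_STEP_PX = 0.25


@dataclasses.dataclass(frozen=True)
class CapillarySpec:
    """Geometry, flow and contrast of one simulated capillary.

    ``centerline_control_points`` are (row, col) positions in microns; the
    rendered centerline is a cubic parametric spline through them.  ``velocity``
    is signed in mm/s — positive flow runs from the first control point toward
    the last.  ``rbc_spacing`` is the mean center-to-center gap between
    consecutive RBCs and must exceed ``rbc_length`` so streaks stay separable.
    """

    centerline_control_points: tuple
    tube_width: float = 10.0
    velocity: float = 1.0
    rbc_length: float = 12.0
    rbc_spacing: float = 80.0
    rbc_contrast: float = 0.5
    rbc_spacing_jitter: float = 0.2

    def __post_init__(self) -> None:
        pts = tuple(tuple(float(v) for v in p) for p in self.centerline_control_points)
        object.__setattr__(self, "centerline_control_points", pts)
        if len(pts) < 2 or len(set(pts)) < 2:
            raise ConfigError("centerline needs at least 2 distinct control points")
        if not self.tube_width > 0:
            raise ConfigError("tube_width must be positive")
        if not self.rbc_length > 0:
            raise ConfigError("rbc_length must be positive")
        if not self.rbc_spacing > self.rbc_length:
            raise ConfigError(
                "rbc_spacing must exceed rbc_length (RBCs must be separable)"
            )
        if not (0.0 < self.rbc_contrast <= 1.0):
            raise ConfigError("rbc_contrast must lie in (0, 1]")
        if not (0.0 <= self.rbc_spacing_jitter < 0.5):
            raise ConfigError("rbc_spacing_jitter must lie in [0, 0.5)")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Scene and sensor parameters of one synthetic video.

    Defaults mirror the reference acquisition device: a 744x482 px sensor at
    60 fps.  ``um_per_px`` has no device default (optical magnification is an
    explicit calibration input) and defaults to 1.0.
    """

    capillaries: tuple
    frame_shape: tuple[int, int] = (482, 744)
    n_frames: int = 120
    um_per_px: float = 1.0
    fps: float = 60.0
    background_level: float = 200.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        caps = tuple(self.capillaries)
        for c in caps:
            if not isinstance(c, CapillarySpec):
                raise ConfigError("capillaries must be CapillarySpec instances")
        object.__setattr__(self, "capillaries", caps)
        object.__setattr__(self, "frame_shape", tuple(int(v) for v in self.frame_shape))
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if not (self.um_per_px > 0 and self.fps > 0):
            raise ConfigError("um_per_px and fps must be positive")
        if self.background_level <= 0:
            raise ConfigError("background_level must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclasses.dataclass
class CapillaryTruth:
    """Ground truth for one rendered capillary."""

    box: CapillaryBox
    skeleton_px: np.ndarray  # (N, 2) float, ~1 px arc steps, frame coords
    velocity: float  # mm/s, signed along the skeleton ordering
    tube_mask: np.ndarray  # boolean frame-size support of the tube band
    length_um: float


@dataclasses.dataclass
class SimulationTruth:
    """Per-capillary ground truth plus the global calibration of the scene."""

    capillaries: list[CapillaryTruth]
    um_per_px: float
    fps: float
    seed: int


def _dense_centerline(points_um, um_per_px: float):
    """Cubic-spline centerline resampled at uniform ~DENSE_STEP_PX arc steps.

    Returns (points_px (N,2), arc_um (N,)).
    """
    pts = np.asarray(points_um, dtype=float) / um_per_px
    k = min(3, len(pts) - 1)
    tck, _ = splprep(pts.T, s=0, k=k)
    uu = np.linspace(0.0, 1.0, max(1000, 50 * len(pts)))
    xy = np.stack(splev(uu, tck), axis=1)
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        raise ConfigError("degenerate centerline (zero length)")
    n = int(np.ceil(total / DENSE_STEP_PX)) + 1
    s = np.linspace(0.0, total, n)
    dense = np.stack([np.interp(s, arc, xy[:, 0]), np.interp(s, arc, xy[:, 1])], axis=1)
    return dense, s * um_per_px


class _RenderedCapillary:
    """Precomputed geometry of one capillary within a frame."""

    def __init__(self, spec: CapillarySpec, config: SimulationConfig):
        self.spec = spec
        self.upp = config.um_per_px
        self.dense_px, self.arc_um = _dense_centerline(
            spec.centerline_control_points, self.upp
        )
        self.total_um = float(self.arc_um[-1])
        self.tree = cKDTree(self.dense_px)
        self.sigma_par_um = spec.rbc_length / _FWHM
        # perpendicular profile is a flat-top quartic: the cell fills the tube
        # cross-section and falls off sharply at the vessel wall; scale chosen
        # so the half-maximum sits at the tube radius
        self.sigma_perp_um = 0.5 * spec.tube_width / (2.0 * math.log(2.0)) ** 0.25
        h, w = config.frame_shape
        half_px = 0.5 * spec.tube_width / self.upp
        # window must hold the tube band plus the farthest RBC tail reach
        pad = (
            int(np.ceil(half_px))
            + int(np.ceil((4.5 * self.sigma_par_um + 3.0 * self.sigma_perp_um) / self.upp))
            + 2
        )
        r0 = max(int(np.floor(self.dense_px[:, 0].min())) - pad, 0)
        r1 = min(int(np.ceil(self.dense_px[:, 0].max())) + pad + 1, h)
        c0 = max(int(np.floor(self.dense_px[:, 1].min())) - pad, 0)
        c1 = min(int(np.ceil(self.dense_px[:, 1].max())) + pad + 1, w)
        self.window = (r0, r1, c0, c1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
        d, _ = self.tree.query(grid)
        d = d.reshape(rr.shape)
        # soft-edged band: full shade inside the tube, 1-px linear roll-off
        shade = TUBE_SHADE_FRACTION * spec.rbc_contrast * config.background_level
        self.tube_dip = shade * np.clip(half_px + 0.5 - d, 0.0, 1.0)
        # the rendered tube support (where the band is visibly darkened)
        self.tube_mask_local = self.tube_dip > 0
        self.tube_mask = np.zeros((h, w), dtype=bool)
        self.tube_mask[r0:r1, c0:c1] = self.tube_mask_local

    def init_train(self, rng: np.random.Generator, duration_s: float) -> None:
        """Draw the jittered RBC train covering the path for the whole video."""
        sp = self.spec
        travel = abs(sp.velocity) * 1000.0 * duration_s
        lo = -2.0 * sp.rbc_length - travel - sp.rbc_spacing
        hi = self.total_um + 2.0 * sp.rbc_length + travel + sp.rbc_spacing
        n = int(np.ceil((hi - lo) / sp.rbc_spacing)) + 3
        gaps = sp.rbc_spacing * (
            1.0 + sp.rbc_spacing_jitter * rng.uniform(-1.0, 1.0, size=n)
        )
        start = lo + rng.uniform(0.0, sp.rbc_spacing)
        self.centers0_um = start + np.concatenate([[0.0], np.cumsum(gaps[:-1])])

    def rbc_dip(self, t_s: float, background: float) -> np.ndarray:
        """Absorption dip field of the RBC train at time ``t_s`` (window coords)."""
        sp = self.spec
        r0, r1, c0, c1 = self.window
        field = np.zeros((r1 - r0, c1 - c0), dtype=float)
        centers = self.centers0_um + sp.velocity * 1000.0 * t_s
        margin = 2.0 * sp.rbc_length
        centers = centers[(centers > -margin) & (centers < self.total_um + margin)]
        # generous reach so window truncation is negligible (< 1e-4 of the dip)
        reach_par = 4.5 * self.sigma_par_um
        reach_perp_px = 3.0 * self.sigma_perp_um / self.upp
        for s_c in centers:
            i0 = int(np.searchsorted(self.arc_um, s_c - reach_par))
            i1 = int(np.searchsorted(self.arc_um, s_c + reach_par))
            if i1 <= i0:
                continue
            seg = self.dense_px[i0:i1]
            pad = reach_perp_px
            if i0 == 0 or i1 == len(self.arc_um):
                # blob overhangs a path endpoint: its parallel tail extends
                # beyond the clipped segment's bounding box
                pad += reach_par / self.upp
            pr0 = max(int(np.floor(seg[:, 0].min() - pad)) - 1, r0)
            pr1 = min(int(np.ceil(seg[:, 0].max() + pad)) + 2, r1)
            pc0 = max(int(np.floor(seg[:, 1].min() - pad)) - 1, c0)
            pc1 = min(int(np.ceil(seg[:, 1].max() + pad)) + 2, c1)
            if pr1 <= pr0 or pc1 <= pc0:
                continue
            rr, cc = np.mgrid[pr0:pr1, pc0:pc1]
            pix = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
            d_perp_px, idx = self.tree.query(pix)
            d_par_um = self.arc_um[idx] - s_c
            d_perp_um = d_perp_px * self.upp
            g = np.exp(
                -0.5 * (d_par_um / self.sigma_par_um) ** 2
                - 0.5 * (d_perp_um / self.sigma_perp_um) ** 4
            ).reshape(rr.shape)
            sub = field[pr0 - r0 : pr1 - r0, pc0 - c0 : pc1 - c0]
            np.maximum(sub, g, out=sub)
        return sp.rbc_contrast * background * field


def simulate_video(config: SimulationConfig) -> tuple[VideoStack, SimulationTruth]:
    """Render a synthetic microcirculation video and its ground truth.

    Deterministic: identical ``config`` (including ``seed``) gives identical
    pixel arrays.  RBC centers advance by ``velocity * dt`` of arc length per
    frame; intensity ordering is RBC < tube band < background before noise.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.frame_shape
    duration = (config.n_frames - 1) / config.fps
    caps = [_RenderedCapillary(spec, config) for spec in config.capillaries]
    for cap in caps:
        cap.init_train(rng, duration)

    static = np.full((h, w), config.background_level, dtype=float)
    for cap in caps:
        r0, r1, c0, c1 = cap.window
        static[r0:r1, c0:c1] -= cap.tube_dip

    frames = np.empty((config.n_frames, h, w), dtype=np.float32)
    for t in range(config.n_frames):
        frame = static.copy()
        for cap in caps:
            r0, r1, c0, c1 = cap.window
            frame[r0:r1, c0:c1] -= cap.rbc_dip(t / config.fps, config.background_level)
        frames[t] = frame
    if config.noise_sd > 0:
        noise = rng.standard_normal(frames.shape, dtype=np.float32)
        frames += config.noise_sd * noise
    np.clip(frames, 0.0, None, out=frames)

    truths = []
    for cap in caps:
        rows, cols = np.nonzero(cap.tube_mask)
        if rows.size == 0:
            raise ConfigError("capillary tube lies entirely outside the frame")
        box = CapillaryBox(
            int(rows.min()), int(cols.min()),
            int(rows.max()) + 1, int(cols.max()) + 1,
            None, "truth",
        ).clip((h, w))
        step = max(int(round(1.0 / DENSE_STEP_PX)), 1)
        skel = cap.dense_px[::step].copy()
        truths.append(
            CapillaryTruth(
                box=box,
                skeleton_px=skel,
                velocity=cap.spec.velocity,
                tube_mask=cap.tube_mask,
                length_um=cap.total_um,
            )
        )
    video = VideoStack(frames, config.um_per_px, config.fps)
    truth = SimulationTruth(truths, config.um_per_px, config.fps, config.seed)
    return video, truth


def render_truth_boxes(truth: SimulationTruth) -> list[CapillaryBox]:
    """Tight boxes around each capillary's rendered tube extent."""
    return [t.box for t in truth.capillaries]


def save_truth(truth: SimulationTruth, path) -> None:
    """Serialize ground truth (boxes, skeleton polylines, velocities) as JSON."""
    payload = {
        "um_per_px": truth.um_per_px,
        "fps": truth.fps,
        "seed": truth.seed,
        "capillaries": [
            {
                "box": [t.box.row_min, t.box.col_min, t.box.row_max, t.box.col_max],
                "skeleton_px": np.asarray(t.skeleton_px).tolist(),
                "velocity_mm_s": t.velocity,
                "length_um": t.length_um,
            }
            for t in truth.capillaries
        ],
    }
    pathlib.Path(path).write_text(json.dumps(payload))


def load_truth(path) -> SimulationTruth:
    """Load a truth manifest written by :func:`save_truth` (masks not stored)."""
    payload = json.loads(pathlib.Path(path).read_text())
    caps = []
    for rec in payload["capillaries"]:
        r0, c0, r1, c1 = rec["box"]
        caps.append(
            CapillaryTruth(
                box=CapillaryBox(r0, c0, r1, c1, None, "truth"),
                skeleton_px=np.asarray(rec["skeleton_px"], dtype=float),
                velocity=float(rec["velocity_mm_s"]),
                tube_mask=np.zeros((0, 0), dtype=bool),
                length_um=float(rec["length_um"]),
            )
        )
    return SimulationTruth(caps, payload["um_per_px"], payload["fps"], payload["seed"])
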