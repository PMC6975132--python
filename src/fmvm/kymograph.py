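"""Spatiotemporal (kymograph) diagram construction and streak velocimetry.

Sampling each video frame along a capillary's centerline gives a 1-D
intensity profile; stacking the profiles of consecutive frames column by
column yields the kymograph — horizontal axis time, vertical axis arc-length
position.  A red blood cell moving at constant speed traces a dark diagonal
streak whose slope (microns of arc length per second) is the flow velocity;
positive slopes mean flow from path start toward path end.

Streaks are segmented automatically: the diagram is contrast-normalized per
column, dark pixels below a quantile threshold are labeled, connected
components are formed in a shear-compensated frame (so steep streaks at high
velocity remain connected across columns), and each component's (time, space)
point cloud is fitted by darkness-weighted total least squares.  The coarse
shear slope comes from adjacent-column cross-correlation and is refined
against the component fits; the per-streak slopes themselves are always the
total-least-squares estimates.
"""

from __future__ import annotations

import dataclasses
import statistics

import numpy as np
from scipy import ndimage

from .errors import InputError, NoStreaksError, OutOfBoundsError
from .skeletonize import SkeletonPath
from .video import VideoStack

__all__ = [
    "Kymograph",
    "StreakFit",
    "VelocityEstimate",
    "build_kymograph",
    "fit_streaks_auto",
    "fit_streak_manual",
    "summarize_velocity",
]


@dataclasses.dataclass
class Kymograph:
    """2-D diagram: rows = arc-length samples, columns = frames."""

    data: np.ndarray
    space_step_um: float
    time_step_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError("kymograph data must be 2-D (space x time)")
        if not (self.space_step_um > 0 and self.time_step_s > 0):
            raise InputError("space_step_um and time_step_s must be positive")

    @property
    def n_space(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass(frozen=True)
class StreakFit:
    """A straight line fitted to one dark trajectory.

    ``slope_um_per_s`` is signed: positive = motion from path start toward
    path end.  Endpoints are ((t_start, s_start), (t_end, s_end)) in seconds
    and microns; ``residual_um`` is the RMS perpendicular scatter of the
    streak's pixels about the line, in microns.
    """

    slope_um_per_s: float
    t_start: float
    s_start: float
    t_end: float
    s_end: float
    residual_um: float
    n_pixels: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope_um_per_s):
            raise InputError("streak slope must be finite")
        if not self.t_end > self.t_start:
            raise InputError("t_end must exceed t_start")


@dataclasses.dataclass(frozen=True)
class VelocityEstimate:
    """Signed mean velocity over streaks, with dispersion and direction."""

    mean_velocity_mm_s: float
    sd_mm_s: float
    n_streaks: int
    direction: str  # forward | backward | mixed

    def __post_init__(self) -> None:
        if self.n_streaks < 1:
            raise InputError("a velocity estimate needs at least one streak")
        if self.sd_mm_s < 0:
            raise InputError("sd must be non-negative")


def build_kymograph(video: VideoStack, path: SkeletonPath) -> Kymograph:
    """Sample every frame along the skeleton path, bilinearly interpolated.

    The path is resampled at uniform arc-length steps of one pixel-equivalent
    (``space_step`` = total length / (n-1), within a fraction of a percent of
    ``um_per_px``); the grid includes both endpoints, so reversing the path
    flips the diagram's rows exactly.  Column t holds frame t's samples.
    """
    pts = path.frame_points.astype(float)
    if len(pts) < 2:
        raise InputError("skeleton path needs at least 2 points")
    n_s = int(np.floor(path.total_length_um / video.um_per_px + 1e-9)) + 1
    if n_s < 2:
        raise InputError("skeleton path shorter than one pixel")
    step = path.total_length_um / (n_s - 1)
    s = np.linspace(0.0, path.total_length_um, n_s)
    rows = np.interp(s, path.cum_length_um, pts[:, 0])
    cols = np.interp(s, path.cum_length_um, pts[:, 1])
    h, w = video.frame_shape
    bad = (rows < 0) | (rows > h - 1) | (cols < 0) | (cols > w - 1)
    if bad.any():
        i = int(np.argmax(bad))
        raise OutOfBoundsError(
            f"skeleton point ({rows[i]:.1f}, {cols[i]:.1f}) at arc {s[i]:.1f} um "
            f"lies outside the {h}x{w} frame"
        )
    coords = np.stack([rows, cols])
    data = np.empty((n_s, video.n_frames))
    for t in range(video.n_frames):
        data[:, t] = ndimage.map_coordinates(
            video.frames[t].astype(float), coords, order=1, mode="nearest"
        )
    return Kymograph(data, space_step_um=step, time_step_s=video.dt)


# ---------------------------------------------------------------------------
# automatic streak segmentation and fitting
# ---------------------------------------------------------------------------

def _coarse_slope(dark: np.ndarray, max_slope: float) -> float:
    """Dominant streak slope (rows per column) by adjacent-column correlation.

    The mean cross-correlation of consecutive darkness columns peaks at the
    per-frame displacement of the RBC pattern; a parabolic fit around the
    peak gives sub-pixel precision.  Handles arbitrarily steep streaks, which
    are not 8-connected in raw pixels."""
    n_space, n_frames = dark.shape
    cols = dark - dark.mean(axis=0, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n_space)))
    f = np.fft.rfft(cols, n=nfft, axis=0)
    # sum over adjacent pairs of cross-power spectra
    cross = (f[:, 1:] * np.conj(f[:, :-1])).sum(axis=1)
    ccf = np.fft.irfft(cross, n=nfft)
    max_lag = min(n_space - 2, int(np.ceil(max_slope)))
    lags = np.arange(-max_lag, max_lag + 1)
    vals = ccf[lags % nfft]
    k = int(np.argmax(vals))
    lag = float(lags[k])
    if 0 < k < len(vals) - 1:  # parabolic sub-pixel refinement
        y0, y1, y2 = vals[k - 1], vals[k], vals[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            lag += 0.5 * (y0 - y2) / denom
    return float(np.clip(lag, -max_slope, max_slope))


def _label_sheared(
    mask: np.ndarray, slope: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Connected components of dark pixels after shear compensation.

    Pixel (r, t) maps to (r - slope*t, t); components are labeled with
    8-connectivity on the sheared grid after a 1-px dilation, which also
    merges streak fragments adjacent within one pixel.  Returns (rows, cols,
    component_id) for every masked pixel."""
    rs, ts = np.nonzero(mask)
    shear = rs - slope * ts
    s0 = int(np.floor(shear.min()))
    si = np.round(shear - s0).astype(int)
    grid = np.zeros((si.max() + 1, mask.shape[1]), dtype=bool)
    grid[si, ts] = True
    grid = ndimage.binary_dilation(grid, structure=np.ones((3, 3), dtype=bool))
    lab, _ = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))
    return rs, ts, lab[si, ts]


def _tls_fit(
    ts: np.ndarray, rs: np.ndarray, w: np.ndarray, kymo: Kymograph
) -> StreakFit | None:
    """Darkness-weighted total-least-squares line through a point cloud."""
    wsum = w.sum()
    if wsum <= 0:
        return None
    mt = float(np.sum(w * ts) / wsum)
    mr = float(np.sum(w * rs) / wsum)
    dt_ = ts - mt
    dr = rs - mr
    cov = np.array(
        [
            [np.sum(w * dt_ * dt_), np.sum(w * dt_ * dr)],
            [np.sum(w * dt_ * dr), np.sum(w * dr * dr)],
        ]
    ) / wsum
    evals, evecs = np.linalg.eigh(cov)
    vt, vr = evecs[:, 1]  # principal axis
    if abs(vt) < 1e-12:
        return None  # streak unresolved in time
    if vt < 0:
        vt, vr = -vt, -vr
    slope_px = vr / vt
    slope = slope_px * kymo.space_step_um / kymo.time_step_s
    proj = dt_ * vt + dr * vr
    i0, i1 = int(np.argmin(proj)), int(np.argmax(proj))
    t0, r0 = float(ts[i0]), float(rs[i0])
    t1, r1 = float(ts[i1]), float(rs[i1])
    if t1 <= t0:
        return None
    perp = -dt_ * vr + dr * vt
    rms_px = float(np.sqrt(np.sum(w * perp**2) / wsum))
    return StreakFit(
        slope_um_per_s=float(slope),
        t_start=t0 * kymo.time_step_s,
        s_start=r0 * kymo.space_step_um,
        t_end=t1 * kymo.time_step_s,
        s_end=r1 * kymo.space_step_um,
        residual_um=rms_px * kymo.space_step_um,
        n_pixels=int(len(ts)),
    )


def fit_streaks_auto(
    kymo: Kymograph,
    dark_quantile: float = 0.2,
    min_streak_len_frames: int = 5,
    smooth_sigma: float = 1.0,
    max_refine_iter: int = 4,
) -> list[StreakFit]:
    """Segment and fit every dark streak in a kymograph.

    Raises :class:`NoStreaksError` when no dark component spans at least
    ``min_streak_len_frames`` columns.
    """
    if kymo.n_frames < min_streak_len_frames:
        raise NoStreaksError(
            f"kymograph has {kymo.n_frames} columns < {min_streak_len_frames}"
        )
    if not (0.0 < dark_quantile < 1.0):
        raise InputError("dark_quantile must lie in (0, 1)")
    a = ndimage.gaussian_filter(kymo.data, smooth_sigma)
    norm = a - np.median(a, axis=0, keepdims=True)
    sigma = 1.4826 * float(np.median(np.abs(norm)))
    sigma = max(sigma, 1e-9)
    dark = -norm  # positive where darker than the column's median
    qt = np.quantile(norm, dark_quantile, axis=0, keepdims=True)
    # floor: above the noise scale and a fixed fraction of the deepest dip,
    # so near-blank columns and faint tails are not labeled
    floor = max(sigma, 0.05 * float(dark.max()))
    mask = (norm < qt) & (norm < -floor)
    if not mask.any():
        raise NoStreaksError("no pixels below the dark-quantile threshold")
    weights = np.where(mask, dark, 0.0)
    max_slope = float(kymo.n_space)  # one full path traversal per frame
    slope0 = _coarse_slope(np.clip(dark, 0.0, None), max_slope)

    fits: list[StreakFit] = []
    for _ in range(max_refine_iter):
        rs, ts, comp = _label_sheared(mask, slope0)
        fits = []
        for cid in np.unique(comp):
            sel = comp == cid
            if len(np.unique(ts[sel])) < min_streak_len_frames:
                continue
            fit = _tls_fit(
                ts[sel].astype(float), rs[sel].astype(float),
                weights[rs[sel], ts[sel]], kymo,
            )
            if fit is not None:
                fits.append(fit)
        if not fits:
            break
        slope_med_px = statistics.median(
            f.slope_um_per_s * kymo.time_step_s / kymo.space_step_um for f in fits
        )
        if abs(slope_med_px - slope0) <= 0.5:
            break
        slope0 = float(np.clip(slope_med_px, -max_slope, max_slope))
    if not fits:
        raise NoStreaksError(
            f"no dark component spans >= {min_streak_len_frames} frames"
        )
    fits.sort(key=lambda f: (f.t_start, f.s_start))
    return fits


def fit_streak_manual(
    kymo: Kymograph,
    p1: tuple[int, int],
    p2: tuple[int, int],
) -> StreakFit:
    """Slope of a manually selected streak through two diagram points.

    Points are (frame_index, space_index); slope = ds/dt in microns/second.
    """
    (t1, s1), (t2, s2) = p1, p2
    for t, s in (p1, p2):
        if not (0 <= t < kymo.n_frames and 0 <= s < kymo.n_space):
            raise InputError(f"point ({t}, {s}) outside kymograph {kymo.data.shape}")
    if t1 == t2:
        raise InputError("equal frame indices: slope undefined")
    if t1 > t2:
        t1, s1, t2, s2 = t2, s2, t1, s1
    slope = ((s2 - s1) * kymo.space_step_um) / ((t2 - t1) * kymo.time_step_s)
    return StreakFit(
        slope_um_per_s=float(slope),
        t_start=t1 * kymo.time_step_s,
        s_start=s1 * kymo.space_step_um,
        t_end=t2 * kymo.time_step_s,
        s_end=s2 * kymo.space_step_um,
        residual_um=0.0,
        n_pixels=2,
    )


def summarize_velocity(streaks: list[StreakFit]) -> VelocityEstimate:
    """Mean and sample-sd of streak slopes, converted to mm/s, with direction.

    Direction is "mixed" when streak slopes disagree in sign, otherwise
    forward (mean >= 0, i.e. flow from path start toward end) or backward.
    """
    if not streaks:
        raise InputError("summarize_velocity needs at least one streak")
    v = np.array([f.slope_um_per_s for f in streaks]) / 1000.0
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    signs = {1 if x > 0 else -1 for x in v if x != 0}
    if len(signs) > 1:
        direction = "mixed"
    else:
        direction = "forward" if mean >= 0 else "backward"
    return VelocityEstimate(mean, sd, len(v), direction)
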