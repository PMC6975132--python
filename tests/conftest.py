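"""Shared fixtures: cached synthetic videos, synthetic kymographs, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from fmvm import CapillarySpec, SimulationConfig, simulate_video

#: Moderate sensor noise (about 2.5% of the background level) used as the
#: standard study condition in end-to-end tests.
NOISE_SD = 5.0

S_CURVE = ((40.0, 30.0), (90.0, 100.0), (160.0, 140.0), (220.0, 220.0))


def single_capillary_config(
    velocity: float,
    seed: int,
    noise_sd: float = NOISE_SD,
    n_frames: int = 120,
    frame_shape=(256, 256),
    points=S_CURVE,
    **cap_kwargs,
) -> SimulationConfig:
    """One S-curved capillary crossing a small field of view."""
    return SimulationConfig(
        capillaries=[CapillarySpec(points, velocity=velocity, **cap_kwargs)],
        frame_shape=frame_shape,
        n_frames=n_frames,
        um_per_px=1.0,
        fps=60.0,
        background_level=200.0,
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def sim_cache():
    """Session-wide cache so identical scenes are rendered once."""
    cache: dict = {}

    def get(config: SimulationConfig):
        if config not in cache:
            cache[config] = simulate_video(config)
        return cache[config]

    return get


@pytest.fixture(scope="session")
def video_v1(sim_cache):
    """Standard moving-capillary video: v = 1.0 mm/s, moderate noise."""
    return sim_cache(single_capillary_config(1.0, seed=42))


@pytest.fixture(scope="session")
def two_capillary_scene(sim_cache):
    """One flowing (1.0 mm/s) and one stalled (0 mm/s) capillary."""
    caps = (
        CapillarySpec(((40, 30), (60, 100), (50, 180), (80, 230)), velocity=1.0),
        CapillarySpec(((180, 30), (160, 100), (200, 180), (170, 230)), velocity=0.0),
    )
    cfg = SimulationConfig(
        capillaries=caps, frame_shape=(256, 256), n_frames=120,
        noise_sd=NOISE_SD, seed=7,
    )
    return sim_cache(cfg)


def synth_kymograph(
    slope_px_per_frame: float,
    n_space: int = 250,
    n_frames: int = 120,
    thickness_px: float = 4.0,
    background: float = 200.0,
    depth: float = 100.0,
    space_step_um: float = 1.0,
    fps: float = 60.0,
):
    """Analytic single-streak kymograph: one dark line of known slope.

    The streak crosses the center of the diagram, so steep streaks span at
    least a handful of columns before leaving the space range.
    """
    from fmvm import Kymograph

    t = np.arange(n_frames)
    r = np.arange(n_space)[:, None]
    center = (n_space - 1) / 2.0 + slope_px_per_frame * (t - (n_frames - 1) / 2.0)
    data = background - depth * np.exp(-0.5 * ((r - center[None, :]) / thickness_px) ** 2)
    return Kymograph(data, space_step_um=space_step_um, time_step_s=1.0 / fps)


def radon_slope_oracle(
    kymo, slope_lo: float, slope_hi: float, n_coarse: int = 201, n_refine: int = 3
) -> float:
    """Brute-force angle search: the slope (px/frame) whose sheared line
    integral of darkness is maximal.  Independent of the production fit."""
    data = kymo.data
    n_space, n_frames = data.shape
    dark = np.clip(np.median(data, axis=0, keepdims=True) - data, 0.0, None)
    t = np.arange(n_frames)
    rows = np.arange(n_space)

    def score(m: float) -> float:
        best = 0.0
        # profile of line-integrated darkness over all offsets b
        total = np.zeros(n_space)
        for j in range(n_frames):
            shifted = np.interp(rows + m * (t[j] - (n_frames - 1) / 2.0),
                                rows, dark[:, j], left=0.0, right=0.0)
            total += shifted
        best = float(total.max())
        return best

    lo, hi = slope_lo, slope_hi
    for _ in range(n_refine):
        grid = np.linspace(lo, hi, n_coarse)
        scores = [score(m) for m in grid]
        k = int(np.argmax(scores))
        step = grid[1] - grid[0]
        lo, hi = grid[k] - step, grid[k] + step
    return float(grid[k])
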