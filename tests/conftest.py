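"""Shared fixtures: a fast small-sensor rig for unit tests and a noiseless
lighting condition, plus a calibrated model built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from clptrack import (
    CalibrationChart,
    Condition,
    RigConfig,
    generate_trajectory,
    render_sequence,
)
from clptrack.calibration import calibrate_from_frames


@pytest.fixture(scope="session")
def rig() -> RigConfig:
    """Default full-size rig (400x400, 8 px/deg)."""
    return RigConfig()


@pytest.fixture(scope="session")
def small_rig() -> RigConfig:
    """Scaled-down sensor for fast unit tests; same optical model."""
    return RigConfig(
        image_width=120,
        image_height=120,
        px_per_degree=2.0,
        spot_separation=24.0,
        spot_sigma=2.0,
    )


@pytest.fixture(scope="session")
def chart() -> CalibrationChart:
    return CalibrationChart()


def make_condition(
    name: str = "test",
    background_mean: float = 0.0,
    background_sd: float = 0.0,
    saturation_prob: float = 0.0,
    **kwargs,
) -> Condition:
    """Ad-hoc lighting condition for controlled experiments."""
    return Condition(
        name=name,
        illuminance_lx=0.0,
        background_mean=background_mean,
        background_sd=background_sd,
        saturation_prob=saturation_prob,
        **kwargs,
    )


@pytest.fixture(scope="session")
def noiseless() -> Condition:
    return make_condition("noiseless")


@pytest.fixture(scope="session")
def noiseless_model(small_rig, chart, noiseless):
    """Calibration fitted on a noiseless chart recording of the small rig."""
    poses = generate_trajectory(chart, 0.25, small_rig)
    frames = render_sequence(poses, small_rig, noiseless, seed=11)
    return calibrate_from_frames(frames, small_rig)


def brute_force_centroids(
    pixels: np.ndarray, threshold: float, min_area: int
) -> list[tuple[float, float, int, float, bool]]:
    """Independent per-pixel oracle for blob centroids.

    Pure-Python flood fill over 8-connected above-threshold pixels followed by
    explicit Sum(I*x)/Sum(I) accumulation on raw intensities.  Returns
    (centroid_x, centroid_y, area, mass, saturated) per component, sorted by
    centroid for stable comparison.
    """
    h, w = pixels.shape
    seen = [[False] * w for _ in range(h)]
    out = []
    for y0 in range(h):
        for x0 in range(w):
            if seen[y0][x0] or pixels[y0][x0] < threshold:
                continue
            stack = [(y0, x0)]
            seen[y0][x0] = True
            members = []
            while stack:
                y, x = stack.pop()
                members.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (
                            0 <= ny < h
                            and 0 <= nx < w
                            and not seen[ny][nx]
                            and pixels[ny][nx] >= threshold
                        ):
                            seen[ny][nx] = True
                            stack.append((ny, nx))
            if len(members) < min_area:
                continue
            sw = swx = swy = 0.0
            saturated = False
            for y, x in members:
                v = float(pixels[y][x])
                sw += v
                swx += v * x
                swy += v * y
                if pixels[y][x] == 255:
                    saturated = True
            out.append((swx / sw, swy / sw, len(members), sw, saturated))
    return sorted(out)
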