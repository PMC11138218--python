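"""Laser-spot detection: the entire feature-extraction stage of the CLP.

Because the eye camera sits behind an IR bandpass filter, frames are
near-binary — a dark background with two bright spots — so tracking the eye
reduces to segmenting the two blobs and computing their intensity-weighted
centroids.  A fixed threshold suffices (exposure is fixed before calibration
and no auto-exposure runs), which is what keeps the method real-time and
robust across lighting conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .rig import Frame, RigConfig

__all__ = [
    "SpotObservation",
    "SpotPair",
    "detect_blobs",
    "pair_spots",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MIN_AREA",
]

#: default binarization threshold (8-bit intensity); exposure is fixed, so a
#: constant works across all four lighting conditions
DEFAULT_THRESHOLD = 100
#: smallest accepted blob, pixels; rejects hot pixels
DEFAULT_MIN_AREA = 3


@dataclass(frozen=True)
class SpotObservation:
    """One detected blob: sub-pixel centroid plus bookkeeping."""

    centroid_x: float
    centroid_y: float
    area: int
    mass: float  # summed raw intensity of member pixels
    saturated: bool  # any member pixel at the 8-bit ceiling


@dataclass(frozen=True)
class SpotPair:
    """The two VCSEL spots, assigned left/right by image x coordinate."""

    left: SpotObservation
    right: SpotObservation

    def __post_init__(self) -> None:
        if not self.left.centroid_x < self.right.centroid_x:
            if (
                self.left.centroid_x == self.right.centroid_x
                and self.left.centroid_y < self.right.centroid_y
            ):
                return  # x tie broken by smaller y as left
            raise ValueError("left spot must lie left of the right spot")

    @property
    def coords(self) -> tuple[float, float, float, float]:
        """(x_left, y_left, x_right, y_right) — the measured feature vector."""
        return (
            self.left.centroid_x,
            self.left.centroid_y,
            self.right.centroid_x,
            self.right.centroid_y,
        )


def detect_blobs(
    frame: Frame | np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    min_area: int = DEFAULT_MIN_AREA,
) -> list[SpotObservation]:
    """Segment bright blobs and return their intensity-weighted centroids.

    Pixels at or above ``threshold`` are labeled into 8-connected components;
    components smaller than ``min_area`` are discarded.  Centroids are
    computed on the *raw* intensities of member pixels (not the binary mask),
    which is what makes them sensitive to saturation-induced plateau
    asymmetry.  An empty list is a valid return.
    """
    if not 0 < threshold < 255:
        raise ValueError("threshold must lie strictly between 0 and 255")
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    mask = pixels >= threshold
    labels = measure.label(mask, connectivity=2)
    out: list[SpotObservation] = []
    for region in measure.regionprops(labels, intensity_image=pixels):
        if region.area < min_area:
            continue
        vals = region.image_intensity[region.image].astype(float)
        cy, cx = region.centroid_weighted
        out.append(
            SpotObservation(
                centroid_x=float(cx),
                centroid_y=float(cy),
                area=int(region.area),
                mass=float(vals.sum()),
                saturated=bool((vals == 255).any()),
            )
        )
    return out


def pair_spots(
    blobs: list[SpotObservation], cfg: RigConfig
) -> SpotPair | None:
    """Form the left/right spot pair, or report no-detection (``None``).

    Keeps the two blobs of largest mass, orders them by centroid x (ties by
    smaller y as left) and rejects pairs farther apart than twice the expected
    spot separation — a sanity gate against background structures.
    No-detection is a value, not an exception: the robustness protocol counts
    these frames.
    """
    if len(blobs) < 2:
        return None
    a, b = sorted(blobs, key=lambda s: s.mass, reverse=True)[:2]
    first, second = sorted((a, b), key=lambda s: (s.centroid_x, s.centroid_y))
    dist = float(
        np.hypot(
            second.centroid_x - first.centroid_x,
            second.centroid_y - first.centroid_y,
        )
    )
    if dist > 2.0 * cfg.spot_separation:
        return None
    return SpotPair(left=first, right=second)
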