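"""Synthetic model-eye rig: forward imaging model of the contact-lens-pointer
(CLP) test bench.

The physical bench holds an artificial eye wearing a scleral contact lens with
two embedded 850 nm VCSELs.  An eye camera behind an IR bandpass filter sees a
dark frame with only the two laser spots; a motorized two-axis stage rotates
the eye to known azimuth/elevation poses.  This module renders those frames
and generates the pose trajectories of the calibration and test protocols, so
the whole pipeline is testable with analytic ground truth and no hardware.

Coordinate conventions (used everywhere in the package):

* pixel coordinates are 0-based ``(x, y)`` = (column, row), origin at the
  top-left pixel center;
* azimuth is positive rightward, elevation positive upward; because image rows
  grow downward, increasing elevation decreases the row coordinate;
* both spots translate rigidly with the eye pose at ``px_per_degree``
  pixels/degree — a linear small-angle model adequate for the ±10° useful
  range of the highly directional VCSELs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EyePose",
    "RigConfig",
    "Condition",
    "Frame",
    "CalibrationChart",
    "PoseOutOfRangeError",
    "condition_profile",
    "generate_trajectory",
    "render_frame",
    "render_sequence",
    "draw_saturation_flags",
    "static_trajectory",
    "CONDITION_NAMES",
]

#: hard mechanical limit of the simulated rotation stage, degrees
POSE_LIMIT_DEG = 20.0

#: multiplier applied to a spot's peak when the saturation failure mode fires;
#: drives the Gaussian far past the 8-bit clip so a flat-top plateau forms
SATURATION_SCALE = 10.0

CONDITION_NAMES = ("C-In", "C-Dark", "C-Alt", "C-Out")


class PoseOutOfRangeError(ValueError):
    """Raised when a requested pose exceeds the ±20° stage limit."""


@dataclass(frozen=True)
class EyePose:
    """Gaze direction of the model eye.

    Parameters
    ----------
    azimuth, elevation : float
        Degrees; positive azimuth is rightward, positive elevation upward.
    timestamp : float
        Seconds since the start of the recording.
    """

    azimuth: float
    elevation: float
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.azimuth) > POSE_LIMIT_DEG or abs(self.elevation) > POSE_LIMIT_DEG:
            raise PoseOutOfRangeError(
                f"pose ({self.azimuth}, {self.elevation})° outside the "
                f"±{POSE_LIMIT_DEG}° stage range"
            )


@dataclass(frozen=True)
class RigConfig:
    """Geometry and sensor parameters of the synthetic bench.

    Defaults reproduce the study conditions: a 400×400 px eye camera at
    120 Hz, two spots 60 px apart at the primary position, moving rigidly at
    8 px/degree, and a rotation stage stepping 0.5° horizontally and 0.02°
    vertically.
    """

    image_width: int = 400
    image_height: int = 400
    px_per_degree: float = 8.0
    spot_separation: float = 60.0
    spot_sigma: float = 3.0
    spot_peak: float = 230.0
    #: off-axis angle (degrees) at which the VCSEL beam intensity halves;
    #: this directionality is what limits the useful range to about ±10°
    divergence_halfangle: float = 15.0
    stage_step_h: float = 0.5
    stage_step_v: float = 0.02
    frame_rate: float = 120.0
    #: e-folding length (pixels) of the blooming tail a saturated spot spills
    #: down the sensor column; the source of saturation-induced centroid bias
    bloom_length: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.px_per_degree * POSE_LIMIT_DEG >= self.image_width / 2:
            raise ValueError(
                "px_per_degree too large: the chart trajectory would push "
                "spots off the sensor"
            )
        if min(self.image_width, self.image_height) <= 0:
            raise ValueError("image dimensions must be positive")
        if self.spot_sigma <= 0 or self.spot_peak <= 0:
            raise ValueError("spot_sigma and spot_peak must be positive")

    @property
    def center(self) -> tuple[float, float]:
        """Image center (x, y) in pixel coordinates."""
        return ((self.image_width - 1) / 2.0, (self.image_height - 1) / 2.0)

    def quantize(self, pose: EyePose) -> EyePose:
        """Snap a commanded pose to the stage's step grid."""
        qaz = round(pose.azimuth / self.stage_step_h) * self.stage_step_h
        qel = round(pose.elevation / self.stage_step_v) * self.stage_step_v
        return EyePose(qaz, qel, pose.timestamp)

    def spot_centers(self, pose: EyePose) -> list[tuple[float, float]]:
        """Sub-pixel (x, y) centers of the left and right spots for a pose."""
        cx, cy = self.center
        dx = self.px_per_degree * pose.azimuth
        dy = -self.px_per_degree * pose.elevation  # elevation up = row down
        half = self.spot_separation / 2.0
        return [(cx - half + dx, cy + dy), (cx + half + dx, cy + dy)]


@dataclass(frozen=True)
class Condition:
    """One lighting condition of the robustness protocol.

    ``background_mean``/``background_sd`` are the IR leakage reaching the
    sensor *behind the bandpass filter*, in 8-bit intensity units; for C-Alt
    they describe the lights-on phase and the background toggles between the
    on and off levels every ``alternation_period`` seconds (lights start on).
    """

    name: str
    illuminance_lx: float
    background_mean: float
    background_sd: float
    saturation_prob: float = 0.0
    alternation_period: float | None = None
    #: lights-off background for the alternating condition
    background_mean_off: float = 0.0
    duration: float = 5.0
    #: protocol holds the primary position instead of replaying the chart
    static_pose: bool = False

    def background_at(self, t: float) -> tuple[float, float]:
        """Background (mean, sd) at recording time ``t`` seconds."""
        if self.alternation_period is None:
            return self.background_mean, self.background_sd
        lights_on = int(t / self.alternation_period) % 2 == 0
        mean = self.background_mean if lights_on else self.background_mean_off
        return mean, self.background_sd


def _leakage_mean(illuminance_lx: float) -> float:
    """Visible/IR illuminance -> mean sensor background behind the IR filter.

    Indoor visible light barely leaks through the bandpass filter; sunlight
    carries a large IR component the filter passes.  The map is the documented
    piecewise-linear leakage table (intensity units per lux differ indoors and
    out because the spectra differ).
    """
    table = {1.0: 0.0, 250.0: 0.5, 50_000.0: 25.0}
    return table.get(illuminance_lx, min(25.0, illuminance_lx * 0.002))


def _leakage_sd(mean: float) -> float:
    # shot-noise-like scaling with a 1-count read-noise floor
    return max(1.0, math.sqrt(mean))


def condition_profile(name: str) -> Condition:
    """Return the documented profile for one of the four protocol conditions.

    ======  ==============  ==========  =========================
    name    illuminance     background  notes
    ======  ==============  ==========  =========================
    C-In    250 lx          0.5 ± 1.0   indoor neon lighting
    C-Dark  1 lx            0.0 ± 1.0   dark room
    C-Alt   1 / 250 lx      toggling    3 s period, 20 s, static
    C-Out   50 klux         25 ± 5      sunlight; saturation risk
    ======  ==============  ==========  =========================
    """
    if name == "C-In":
        mean = _leakage_mean(250.0)
        return Condition("C-In", 250.0, mean, _leakage_sd(mean))
    if name == "C-Dark":
        mean = _leakage_mean(1.0)
        return Condition("C-Dark", 1.0, mean, _leakage_sd(mean))
    if name == "C-Alt":
        mean_on = _leakage_mean(250.0)
        return Condition(
            "C-Alt",
            250.0,
            mean_on,
            _leakage_sd(mean_on),
            alternation_period=3.0,
            background_mean_off=_leakage_mean(1.0),
            duration=20.0,
            static_pose=True,
        )
    if name == "C-Out":
        mean = _leakage_mean(50_000.0)
        return Condition("C-Out", 50_000.0, mean, _leakage_sd(mean), saturation_prob=0.001)
    raise ValueError(f"unknown condition {name!r}; expected one of {CONDITION_NAMES}")


@dataclass(frozen=True)
class Frame:
    """One 8-bit eye-camera image with ground truth attached."""

    pixels: np.ndarray  # uint8, (image_height, image_width)
    true_pose: EyePose  # stage-quantized pose actually rendered
    condition: str
    frame_index: int = 0
    saturated: bool = False  # the saturation failure mode fired on this frame
    off_sensor: bool = False  # at least one spot center left the sensor

    @property
    def clipped_mask(self) -> np.ndarray:
        """Boolean mask of pixels clipped at the 8-bit ceiling."""
        return self.pixels == 255


@dataclass(frozen=True)
class CalibrationChart:
    """Five fixation targets at the extremities of a square plus its center.

    The default chart is a 20°-side square centered on (0°, 0°); the sequence
    starts at the center and proceeds from the bottom-right corner clockwise
    to the top-right corner.
    """

    side: float = 20.0
    center: tuple[float, float] = (0.0, 0.0)
    targets: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.targets is None:
            h = self.side / 2.0
            cx, cy = self.center
            object.__setattr__(
                self,
                "targets",
                (
                    (cx, cy),  # center first
                    (cx + h, cy - h),  # bottom-right, then clockwise
                    (cx - h, cy - h),
                    (cx - h, cy + h),
                    (cx + h, cy + h),  # top-right last
                ),
            )
        if len(self.targets) != 5:
            raise ValueError("a calibration chart has exactly 5 targets")


def generate_trajectory(
    chart: CalibrationChart, dwell: float, cfg: RigConfig
) -> list[EyePose]:
    """Pose sequence visiting the chart targets in protocol order.

    Each target is held for ``dwell`` seconds (``dwell * frame_rate`` frames,
    at least one); timestamps advance by one frame period throughout.
    """
    if dwell <= 0:
        raise ValueError("dwell must be positive")
    n_hold = max(1, round(dwell * cfg.frame_rate))
    dt = 1.0 / cfg.frame_rate
    poses: list[EyePose] = []
    for az, el in chart.targets:
        for _ in range(n_hold):
            poses.append(EyePose(az, el, timestamp=len(poses) * dt))
    return poses


def draw_saturation_flags(seed: int, n_frames: int, prob: float) -> np.ndarray:
    """Per-frame Bernoulli saturation decisions for a rendering run.

    Drawn from a dedicated child stream (``SeedSequence(seed).spawn(2)[0]``)
    so the flag sequence depends only on the run seed, never on how many
    noise variates each frame consumed.
    """
    sat_ss, _ = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(sat_ss)
    return rng.random(n_frames) < prob


def render_frame(
    pose: EyePose,
    cfg: RigConfig,
    cond: Condition,
    rng: np.random.Generator,
    *,
    saturate: bool | None = None,
    t: float | None = None,
    frame_index: int = 0,
) -> Frame:
    """Render one eye-camera frame: dark background plus two laser spots.

    The commanded ``pose`` is first snapped to the stage step grid; each spot
    is an isotropic Gaussian of width ``spot_sigma`` whose peak is attenuated
    by the beam-divergence law, added to the condition's IR background noise
    and clipped to [0, 255].  With probability ``cond.saturation_prob`` (or
    when ``saturate`` is forced) one spot's amplitude is scaled ×10 before
    clipping, producing a flat-top plateau, and the clipped charge blooms
    down the sensor column as an exponential tail of length ``bloom_length``
    — the mechanism that biases the intensity-weighted centroid on saturated
    frames (the failure mode behind poor-detection frames).

    RNG draw order per frame: saturation Bernoulli (only when ``saturate`` is
    None), saturated-spot choice (only when saturating), then the background
    noise field.
    """
    q = cfg.quantize(pose)
    if t is None:
        t = q.timestamp

    if saturate is None:
        saturate = bool(rng.random() < cond.saturation_prob)
    sat_spot = int(rng.integers(2)) if saturate else -1

    bg_mean, bg_sd = cond.background_at(t)
    h, w = cfg.image_height, cfg.image_width
    if bg_sd > 0:
        img = rng.normal(bg_mean, bg_sd, size=(h, w))
    else:
        img = np.full((h, w), float(bg_mean))

    theta = math.hypot(q.azimuth, q.elevation)
    atten = math.exp(-math.log(2.0) * (theta / cfg.divergence_halfangle) ** 2)

    centers = cfg.spot_centers(q)
    off_sensor = False
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    for i, (sx, sy) in enumerate(centers):
        if not (0 <= sx < w and 0 <= sy < h):
            off_sensor = True
        amp = cfg.spot_peak * atten * (SATURATION_SCALE if i == sat_spot else 1.0)
        # local window: the Gaussian is negligible past a few sigma even when
        # amplified for saturation
        r = int(math.ceil(6 * cfg.spot_sigma))
        x0, x1 = max(0, int(sx) - r), min(w, int(sx) + r + 1)
        y0, y1 = max(0, int(sy) - r), min(h, int(sy) + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        d2 = (xx[:, x0:x1] - sx) ** 2 + (yy[y0:y1, :] - sy) ** 2
        img[y0:y1, x0:x1] += amp * np.exp(-d2 / (2.0 * cfg.spot_sigma**2))
        if i == sat_spot:
            # blooming: overflowing charge spills down the column from the
            # clipped core, clipped-level bright and decaying over bloom_length
            yb0, yb1 = y0, min(h, int(sy) + int(math.ceil(8 * cfg.bloom_length)) + 1)
            dyb = yy[yb0:yb1, :] - sy
            tail = np.where(dyb > 0, np.exp(-dyb / cfg.bloom_length), 0.0)
            xprof = np.exp(
                -((xx[:, x0:x1] - sx) ** 2) / (2.0 * cfg.spot_sigma**2)
            )
            img[yb0:yb1, x0:x1] += 255.0 * tail * xprof

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Frame(
        pixels=pixels,
        true_pose=q,
        condition=cond.name,
        frame_index=frame_index,
        saturated=saturate,
        off_sensor=off_sensor,
    )


def render_sequence(
    poses: list[EyePose], cfg: RigConfig, cond: Condition, seed: int
) -> list[Frame]:
    """Render a full pose sequence deterministically from a single seed.

    Saturation flags are pre-drawn for the whole run with
    :func:`draw_saturation_flags`; the background-noise stream is the second
    child of the same seed sequence, so identical ``(cfg, cond, seed)`` yield
    bit-identical frames.
    """
    flags = draw_saturation_flags(seed, len(poses), cond.saturation_prob)
    _, noise_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(noise_ss)
    return [
        render_frame(
            pose, cfg, cond, rng, saturate=bool(flags[i]), t=pose.timestamp, frame_index=i
        )
        for i, pose in enumerate(poses)
    ]


def static_trajectory(cond: Condition, cfg: RigConfig, pose: EyePose | None = None) -> list[EyePose]:
    """Hold one pose for the condition's duration (the C-Alt protocol)."""
    if pose is None:
        pose = EyePose(0.0, 0.0)
    n = round(cond.duration * cfg.frame_rate)
    dt = 1.0 / cfg.frame_rate
    return [EyePose(pose.azimuth, pose.elevation, timestamp=i * dt) for i in range(n)]
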