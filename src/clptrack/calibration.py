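"""Gaze calibration: the crossed second-order polynomial mapping.

The CLP estimates gaze by mapping the four measured centroid coordinates
``(x_l, y_l, x_r, y_r)`` of the two laser spots to world gaze coordinates
``(X, Y)`` through a second-order polynomial with crossed terms,

    X = a0 + a1 x_l + a2 y_l + a3 x_r + a4 y_r
           + a5 x_l y_r + a6 x_r y_l
           + a7 x_l^2 + a8 y_l^2 + a9 x_r^2 + a10 y_r^2

and identically for ``Y`` with coefficients ``b0..b10``.  The crossed terms
``x_l y_r`` and ``x_r y_l`` account for the geometric dependence between the
two VCSELs.  Coefficients are fitted by penalized least squares on frames
pooled over the five chart fixations.

Fitting note.  Five fixation targets cannot identify eleven coefficients: on
the standard chart (center plus the four corners of a square) the functions
``az²`` and ``el²`` coincide on the sample set, so part of the quadratic
subspace is invisible to the data.  The solver therefore uses a
degree-weighted ridge penalty — second-order features are penalized
``second_order_weight`` times more strongly than linear ones — which resolves
the rank deficiency toward the lowest-order mapping consistent with the data
while leaving genuine curvature fittable when richer calibration data demand
it.  Features are standardized internally (the intercept is unpenalized) and
coefficients are de-standardized back to the raw polynomial form above.

World coordinates are expressed directly in degrees of visual angle rather
than world-camera pixels; the chart geometry is angular and the pixel
conversion would be a fixed linear scale, so folding it in makes accuracy
natively angular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .rig import CalibrationChart, Frame, RigConfig
from .tracker import SpotPair, detect_blobs, pair_spots

__all__ = [
    "N_FEATURES",
    "CalibrationModel",
    "GazeEstimate",
    "SingularFitError",
    "CalibrationDataError",
    "build_features",
    "fit_calibration",
    "calibrate_from_frames",
    "map_gaze",
    "angular_error",
]

#: length of the polynomial feature vector (intercept + 4 linear + 2 crossed
#: + 4 square terms)
N_FEATURES = 11

#: indices of the second-order features within the 11-vector
_SECOND_ORDER = np.arange(5, 11)

#: default ridge weight and the extra penalty factor on second-order terms
DEFAULT_RIDGE_LAMBDA = 1e-6
DEFAULT_SECOND_ORDER_WEIGHT = 1e3


class SingularFitError(np.linalg.LinAlgError):
    """Raised when an unregularized fit meets a rank-deficient design."""


class CalibrationDataError(ValueError):
    """Raised when a fixation target yields no usable spot pairs."""


@dataclass(frozen=True)
class GazeEstimate:
    """Estimated gaze position in world coordinates, degrees."""

    X_world: float
    Y_world: float


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted polynomial coefficients plus fit metadata.

    ``a`` maps the feature vector to the horizontal world coordinate, ``b``
    to the vertical one; both are in the raw (de-standardized) polynomial
    form, so ``a[0]`` is the intercept ``a0`` and so on through ``a10``.
    """

    a: np.ndarray
    b: np.ndarray
    chart: CalibrationChart
    ridge_lambda: float
    rms_residual: float
    n_samples: int
    second_order_weight: float = DEFAULT_SECOND_ORDER_WEIGHT

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != (N_FEATURES,) or b.shape != (N_FEATURES,):
            raise ValueError(f"coefficient vectors must have length {N_FEATURES}")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "ridge_lambda": self.ridge_lambda,
            "second_order_weight": self.second_order_weight,
            "chart": {
                "side": self.chart.side,
                "center": list(self.chart.center),
                "targets": [list(t) for t in self.chart.targets],
            },
            "rms_residual_deg": self.rms_residual,
            "n_samples": self.n_samples,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        chart = CalibrationChart(
            side=d["chart"]["side"],
            center=tuple(d["chart"]["center"]),
            targets=tuple(tuple(t) for t in d["chart"]["targets"]),
        )
        return cls(
            a=np.asarray(d["a"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            chart=chart,
            ridge_lambda=float(d["ridge_lambda"]),
            rms_residual=float(d["rms_residual_deg"]),
            n_samples=int(d["n_samples"]),
            second_order_weight=float(d.get("second_order_weight", DEFAULT_SECOND_ORDER_WEIGHT)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_features(pair: SpotPair | tuple[float, float, float, float]) -> np.ndarray:
    """The 11-term polynomial feature vector, in canonical term order.

    ``[1, x_l, y_l, x_r, y_r, x_l·y_r, x_r·y_l, x_l², y_l², x_r², y_r²]``.
    Note the crossed terms pair each spot's x with the *other* spot's y, so
    the features are not symmetric under a left/right swap.
    """
    xl, yl, xr, yr = pair.coords if isinstance(pair, SpotPair) else pair
    return np.array(
        [1.0, xl, yl, xr, yr, xl * yr, xr * yl, xl**2, yl**2, xr**2, yr**2]
    )


def _solve_one(
    Z: np.ndarray,
    y: np.ndarray,
    ridge_lambda: float,
    penalty: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Penalized LS on standardized, centered features; intercept unpenalized."""
    y0 = float(y.mean())
    rhs = Z.T @ (y - y0)
    if ridge_lambda == 0.0:
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise SingularFitError(
                "calibration design is rank-deficient (5 fixation targets "
                "cannot identify 11 coefficients); set ridge_lambda > 0"
            )
        beta, *_ = np.linalg.lstsq(Z, y - y0, rcond=None)
        return y0, beta
    A = Z.T @ Z + ridge_lambda * np.diag(penalty)
    return y0, np.linalg.solve(A, rhs)


def fit_calibration(
    samples: list[tuple[SpotPair, tuple[float, float]]],
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
    chart: CalibrationChart | None = None,
    second_order_weight: float = DEFAULT_SECOND_ORDER_WEIGHT,
) -> CalibrationModel:
    """Fit the polynomial from pooled (spot pair, world target) samples.

    Solves two independent degree-weighted ridge problems, one per world
    coordinate, on standardized features, and de-standardizes the
    coefficients back to the raw polynomial form.  The stored
    ``rms_residual`` is the root-mean-square angular residual over the
    calibration samples, in degrees.

    Raises
    ------
    ValueError
        If fewer than 11 samples are supplied.
    SingularFitError
        If ``ridge_lambda`` is 0 and the design is rank-deficient (always the
        case for a plain 5-target chart).
    """
    if len(samples) < N_FEATURES:
        raise ValueError(
            f"need at least {N_FEATURES} samples to fit {N_FEATURES} "
            f"coefficients per coordinate, got {len(samples)}"
        )
    F = np.stack([build_features(pair) for pair, _ in samples])
    targets = np.asarray([t for _, t in samples], dtype=float)

    X = F[:, 1:]  # non-intercept features
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd_safe

    penalty = np.ones(N_FEATURES - 1)
    penalty[_SECOND_ORDER - 1] = second_order_weight

    coefs = []
    for j in range(2):
        y0, beta_std = _solve_one(Z, targets[:, j], ridge_lambda, penalty)
        beta_raw = beta_std / sd_safe
        intercept = y0 - float(mu @ beta_raw)
        coefs.append(np.concatenate([[intercept], beta_raw]))

    a, b = coefs
    pred = F @ np.stack([a, b], axis=1)
    rms = float(np.sqrt(np.mean(np.sum((pred - targets) ** 2, axis=1))))

    return CalibrationModel(
        a=a,
        b=b,
        chart=chart if chart is not None else CalibrationChart(),
        ridge_lambda=ridge_lambda,
        rms_residual=rms,
        n_samples=len(samples),
        second_order_weight=second_order_weight,
    )


def calibrate_from_frames(
    frames: list[Frame],
    rig: RigConfig,
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
    chart: CalibrationChart | None = None,
    threshold: float = 100,
    min_area: int = 3,
    second_order_weight: float = DEFAULT_SECOND_ORDER_WEIGHT,
) -> CalibrationModel:
    """Detect spots in recorded calibration frames and fit the mapping.

    Frames are pooled; the world response of each frame is its ground-truth
    pose (what the bench's embedded pointer indicates).  A fixation target on
    which no frame yields a valid spot pair makes the calibration impossible
    and raises :class:`CalibrationDataError` naming the target.
    """
    samples: list[tuple[SpotPair, tuple[float, float]]] = []
    seen: dict[tuple[float, float], int] = {}
    for frame in frames:
        target = (frame.true_pose.azimuth, frame.true_pose.elevation)
        seen.setdefault(target, 0)
        pair = pair_spots(detect_blobs(frame, threshold, min_area), rig)
        if pair is None:
            continue
        seen[target] += 1
        samples.append((pair, target))
    for target, count in seen.items():
        if count == 0:
            raise CalibrationDataError(
                f"no usable spot pair on any frame of target {target}"
            )
    return fit_calibration(
        samples,
        ridge_lambda=ridge_lambda,
        chart=chart,
        second_order_weight=second_order_weight,
    )


def map_gaze(model: CalibrationModel, pair: SpotPair | tuple) -> GazeEstimate:
    """Apply the fitted polynomial to a spot pair."""
    f = build_features(pair)
    return GazeEstimate(X_world=float(model.a @ f), Y_world=float(model.b @ f))


def angular_error(
    estimate: GazeEstimate | tuple[float, float], truth: tuple[float, float]
) -> float:
    """Angular offset between estimate and target, degrees.

    Euclidean distance in the (X, Y) degree plane — the small-angle flat
    approximation, exact enough over the ±10° working range.
    """
    if isinstance(estimate, GazeEstimate):
        ex, ey = estimate.X_world, estimate.Y_world
    else:
        ex, ey = estimate
    return float(np.hypot(ex - truth[0], ey - truth[1]))
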