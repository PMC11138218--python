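"""Configuration, frame/record serialization and run manifests.

Frames are written as 8-bit grayscale PNGs (one per frame, zero-padded index)
with a sidecar CSV carrying ground truth; configuration is a single YAML file
with sections ``rig`` / ``chart`` / ``conditions`` / ``detection`` /
``calibration`` / ``evaluation`` in which every protocol constant is a named,
defaulted key.  Every output directory receives exactly one ``manifest.json``
snapshotting the configuration and seed, so a run can be reproduced from its
outputs alone.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import FrameRecord
from .rig import CalibrationChart, Condition, EyePose, Frame, RigConfig, condition_profile

__all__ = [
    "default_config",
    "load_config",
    "ConfigError",
    "rig_from_config",
    "chart_from_config",
    "condition_from_config",
    "write_frames",
    "read_frames",
    "write_manifest",
    "plot_trajectory_overlay",
]

SIDECAR_NAME = "frames.csv"
SIDECAR_COLUMNS = [
    "frame_index",
    "t",
    "azimuth_deg",
    "elevation_deg",
    "condition",
    "saturated_flag",
]


class ConfigError(ValueError):
    """Raised for unknown or invalid configuration keys."""


def default_config() -> dict:
    """Full default configuration; every key overridable from YAML."""
    return {
        "rig": {
            "image_width": 400,
            "image_height": 400,
            "px_per_degree": 8.0,
            "spot_separation": 60.0,
            "spot_sigma": 3.0,
            "spot_peak": 230.0,
            "divergence_halfangle": 15.0,
            "stage_step_h": 0.5,
            "stage_step_v": 0.02,
            "frame_rate": 120.0,
        },
        "chart": {"side": 20.0, "center": [0.0, 0.0]},
        # per-condition overrides merged onto condition_profile()
        "conditions": {"C-In": {}, "C-Dark": {}, "C-Alt": {}, "C-Out": {}},
        "detection": {"threshold": 100, "min_area": 3},
        "calibration": {
            "ridge_lambda": 1e-6,
            "second_order_weight": 1e3,
            "dwell": 1.0,
        },
        "evaluation": {"accuracy_over": "detected", "dwell": 1.0},
    }


#: per-condition override blocks are validated against Condition fields at
#: resolution time, not against the (empty) defaults
_FREEFORM_SECTIONS = {"conditions"}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            if path in _FREEFORM_SECTIONS:
                out[key] = {**base[key], **val}
            else:
                out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config overlaid on the defaults; unknown keys are errors."""
    cfg = default_config()
    if path is None:
        return cfg
    user = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return _merge(cfg, user)


def rig_from_config(cfg: dict, seed: int = 0) -> RigConfig:
    return RigConfig(seed=seed, **cfg["rig"])


def chart_from_config(cfg: dict) -> CalibrationChart:
    c = cfg["chart"]
    return CalibrationChart(side=float(c["side"]), center=tuple(c["center"]))


def condition_from_config(name: str, cfg: dict) -> Condition:
    cond = condition_profile(name)
    overrides = cfg.get("conditions", {}).get(name, {})
    bad = set(overrides) - {f.name for f in dataclasses.fields(Condition)}
    if bad:
        raise ConfigError(
            f"unknown condition key(s) for {name}: {', '.join(sorted(bad))}"
        )
    return dataclasses.replace(cond, **overrides) if overrides else cond


# -- frame serialization ---------------------------------------------------


def write_frames(frames: list[Frame], outdir: str | Path) -> pd.DataFrame:
    """Write one grayscale PNG per frame plus the ground-truth sidecar CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for frame in frames:
        iio.imwrite(outdir / f"frame_{frame.frame_index:06d}.png", frame.pixels)
        rows.append(
            {
                "frame_index": frame.frame_index,
                "t": frame.true_pose.timestamp,
                "azimuth_deg": frame.true_pose.azimuth,
                "elevation_deg": frame.true_pose.elevation,
                "condition": frame.condition,
                "saturated_flag": int(frame.saturated),
            }
        )
    df = pd.DataFrame(rows, columns=SIDECAR_COLUMNS)
    df.to_csv(outdir / SIDECAR_NAME, index=False)
    return df


def read_frames(indir: str | Path) -> list[Frame]:
    """Load frames written by :func:`write_frames`."""
    indir = Path(indir)
    df = pd.read_csv(indir / SIDECAR_NAME)
    frames = []
    for row in df.itertuples(index=False):
        pixels = np.asarray(iio.imread(indir / f"frame_{row.frame_index:06d}.png"))
        frames.append(
            Frame(
                pixels=pixels,
                true_pose=EyePose(row.azimuth_deg, row.elevation_deg, row.t),
                condition=row.condition,
                frame_index=int(row.frame_index),
                saturated=bool(row.saturated_flag),
            )
        )
    return frames


def write_manifest(
    outdir: str | Path, config: dict, seed: int, outputs: list[str]
) -> Path:
    path = Path(outdir) / "manifest.json"
    manifest = {
        "package": "clptrack",
        "version": __version__,
        "seed": seed,
        "config": config,
        "outputs": sorted(outputs),
        "created_utc": datetime.now(timezone.utc).isoformat(),
    }
    path.write_text(json.dumps(manifest, indent=2))
    return path


def plot_trajectory_overlay(records: list[FrameRecord], path: str | Path) -> None:
    """True chart trajectory vs estimated gaze track, saved as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    truth = np.array([r.true_target for r in records])
    est = np.array(
        [r.estimate if r.estimate else (np.nan, np.nan) for r in records]
    )
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(truth[:, 0], truth[:, 1], "r-", lw=2, label="commanded trajectory")
    ax.plot(est[:, 0], est[:, 1], "b-", lw=0.8, alpha=0.8, label="estimated gaze")
    ax.set_xlabel("azimuth (deg)")
    ax.set_ylabel("elevation (deg)")
    ax.set_aspect("equal")
    ax.legend(loc="upper left", fontsize=8)
    ax.set_title(records[0].condition)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
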