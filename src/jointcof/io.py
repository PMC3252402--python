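"""Delimited-text and config file formats.

Everything is plain comma-separated text with headers, so outputs diff
cleanly and round-trip through Python's shortest-repr float formatting
exactly.  Formats:

* trajectory: ``frame,time_s,<marker>_x_mm,<marker>_y_mm`` x 8 markers,
  one file per pendulum trial;
* angle series: ``time_s,angle_rad,residual_mm``;
* study tables: the tidy CoF and histology tables of
  :class:`jointcof.study.StudyDataset`;
* configs: YAML mirroring the dataclass field names.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pendulum import FrictionParams, MarkerFrames, MarkerLayout, PendulumConfig
from .study import StudyDataset, StudyDesign
from .tracking import AngleSeries

__all__ = [
    "ParseError",
    "write_trajectory",
    "read_trajectory",
    "write_angle_series",
    "read_angle_series",
    "write_study_tables",
    "read_study_tables",
    "load_config",
    "save_config",
    "write_manifest",
]

COF_COLUMNS = [
    "animal_id",
    "genotype",
    "limb",
    "timepoint_id",
    "cumulative_loading_h",
    "wallclock_h",
    "trial_id",
    "cof",
]
HISTOLOGY_COLUMNS = ["animal_id", "genotype", "limb", "plateau", "category", "score"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _check_rectangular(path: Path, expected_fields: int) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n = line.count(",") + 1
            if n != expected_fields:
                raise ParseError(
                    f"{path}: line {lineno} has {n} fields, expected {expected_fields}"
                )


def write_trajectory(path: str | Path, frames: MarkerFrames) -> None:
    path = Path(path)
    cols: dict[str, np.ndarray] = {
        "frame": np.arange(len(frames.times)),
        "time_s": frames.times,
    }
    for m, name in enumerate(frames.marker_names):
        cols[f"{name}_x_mm"] = frames.positions[:, m, 0]
        cols[f"{name}_y_mm"] = frames.positions[:, m, 1]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trajectory(path: str | Path, n_arm: int = 4) -> MarkerFrames:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    fields = header.split(",")
    if fields[:2] != ["frame", "time_s"] or len(fields) < 2 + 2 * 3:
        raise ParseError(f"{path}: line 1: unexpected trajectory header {header!r}")
    names = []
    for fx, fy in zip(fields[2::2], fields[3::2]):
        if not (fx.endswith("_x_mm") and fy.endswith("_y_mm") and fx[:-5] == fy[:-5]):
            raise ParseError(f"{path}: line 1: marker columns must pair as <name>_x_mm,<name>_y_mm")
        names.append(fx[:-5])
    _check_rectangular(path, len(fields))
    df = pd.read_csv(path)
    if df.isna().to_numpy().any() and df[["frame", "time_s"]].isna().to_numpy().any():
        bad = int(df[df[["frame", "time_s"]].isna().any(axis=1)].index[0]) + 2
        raise ParseError(f"{path}: line {bad}: missing frame/time value")
    positions = np.empty((len(df), len(names), 2))
    for m, name in enumerate(names):
        positions[:, m, 0] = df[f"{name}_x_mm"].to_numpy()
        positions[:, m, 1] = df[f"{name}_y_mm"].to_numpy()
    return MarkerFrames(
        times=df["time_s"].to_numpy(),
        positions=positions,
        marker_names=tuple(names),
        n_arm=n_arm,
    )


def write_angle_series(path: str | Path, series: AngleSeries) -> None:
    pd.DataFrame(
        {"time_s": series.times, "angle_rad": series.angles, "residual_mm": series.residual_rms}
    ).to_csv(Path(path), index=False)


def read_angle_series(path: str | Path) -> AngleSeries:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if header.split(",") != ["time_s", "angle_rad", "residual_mm"]:
        raise ParseError(f"{path}: line 1: unexpected angle-series header {header!r}")
    _check_rectangular(path, 3)
    df = pd.read_csv(path)
    return AngleSeries(
        times=df["time_s"].to_numpy(),
        angles=df["angle_rad"].to_numpy(),
        residual_rms=df["residual_mm"].to_numpy(),
    )


def write_study_tables(out_dir: str | Path, dataset: StudyDataset) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cof_path = out_dir / "cof.csv"
    hist_path = out_dir / "histology.csv"
    dataset.cof.to_csv(cof_path, index=False)
    dataset.histology.to_csv(hist_path, index=False)
    return cof_path, hist_path


def read_study_tables(cof_path: str | Path, histology_path: str | Path | None = None) -> StudyDataset:
    cof_path = Path(cof_path)
    with open(cof_path) as fh:
        header = fh.readline().strip().split(",")
    if header != COF_COLUMNS:
        raise ParseError(f"{cof_path}: line 1: expected columns {COF_COLUMNS}")
    _check_rectangular(cof_path, len(COF_COLUMNS))
    cof = pd.read_csv(cof_path)
    histology = pd.DataFrame(columns=HISTOLOGY_COLUMNS)
    if histology_path is not None:
        histology_path = Path(histology_path)
        with open(histology_path) as fh:
            header = fh.readline().strip().split(",")
        if header != HISTOLOGY_COLUMNS:
            raise ParseError(f"{histology_path}: line 1: expected columns {HISTOLOGY_COLUMNS}")
        _check_rectangular(histology_path, len(HISTOLOGY_COLUMNS))
        histology = pd.read_csv(histology_path)
    return StudyDataset(cof=cof, histology=histology)


def _layout_to_dict(layout: MarkerLayout) -> dict:
    return {"arm": layout.arm.tolist(), "base": layout.base.tolist()}


def save_config(
    path: str | Path,
    pendulum: PendulumConfig | None = None,
    friction: FrictionParams | None = None,
    layout: MarkerLayout | None = None,
    extra: dict | None = None,
) -> None:
    doc: dict = {}
    if pendulum is not None:
        doc["pendulum"] = {k: getattr(pendulum, k) for k in (
            "arm_mass", "com_distance", "moment_of_inertia", "joint_load",
            "joint_radius", "gravity", "equilibrium_angle", "start_angle", "sample_rate",
        )}
    if friction is not None:
        doc["friction"] = {"mu": friction.mu, "viscous_coeff": friction.viscous_coeff}
    if layout is not None:
        doc["layout"] = _layout_to_dict(layout)
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML config; typed sections are instantiated, the rest passed through."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out = dict(doc)
    if "pendulum" in doc and doc["pendulum"] is not None:
        out["pendulum"] = PendulumConfig(**doc["pendulum"])
    if "friction" in doc and doc["friction"] is not None:
        out["friction"] = FrictionParams(**doc["friction"])
    if "layout" in doc and doc["layout"] is not None:
        out["layout"] = MarkerLayout(
            arm=np.asarray(doc["layout"]["arm"], dtype=float),
            base=np.asarray(doc["layout"]["base"], dtype=float),
        )
    if "design" in doc and doc["design"] is not None:
        out["design"] = StudyDesign(**doc["design"])
    return out


def write_manifest(out_dir: str | Path, config: dict, seed: int | None) -> Path:
    """Write a reproducibility manifest: config hash, seed, package version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "jointcof_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "config": json.loads(canonical) if canonical else {},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return path
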