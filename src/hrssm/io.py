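"""File formats, configuration and run manifests.

All files are plain CSV (comma-separated, header row, UTF-8, '.' decimal) or
JSON.  Coordinates are planar meters everywhere (UTM easting/northing for
real data); the model is Euclidean and no geographic CRS handling is done.
"""

from __future__ import annotations

import hashlib
import json
import math
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import PosteriorResult
from .observation import CalibrationFit, DetectionCalibration, DetectionMatrix, ReceiverArray
from .ou import DielSchedule, OUParams, Trajectory, eps_from_radius_k

__all__ = [
    "write_trajectory", "read_trajectory",
    "write_receivers", "read_receivers",
    "write_calibration", "read_calibration",
    "write_detections", "read_detections",
    "write_control_tag", "read_control_tag",
    "write_posterior", "write_summary_json",
    "write_latent_paths",
    "load_config", "write_manifest",
]


def _pkg_version() -> str:
    try:
        return version("hrssm")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


# ---------------------------------------------------------------- trajectory

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """CSV columns: minute_index, day_index, x, y (meters, 6 dp)."""
    traj.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        positions=df[["x", "y"]].to_numpy(float),
        day_index=df["day_index"].to_numpy(int),
    )


# ----------------------------------------------------------------- receivers

def write_receivers(array: ReceiverArray, path: str | Path) -> None:
    array.to_frame().to_csv(path, index=False)


def read_receivers(path: str | Path) -> ReceiverArray:
    df = pd.read_csv(path)
    return ReceiverArray(tuple(df["receiver_id"].astype(str)), df[["x", "y"]].to_numpy(float))


# --------------------------------------------------------------- calibration

def write_calibration(calib, path: str | Path) -> None:
    pd.DataFrame(
        {
            "day_index": [c.day_index for c in calib],
            "alpha": [c.alpha for c in calib],
            "beta": [c.beta for c in calib],
        }
    ).to_csv(path, index=False)


def read_calibration(path: str | Path) -> list[DetectionCalibration]:
    df = pd.read_csv(path)
    return [
        DetectionCalibration(int(r.day_index), float(r.alpha), float(r.beta))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------- detections

def write_detections(
    data: DetectionMatrix, array: ReceiverArray, path: str | Path, wide: bool = False
) -> None:
    """Long format (step_index, day_index, receiver_id, count) by default, or
    the wide steps-x-receivers matrix with step metadata columns first."""
    if wide:
        df = pd.DataFrame(data.counts, columns=list(array.receiver_id))
        df.insert(0, "day_index", data.day_index)
        df.insert(0, "step_index", np.arange(data.n_steps))
        df.attrs["step_minutes"] = data.step_minutes
        df.to_csv(path, index=False)
    else:
        data.to_frame_long(array).to_csv(path, index=False)
    meta = {
        "step_minutes": int(data.step_minutes),
        "emissions_per_step": int(data.emissions_per_step),
        "wide": bool(wide),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta))


def read_detections(path: str | Path, array: ReceiverArray) -> DetectionMatrix:
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    df = pd.read_csv(path)
    if meta.get("wide"):
        missing = [r for r in array.receiver_id if r not in df.columns]
        if missing:
            raise ValueError(f"detection file lacks receiver column(s): {missing}")
        counts = df[list(array.receiver_id)].to_numpy(int)
        day_index = df["day_index"].to_numpy(int)
    else:
        ids = set(df["receiver_id"].astype(str))
        missing = ids - set(array.receiver_id)
        if missing:
            raise ValueError(f"detection file names unknown receiver(s): {sorted(missing)}")
        wide = df.pivot_table(index="step_index", columns="receiver_id",
                              values="count", fill_value=0)
        for r in array.receiver_id:
            if r not in wide.columns:
                wide[r] = 0
        counts = wide[list(array.receiver_id)].to_numpy(int)
        day_index = (
            df.drop_duplicates("step_index").sort_values("step_index")["day_index"]
            .to_numpy(int)
        )
    return DetectionMatrix(counts, meta["step_minutes"], day_index,
                           meta["emissions_per_step"])


# --------------------------------------------------------------- control tag

def write_control_tag(control: pd.DataFrame, path: str | Path) -> None:
    cols = ["day_index", "receiver_id", "distance_m", "detections", "emissions"]
    control[cols].to_csv(path, index=False)


def read_control_tag(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ----------------------------------------------------------------- posterior

def write_posterior(result: PosteriorResult, path: str | Path) -> None:
    """Long-format draws CSV: chain, iteration, parameter, value."""
    result.draws_frame().to_csv(path, index=False)


def write_summary_json(result: PosteriorResult, path: str | Path) -> None:
    summ = result.summary()
    payload = {
        "parameters": {
            p: {
                "mean": row["mean"], "median": row["median"],
                "bci2.5": row["bci_2.5"], "bci97.5": row["bci_97.5"],
                "rhat": row["rhat"],
            }
            for p, row in summ.iterrows()
        },
        "converged": result.converged,
        "seed": result.seed,
        "data_hash": result.data_hash,
        "config": {
            "n_chains": result.config.n_chains,
            "n_burnin": result.config.n_burnin,
            "n_samples": result.config.n_samples,
            "thin": result.config.thin,
        },
        "warnings": result.warnings_,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_latent_paths(result: PosteriorResult, path: str | Path,
                       n_draws: int = 100, seed: int = 0) -> None:
    """CSV columns: step_index, draw_id, x, y; draw_id -1 is the posterior mean."""
    from .inference import reconstruct_trajectory

    mean_path, sampled = reconstruct_trajectory(result, n_draws=n_draws, seed=seed)
    n = len(mean_path)
    frames = [pd.DataFrame({"step_index": np.arange(n), "draw_id": -1,
                            "x": mean_path[:, 0], "y": mean_path[:, 1]})]
    for i, p in enumerate(sampled):
        frames.append(pd.DataFrame({"step_index": np.arange(n), "draw_id": i,
                                    "x": p[:, 0], "y": p[:, 1]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


# -------------------------------------------------------------------- config

def load_config(path: str | Path) -> dict:
    """YAML (or JSON, a YAML subset) key/value config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    seeds: dict,
    inputs: dict[str, str | Path] | None = None,
    outputs: list[str] | None = None,
) -> Path:
    """One manifest per CLI run: command, config echo, seeds, input hashes,
    package version, timestamp."""
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "input_hashes": {
            name: sha256_file(p) for name, p in (inputs or {}).items()
        },
        "outputs": outputs or [],
        "package_version": _pkg_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
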