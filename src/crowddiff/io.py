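"""Trajectory/estimate file formats, config files and run manifests.

Trajectories travel as plain CSV with header ``particle_id,t,x,y`` (seconds
and cell diameters, 0-based integer ids), one row per particle per
observation time.  Estimates travel as CSV with header
``particle_id,method,alpha,beta,sigma2_mle,sigma_mode``.  All floats are
written with repr-roundtrip precision, so write -> read is lossless well
below 1e-12.

Configs are YAML with two blocks::

    simulation:
      N: 128
      box_inner: 40
      box_outer: 50
      h: 1
      duration: 14400
      obs_interval: 300
      seed: 7
      sigma: 0.011109
    interaction:
      D_e: 0.00021
      a: 3.5
      r0: 1.0
      phi: exp

Every CLI run also emits a JSON manifest (config echo, seed, package
version, timestamps, SHA-256 digests of inputs and outputs).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .infer import EstimateRecord
from .interaction import InteractionParams
from .simulate import ExperimentConfig, ObservationSet

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_estimates",
    "write_estimates",
    "load_config",
    "config_to_dict",
    "write_manifest",
]

_TRAJ_COLUMNS = ["particle_id", "t", "x", "y"]
_EST_COLUMNS = ["particle_id", "method", "alpha", "beta", "sigma2_mle", "sigma_mode"]


def write_trajectories(obs: ObservationSet, path) -> Path:
    """Write an observation set as a trajectory CSV (sorted by id, then t)."""
    path = Path(path)
    n, kp1 = obs.n_particles, obs.times.size
    frame = pd.DataFrame(
        {
            "particle_id": np.repeat(np.arange(n), kp1),
            "t": np.tile(obs.times, n),
            "x": obs.positions[:, :, 0].ravel(),
            "y": obs.positions[:, :, 1].ravel(),
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trajectories(path) -> ObservationSet:
    """Read and validate a trajectory CSV into an :class:`ObservationSet`.

    Requires every particle to share one sorted, equally spaced time grid;
    malformed input raises with the offending particle/row named.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trajectory file") from None
    if list(frame.columns) != _TRAJ_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(_TRAJ_COLUMNS)}, "
            f"got {','.join(map(str, frame.columns))}"
        )
    if len(frame) == 0:
        raise ValueError(f"{path}: no trajectory rows")
    values = frame[["t", "x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.all(np.isfinite(values), axis=1))[0])
        raise ValueError(f"{path}: non-finite value at data row {bad}")
    dup = frame.duplicated(subset=["particle_id", "t"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"{path}: duplicate (particle_id, t) pair at data row {row}")

    frame = frame.sort_values(["particle_id", "t"], kind="mergesort")
    ids = frame["particle_id"].unique()
    counts = frame.groupby("particle_id", sort=True).size()
    if counts.nunique() != 1:
        bad = counts.index[counts != counts.mode().iloc[0]].tolist()
        raise ValueError(
            f"{path}: ragged time grid — particles {bad} have a different "
            "number of observations"
        )
    kp1 = int(counts.iloc[0])
    times_all = frame["t"].to_numpy(dtype=float).reshape(len(ids), kp1)
    times = times_all[0]
    if np.max(np.abs(times_all - times)) > 1e-9:
        bad = int(np.argmax(np.max(np.abs(times_all - times), axis=1) > 1e-9))
        raise ValueError(
            f"{path}: ragged time grid — particle {ids[bad]} does not share "
            "the common observation times"
        )
    positions = (
        frame[["x", "y"]].to_numpy(dtype=float).reshape(len(ids), kp1, 2)
    )
    return ObservationSet(times=times, positions=positions)


def write_estimates(records: list[EstimateRecord], path) -> Path:
    """Write estimate records as CSV, deterministically sorted by (id, method)."""
    if not records:
        raise ValueError("no estimate records to write")
    path = Path(path)
    rows = sorted(records, key=lambda r: (r.particle_id, r.method))
    frame = pd.DataFrame(
        {
            "particle_id": [r.particle_id for r in rows],
            "method": [r.method for r in rows],
            "alpha": [r.posterior.alpha for r in rows],
            "beta": [r.posterior.beta for r in rows],
            "sigma2_mle": [r.sigma2_mle for r in rows],
            "sigma_mode": [r.sigma_mode for r in rows],
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_estimates(path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    if list(frame.columns) != _EST_COLUMNS:
        raise ValueError(
            f"{path}: expected header {','.join(_EST_COLUMNS)}, "
            f"got {','.join(map(str, frame.columns))}"
        )
    return frame


def config_to_dict(config: ExperimentConfig) -> dict:
    sigma = np.asarray(config.sigma)
    sigma_out = float(sigma[0]) if np.all(sigma == sigma[0]) else sigma.tolist()
    return {
        "simulation": {
            "N": int(config.N),
            "box_inner": float(config.box_inner),
            "box_outer": float(config.box_outer),
            "h": float(config.h),
            "duration": float(config.duration),
            "obs_interval": float(config.obs_interval),
            "seed": int(config.seed),
            "sigma": sigma_out,
            "confined": bool(config.confined),
        },
        "interaction": {
            "D_e": float(config.interaction.D_e),
            "a": float(config.interaction.a),
            "r0": float(config.interaction.r0),
            "phi": config.interaction.phi,
        },
    }


def load_config(path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML config file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "simulation" not in raw:
        raise ValueError(f"{path}: config must contain a 'simulation' block")
    sim = dict(raw["simulation"])
    inter = dict(raw.get("interaction", {}))
    interaction = InteractionParams(
        D_e=float(inter.get("D_e", 0.0)),
        a=float(inter.get("a", 1.0)),
        r0=float(inter.get("r0", 1.0)),
        phi=inter.get("phi", "exp"),
    )
    sigma = sim.get("sigma", 0.01)
    return ExperimentConfig(
        N=int(sim["N"]),
        duration=float(sim["duration"]),
        obs_interval=float(sim["obs_interval"]),
        interaction=interaction,
        sigma=np.asarray(sigma, dtype=float),
        box_inner=float(sim.get("box_inner", 40.0)),
        box_outer=float(sim.get("box_outer", 50.0)),
        h=float(sim.get("h", 1.0)),
        seed=int(sim.get("seed", 0)),
        confined=bool(sim.get("confined", True)),
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(path, *, command: str, config: dict | None, seed, inputs=(), outputs=()) -> Path:
    """Emit the JSON run manifest next to a CLI run's outputs."""
    path = Path(path)
    manifest = {
        "command": command,
        "version": __version__,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
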