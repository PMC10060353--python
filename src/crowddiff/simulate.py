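"""Forward simulation of interacting Brownian cells in a box.

The generator emulates in-vitro migration assays of glioblastoma-like
cells: ``N`` particles seeded uniformly in an inner square (default 40x40
cell diameters, centred), confined to an outer square (default 50x50) by
reflecting hard walls, evolving under the interacting SDE

    dx_i = a_i(x) dt + sigma_i dW_i,

integrated with fine Euler-Maruyama steps of ``h`` seconds (default 1 s —
effectively continuous relative to cell-migration time scales) and observed
every ``obs_interval`` seconds (5-60 minutes in the shipped experiment
presets).

Presets ``exp0`` .. ``exp4`` reproduce the study conditions of the packaged
in-silico experiments: exp0 uses D_e = 0.0004, a = 4, sigma = 1e-2, N = 100;
exp1-exp4 use D_e = 0.00021, a = 3.5, sigma = exp(-9/2) and
N = 64, 128, 256, 512, all over two simulated days by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .interaction import InteractionParams, ParticleState, drift_all

__all__ = [
    "ExperimentConfig",
    "ObservationSet",
    "seed_positions",
    "simulate",
    "experiment_preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full design of one simulation + observation experiment.

    Times are in seconds, lengths in cell diameters.  ``sigma`` may be a
    scalar (shared diffusion parameter) or a length-N vector (per-particle).
    ``confined = False`` removes the walls (free diffusion), used for
    calibration runs.
    """

    N: int
    duration: float
    obs_interval: float
    interaction: InteractionParams
    sigma: float | np.ndarray = 0.01
    box_inner: float = 40.0
    box_outer: float = 50.0
    h: float = 1.0
    seed: int = 0
    confined: bool = True

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0 < self.h <= self.obs_interval:
            raise ValueError("need 0 < h <= obs_interval")
        steps = self.obs_interval / self.h
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("obs_interval must be an integer multiple of h")
        if self.box_inner > self.box_outer:
            raise ValueError("box_inner must not exceed box_outer")
        if self.duration < self.obs_interval:
            raise ValueError("duration must cover at least one observation interval")
        sig = np.broadcast_to(np.asarray(self.sigma, dtype=float), (self.N,)).copy()
        if np.any(sig < 0) or not np.all(np.isfinite(sig)):
            raise ValueError("sigma must be finite and >= 0")
        object.__setattr__(self, "sigma", sig)

    @property
    def steps_per_obs(self) -> int:
        return round(self.obs_interval / self.h)

    @property
    def n_intervals(self) -> int:
        return math.floor(self.duration / self.obs_interval)


@dataclass(frozen=True)
class ObservationSet:
    """N particles observed at K+1 equally spaced times.

    ``positions`` has shape (N, K+1, 2).  ``sigma_true`` carries the
    ground-truth diffusion parameters when the data are synthetic.
    """

    times: np.ndarray
    positions: np.ndarray
    sigma_true: np.ndarray | None = None
    box_outer: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pos = np.asarray(self.positions, dtype=float)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("need at least two observation times (K >= 1)")
        gaps = np.diff(times)
        if np.any(gaps <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.max(np.abs(gaps - gaps[0])) > 1e-9:
            raise ValueError("observation times must be equally spaced")
        if pos.ndim != 3 or pos.shape[1] != times.size or pos.shape[2] != 2:
            raise ValueError(
                f"positions must be (N, {times.size}, 2), got {pos.shape}"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", pos)
        if self.sigma_true is not None:
            sig = np.broadcast_to(
                np.asarray(self.sigma_true, dtype=float), (pos.shape[0],)
            ).copy()
            object.__setattr__(self, "sigma_true", sig)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.times.size - 1

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def snapshot(self, k: int) -> ParticleState:
        """Full population state at observation index ``k``."""
        return ParticleState(self.positions[:, k, :], time=float(self.times[k]))


def seed_positions(config: ExperimentConfig) -> ParticleState:
    """Seed N positions i.i.d. uniform on the centred inner square."""
    rng = np.random.default_rng(_seed_children(config.seed)[0])
    offset = (config.box_outer - config.box_inner) / 2.0
    pos = offset + config.box_inner * rng.random((config.N, 2))
    return ParticleState(pos, time=0.0)


def _seed_children(seed: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(2)


def _reflect(pos: np.ndarray, box: float) -> np.ndarray:
    """Fold coordinates back into [0, box] (reflecting walls)."""
    period = 2.0 * box
    folded = np.mod(pos, period)
    return np.where(folded > box, period - folded, folded)


def simulate(config: ExperimentConfig) -> ObservationSet:
    """Integrate the system and return observations every ``obs_interval``.

    Fine Euler-Maruyama steps ``x <- x + a(x) h + sigma sqrt(h) xi`` with
    per-step wall reflection; the state is recorded at t = 0 and after each
    block of ``obs_interval / h`` steps.  Identical config + seed yields a
    bit-identical result.
    """
    children = _seed_children(config.seed)
    state = seed_positions(config)
    rng = np.random.default_rng(children[1])
    sigma = np.asarray(config.sigma)  # (N,)
    noise_scale = (sigma * np.sqrt(config.h))[:, None]
    h = config.h
    n_obs = config.n_intervals
    spo = config.steps_per_obs

    pos = state.positions.copy()
    out = np.empty((config.N, n_obs + 1, 2))
    out[:, 0, :] = pos
    step = 0
    for k in range(1, n_obs + 1):
        for _ in range(spo):
            a = drift_all(pos, config.interaction)
            pos = pos + a * h + noise_scale * rng.standard_normal((config.N, 2))
            if config.confined:
                pos = _reflect(pos, config.box_outer)
            step += 1
            if not np.all(np.isfinite(pos)):
                raise FloatingPointError(
                    f"non-finite particle state at integration step {step} "
                    f"(t = {step * h:g} s)"
                )
        out[:, k, :] = pos

    times = np.arange(n_obs + 1, dtype=float) * config.obs_interval
    return ObservationSet(
        times=times,
        positions=out,
        sigma_true=sigma.copy(),
        box_outer=config.box_outer if config.confined else None,
    )


_PRESETS = {
    "exp0": dict(D_e=0.0004, a=4.0, sigma=1e-2, N=100),
    "exp1": dict(D_e=0.00021, a=3.5, sigma=math.exp(-4.5), N=64),
    "exp2": dict(D_e=0.00021, a=3.5, sigma=math.exp(-4.5), N=128),
    "exp3": dict(D_e=0.00021, a=3.5, sigma=math.exp(-4.5), N=256),
    "exp4": dict(D_e=0.00021, a=3.5, sigma=math.exp(-4.5), N=512),
}

PRESET_NAMES = tuple(_PRESETS)

#: Two simulated days.
DEFAULT_DURATION = 172_800.0


def experiment_preset(name: str, **overrides) -> ExperimentConfig:
    """Configuration for one of the packaged experiments ``exp0`` .. ``exp4``.

    Keyword overrides (e.g. ``duration``, ``obs_interval``, ``seed``, ``N``)
    replace the corresponding config fields, enabling scaled-down runs.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    p = _PRESETS[name]
    fields_ = dict(
        N=p["N"],
        duration=DEFAULT_DURATION,
        obs_interval=300.0,
        interaction=InteractionParams(D_e=p["D_e"], a=p["a"], r0=1.0, phi="exp"),
        sigma=p["sigma"],
        box_inner=40.0,
        box_outer=50.0,
        h=1.0,
        seed=0,
    )
    inter_over = {
        k: overrides.pop(k) for k in ("D_e", "a", "r0", "phi") if k in overrides
    }
    if inter_over:
        fields_["interaction"] = replace(fields_["interaction"], **inter_over)
    fields_.update(overrides)
    return ExperimentConfig(**fields_)
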