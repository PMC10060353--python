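"""Pairwise attractive-repulsive cell-cell interaction potentials.

Cells are point particles in the plane interacting through a smooth radial
potential

    U(r) = D_e * [1 - (phi(r)/phi(r0))**a]**2 - D_e,

where ``phi`` is a positive, strictly decreasing decay function vanishing at
infinity.  ``phi(r) = exp(-r)`` yields the Morse potential, ``phi(r) = 1/r``
the Lennard-Jones potential.  ``D_e`` is the well depth (the minimum value
``U(r0) = -D_e`` is attained at the equilibrium distance ``r0``) and ``a``
sets the well steepness.  Lengths are measured in average cell diameters, so
``r0 = 1`` in all the in-silico migration experiments shipped with this
package.

The module provides the drift vector of each particle (the negative gradient
of the summed pairwise potential) and its Jacobian (negative summed Hessian),
both analytically — the inference scheme consumes them at every observation
of every particle, so finite differences would be both slow and noisy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InteractionParams",
    "ParticleState",
    "DegenerateGeometryError",
    "potential_value",
    "total_potential",
    "drift",
    "drift_all",
    "jacobian",
    "jacobian_all",
]

_PHI_KINDS = ("exp", "reciprocal")


class DegenerateGeometryError(ValueError):
    """Raised when two particles are closer than the resolvable minimum.

    Gradient and Hessian magnitudes of the pair potential diverge as the
    separation shrinks, so configurations with (near-)coincident particles
    are rejected rather than silently producing huge forces.
    """


@dataclass(frozen=True)
class InteractionParams:
    """Parameters of the pairwise potential.

    Parameters
    ----------
    D_e : float
        Well depth (dimensionless energy in cell-diameter units).  ``D_e = 0``
        switches interactions off entirely.
    a : float
        Well steepness, > 0.
    r0 : float
        Equilibrium pair distance in cell diameters (default 1).
    phi : {"exp", "reciprocal"}
        Decay function: ``exp`` gives the Morse potential, ``reciprocal``
        the Lennard-Jones potential.
    min_distance : float
        Pair separations below this are treated as degenerate geometry.
    cutoff : float or None
        Optional interaction cutoff radius.  ``None`` (default) means exact
        all-pairs sums; the experiments in this package never use a cutoff.
    """

    D_e: float
    a: float
    r0: float = 1.0
    phi: str = "exp"
    min_distance: float = 1e-8
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.D_e) or self.D_e < 0:
            raise ValueError(f"D_e must be finite and >= 0, got {self.D_e}")
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"a must be finite and > 0, got {self.a}")
        if not np.isfinite(self.r0) or self.r0 <= 0:
            raise ValueError(f"r0 must be finite and > 0, got {self.r0}")
        if self.phi not in _PHI_KINDS:
            raise ValueError(f"phi must be one of {_PHI_KINDS}, got {self.phi!r}")
        if self.min_distance <= 0:
            raise ValueError("min_distance must be > 0")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be > 0 or None")


@dataclass(frozen=True)
class ParticleState:
    """Snapshot of all particle positions at one instant.

    ``positions`` is an (N, 2) array in cell diameters; ``time`` in seconds.
    """

    positions: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 1:
            raise ValueError(f"positions must be (N, 2) with N >= 1, got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]


def _ratio_terms(r, p: InteractionParams):
    """g = (phi(r)/phi(r0))**a and its first two radial derivatives."""
    r = np.asarray(r, dtype=float)
    if p.phi == "exp":
        g = np.exp(-p.a * (r - p.r0))
        gp = -p.a * g
        gpp = p.a**2 * g
    else:  # reciprocal
        g = (p.r0 / r) ** p.a
        gp = -p.a * g / r
        gpp = p.a * (p.a + 1.0) * g / r**2
    return g, gp, gpp


def _u_derivatives(r, p: InteractionParams):
    """U'(r) and U''(r) via the chain rule on U = D_e(1-g)^2 - D_e."""
    g, gp, gpp = _ratio_terms(r, p)
    du = -2.0 * p.D_e * (1.0 - g) * gp
    d2u = 2.0 * p.D_e * (gp**2 - (1.0 - g) * gpp)
    return du, d2u


def potential_value(r, params: InteractionParams):
    """Pair potential U(r).

    ``r = 0`` is allowed for the exponential decay (finite value) but is a
    domain error for the reciprocal decay, which diverges at the origin.
    """
    r_arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r_arr)):
        raise ValueError("r must be finite")
    if np.any(r_arr < 0):
        raise ValueError("r must be >= 0")
    if params.phi == "reciprocal" and np.any(r_arr == 0):
        raise ValueError("r = 0 is outside the domain of the reciprocal decay")
    g, _, _ = _ratio_terms(r_arr, params)
    u = params.D_e * (1.0 - g) ** 2 - params.D_e
    return u if np.ndim(r) else float(u)


def total_potential(positions: np.ndarray, params: InteractionParams) -> float:
    """Sum of U over all unordered particle pairs (the system energy V)."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < 2:
        return 0.0
    iu, ju = np.triu_indices(n, k=1)
    r = np.linalg.norm(positions[iu] - positions[ju], axis=1)
    _check_separations(r, params)
    return float(np.sum(potential_value(r, params)))


def _check_separations(r: np.ndarray, params: InteractionParams) -> None:
    if r.size and r.min() < params.min_distance:
        raise DegenerateGeometryError(
            f"pair separation {r.min():.3e} below minimum {params.min_distance:.3e}"
        )


def _pair_geometry(positions: np.ndarray, params: InteractionParams):
    """All-pairs displacement tensor dx[i, j] = x_i - x_j and distances."""
    dx = positions[:, None, :] - positions[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", dx, dx))
    off = ~np.eye(positions.shape[0], dtype=bool)
    _check_separations(r[off], params)
    np.fill_diagonal(r, np.inf)  # diagonal never contributes
    if params.cutoff is not None:
        r = np.where(r > params.cutoff, np.inf, r)
    return dx, r


def drift_all(positions: np.ndarray, params: InteractionParams) -> np.ndarray:
    """Drift a_i = -sum_{j != i} grad_{x_i} U(||x_i - x_j||), for every i.

    Returns an (N, 2) array in cell diameters per second.  Pairwise forces
    are equal and opposite, so the drifts sum to zero over the population.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] == 1 or params.D_e == 0.0:
        return np.zeros_like(positions)
    dx, r = _pair_geometry(positions, params)
    du, _ = _u_derivatives(r, params)
    w = du / r  # finite: du -> 0 faster than 1/r on the inf-masked entries
    return -np.einsum("ij,ijk->ik", w, dx)


def drift(state: ParticleState, i: int, params: InteractionParams) -> np.ndarray:
    """Drift vector of particle ``i`` given the full population snapshot."""
    pos = state.positions
    n = pos.shape[0]
    if not 0 <= i < n:
        raise IndexError(f"particle index {i} out of range for N={n}")
    if n == 1 or params.D_e == 0.0:
        return np.zeros(2)
    dx = pos[i] - np.delete(pos, i, axis=0)
    r = np.linalg.norm(dx, axis=1)
    _check_separations(r, params)
    if params.cutoff is not None:
        keep = r <= params.cutoff
        dx, r = dx[keep], r[keep]
        if r.size == 0:
            return np.zeros(2)
    du, _ = _u_derivatives(r, params)
    return -np.sum((du / r)[:, None] * dx, axis=0)


def _hessian_weights(r, params: InteractionParams):
    """Radial/tangential decomposition of the pair Hessian.

    Hess U(||d||) = c_rad * (u u^T) + c_tan * I with u = d/r,
    c_rad = U'' - U'/r and c_tan = U'/r.
    """
    du, d2u = _u_derivatives(r, params)
    c_tan = du / r
    c_rad = d2u - c_tan
    return c_rad, c_tan


def jacobian_all(positions: np.ndarray, params: InteractionParams) -> np.ndarray:
    """Drift Jacobian A_i = -sum_{j != i} Hess U(x_i - x_j), for every i.

    Returns an (N, 2, 2) array of symmetric matrices (1/s).
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n == 1 or params.D_e == 0.0:
        return np.zeros((n, 2, 2))
    dx, r = _pair_geometry(positions, params)
    u = dx / r[:, :, None]
    c_rad, c_tan = _hessian_weights(r, params)
    iso = c_tan.sum(axis=1)
    # assembled from the three unique components: symmetric by construction
    h11 = np.sum(c_rad * u[:, :, 0] ** 2, axis=1) + iso
    h22 = np.sum(c_rad * u[:, :, 1] ** 2, axis=1) + iso
    h12 = np.sum(c_rad * u[:, :, 0] * u[:, :, 1], axis=1)
    out = np.empty((positions.shape[0], 2, 2))
    out[:, 0, 0] = -h11
    out[:, 1, 1] = -h22
    out[:, 0, 1] = -h12
    out[:, 1, 0] = -h12
    return out


def jacobian(state: ParticleState, i: int, params: InteractionParams) -> np.ndarray:
    """Jacobian of particle ``i``'s drift with respect to its own coordinates.

    Symmetric by construction (it is a sum of Hessians of scalar potentials).
    """
    pos = state.positions
    n = pos.shape[0]
    if not 0 <= i < n:
        raise IndexError(f"particle index {i} out of range for N={n}")
    if n == 1 or params.D_e == 0.0:
        return np.zeros((2, 2))
    dx = pos[i] - np.delete(pos, i, axis=0)
    r = np.linalg.norm(dx, axis=1)
    _check_separations(r, params)
    if params.cutoff is not None:
        keep = r <= params.cutoff
        dx, r = dx[keep], r[keep]
        if r.size == 0:
            return np.zeros((2, 2))
    u = dx / r[:, None]
    c_rad, c_tan = _hessian_weights(r, params)
    iso = c_tan.sum()
    h11 = float(np.sum(c_rad * u[:, 0] ** 2) + iso)
    h22 = float(np.sum(c_rad * u[:, 1] ** 2) + iso)
    h12 = float(np.sum(c_rad * u[:, 0] * u[:, 1]))
    return -np.array([[h11, h12], [h12, h22]])
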