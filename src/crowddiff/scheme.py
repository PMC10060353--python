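"""Gaussian transition densities for one particle over one observation gap.

For an isotropic-diffusion SDE ``dx_i = a_i(x) dt + sigma_i dW_i`` observed
at ``t_k`` and ``t_k + dt``, two Gaussian approximations of
``x_i(t_k + dt) | x(t_k)`` are provided:

* the Euler-Maruyama density ``N(x + a*dt, sigma^2 * dt * I)``, and
* a higher-order density whose covariance carries the drift Jacobian
  ``A = grad_{x_i} a_i`` through the factors

      S1 = sigma * sqrt(dt) * (I + dt/2 * A),
      S2 = sigma * dt^{3/2} / sqrt(12) * A,
      cov = S1^T S1 + S2^T S2.

The higher-order covariance arises from expanding the drift to first order
inside the gap: the update is ``x + a*dt + sigma*Z1 + sigma*A*Z2`` with
``Z1`` the Wiener increment and ``Z2`` its time integral, which are jointly
Gaussian with ``Var(Z1) = dt``, ``Var(Z2) = dt^3/3`` and
``Cov(Z1, Z2) = dt^2/2`` per spatial dimension.

For symmetric ``A`` (always the case when the drift is a potential
gradient) the higher-order covariance is provably positive definite; its
smallest eigenvalue has a closed form in terms of the trace and
determinant, exposed here both for the non-degeneracy guarantee and as a
cross-check of the covariance algebra.

Everything is expressed through the sigma-free normalized covariance
``Sbar = cov / sigma^2`` wherever possible, so that inference code can scan
sigma without rebuilding matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SchemeInputs",
    "TransitionDensity",
    "DegenerateCovarianceError",
    "SYMMETRY_TOL",
    "euler_transition",
    "hom_transition",
    "normalized_hom_cov",
    "closed_form_trace_det",
    "smallest_eigenvalue_closed_form",
    "sample_z1_z2",
]

#: Symmetry slack for drift Jacobians; analytic Hessians are exactly
#: symmetric, so this only absorbs round-off.
SYMMETRY_TOL = 1e-9


class DegenerateCovarianceError(ValueError):
    """The requested transition covariance is not positive definite."""


@dataclass(frozen=True)
class SchemeInputs:
    """Inputs for one particle over one inter-observation interval.

    ``x``: observed position at ``t_k`` (2-vector, cell diameters);
    ``a``: drift at ``t_k`` (cell diameters / s);
    ``A``: drift Jacobian at ``t_k`` (2x2, 1/s);
    ``sigma``: diffusion parameter (cell diameter / sqrt(s));
    ``dt``: interval length t - t_k (s).
    """

    x: np.ndarray
    a: np.ndarray
    A: np.ndarray
    sigma: float
    dt: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float).reshape(2)
        a = np.asarray(self.a, dtype=float).reshape(2)
        A = np.asarray(self.A, dtype=float).reshape(2, 2)
        for name, arr in (("x", x), ("a", a), ("A", A)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "A", A)


@dataclass(frozen=True)
class TransitionDensity:
    """A 2-D Gaussian transition law.

    ``cov = sigma**2 * normalized_cov`` exactly; ``normalized_cov`` is
    independent of sigma.
    """

    mean: np.ndarray
    cov: np.ndarray
    normalized_cov: np.ndarray


def euler_transition(inp: SchemeInputs) -> TransitionDensity:
    """Euler-Maruyama transition: mean ``x + a*dt``, isotropic cov ``sigma^2 dt I``."""
    mean = inp.x + inp.a * inp.dt
    sbar = inp.dt * np.eye(2)
    return TransitionDensity(mean=mean, cov=inp.sigma**2 * sbar, normalized_cov=sbar)


def normalized_hom_cov(A: np.ndarray, dt: float) -> np.ndarray:
    """Sigma-free higher-order covariance Sbar = cov / sigma^2.

    Sbar = dt * B^T B + dt^3/12 * A^T A with B = I + dt/2 * A.
    """
    A = np.asarray(A, dtype=float).reshape(2, 2)
    B = np.eye(2) + 0.5 * dt * A
    return dt * B.T @ B + dt**3 / 12.0 * A.T @ A


def _check_symmetry(A: np.ndarray) -> float:
    return float(np.max(np.abs(A - A.T)))


def hom_transition(inp: SchemeInputs) -> TransitionDensity:
    """Higher-order transition density.

    For symmetric Jacobians the covariance is positive definite by
    construction.  A Jacobian that is asymmetric beyond ``SYMMETRY_TOL``
    falls outside that guarantee: a warning is emitted and the covariance is
    checked numerically, with a :class:`DegenerateCovarianceError` if it is
    not positive definite.
    """
    asym = _check_symmetry(inp.A)
    sbar = normalized_hom_cov(inp.A, inp.dt)
    if asym > SYMMETRY_TOL:
        warnings.warn(
            f"drift Jacobian asymmetric (max|A - A^T| = {asym:.3e}); "
            "positive-definiteness is not guaranteed and is checked numerically",
            RuntimeWarning,
            stacklevel=2,
        )
        if np.linalg.eigvalsh(0.5 * (sbar + sbar.T)).min() <= 0:
            raise DegenerateCovarianceError(
                "higher-order covariance is not positive definite for the "
                "supplied asymmetric Jacobian"
            )
    mean = inp.x + inp.a * inp.dt
    return TransitionDensity(mean=mean, cov=inp.sigma**2 * sbar, normalized_cov=sbar)


def closed_form_trace_det(A: np.ndarray, sigma: float, dt: float) -> tuple[float, float]:
    """Trace and determinant of the higher-order covariance, in closed form.

    Valid for symmetric ``A`` with entries ``a11, a22, a12``:

        Tr = sigma^2 dt / 3 * [3/2 + (3/2 + dt*a11)^2 + (3/2 + dt*a22)^2
                               + 2 (dt*a12)^2]
        det = sigma^4 dt^2 / 9 * [(3/4 + (3/2 + dt*a11)^2 + (dt*a12)^2)
                                  * (3/4 + (3/2 + dt*a22)^2 + (dt*a12)^2)
                                  - ((3 + dt*a11 + dt*a22) * dt*a12)^2]
    """
    A = np.asarray(A, dtype=float).reshape(2, 2)
    if _check_symmetry(A) > SYMMETRY_TOL:
        raise ValueError("closed forms require a symmetric Jacobian")
    a11, a22, a12 = A[0, 0], A[1, 1], A[0, 1]
    p, q, w = dt * a11, dt * a22, dt * a12
    tr = sigma**2 * dt / 3.0 * (1.5 + (1.5 + p) ** 2 + (1.5 + q) ** 2 + 2.0 * w**2)
    det = (
        sigma**4
        * dt**2
        / 9.0
        * (
            (0.75 + (1.5 + p) ** 2 + w**2) * (0.75 + (1.5 + q) ** 2 + w**2)
            - ((3.0 + p + q) * w) ** 2
        )
    )
    return float(tr), float(det)


def smallest_eigenvalue_closed_form(inp: SchemeInputs) -> float:
    """Smallest eigenvalue of the higher-order covariance, in closed form.

    lam_min = (Tr - sqrt(Tr^2 - 4 det)) / 2.  The discriminant is a sum of
    squares for symmetric ``A``, so the eigenvalues are always real, and the
    determinant is strictly positive, so lam_min > 0: the higher-order
    density is a proper distribution for every symmetric Jacobian.
    """
    if _check_symmetry(inp.A) > SYMMETRY_TOL:
        raise ValueError("the non-degeneracy closed form requires a symmetric Jacobian")
    tr, det = closed_form_trace_det(inp.A, inp.sigma, inp.dt)
    disc = tr**2 - 4.0 * det
    return float((tr - np.sqrt(max(disc, 0.0))) / 2.0)


def sample_z1_z2(
    dt: float, n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the Wiener increment Z1 and its time integral Z2 jointly.

    Per spatial dimension, with independent standard normals U1, U2:

        Z1 = sqrt(dt) * U1,
        Z2 = dt^{3/2} / 2 * (U1 + U2 / sqrt(3)),

    which realises Var(Z1) = dt, Var(Z2) = dt^3/3, Cov(Z1, Z2) = dt^2/2.
    The two spatial dimensions are independent.

    Returns ``(Z1, Z2)``, each of shape ``(n, 2)``.
    """
    if not (np.isfinite(dt) and dt > 0):
        raise ValueError(f"dt must be > 0, got {dt}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u1 = rng.standard_normal((n, 2))
    u2 = rng.standard_normal((n, 2))
    z1 = np.sqrt(dt) * u1
    z2 = dt**1.5 / 2.0 * (u1 + u2 / np.sqrt(3.0))
    return z1, z2
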