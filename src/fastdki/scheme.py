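"""Fast-DKI acquisition design: the 1-3-9 scheme and spherical quadrature.

The 1-3-9 protocol acquires 13 volumes: one b = 0 image, the three
coordinate axes at a moderate b-value (default 1000 s/mm^2), and nine
directions at a high b-value (default 2500 s/mm^2).  The nine high-b
directions, together with non-negative quadrature weights, form a degree-4
spherical quadrature: their weighted second and fourth direction moments
equal those of the uniform distribution on the sphere.  That exactness is
what makes the closed-form mean-kurtosis-tensor estimator unbiased on
noise-free data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "DiffusionScheme",
    "SchemeError",
    "QuadratureInfeasibleError",
    "build_139_scheme",
    "quadrature_weights",
]

_MOMENT_TOL = 1e-12


class SchemeError(ValueError):
    """Invalid acquisition design (b-values, directions or weights)."""


class QuadratureInfeasibleError(SchemeError):
    """No non-negative weights make the direction set a degree-4 quadrature."""


def _fourth_moment_indices():
    return list(combinations_with_replacement(range(3), 4))


def _isotropic_fourth_moment(i, j, l, m):
    d = lambda a, b: 1.0 if a == b else 0.0
    return (d(i, j) * d(l, m) + d(i, l) * d(j, m) + d(i, m) * d(j, l)) / 15.0


def _moment_system(directions: np.ndarray):
    """Linear system A w = b encoding sum-to-one and isotropic 2nd/4th moments."""
    n = np.asarray(directions, dtype=float)
    rows = [np.ones(len(n))]
    rhs = [1.0]
    for i in range(3):
        for j in range(i, 3):
            rows.append(n[:, i] * n[:, j])
            rhs.append(1.0 / 3.0 if i == j else 0.0)
    for (i, j, l, m) in _fourth_moment_indices():
        rows.append(n[:, i] * n[:, j] * n[:, l] * n[:, m])
        rhs.append(_isotropic_fourth_moment(i, j, l, m))
    return np.array(rows), np.array(rhs)


def quadrature_weights(directions: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Non-negative weights giving exact degree-4 spherical quadrature.

    Parameters
    ----------
    directions : (K, 3) array of unit vectors, K >= 6, spanning 3-space.
    tol : maximum allowed residual of the moment conditions.

    Returns
    -------
    (K,) array of non-negative weights summing to one whose weighted second
    and fourth direction moments are isotropic.

    Raises
    ------
    QuadratureInfeasibleError
        If the direction set admits no such weights (e.g. coplanar sets).
    """
    dirs = np.asarray(directions, dtype=float)
    if dirs.ndim != 2 or dirs.shape[1] != 3 or dirs.shape[0] < 6:
        raise SchemeError("need at least 6 direction vectors of dimension 3")
    norms = np.linalg.norm(dirs, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-9):
        raise SchemeError("directions must be unit vectors")
    if np.linalg.matrix_rank(dirs, tol=1e-9) < 3:
        raise QuadratureInfeasibleError("directions do not span 3-space")
    a, b = _moment_system(dirs)
    w, residual = nnls(a, b)
    if residual > tol:
        raise QuadratureInfeasibleError(
            f"no non-negative degree-4 quadrature weights exist for this "
            f"direction set (moment residual {residual:.3e} > {tol:.1e})"
        )
    return w


@dataclass(frozen=True)
class DiffusionScheme:
    """The 1-3-9 acquisition design.

    Canonical volume order: one b = 0 image, the three axis directions at
    ``b1``, then the nine second-shell directions at ``b2``.
    """

    b1: float
    b2: float
    axis_directions: np.ndarray
    shell2_directions: np.ndarray
    shell2_weights: np.ndarray
    b0_count: int = 1

    def __post_init__(self):
        object.__setattr__(self, "axis_directions", np.asarray(self.axis_directions, float))
        object.__setattr__(self, "shell2_directions", np.asarray(self.shell2_directions, float))
        object.__setattr__(self, "shell2_weights", np.asarray(self.shell2_weights, float))
        if not (0 < self.b1 < self.b2):
            raise SchemeError(f"require 0 < b1 < b2, got b1={self.b1}, b2={self.b2}")
        if self.axis_directions.shape != (3, 3) or self.shell2_directions.shape[1] != 3:
            raise SchemeError("malformed direction arrays")
        for dirs in (self.axis_directions, self.shell2_directions):
            if np.max(np.abs(np.linalg.norm(dirs, axis=1) - 1.0)) > 1e-12:
                raise SchemeError("directions must have unit norm (tol 1e-12)")
        w, n = self.shell2_weights, self.shell2_directions
        if w.shape != (len(n),) or np.any(w < 0):
            raise SchemeError("weights must be non-negative, one per direction")
        if abs(w.sum() - 1.0) > 1e-12:
            raise SchemeError("weights must sum to 1 (tol 1e-12)")
        m2 = np.einsum("k,ki,kj->ij", w, n, n)
        if np.max(np.abs(m2 - np.eye(3) / 3.0)) > _MOMENT_TOL:
            raise SchemeError("weighted second moment is not I/3")
        m4 = np.einsum("k,ki,kj,kl,km->ijlm", w, n, n, n, n)
        iso4 = np.empty((3, 3, 3, 3))
        for i in range(3):
            for j in range(3):
                for l in range(3):
                    for m in range(3):
                        iso4[i, j, l, m] = _isotropic_fourth_moment(i, j, l, m)
        if np.max(np.abs(m4 - iso4)) > _MOMENT_TOL:
            raise SchemeError("weighted fourth moment is not isotropic")

    @property
    def n_volumes(self) -> int:
        return self.b0_count + len(self.axis_directions) + len(self.shell2_directions)

    @property
    def bvals(self) -> np.ndarray:
        """b-values in canonical volume order (s/mm^2)."""
        return np.concatenate([
            np.zeros(self.b0_count),
            np.full(len(self.axis_directions), self.b1),
            np.full(len(self.shell2_directions), self.b2),
        ])

    @property
    def bvecs(self) -> np.ndarray:
        """(n_volumes, 3) encoding directions in canonical order; zeros for b0."""
        return np.vstack([
            np.zeros((self.b0_count, 3)),
            self.axis_directions,
            self.shell2_directions,
        ])

    @property
    def axis_indices_in_shell2(self) -> np.ndarray:
        """Index of each axis direction within the second shell (sign-blind)."""
        idx = []
        for a in self.axis_directions:
            dots = np.abs(self.shell2_directions @ a)
            k = int(np.argmax(dots))
            if dots[k] < 1.0 - 1e-9:
                raise SchemeError("second shell does not contain the axis directions")
            idx.append(k)
        return np.array(idx)


def build_139_scheme(b1: float = 1000.0, b2: float = 2500.0) -> DiffusionScheme:
    """Default 1-3-9 scheme: axes plus axis-pair bisectors with exact weights.

    The second shell is {x, y, z} plus the six normalized bisectors
    (e_i +- e_j)/sqrt(2); weights 1/15 on each axis and 2/15 on each
    bisector satisfy the degree-4 moment conditions analytically.  This is
    one valid realization of a 9-direction fast-DKI set; alternatives can
    be built with :func:`quadrature_weights`.
    """
    if not (0 < b1 < b2):
        raise SchemeError(f"require 0 < b1 < b2, got b1={b1}, b2={b2}")
    axes = np.eye(3)
    bisectors = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        for s in (1.0, -1.0):
            v = axes[i] + s * axes[j]
            bisectors.append(v / np.sqrt(2.0))
    shell2 = np.vstack([axes, np.array(bisectors)])
    weights = np.concatenate([np.full(3, 1.0 / 15.0), np.full(6, 2.0 / 15.0)])
    return DiffusionScheme(
        b1=float(b1), b2=float(b2),
        axis_directions=axes,
        shell2_directions=shell2,
        shell2_weights=weights,
    )
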