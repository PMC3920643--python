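"""Phylogenetic signal representation (PSR) curves and Blomberg's K.

Phylogenetic eigenvector regression (PVR) regresses a trait on principal
coordinates of the patristic distance matrix.  The PSR curve plots the
:math:`R^2` of sequential PVR fits (axes 1..k) against the cumulative
eigenvalue fraction.  Under Brownian motion the curve is linear along the 45°
diagonal; constrained (OU-like) evolution pushes it below.  The signed area
between curve and diagonal (the *PSR area*) summarizes the deviation and is
positively correlated with Blomberg's K.

The eigenbasis is a principal-coordinate decomposition with Gower centering of
``-1/2 * D`` (patristic distances treated as squared Euclidean distances,
which on an ultrametric tree they are: ``-1/2 J D J = J S J``, the centered
Brownian covariance).  Under this convention a Brownian trait projects
independent variance ``sigma2 * lambda_k`` onto axis ``k``, which is exactly
what makes the Brownian PSR expectation linear; centering ``-1/2 * D**2``
(classical PCoA of the raw distances) is available as an option.  The
centering annihilates the constant vector, so the retained axes are mutually
orthogonal and orthogonal to the intercept; sequential OLS :math:`R^2` values
therefore reduce to cumulative squared correlations, which is how they are
computed here (the normal-equations route gives identical values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTraitError, ValidationError
from .phylo import Phylogeny, shared_path_matrix

__all__ = ["EigenBasis", "PSRResult", "decompose", "psr_curve", "psr_area", "blomberg_k"]

#: eigenvalues below this fraction of the largest are treated as null axes
EIGEN_RTOL = 1e-10


@dataclass
class EigenBasis:
    """Principal-coordinate axes of a phylogenetic distance matrix."""

    eigenvectors: np.ndarray  # (n_tips, m), orthonormal columns
    eigenvalues: np.ndarray  # (m,), positive, descending
    cum_frac: np.ndarray  # (m,), nondecreasing, last = 1

    @property
    def n_axes(self) -> int:
        return int(self.eigenvalues.size)


@dataclass
class PSRResult:
    """PSR curve with its signed area; the origin (0, 0) is implicit."""

    cum_frac: np.ndarray
    r2: np.ndarray
    area: float | None = None
    K: float | None = None

    @property
    def curve(self) -> list[tuple[float, float]]:
        return list(zip(self.cum_frac.tolist(), self.r2.tolist()))


def decompose(distances: np.ndarray, squared: bool = False) -> EigenBasis:
    """Principal-coordinate decomposition of a phylogenetic distance matrix.

    ``squared=False`` (default) applies Gower centering to ``-1/2 * D``: on an
    ultrametric tree this equals the centered Brownian covariance, the
    convention under which the Brownian PSR expectation is the 45-degree
    diagonal.  ``squared=True`` centers ``-1/2 * D**2`` instead (classical
    PCoA of the raw distances).  Axes with eigenvalue at or below ``1e-10`` of
    the leading one — including any negative eigenvalues from non-Euclidean
    inputs — are dropped.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    if D.shape[0] < 4:
        raise ValidationError("need at least 4 taxa for an eigendecomposition")
    A = -0.5 * (D**2 if squared else D)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > EIGEN_RTOL * max(vals[0], 0.0)
    vals, vecs = vals[keep], vecs[:, keep]
    if vals.size == 0:
        raise ValidationError("distance matrix has no positive eigenvalues")
    cum = np.cumsum(vals) / vals.sum()
    return EigenBasis(eigenvectors=vecs, eigenvalues=vals, cum_frac=cum)


def psr_curve(trait, basis: EigenBasis, tips=None) -> PSRResult:
    """Sequential-PVR :math:`R^2` against cumulative eigenvalue fraction.

    ``R^2_k`` is the coefficient of determination of the OLS fit of the trait
    on the first ``k`` axes plus an intercept, for ``k = 1..m``.
    """
    from .trait_models import _as_aligned_values

    if tips is not None:
        x = _as_aligned_values(trait, tips)
    else:
        x = np.asarray(trait, dtype=float)
    if x.size != basis.eigenvectors.shape[0]:
        raise ValidationError("trait length does not match basis rows")
    if not np.all(np.isfinite(x)):
        raise ValidationError("trait contains non-finite values")
    xc = x - x.mean()
    ss_tot = float(xc @ xc)
    if ss_tot == 0.0:
        raise DegenerateTraitError("trait has zero variance")
    # columns are orthonormal and centered, so sequential R^2 accumulates
    proj = basis.eigenvectors.T @ xc
    r2 = np.minimum(np.cumsum(proj**2) / ss_tot, 1.0)
    return PSRResult(cum_frac=basis.cum_frac.copy(), r2=r2)


def psr_area(result: PSRResult) -> float:
    """Signed trapezoidal area between the PSR curve and the 45° diagonal.

    Integrates ``R^2 - cum_frac`` over ``cum_frac`` starting from the implicit
    origin.  Positive above the diagonal (anti-conserved / accelerating),
    negative below (OU-like constraint); bounded by [-1, 1].
    """
    x = np.concatenate([[0.0], result.cum_frac])
    y = np.concatenate([[0.0], result.r2])
    return float(np.trapezoid(y - x, x))


def psr_area_of(trait, basis: EigenBasis, tips=None) -> float:
    """Convenience: curve + area in one call (used by the simulation null)."""
    return psr_area(psr_curve(trait, basis, tips=tips))


def blomberg_k(tree: Phylogeny, trait) -> float:
    """Blomberg's K: observed vs Brownian-expected signal ratio (K=1 under BM).

    ``K = (MSE0/MSE)_obs / (MSE0/MSE)_exp`` where, with V the shared-path
    matrix and ``a`` the GLS (phylogenetic) mean, ``MSE0`` is the mean squared
    deviation of tip values from ``a`` and ``MSE`` the GLS quadratic form
    ``(x-a)' V^-1 (x-a) / (n-1)``; the Brownian expectation of the ratio is
    ``(tr V - n / sum(V^-1)) / (n - 1)``.
    """
    from .trait_models import _as_aligned_values

    x = _as_aligned_values(trait, tree.tips)
    if np.ptp(x) == 0:
        raise DegenerateTraitError("trait has zero variance")
    V = shared_path_matrix(tree)
    n = x.size
    Vi = np.linalg.inv(V)
    ones = np.ones(n)
    a = float(ones @ Vi @ x / (ones @ Vi @ ones))
    r = x - a
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ Vi @ r) / (n - 1)
    expected = (np.trace(V) - n / float(ones @ Vi @ ones)) / (n - 1)
    return (mse0 / mse) / expected
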