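"""Maximum-likelihood fitting of trait-evolution models by phylogenetic GLS.

Three models of continuous-trait evolution are fitted to tip values on a
calibrated phylogeny:

* **WN** (white noise): tip values are i.i.d. normal; species similarity is
  independent of phylogeny.  Parameters: mean ``mu`` and variance ``sigma2``.
* **BM** (Brownian motion): gradual drift; covariance between tips is
  ``sigma2`` times the shared root-to-MRCA path length.  Parameters: root
  state ``mu`` and rate ``sigma2`` (trait units² / Myr).
* **OU** (Ornstein–Uhlenbeck): drift pulled toward an optimum with restraining
  force ``alpha`` (per Myr); the stationary covariance is

  ``V_ij = sigma2 / (2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha s_ij))``

  with ``d`` the patristic distance and ``s`` the shared path.  BM is the
  ``alpha -> 0`` limit and WN the ``alpha -> inf`` limit, so the OU
  log-likelihood dominates both (up to optimizer tolerance).

In every model the mean/optimum is the GLS mean and ``sigma2`` is profiled in
closed form, leaving OU with a single bounded 1-D search over ``log(alpha)``.
Model comparison uses twice the log-likelihood difference against a chi-square
reference (optionally the 50:50 boundary mixture for OU-vs-BM) and Akaike
weights ``exp(-0.5 dAIC)`` normalized over the candidate set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .errors import (
    ConditioningError,
    ConvergenceError,
    DegenerateTraitError,
    ValidationError,
)
from .phylo import Phylogeny, patristic_matrix, shared_path_matrix

__all__ = [
    "ModelFit",
    "ModelComparison",
    "fit_wn",
    "fit_bm",
    "fit_ou",
    "fit_all",
    "compare_models",
]

#: search bounds for the OU restraining force, per Myr.  The bounds are set so
#: both nested limits are numerically reachable: the lower bound leaves the
#: profile within ~1e-6 log-likelihood units of the Brownian limit on
#: century-depth trees, and the upper bound reaches the white-noise limit even
#: when the youngest divergence in the tree is very recent
ALPHA_BOUNDS = (1e-9, 1e4)
#: refuse covariance matrices worse conditioned than this
MAX_CONDITION = 1e12


@dataclass
class ModelFit:
    """A fitted trait-evolution model.

    ``sigma2`` is in trait units² per Myr for BM/OU and plain trait units² for
    WN; ``alpha`` (OU only) is per Myr.  ``k`` counts free parameters
    (WN: mean + variance; BM: root state + rate; OU: optimum + rate + alpha).
    """

    model: str
    mu: float
    sigma2: float
    lnL: float
    k: int
    alpha: float | None = None
    taxa: tuple = field(default=(), repr=False)

    @property
    def AIC(self) -> float:
        return -2.0 * self.lnL + 2.0 * self.k

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "mu": self.mu,
            "sigma2": self.sigma2,
            "lnL": self.lnL,
            "k": self.k,
            "AIC": self.AIC,
        }
        if self.alpha is not None:
            d["alpha"] = self.alpha
        return d


@dataclass
class ModelComparison:
    """Likelihood-ratio tests and Akaike weights over a set of fits."""

    lr2: dict  # (model_a, model_b) -> 2*(lnL_a - lnL_b)
    df: dict
    p_chi2: dict
    waic: dict  # model -> Akaike weight

    def to_dict(self) -> dict:
        return {
            "lr2": {f"{a}-{b}": v for (a, b), v in self.lr2.items()},
            "p_chi2": {f"{a}-{b}": v for (a, b), v in self.p_chi2.items()},
            "waic": dict(self.waic),
        }


def _as_aligned_values(trait, tips: Sequence[str]) -> np.ndarray:
    """Align a trait (mapping / pandas Series / positional array) to tip order."""
    if isinstance(trait, Mapping) or hasattr(trait, "reindex"):
        missing = [t for t in tips if t not in trait]
        if missing:
            raise ValidationError(f"trait missing values for taxa: {missing[:5]}")
        x = np.array([float(trait[t]) for t in tips])
    else:
        x = np.asarray(trait, dtype=float)
        if x.shape != (len(tips),):
            raise ValidationError(
                f"positional trait length {x.shape} does not match {len(tips)} tips"
            )
    if not np.all(np.isfinite(x)):
        raise ValidationError("trait contains non-finite values")
    return x


def _check_variance(x: np.ndarray) -> None:
    if np.ptp(x) == 0.0:
        raise DegenerateTraitError("trait is constant: no model can be fitted")


def fit_wn(trait, tips: Sequence[str] | None = None) -> ModelFit:
    """Fit the white-noise (phylogeny-free i.i.d. normal) model by ML."""
    if tips is None:
        x = np.asarray(trait, dtype=float)
        tips = tuple(range(len(x)))
    else:
        x = _as_aligned_values(trait, tips)
    if x.size < 2:
        raise ValidationError("need at least 2 values")
    _check_variance(x)
    n = x.size
    mu = float(x.mean())
    sigma2 = float(np.mean((x - mu) ** 2))  # ML (divide by n)
    lnL = -0.5 * n * math.log(2.0 * math.pi * sigma2) - 0.5 * n
    return ModelFit("WN", mu, sigma2, lnL, k=2, taxa=tuple(tips))


def _gls_profile(
    C: np.ndarray, x: np.ndarray, check_cond: bool = True
) -> tuple[float, float, float]:
    """GLS mean, profiled ML sigma2, and log-likelihood for V = sigma2 * C.

    ``check_cond=False`` skips the O(n^3) condition-number audit (used during
    line searches; the returned fit is always re-evaluated with the check on).
    """
    n = x.size
    if check_cond:
        cond = np.linalg.cond(C)
        if not np.isfinite(cond) or cond > MAX_CONDITION:
            raise ConditioningError(
                f"covariance condition number {cond:.3g} exceeds {MAX_CONDITION:.0e}; "
                "duplicate zero-distance tips? consider jittering branch lengths"
            )
    try:
        cho = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError as exc:
        raise ConditioningError(f"covariance not positive definite: {exc}") from exc
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cho, ones)
    Cix = linalg.cho_solve(cho, x)
    mu = float(ones @ Cix / (ones @ Ci1))
    r = x - mu
    quad = float(r @ linalg.cho_solve(cho, r))
    sigma2 = quad / n
    if sigma2 <= 0:
        raise DegenerateTraitError("zero GLS residual variance")
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    lnL = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return mu, sigma2, lnL


def fit_bm(tree: Phylogeny, trait) -> ModelFit:
    """Fit Brownian motion by pGLS; ``sigma2`` and the root state in closed form."""
    tips = tree.tips
    x = _as_aligned_values(trait, tips)
    _check_variance(x)
    S = shared_path_matrix(tree)
    mu, sigma2, lnL = _gls_profile(S, x)
    return ModelFit("BM", mu, sigma2, lnL, k=2, taxa=tuple(tips))


def _ou_correlation(alpha: float, D: np.ndarray, S: np.ndarray) -> np.ndarray:
    """OU covariance at unit sigma2: exp(-a d)(1 - exp(-2 a s)) / (2 a)."""
    return np.exp(-alpha * D) * (-np.expm1(-2.0 * alpha * S)) / (2.0 * alpha)


def fit_ou(
    tree: Phylogeny,
    trait,
    alpha_bounds: tuple[float, float] = ALPHA_BOUNDS,
    alpha: float | None = None,
) -> ModelFit:
    """Fit a single-optimum stationary OU model by pGLS.

    ``alpha`` is maximized on a log scale over ``alpha_bounds`` (profile
    likelihood; ``mu`` and ``sigma2`` concentrated out in closed form).  Pass
    ``alpha`` explicitly to evaluate the profile at a fixed value — ``alpha=0``
    reproduces the BM fit exactly.
    """
    tips = tree.tips
    x = _as_aligned_values(trait, tips)
    _check_variance(x)
    D = patristic_matrix(tree)
    S = shared_path_matrix(tree)

    if alpha is not None:
        if alpha == 0.0:
            f = fit_bm(tree, trait)
            return ModelFit("OU", f.mu, f.sigma2, f.lnL, k=3, alpha=0.0, taxa=tuple(tips))
        mu, sigma2, lnL = _gls_profile(_ou_correlation(alpha, D, S), x)
        return ModelFit("OU", mu, sigma2, lnL, k=3, alpha=float(alpha), taxa=tuple(tips))

    lo, hi = alpha_bounds

    def neg_profile(log_a: float) -> float:
        try:
            return -_gls_profile(
                _ou_correlation(math.exp(log_a), D, S), x, check_cond=False
            )[2]
        except ConditioningError:
            return np.inf

    # the profile in log(alpha) can be multimodal (interior optimum vs a
    # boundary plateau), so bracket with a coarse grid before local refinement
    grid = np.linspace(math.log(lo), math.log(hi), 30)
    vals = np.array([neg_profile(g) for g in grid])
    k = int(np.argmin(vals))
    blo = grid[max(k - 1, 0)]
    bhi = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        neg_profile,
        bounds=(blo, bhi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    a_hat = math.exp(res.x if res.fun <= vals[k] else grid[k])
    try:
        mu, sigma2, lnL = _gls_profile(_ou_correlation(a_hat, D, S), x)
    except ConditioningError as exc:
        raise ConvergenceError(f"OU profile ill-conditioned at alpha={a_hat:.3g}") from exc
    fit = ModelFit("OU", mu, sigma2, lnL, k=3, alpha=a_hat, taxa=tuple(tips))
    if not res.success:
        raise ConvergenceError("OU alpha search did not converge", best_fit=fit)
    return fit


def fit_all(tree: Phylogeny, trait) -> dict[str, ModelFit]:
    """Fit WN, BM and OU to the same trait on the same tree."""
    return {
        "WN": fit_wn(trait, tree.tips),
        "BM": fit_bm(tree, trait),
        "OU": fit_ou(tree, trait),
    }


def compare_models(
    fits: Mapping[str, ModelFit] | Sequence[ModelFit],
    boundary_mixture: bool = False,
) -> ModelComparison:
    """Likelihood-ratio tests and Akaike weights for a set of fits.

    Every pair (a, b) with ``k_a > k_b`` gets ``lr2 = 2 (lnL_a - lnL_b)`` and a
    chi-square p-value on ``df = k_a - k_b``.  With ``boundary_mixture=True``
    the OU-vs-BM test uses the 50:50 mixture of chi2(0) and chi2(1) appropriate
    for ``alpha`` on its boundary; the plain chi-square is the default.
    """
    if not isinstance(fits, Mapping):
        names = [f.model for f in fits]
        if len(names) != len(set(names)):
            raise ValidationError(f"duplicate model names in comparison: {names}")
        fits = {f.model: f for f in fits}
    taxa_sets = {f.taxa for f in fits.values()}
    if len(taxa_sets) > 1:
        raise ValidationError("fits were computed on different taxon sets")

    models = list(fits)
    lr2, df, p = {}, {}, {}
    for a in models:
        for b in models:
            fa, fb = fits[a], fits[b]
            if fa.k <= fb.k:
                continue
            key = (a, b)
            lr2[key] = 2.0 * (fa.lnL - fb.lnL)
            df[key] = fa.k - fb.k
            stat = max(lr2[key], 0.0)
            tail = stats.chi2.sf(stat, df[key])
            if boundary_mixture and df[key] == 1:
                tail = 0.5 * tail + (0.0 if stat > 0 else 0.5)
            p[key] = float(tail)

    aics = np.array([fits[m].AIC for m in models])
    rel = np.exp(-0.5 * (aics - aics.min()))
    waic = dict(zip(models, rel / rel.sum()))
    return ModelComparison(lr2=lr2, df=df, p_chi2=p, waic=waic)
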