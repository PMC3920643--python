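"""Moran's I spatial autocorrelation and distance-class correlograms.

A correlogram reports Moran's I per geographic distance class; comparing the
correlogram of raw plot values (e.g. mean family age) with that of model
residuals quantifies how much spatial structure the model explains at each
scale.  Distances are great-circle (haversine, spherical Earth of radius
6371 km); classes are equal-frequency so every class carries a comparable
number of pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CommPhyloError, ValidationError

__all__ = ["Correlogram", "morans_i", "haversine_matrix", "correlogram"]

EARTH_RADIUS_KM = 6371.0


@dataclass
class Correlogram:
    """Moran's I per contiguous distance class (km)."""

    class_edges: np.ndarray  # length n_classes + 1
    I: np.ndarray
    n_pairs: np.ndarray
    subsample_seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lower_km": self.class_edges[:-1],
                "upper_km": self.class_edges[1:],
                "morans_i": self.I,
                "n_pairs": self.n_pairs,
            }
        )


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I with a binary (or general) symmetric weight matrix.

    ``I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2``
    with ``W`` the total weight; the diagonal must be zero.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = x.size
    if n < 2:
        raise ValidationError("need at least 2 observations")
    if w.shape != (n, n):
        raise ValidationError("weight matrix shape does not match values")
    if not np.allclose(w, w.T):
        raise ValidationError("weight matrix must be symmetric")
    if np.any(np.diag(w) != 0):
        raise ValidationError("weight matrix diagonal must be zero")
    W = w.sum()
    if W == 0:
        raise CommPhyloError("zero total weight: Moran's I undefined for this class")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise CommPhyloError("zero variance: Moran's I undefined")
    return float((n / W) * (z @ w @ z) / denom)


def haversine_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) between decimal-degree points."""
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def correlogram(
    values,
    coords,
    n_classes: int = 12,
    subsample_n: int | None = None,
    seed: int | None = None,
) -> Correlogram:
    """Equal-frequency distance-class correlogram of a plot-level variable.

    ``coords`` is an (n, 2) array or DataFrame of lon/lat in decimal degrees.
    When ``subsample_n`` is below n, a random subsample without replacement is
    drawn under ``seed`` (the large-n escape hatch the full pairwise matrix
    requires).  Classes that would be empty are merged with their neighbor.
    """
    x = np.asarray(values, dtype=float)
    if hasattr(coords, "to_numpy"):
        coords = coords[["lon", "lat"]].to_numpy() if hasattr(coords, "columns") else coords.to_numpy()
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (x.size, 2):
        raise ValidationError("coords must be (n, 2) lon/lat")
    n = x.size
    if subsample_n is not None and subsample_n < n:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=subsample_n, replace=False)
        x, coords = x[idx], coords[idx]
        n = subsample_n

    D = haversine_matrix(coords[:, 0], coords[:, 1])
    iu = np.triu_indices(n, k=1)
    dists = D[iu]
    qs = np.linspace(0.0, 1.0, n_classes + 1)
    edges = np.quantile(dists, qs)
    edges[0], edges[-1] = 0.0, dists.max() + 1e-9
    edges = np.unique(edges)
    if edges.size - 1 < n_classes:
        warnings.warn("empty distance classes merged with neighbors")

    Is, pairs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        w = ((D > lo) & (D <= hi)).astype(float)
        np.fill_diagonal(w, 0.0)
        np_pairs = int(w.sum() / 2)
        Is.append(morans_i(x, w))
        pairs.append(np_pairs)
    return Correlogram(
        class_edges=edges,
        I=np.array(Is),
        n_pairs=np.array(pairs),
        subsample_seed=seed,
    )
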