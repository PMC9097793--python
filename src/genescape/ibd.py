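"""Isolation by distance: Mantel correlation of geographic vs genetic distance.

Under IBD, genetic differentiation between population pairs grows with the
geographic distance separating them.  The Mantel statistic is the Pearson
correlation of the two distance matrices' upper triangles; significance
comes from jointly permuting the rows and columns of the genetic matrix
(one-tailed, positive association), or from exhaustive enumeration of all
label permutations for small n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _perms

import numpy as np

from .geo import pairwise_haversine_km

__all__ = ["DistanceMatrix", "geodesic_distance_matrix", "euclidean_degree_distance_matrix", "mantel_test"]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        self.values = 0.5 * (v + v.T)
        np.fill_diagonal(self.values, 0.0)


def geodesic_distance_matrix(coords, labels=None) -> DistanceMatrix:
    """Great-circle distance matrix (km) from (lon, lat) pairs."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    if len(coords) < 2:
        raise ValueError("need >= 2 coordinates")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(coords))]
    return DistanceMatrix(labels, pairwise_haversine_km(coords[:, 0], coords[:, 1]))


def euclidean_degree_distance_matrix(coords, labels=None) -> DistanceMatrix:
    """Planar Euclidean distance in decimal degrees (alternative geodistance)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    if len(coords) < 2:
        raise ValueError("need >= 2 coordinates")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(coords))]
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(labels, d)


def _triangle(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(
    d_geo: DistanceMatrix,
    d_gen: DistanceMatrix,
    n_perm: int | str = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel r and one-tailed (greater) permutation p-value.

    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)`` with the genetic matrix's
    labels permuted jointly over rows and columns.  ``n_perm='exact'``
    enumerates all n! permutations (only sensible for n <= 7), in which case
    p is the exact fraction of permutations with r_perm >= r_obs.
    """
    if d_geo.labels != d_gen.labels:
        raise ValueError("distance matrices must share labels and order")
    n = len(d_geo.labels)
    if n < 4:
        raise ValueError("Mantel test needs n >= 4")
    x = _triangle(d_geo.values)

    def corr_with_perm(perm: np.ndarray) -> float:
        y = _triangle(d_gen.values[np.ix_(perm, perm)])
        return float(np.dot(xs, (y - y.mean()) / y.std()) / len(xs))

    if x.std() == 0 or _triangle(d_gen.values).std() == 0:
        raise ValueError("zero variance in a distance triangle: Mantel r undefined")
    xs = (x - x.mean()) / x.std()

    identity = np.arange(n)
    r_obs = corr_with_perm(identity)

    if n_perm == "exact":
        rs = np.array([corr_with_perm(np.array(p)) for p in _perms(range(n))])
        p_value = float(np.mean(rs >= r_obs - 1e-12))
        return r_obs, p_value

    n_perm = int(n_perm)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with_perm(perm) >= r_obs - 1e-12:
            count += 1
    p_value = (1 + count) / (n_perm + 1)
    return r_obs, float(p_value)
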