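"""NMDS ordination and distance-matrix concordance.

Non-metric multidimensional scaling (NMDS) embeds a dissimilarity matrix
into a low-dimensional space preserving rank order, with goodness of fit
measured by Kruskal stress-1; the best of several random restarts is
reported.  Concordance between two distance structures (e.g. taxonomic
theta-YC vs functional theta-YC over the same samples) is measured with a
Mantel test — the correlation of the vectorized off-diagonal entries, with
significance from joint row/column permutations — or alternatively by
Procrustes correlation of the two NMDS embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.spatial
import scipy.stats
from sklearn.manifold import MDS

from .diversity import DistanceMatrix
from .tables import SeedLike, as_rng

__all__ = [
    "OrdinationResult",
    "ConcordanceResult",
    "nmds",
    "nmds_scan",
    "mantel",
    "procrustes_concordance",
]


@dataclass
class OrdinationResult:
    """An NMDS embedding: coordinates, Kruskal stress-1 and provenance."""

    ids: tuple[str, ...]
    coordinates: np.ndarray
    stress: float
    dim: int
    restarts: int
    seed: int | None
    converged: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.stress < 0:
            raise ValueError("stress must be non-negative")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("non-finite coordinates")

    def embedded_distances(self) -> np.ndarray:
        """Condensed pairwise Euclidean distances of the embedding."""
        return scipy.spatial.distance.pdist(self.coordinates)


@dataclass
class ConcordanceResult:
    """Mantel-style concordance between two distance matrices."""

    r: float
    p: float
    n_permutations: int
    method: str

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.r <= 1.0 + 1e-9):
            raise ValueError("correlation outside [-1, 1]")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("permutation p must lie in (0, 1]")


def nmds(
    dist: DistanceMatrix,
    dim: int = 2,
    restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
    init: np.ndarray | None = None,
) -> OrdinationResult:
    """Non-metric MDS of a distance matrix, best of ``restarts`` random starts.

    Minimizes Kruskal stress-1 by iterative majorization with monotone
    regression of the disparities.  When ``init`` coordinates are supplied
    they seed one extra optimization and the better solution wins (used by
    :func:`nmds_scan` to keep stress monotone across dimensions).  A matrix
    whose off-diagonal entries are all equal carries no rank information;
    the result is flagged ``degenerate``.
    """
    n = len(dist.ids)
    if n < dim + 1:
        raise ValueError(f"need at least dim+1={dim + 1} points, got {n}")
    off = dist.condensed()
    degenerate = bool(off.size) and bool(np.allclose(off, off[0]))
    if degenerate:
        warnings.warn("all pairwise distances equal; NMDS solution is degenerate")
    def _fit(n_init: int, init_coords: np.ndarray | None):
        model = MDS(
            n_components=dim,
            metric_mds=False,
            n_init=n_init,
            init="random",
            max_iter=max_iter,
            eps=tol,
            metric="precomputed",
            random_state=seed,
            normalized_stress=True,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = model.fit_transform(dist.values, init=init_coords)
        return coords, float(model.stress_), int(model.n_iter_)

    coords, stress, n_iter = _fit(restarts, None)
    if init is not None:
        if init.shape != (n, dim):
            raise ValueError(f"init shape {init.shape} != ({n}, {dim})")
        coords2, stress2, n_iter2 = _fit(1, init)
        if stress2 < stress:
            coords, stress, n_iter = coords2, stress2, n_iter2
    return OrdinationResult(
        ids=dist.ids,
        coordinates=coords,
        stress=stress,
        dim=dim,
        restarts=restarts,
        seed=seed,
        converged=n_iter < max_iter,
        degenerate=degenerate,
    )


def nmds_scan(
    dist: DistanceMatrix,
    dims: list[int] | tuple[int, ...] = (1, 2, 3),
    restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> dict[int, OrdinationResult]:
    """NMDS over increasing dimensions, chaining initializations.

    Each dimension also starts from the best lower-dimensional solution
    padded with a zero coordinate — embedding distances are unchanged by
    the padding, so the reported stress is non-increasing in dimension.
    """
    dims = sorted(dims)
    results: dict[int, OrdinationResult] = {}
    previous: OrdinationResult | None = None
    for dim in dims:
        init = None
        if previous is not None and previous.dim < dim:
            pad = np.zeros((previous.coordinates.shape[0], dim - previous.dim))
            init = np.hstack([previous.coordinates, pad])
        result = nmds(dist, dim=dim, restarts=restarts, max_iter=max_iter,
                      tol=tol, seed=seed, init=init)
        if previous is not None and result.stress > previous.stress:
            # optimizer noise: fall back to the padded lower-dim solution,
            # whose stress equals the lower-dim stress by construction
            padded = np.hstack(
                [previous.coordinates,
                 np.zeros((previous.coordinates.shape[0], dim - previous.dim))]
            )
            result = OrdinationResult(
                ids=previous.ids, coordinates=padded, stress=previous.stress,
                dim=dim, restarts=restarts, seed=seed,
                converged=previous.converged, degenerate=previous.degenerate,
            )
        results[dim] = result
        previous = result
    return results


def _condensed_in_order(dist: DistanceMatrix, ids: tuple[str, ...]) -> np.ndarray:
    idx = [dist.ids.index(i) for i in ids]
    sub = dist.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(ids), k=1)
    return sub[iu]


def mantel(
    dist_a: DistanceMatrix,
    dist_b: DistanceMatrix,
    n_permutations: int = 999,
    method: str = "pearson",
    seed: SeedLike = None,
) -> ConcordanceResult:
    """Mantel test of concordance between two distance matrices.

    r is the Pearson (or Spearman) correlation of the vectorized
    off-diagonal entries; the one-sided upper p-value is
    ``(1 + #{r_perm >= r_obs}) / (1 + n_permutations)`` with rows and
    columns of the second matrix permuted jointly.
    """
    if set(dist_a.ids) != set(dist_b.ids):
        raise ValueError("distance matrices must share the same ids")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    ids = dist_a.ids
    va = _condensed_in_order(dist_a, ids)
    idx_b = [dist_b.ids.index(i) for i in ids]
    b_vals = dist_b.values[np.ix_(idx_b, idx_b)]
    n = len(ids)
    iu = np.triu_indices(n, k=1)

    def corr(vb: np.ndarray) -> float:
        xa, xb = va, vb
        if method == "spearman":
            xa = scipy.stats.rankdata(xa)
            xb = scipy.stats.rankdata(xb)
        xa = xa - xa.mean()
        xb = xb - xb.mean()
        denom = np.sqrt((xa @ xa) * (xb @ xb))
        if denom == 0:
            raise ValueError("constant distance matrix; Mantel r undefined")
        return float((xa @ xb) / denom)

    r_obs = corr(b_vals[iu])
    rng = as_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        permuted = b_vals[np.ix_(perm, perm)]
        if corr(permuted[iu]) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return ConcordanceResult(r=r_obs, p=float(p), n_permutations=n_permutations, method=f"mantel_{method}")


def procrustes_concordance(ord_a: OrdinationResult, ord_b: OrdinationResult) -> ConcordanceResult:
    """Procrustes correlation of two ordinations over the same samples.

    After optimal translation/scaling/rotation the residual disparity m2 is
    converted to a correlation-like statistic r = sqrt(1 - m2).  No
    permutation test is attached (p reported as 1).
    """
    if set(ord_a.ids) != set(ord_b.ids):
        raise ValueError("ordinations must share the same ids")
    order = [ord_b.ids.index(i) for i in ord_a.ids]
    _, _, m2 = scipy.spatial.procrustes(ord_a.coordinates, ord_b.coordinates[order])
    return ConcordanceResult(
        r=float(np.sqrt(max(0.0, 1.0 - m2))), p=1.0, n_permutations=0, method="procrustes"
    )
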