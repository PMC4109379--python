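"""Alpha diversity (inverse Simpson) and the Yue-Clayton theta-YC dissimilarity.

The Yue-Clayton theta measures the similarity of two communities from their
proportional abundances, weighting both shared and unshared taxa:

    theta(a, b) = sum(a_i * b_i) / (sum((a_i - b_i)^2) + sum(a_i * b_i))

We work throughout with the *dissimilarity* ``1 - theta``, which is 0 for
identical compositions and 1 for communities with disjoint support.  To
remove uneven-sampling artifacts, pairwise dissimilarities and per-sample
diversities are computed on rarefied subsamples and averaged over many
independent draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import CountTable, SeedLike, as_rng, rarefy

__all__ = [
    "DistanceMatrix",
    "DiversityReport",
    "inverse_simpson",
    "thetayc_dissimilarity",
    "thetayc_matrix",
    "distance_matrix",
    "rarefied_inverse_simpson",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity with id labels and provenance tag."""

    ids: tuple[str, ...]
    values: np.ndarray
    metric_tag: str = ""

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n},{n})")
        if n and not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if n and not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal not zero")
        if n and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("values outside [0, 1]")
        # enforce exact symmetry / clipping so downstream equality checks hold
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(tuple(ids), self.values[np.ix_(idx, idx)], self.metric_tag)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.values, ids=self.ids)

    def write_phylip(self, path, lower: bool = False) -> None:
        """Serialize as phylip square (default) or lower-triangle format."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sample in enumerate(self.ids):
                row = self.values[i, :i] if lower else self.values[i]
                cells = "\t".join(format(v, ".6f") for v in row)
                fh.write(f"{sample}\t{cells}\n" if cells else f"{sample}\n")


@dataclass
class DiversityReport:
    """Per-sample inverse Simpson diversity, averaged over subsample draws."""

    per_sample: pd.Series
    iters: int
    depth: int
    estimator: str

    def __post_init__(self) -> None:
        if (self.per_sample < 1 - 1e-9).any():
            raise ValueError("inverse Simpson values must be >= 1")


def inverse_simpson(counts, estimator: str = "unbiased") -> float:
    """Inverse Simpson diversity of one sample.

    ``unbiased`` (the mothur convention) uses D = N(N-1) / sum(n_i (n_i - 1));
    when every taxon is a singleton the denominator vanishes and D is defined
    as the number of observed taxa (with a warning).  ``ml`` is the plug-in
    1 / sum(p_i^2).
    """
    n = np.asarray(counts, dtype=float)
    if n.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (n < 0).any():
        raise ValueError("counts must be non-negative")
    total = n.sum()
    if total <= 0:
        raise ValueError("all-zero count vector has no diversity")
    if estimator == "ml":
        p = n / total
        return float(1.0 / np.sum(p * p))
    if estimator == "unbiased":
        denom = np.sum(n * (n - 1.0))
        if denom == 0:
            observed = int((n > 0).sum())
            warnings.warn(
                "all observed taxa are singletons; reporting observed richness "
                f"({observed}) as the inverse Simpson estimate"
            )
            return float(observed)
        return float(total * (total - 1.0) / denom)
    raise ValueError(f"unknown estimator {estimator!r}")


def thetayc_dissimilarity(a, b) -> float:
    """Yue-Clayton dissimilarity (1 - theta) between two composition vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"mismatched composition axes: {a.shape} vs {b.shape}")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("theta-YC is undefined for an all-zero community")
    cross = float(np.dot(a, b))
    sq = float(np.dot(a - b, a - b))
    if cross == 0.0:
        return 1.0
    return 1.0 - cross / (sq + cross)


def thetayc_matrix(rel: np.ndarray) -> np.ndarray:
    """Pairwise theta-YC dissimilarity for rows of a relative-abundance matrix."""
    rel = np.asarray(rel, dtype=float)
    cross = rel @ rel.T
    sq = np.einsum("ij,ij->i", rel, rel)
    d2 = sq[:, None] + sq[None, :] - 2.0 * cross
    denom = d2 + cross
    with np.errstate(invalid="ignore", divide="ignore"):
        dis = 1.0 - np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), 0.0)
    dis = np.clip((dis + dis.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(dis, 0.0)
    return dis


def distance_matrix(
    table: CountTable,
    depth: int,
    iters: int = 100,
    seed: SeedLike = None,
) -> DistanceMatrix:
    """Mean theta-YC dissimilarity over ``iters`` independent rarefied draws.

    Samples shallower than ``depth`` are dropped (rarefy semantics); at least
    two samples must survive.  Deterministic given ``seed``; provenance is
    recorded in ``metric_tag``.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    rng = as_rng(seed)
    totals = table.depths
    survivors = [s for s in table.sample_ids if totals[s] >= depth]
    if len(survivors) < 2:
        raise ValueError(
            f"fewer than 2 samples have depth >= {depth}; cannot build a distance matrix"
        )
    sub = table.subset_samples(survivors)
    acc = np.zeros((len(survivors), len(survivors)))
    for _ in range(iters):
        drawn = rarefy(sub, depth, rng)
        rel = drawn.data.to_numpy(dtype=float) / depth
        acc += thetayc_matrix(rel)
    tag = f"thetayc,avg{iters}@{depth},seed={seed if not isinstance(seed, np.random.Generator) else 'generator'}"
    return DistanceMatrix(tuple(survivors), acc / iters, metric_tag=tag)


def rarefied_inverse_simpson(
    table: CountTable,
    depth: int,
    iters: int = 100,
    seed: SeedLike = None,
    estimator: str = "unbiased",
) -> DiversityReport:
    """Per-sample inverse Simpson, averaged over ``iters`` rarefied draws."""
    if iters < 1:
        raise ValueError("iters must be >= 1")
    rng = as_rng(seed)
    totals = table.depths
    survivors = [s for s in table.sample_ids if totals[s] >= depth]
    if not survivors:
        raise ValueError(f"no samples have depth >= {depth}")
    sub = table.subset_samples(survivors)
    acc = np.zeros(len(survivors))
    for _ in range(iters):
        drawn = rarefy(sub, depth, rng)
        counts = drawn.data.to_numpy(dtype=np.int64)
        acc += np.array([inverse_simpson(row, estimator=estimator) for row in counts])
    series = pd.Series(acc / iters, index=list(survivors), name="invsimpson")
    return DiversityReport(series, iters=iters, depth=depth, estimator=estimator)
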