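"""Operational protein families: score-to-distance conversion and
sparse average-neighbor clustering.

ORFs are grouped into operational protein families (OPFs) — the
database-independent functional analogue of an OTU — by converting pairwise
alignment bitscores into dissimilarities and clustering with the average
neighbor (average linkage) algorithm cut at a dissimilarity threshold
(25% by default).

Score-to-distance rule (recorded in output provenance so alternatives can
be swapped in): for each unordered pair with at least one directed hit, the
symmetrized score s is the mean of the available directed bitscores and

    d = 1 - s / min(self_a, self_b),   clamped to [0, 1].

Pairs with no hit at all are simply absent from the sparse matrix and count
as distance 1 inside linkage averages — the behaviour of sparse
average-neighbor clustering with a saturating placeholder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tables import CountTable, SampleMetadata

__all__ = [
    "PairwiseScoreSet",
    "SparseDistance",
    "OPFAssignment",
    "read_blast_scores",
    "scores_to_distances",
    "average_neighbor",
    "feature_sharing",
    "opf_sharing",
]

MISSING_DISTANCE = 1.0  # absent pairs saturate linkage averages at this value


@dataclass
class PairwiseScoreSet:
    """Directed pairwise alignment bitscores plus per-ORF self-scores."""

    hits: pd.DataFrame  # columns: query, subject, bitscore
    self_scores: pd.Series  # orf id -> self bitscore

    def __post_init__(self) -> None:
        required = {"query", "subject", "bitscore"}
        missing = required - set(self.hits.columns)
        if missing:
            raise ValueError(f"hits table missing columns: {sorted(missing)}")
        scores = self.hits["bitscore"].to_numpy(dtype=float)
        if scores.size and (~np.isfinite(scores) | (scores <= 0)).any():
            raise ValueError("bitscores must be finite and positive")
        if (self.self_scores <= 0).any():
            bad = sorted(self.self_scores.index[self.self_scores <= 0])
            raise ValueError(f"non-positive self-scores for: {bad}")

    @property
    def orf_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.self_scores.index))


@dataclass
class SparseDistance:
    """Sparse symmetric dissimilarities; absent pairs are beyond the cutoff."""

    ids: tuple[str, ...]
    pairs: dict[tuple[str, str], float]  # keys sorted (a, b), a < b
    provenance: str = "mean-bitscore / min-self, clamped"

    def __post_init__(self) -> None:
        self.ids = tuple(sorted(self.ids))
        for (a, b), d in self.pairs.items():
            if a >= b:
                raise ValueError(f"pair key not sorted: {(a, b)}")
            if not (0.0 <= d <= 1.0):
                raise ValueError(f"distance for {(a, b)} outside [0,1]: {d}")

    def dense(self) -> np.ndarray:
        """Dense matrix with missing pairs filled at the saturating distance."""
        n = len(self.ids)
        index = {x: i for i, x in enumerate(self.ids)}
        m = np.full((n, n), MISSING_DISTANCE)
        np.fill_diagonal(m, 0.0)
        for (a, b), d in self.pairs.items():
            i, j = index[a], index[b]
            m[i, j] = m[j, i] = d
        return m


@dataclass
class OPFAssignment:
    """A partition of ORFs into clusters at a stated dissimilarity cutoff."""

    assignments: dict[str, str]  # orf id -> cluster id
    cutoff: float
    linkage: str = "average_neighbor"

    def clusters(self) -> list[list[str]]:
        """Member lists, each sorted, ordered by smallest member id."""
        by_cluster: dict[str, list[str]] = {}
        for orf, cluster in self.assignments.items():
            by_cluster.setdefault(cluster, []).append(orf)
        groups = [sorted(members) for members in by_cluster.values()]
        return sorted(groups, key=lambda g: g[0])

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def write_list(self, path, label: str | None = None) -> None:
        """mothur list-file format: label, numOtus, comma-joined members."""
        groups = self.clusters()
        tag = label if label is not None else format(self.cutoff, "g")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            cells = [tag, str(len(groups))] + [",".join(g) for g in groups]
            fh.write("\t".join(cells) + "\n")


def read_blast_scores(hits_path, self_path) -> PairwiseScoreSet:
    """Read a 3-column hit TSV (query, subject, bitscore) and a self-score TSV."""
    hits = pd.read_csv(
        hits_path, sep="\t", header=None, names=["query", "subject", "bitscore"],
        dtype={"query": str, "subject": str},
    )
    selfs = pd.read_csv(
        self_path, sep="\t", header=None, names=["orf", "bitscore"], dtype={"orf": str}
    ).set_index("orf")["bitscore"]
    return PairwiseScoreSet(hits, selfs)


def scores_to_distances(scores: PairwiseScoreSet) -> SparseDistance:
    """Convert directed bitscores to sparse symmetric distances.

    Self-hits in the hit list are ignored (self-scores are supplied
    separately).  Values falling outside [0, 1] before clamping are logged.
    """
    selfs = scores.self_scores
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for query, subject, score in scores.hits.itertuples(index=False):
        if query == subject:
            continue
        for orf in (query, subject):
            if orf not in selfs.index:
                raise ValueError(f"missing self-score for ORF {orf!r}")
        key = (query, subject) if query < subject else (subject, query)
        sums[key] = sums.get(key, 0.0) + float(score)
        counts[key] = counts.get(key, 0) + 1
    pairs: dict[tuple[str, str], float] = {}
    n_clamped = 0
    for key, total in sums.items():
        a, b = key
        s = total / counts[key]
        d = 1.0 - s / min(float(selfs[a]), float(selfs[b]))
        if d < 0.0 or d > 1.0:
            n_clamped += 1
        pairs[key] = float(np.clip(d, 0.0, 1.0))
    if n_clamped:
        warnings.warn(f"{n_clamped} pairwise distance(s) clamped into [0, 1]")
    return SparseDistance(ids=tuple(selfs.index), pairs=pairs)


def average_neighbor(dist: SparseDistance, cutoff: float = 0.25) -> OPFAssignment:
    """Agglomerative average-linkage clustering cut at ``cutoff``.

    Clusters merge while the smallest average linkage is <= cutoff; missing
    pairs contribute the saturating distance to linkage averages.  Ties on
    the merge distance are broken deterministically: the candidate pair
    whose smallest member id is lexicographically least wins (then the
    other member).  Average linkage is monotone, so the greedy cut equals
    cutting the full dendrogram at ``cutoff``.
    """
    ids = list(dist.ids)
    n = len(ids)
    if n == 0:
        return OPFAssignment({}, cutoff)
    dense = dist.dense()
    members: list[list[str] | None] = [[x] for x in ids]
    # sums[i][j] = total pairwise distance mass between clusters i and j
    sums = dense.copy()
    sizes = np.ones(n, dtype=np.int64)
    active = set(range(n))
    while len(active) > 1:
        best: tuple[float, str, str] | None = None
        best_pair: tuple[int, int] | None = None
        act = sorted(active)
        for ai, i in enumerate(act):
            for j in act[ai + 1 :]:
                avg = sums[i, j] / (sizes[i] * sizes[j])
                key = tuple(sorted((members[i][0], members[j][0])))
                cand = (avg, key[0], key[1])
                if best is None or cand < best:
                    best = cand
                    best_pair = (i, j)
        assert best is not None and best_pair is not None
        if best[0] > cutoff:
            break
        i, j = best_pair
        members[i] = sorted(members[i] + members[j])
        members[j] = None
        for k in active:
            if k not in (i, j):
                sums[i, k] = sums[k, i] = sums[i, k] + sums[j, k]
        sizes[i] += sizes[j]
        active.remove(j)
    groups = sorted((members[i] for i in active), key=lambda g: g[0])
    assignments: dict[str, str] = {}
    width = max(4, len(str(len(groups))))
    for idx, group in enumerate(groups, start=1):
        name = f"OPF{idx:0{width}d}"
        for orf in group:
            assignments[orf] = name
    return OPFAssignment(assignments, cutoff)


def _presence_by_subject(
    table: CountTable, meta: SampleMetadata, subjects: Iterable[str]
) -> pd.DataFrame:
    rows = {}
    for subject in subjects:
        samples = [s for s in meta.samples_of(subject) if s in set(table.sample_ids)]
        if not samples:
            raise ValueError(f"subject {subject!r} has no samples in the table")
        rows[subject] = (table.data.loc[samples].sum(axis=0) > 0)
    return pd.DataFrame(rows).T


def feature_sharing(
    table: CountTable, meta: SampleMetadata, subjects: Iterable[str]
) -> float:
    """Fraction of features detected in *every* group member, among features
    detected in *any* member (presence = count > 0 in >= 1 sample)."""
    subjects = list(subjects)
    if not subjects:
        raise ValueError("empty group for sharing computation")
    presence = _presence_by_subject(table, meta, subjects)
    in_any = presence.any(axis=0)
    if in_any.sum() == 0:
        raise ValueError("no features detected in the group")
    in_all = presence.all(axis=0)
    return float(in_all.sum() / in_any.sum())


def opf_sharing(
    assignment: OPFAssignment,
    orf_subject: Mapping[str, str],
    subjects: Iterable[str],
) -> float:
    """Sharing fraction over clusters: a cluster is detected in a subject if
    any member ORF originates from that subject."""
    subjects = set(subjects)
    if not subjects:
        raise ValueError("empty group for sharing computation")
    cluster_subjects: dict[str, set[str]] = {}
    for orf, cluster in assignment.assignments.items():
        subject = orf_subject.get(orf)
        if subject is not None:
            cluster_subjects.setdefault(cluster, set()).add(subject)
    detected = {c: s & subjects for c, s in cluster_subjects.items() if s & subjects}
    if not detected:
        raise ValueError("no clusters detected in the group")
    shared = sum(1 for s in detected.values() if s == subjects)
    return shared / len(detected)
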