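"""Core-microbiota detection by abundance/prevalence thresholding.

An OTU belongs to an individual's core microbiota when its relative
abundance exceeds an abundance floor (default 0.05%, strict ``>``) in at
least a prevalence fraction (default 95%, ``>=``) of that individual's
samples.  A group core (e.g. the family core) is the intersection of the
member cores; a cross-sectional cohort core keeps features that pass the
abundance rule in at least a fraction of the cohort's members.  Coverage is
the percentage of sequences a core accounts for in a given scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Sequence, Union

import pandas as pd

from .tables import CountTable, RelAbundTable, SampleMetadata

__all__ = [
    "CoreSet",
    "individual_core",
    "shared_core",
    "core_coverage",
    "cohort_core",
    "write_coresets",
]

DEFAULT_ABUND_THRESH = 0.0005  # "over 0.05 %" relative abundance
DEFAULT_PREVALENCE = 0.95  # "in at least 95 % of samples"


@dataclass(frozen=True)
class CoreSet:
    """A set of features satisfying a core rule, with its provenance."""

    feature_ids: frozenset[str]
    abund_thresh: float
    prevalence_thresh: float
    scope: str

    def __post_init__(self) -> None:
        for name, value in (
            ("abund_thresh", self.abund_thresh),
            ("prevalence_thresh", self.prevalence_thresh),
        ):
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {value}")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def sorted_features(self) -> list[str]:
        return sorted(self.feature_ids)


def individual_core(
    rel: RelAbundTable,
    meta: SampleMetadata,
    subject: str,
    abund_thresh: float = DEFAULT_ABUND_THRESH,
    prevalence_thresh: float = DEFAULT_PREVALENCE,
) -> CoreSet:
    """Core features of one subject.

    A feature is kept iff the fraction of the subject's samples where its
    relative abundance is strictly greater than ``abund_thresh`` is at least
    ``prevalence_thresh``.  The prevalence comparison is made on the exact
    fraction — no rounding of ``prevalence_thresh * n_samples``.
    """
    samples = [s for s in meta.samples_of(subject) if s in set(rel.sample_ids)]
    if not samples:
        raise ValueError(f"subject {subject!r} has no samples in the abundance table")
    block = rel.data.loc[samples]
    prevalence = (block > abund_thresh).mean(axis=0)
    kept = frozenset(prevalence.index[prevalence >= prevalence_thresh])
    return CoreSet(kept, abund_thresh, prevalence_thresh, scope=subject)


def shared_core(cores: Sequence[CoreSet]) -> CoreSet:
    """Intersection of two or more individual cores (a group core)."""
    if len(cores) < 2:
        raise ValueError("shared_core needs at least 2 input cores")
    features = reduce(lambda a, b: a & b, (c.feature_ids for c in cores))
    scope = "&".join(c.scope for c in cores)
    return CoreSet(
        frozenset(features),
        cores[0].abund_thresh,
        cores[0].prevalence_thresh,
        scope=scope,
    )


def core_coverage(
    table: CountTable,
    core: CoreSet,
    meta: SampleMetadata,
    scope: Union[str, Iterable[str]],
) -> float:
    """Percentage of sequences assigned to ``core`` within a subject or group.

    ``scope`` is a subject id or an iterable of subject ids; their samples'
    counts are pooled.  Returns a value in [0, 100].
    """
    subjects = [scope] if isinstance(scope, str) else list(scope)
    if not subjects:
        raise ValueError("empty coverage scope")
    samples: list[str] = []
    for subject in subjects:
        samples.extend(s for s in meta.samples_of(subject) if s in set(table.sample_ids))
    if not samples:
        raise ValueError(f"no samples found for scope {subjects}")
    block = table.data.loc[samples]
    total = block.to_numpy().sum()
    if total == 0:
        raise ValueError(f"scope {subjects} has zero total counts")
    core_features = [f for f in table.feature_ids if f in core.feature_ids]
    in_core = block[core_features].to_numpy().sum() if core_features else 0
    return 100.0 * in_core / total


def cohort_core(
    rel: RelAbundTable,
    meta: SampleMetadata,
    cohort_label: str = "community",
    abund_thresh: float = DEFAULT_ABUND_THRESH,
    member_prevalence: float = DEFAULT_PREVALENCE,
    presence_only: bool = False,
) -> CoreSet:
    """Core features of a (typically cross-sectional) cohort.

    A member "has" a feature iff the feature passes the abundance rule in
    every one of that member's samples (with one sample per member this
    degenerates to the per-sample rule); a feature is kept iff at least
    ``member_prevalence`` of the members have it.  With ``presence_only``
    the abundance floor is replaced by bare presence (> 0).
    """
    members = meta.subjects_in_cohort(cohort_label)
    if len(members) < 2:
        raise ValueError(f"cohort {cohort_label!r} has fewer than 2 members")
    floor = 0.0 if presence_only else abund_thresh
    flags = []
    skipped = []
    present = set(rel.sample_ids)
    for member in members:
        samples = [s for s in meta.samples_of(member) if s in present]
        if not samples:
            # e.g. the member's only sample fell below the rarefaction depth
            skipped.append(member)
            continue
        flags.append((rel.data.loc[samples] > floor).all(axis=0))
    if skipped:
        warnings.warn(
            f"cohort_core: excluding {len(skipped)} member(s) with no samples "
            f"in the table: {skipped}"
        )
    if len(flags) < 2:
        raise ValueError(f"cohort {cohort_label!r} has fewer than 2 members with samples")
    member_fraction = pd.concat(flags, axis=1).mean(axis=1)
    kept = frozenset(member_fraction.index[member_fraction >= member_prevalence])
    return CoreSet(kept, abund_thresh, member_prevalence, scope=f"cohort:{cohort_label}")


def write_coresets(cores: Sequence[CoreSet], path) -> None:
    """Serialize core sets as a TSV (feature_id, scope, thresholds)."""
    rows = [
        {
            "feature_id": feature,
            "scope": core.scope,
            "abund_thresh": core.abund_thresh,
            "prevalence_thresh": core.prevalence_thresh,
        }
        for core in cores
        for feature in core.sorted_features()
    ]
    pd.DataFrame(
        rows, columns=["feature_id", "scope", "abund_thresh", "prevalence_thresh"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
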