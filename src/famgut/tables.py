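"""Count-table containers, mothur-dialect I/O, rarefaction and relative abundance.

The sample x feature count matrix is the central object of the whole
pipeline: every downstream analysis (diversity, core detection, stability,
classification, ordination) consumes either raw counts or a rarefied /
relative-abundance view of them.  Tables are stored as pandas DataFrames
with samples on the rows and features (OTUs, KEGG KOs, or OPFs) on the
columns; thin dataclass wrappers enforce the invariants that the analyses
rely on (integral non-negative counts, unique labels, positive depths).

File formats follow the mothur conventions common in 16S workflows:

* "shared" files: tab-delimited, header ``label  Group  numOtus  Otu001 ...``,
  one row per sample with integer counts;
* "design" files: tab-delimited sample metadata with columns
  ``sample_id  subject_id  day  cohort  feeding``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "RelAbundTable",
    "SampleMetadata",
    "SharedFormatError",
    "read_shared",
    "write_shared",
    "read_design",
    "write_design",
    "rarefy",
    "to_relabund",
    "merge_tables",
    "as_rng",
]

COHORTS = frozenset({"family", "community"})
FEEDING_STATES = frozenset({"exclusively_breastfed", "mixed", "weaned", "adult"})

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def as_rng(seed: SeedLike) -> np.random.Generator:
    """Return a numpy Generator, passing through an existing one unchanged."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class SharedFormatError(ValueError):
    """Raised when a shared-format file violates the dialect."""


@dataclass
class CountTable:
    """Integer sample x feature abundance matrix.

    Parameters
    ----------
    data
        DataFrame with sample ids as the index and feature ids as columns.
        Values must be non-negative integers.
    label
        Clustering-level tag carried through to shared-file output
        (mothur's ``label`` column, e.g. ``"0.03"``).
    """

    data: pd.DataFrame
    label: str = "0.03"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integral")
            self.data = self.data.round().astype(np.int64)
        if values.size and (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def depths(self) -> pd.Series:
        """Per-sample sequence totals (row sums)."""
        return self.data.sum(axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return CountTable(self.data.loc[list(sample_ids)].copy(), label=self.label)

    def subset_features(self, feature_ids: Sequence[str]) -> "CountTable":
        missing = [f for f in feature_ids if f not in self.data.columns]
        if missing:
            raise KeyError(f"unknown feature ids: {missing}")
        return CountTable(self.data[list(feature_ids)].copy(), label=self.label)


@dataclass
class RelAbundTable:
    """Sample x feature proportions; each retained row sums to 1.

    ``dropped`` records sample ids excluded because their depth was zero.
    """

    data: pd.DataFrame
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=1).to_numpy()
        if self.data.shape[0] and not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.data.index[~np.isclose(sums, 1.0, atol=1e-9)].tolist()
            raise ValueError(f"rows do not sum to 1: {bad}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)


@dataclass
class SampleMetadata:
    """Per-sample subject identity, collection day, cohort and feeding status.

    The ``data`` frame is indexed by sample id with columns ``subject_id``,
    ``day`` (nullable integer; community-cohort samples may lack one),
    ``cohort`` and ``feeding``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "day", "cohort", "feeding"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        bad_cohort = set(self.data["cohort"]) - COHORTS
        if bad_cohort:
            raise ValueError(f"unknown cohort values: {sorted(bad_cohort)}")
        bad_feeding = set(self.data["feeding"]) - FEEDING_STATES
        if bad_feeding:
            raise ValueError(f"unknown feeding values: {sorted(bad_feeding)}")
        dated = self.data.dropna(subset=["day"])
        if dated.duplicated(subset=["subject_id", "day"]).any():
            dupes = dated[dated.duplicated(subset=["subject_id", "day"], keep=False)]
            raise ValueError(
                "duplicate (subject, day) pairs: "
                f"{sorted(set(map(tuple, dupes[['subject_id', 'day']].to_numpy())))}"
            )
        days = dated["day"].to_numpy()
        if days.size and (days < 1).any():
            raise ValueError("study days must be >= 1")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def subjects(self) -> tuple[str, ...]:
        """Subject ids in first-appearance order."""
        return tuple(dict.fromkeys(self.data["subject_id"]))

    def samples_of(self, subject: str) -> tuple[str, ...]:
        if subject not in set(self.data["subject_id"]):
            raise KeyError(f"unknown subject: {subject}")
        return tuple(self.data.index[self.data["subject_id"] == subject])

    def subjects_in_cohort(self, cohort: str) -> tuple[str, ...]:
        sel = self.data[self.data["cohort"] == cohort]
        return tuple(dict.fromkeys(sel["subject_id"]))

    def day_of(self, sample_id: str) -> int:
        day = self.data.loc[sample_id, "day"]
        if pd.isna(day):
            raise ValueError(f"sample {sample_id} has no collection day")
        return int(day)

    def feeding_of(self, subject: str) -> str:
        rows = self.data[self.data["subject_id"] == subject]
        if rows.empty:
            raise KeyError(f"unknown subject: {subject}")
        return str(rows["feeding"].iloc[0])


# ---------------------------------------------------------------------------
# shared-file dialect
# ---------------------------------------------------------------------------

def read_shared(path: Union[str, Path], strict: bool = True) -> CountTable:
    """Read a mothur shared file into a :class:`CountTable`.

    The header must start with ``label``, ``Group``, ``numOtus``; every data
    row's ``numOtus`` is cross-checked against the parsed column count.  In
    strict mode a duplicated ``Group`` (sample id) is an error.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 3 or cols[0] != "label" or cols[1] != "Group" or cols[2] != "numOtus":
            raise SharedFormatError(
                f"{path}: malformed shared header (expected 'label\\tGroup\\tnumOtus\\t...')"
            )
        feature_ids = cols[3:]
        if len(set(feature_ids)) != len(feature_ids):
            raise SharedFormatError(f"{path}: duplicate OTU columns in header")
        rows: list[list[int]] = []
        sample_ids: list[str] = []
        label = "0.03"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3 + len(feature_ids):
                raise SharedFormatError(
                    f"{path}:{lineno}: expected {3 + len(feature_ids)} fields, got {len(parts)}"
                )
            label, group, n_otus = parts[0], parts[1], parts[2]
            try:
                declared = int(n_otus)
            except ValueError as exc:
                raise SharedFormatError(f"{path}:{lineno}: numOtus not an integer") from exc
            if declared != len(feature_ids):
                raise SharedFormatError(
                    f"{path}:{lineno}: numOtus={declared} but header lists "
                    f"{len(feature_ids)} OTU columns"
                )
            counts = []
            for feature, cell in zip(feature_ids, parts[3:]):
                try:
                    value = int(cell)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer count for sample {group!r}, "
                        f"feature {feature!r}: {cell!r}"
                    ) from exc
                if value < 0:
                    raise ValueError(
                        f"{path}:{lineno}: negative count for sample {group!r}, "
                        f"feature {feature!r}"
                    )
                counts.append(value)
            if group in sample_ids:
                if strict:
                    raise SharedFormatError(f"{path}:{lineno}: duplicate Group {group!r}")
                warnings.warn(f"duplicate Group {group!r}; keeping first occurrence")
                continue
            sample_ids.append(group)
            rows.append(counts)
    data = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(rows), len(feature_ids)),
        index=pd.Index(sample_ids, name="Group"),
        columns=feature_ids,
    )
    return CountTable(data, label=label)


def write_shared(table: CountTable, path: Union[str, Path]) -> None:
    """Write a :class:`CountTable` in the mothur shared dialect (UTF-8, LF)."""
    path = Path(path)
    features = list(table.feature_ids)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["label", "Group", "numOtus"] + features) + "\n")
        for sample in table.sample_ids:
            row = table.data.loc[sample]
            cells = [table.label, str(sample), str(len(features))]
            cells.extend(str(int(v)) for v in row.to_numpy())
            fh.write("\t".join(cells) + "\n")


def read_design(path: Union[str, Path]) -> SampleMetadata:
    """Read a design/metadata TSV (sample_id, subject_id, day, cohort, feeding)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    required = {"sample_id", "subject_id", "day", "cohort", "feeding"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design file missing columns {sorted(missing)}")
    df = df.set_index("sample_id")
    df["day"] = df["day"].astype("Int64")
    return SampleMetadata(df)


def write_design(meta: SampleMetadata, path: Union[str, Path]) -> None:
    out = meta.data.reset_index()
    if "index" in out.columns:
        out = out.rename(columns={"index": "sample_id"})
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: SeedLike = None) -> CountTable:
    """Subsample each sample to exactly ``depth`` counts without replacement.

    Samples whose total is below ``depth`` are dropped with a warning (the
    alternative — keeping shallow samples — would defeat the point of
    rarefying, which is to remove depth artifacts).  A sample whose total
    equals ``depth`` is passed through unchanged.  Deterministic given
    ``seed``; samples are processed in table order.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = as_rng(seed)
    totals = table.depths
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        warnings.warn(
            f"rarefy: dropping {len(dropped)} sample(s) below depth {depth}: {dropped}"
        )
    # draw in a canonical (sorted) feature order so the result is invariant
    # to the table's column order
    order = np.argsort(np.asarray(table.feature_ids, dtype=object))
    inverse = np.argsort(order)
    rows = []
    kept_ids = [s for s in table.sample_ids if s in set(keep)]
    for sample in kept_ids:
        counts = table.data.loc[sample].to_numpy(dtype=np.int64)
        if counts.sum() == depth:
            rows.append(counts)
        else:
            drawn = rng.multivariate_hypergeometric(counts[order], depth)
            rows.append(drawn[inverse])
    data = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(kept_ids), len(table.feature_ids)),
        index=pd.Index(kept_ids, name=table.data.index.name),
        columns=table.data.columns,
    )
    return CountTable(data, label=table.label)


def to_relabund(table: CountTable) -> RelAbundTable:
    """Convert counts to per-sample proportions; zero-depth samples are dropped."""
    totals = table.depths
    zero = tuple(totals.index[totals == 0])
    if zero:
        warnings.warn(f"to_relabund: excluding zero-depth sample(s): {list(zero)}")
    kept = table.data.loc[totals[totals > 0].index]
    rel = kept.div(kept.sum(axis=1), axis=0)
    return RelAbundTable(rel, dropped=zero)


def merge_tables(a: CountTable, b: CountTable) -> CountTable:
    """Stack two count tables on the union of their feature axes (zeros fill)."""
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValueError(f"sample ids present in both tables: {sorted(overlap)}")
    merged = pd.concat([a.data, b.data]).fillna(0).astype(np.int64)
    return CountTable(merged, label=a.label)
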