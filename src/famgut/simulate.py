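"""Synthetic longitudinal family-microbiome generator with full ground truth.

Emulates the sampling design the analyses assume: a household of eight
(an exclusively breastfed infant dominated by two alternating taxa, a
partially weaned toddler intermediate between the infant and her weaned
siblings, four weaned children and two parents) sampled daily for 26 days,
plus a cross-sectional community cohort, plus paired functional (KEGG-KO-
and OPF-like) tables and a pairwise alignment-score set with planted
protein families.

The noise model is Dirichlet-multinomial: each subject has a fixed base
composition; each day's composition is Dirichlet(base * concentration) and
counts are multinomial at a lognormally distributed depth.  A family core
of ``n_core`` OTUs is planted with expected mass ``core_mass`` in every
non-infant member (subject-specific proportions), personal OTUs make every
subject separable, and a shared environmental pool provides features that
are widespread but — by construction — never prevalent in *all* non-infant
members, so the planted core is exactly identifiable by the
abundance/prevalence rule.

Every generator is bit-reproducible given its config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .opf import PairwiseScoreSet
from .tables import CountTable, SampleMetadata, as_rng

__all__ = [
    "SubjectSpec",
    "FamilyConfig",
    "CohortConfig",
    "FunctionalConfig",
    "FamilyTruth",
    "CohortTruth",
    "FunctionalTruth",
    "default_subjects",
    "generate_family",
    "generate_cohort",
    "generate_infant_series",
    "generate_functional_tables",
]


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    feeding: str
    days: tuple[int, ...] = tuple(range(1, 27))


def default_subjects() -> tuple[SubjectSpec, ...]:
    """The study household: infant, toddler, four weaned children, parents."""
    days = tuple(range(1, 27))
    return (
        SubjectSpec("infant", "exclusively_breastfed", days),
        SubjectSpec("toddler", "mixed", days),
        SubjectSpec("child3", "weaned", days),
        SubjectSpec("child4", "weaned", days),
        SubjectSpec("child5", "weaned", days),
        SubjectSpec("child6", "weaned", days),
        SubjectSpec("mother", "adult", days),
        SubjectSpec("father", "adult", days),
    )


@dataclass
class FamilyConfig:
    """Knobs of the family generator; defaults mirror the study design."""

    n_core: int = 12
    core_mass: float = 0.40
    n_personal: int = 15
    personal_mass: float = 0.35
    n_shared_pool: int = 40
    pool_mass: float = 0.25
    pool_inclusion_prob: float = 0.5
    subjects: tuple[SubjectSpec, ...] = field(default_factory=default_subjects)
    concentration: float = 300.0
    core_alpha: float = 25.0
    depth_mean: float = 5000.0
    depth_sigma: float = 0.3
    infant_switch_prob: float = 0.2
    infant_dominant_mass: float = 0.65
    infant_secondary_mass: float = 0.10
    infant_core_mass: float = 0.03
    infant_stable_mass: float = 0.06
    toddler_lambda: float = 0.4
    child_core_coupling: float = 150.0
    seed: int | None = None

    def __post_init__(self) -> None:
        block = self.core_mass + self.personal_mass + self.pool_mass
        if not np.isclose(block, 1.0):
            raise ValueError(
                f"core+personal+pool masses must sum to 1, got {block:.4f}"
            )
        if self.n_core < 0 or self.concentration <= 0:
            raise ValueError("n_core must be >= 0 and concentration > 0")
        infant_total = (
            self.infant_dominant_mass
            + self.infant_secondary_mass
            + self.infant_core_mass
            + self.infant_stable_mass
        )
        if infant_total >= 1.0:
            raise ValueError("infant block masses must leave room for background")


@dataclass
class FamilyTruth:
    """Everything a downstream test needs to verify recovery."""

    core_features: tuple[str, ...]
    personal_features: dict[str, tuple[str, ...]]
    pool_features: tuple[str, ...]
    infant_dominants: tuple[str, str]
    infant_trajectory: dict[str, dict[int, str]]  # subject -> day -> dominant feature
    base_compositions: pd.DataFrame  # subject x feature expected composition
    core_mass: float


def _lognormal_depth(rng: np.random.Generator, mean: float, sigma: float) -> int:
    mu = np.log(mean) - sigma**2 / 2.0
    return max(1, int(round(rng.lognormal(mu, sigma))))


def _dirichlet_on_support(
    rng: np.random.Generator, base: np.ndarray, concentration: float
) -> np.ndarray:
    """Dirichlet draw restricted to the positive entries of ``base``."""
    out = np.zeros_like(base)
    support = base > 0
    alpha = base[support] * concentration
    out[support] = rng.dirichlet(alpha)
    return out


def _draw_pool_inclusion(
    rng: np.random.Generator, config: FamilyConfig, non_infant: list[str]
) -> dict[str, np.ndarray]:
    """Per-subject boolean inclusion over pool features.

    Guarantees every pool feature is excluded from at least one non-infant
    subject, so no environmental feature can masquerade as family core.
    (With fewer than two non-infant subjects there is no shared core to
    protect and the constraint is skipped.)
    """
    subjects = [s.subject_id for s in config.subjects]
    inclusion = {
        s: rng.random(config.n_shared_pool) < config.pool_inclusion_prob
        for s in subjects
    }
    if len(non_infant) >= 2:
        for j in range(config.n_shared_pool):
            holders = [s for s in non_infant if inclusion[s][j]]
            if len(holders) == len(non_infant):
                drop = non_infant[rng.integers(len(non_infant))]
                inclusion[drop][j] = False
    return inclusion


def generate_family(config: FamilyConfig) -> tuple[CountTable, SampleMetadata, FamilyTruth]:
    """Simulate the full household's daily OTU count table with ground truth."""
    rng = as_rng(config.seed)
    subjects = list(config.subjects)
    subject_ids = [s.subject_id for s in subjects]
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids in config")
    infants = [s.subject_id for s in subjects if s.feeding == "exclusively_breastfed"]
    non_infant = [s.subject_id for s in subjects if s.feeding != "exclusively_breastfed"]

    # --- feature registry -------------------------------------------------
    core = [f"Otu{i:04d}" for i in range(1, config.n_core + 1)]
    nxt = config.n_core + 1
    dominants = (f"Otu{nxt:04d}", f"Otu{nxt + 1:04d}")
    infant_stable = (f"Otu{nxt + 2:04d}", f"Otu{nxt + 3:04d}")
    nxt += 4
    pool = [f"Otu{i:04d}" for i in range(nxt, nxt + config.n_shared_pool)]
    nxt += config.n_shared_pool
    personal: dict[str, tuple[str, ...]] = {}
    for sid in subject_ids:
        personal[sid] = tuple(f"Otu{i:04d}" for i in range(nxt, nxt + config.n_personal))
        nxt += config.n_personal
    features = core + list(dominants) + list(infant_stable) + pool
    for sid in subject_ids:
        features.extend(personal[sid])
    f_index = {f: i for i, f in enumerate(features)}

    inclusion = _draw_pool_inclusion(rng, config, non_infant)

    # --- per-subject expected compositions --------------------------------
    # the children's core proportions cluster around a shared template, so
    # siblings resemble each other more than they resemble their parents
    child_template = (
        rng.dirichlet(np.full(config.n_core, config.core_alpha))
        if config.n_core
        else np.zeros(0)
    )

    def weaned_base(sid: str, child: bool) -> np.ndarray:
        base = np.zeros(len(features))
        if config.n_core:
            if child:
                core_w = rng.dirichlet(child_template * config.child_core_coupling)
            else:
                core_w = rng.dirichlet(np.full(config.n_core, config.core_alpha))
            for f, w in zip(core, core_w):
                base[f_index[f]] = config.core_mass * w
        pers_w = rng.dirichlet(np.full(config.n_personal, 3.0))
        for f, w in zip(personal[sid], pers_w):
            base[f_index[f]] = config.personal_mass * w
        included = [f for f, inc in zip(pool, inclusion[sid]) if inc]
        if included:
            pool_w = rng.dirichlet(np.full(len(included), 2.0))
            for f, w in zip(included, pool_w):
                base[f_index[f]] = config.pool_mass * w
        return base / base.sum()

    def infant_template(sid: str) -> np.ndarray:
        """Infant composition apart from the day-switching dominant pair."""
        base = np.zeros(len(features))
        if config.n_core:
            core_w = rng.dirichlet(np.full(config.n_core, config.core_alpha))
            for f, w in zip(core, core_w):
                base[f_index[f]] = config.infant_core_mass * w
        stable_w = rng.dirichlet(np.full(2, 20.0))
        for f, w in zip(infant_stable, stable_w):
            base[f_index[f]] = config.infant_stable_mass * w
        background_mass = 1.0 - (
            config.infant_dominant_mass
            + config.infant_secondary_mass
            + config.infant_core_mass
            + config.infant_stable_mass
        )
        included = [f for f, inc in zip(pool, inclusion[sid]) if inc]
        if not included:
            included = [pool[0]] if pool else list(personal[sid][:3])
        bg_w = rng.dirichlet(np.full(len(included), 1.0))
        for f, w in zip(included, bg_w):
            base[f_index[f]] += background_mass * w
        return base

    bases: dict[str, np.ndarray] = {}
    templates: dict[str, np.ndarray] = {}
    for spec in subjects:
        sid = spec.subject_id
        if spec.feeding == "exclusively_breastfed":
            templates[sid] = infant_template(sid)
            static = templates[sid].copy()
            static[f_index[dominants[0]]] = config.infant_dominant_mass
            static[f_index[dominants[1]]] = config.infant_secondary_mass
            bases[sid] = static / static.sum()
        else:
            bases[sid] = weaned_base(sid, child=spec.feeding in ("weaned", "mixed"))
    # the partially weaned toddler interpolates infant-like and weaned bases
    for spec in subjects:
        if spec.feeding == "mixed":
            sid = spec.subject_id
            infant_like = (
                bases[infants[0]]
                if infants
                else bases[sid]  # no infant configured: stay weaned-like
            )
            mixed = config.toddler_lambda * infant_like + (1 - config.toddler_lambda) * bases[sid]
            bases[sid] = mixed / mixed.sum()

    # --- daily draws -------------------------------------------------------
    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    trajectory: dict[str, dict[int, str]] = {}
    for spec in subjects:
        sid = spec.subject_id
        if spec.feeding == "exclusively_breastfed":
            state = int(rng.integers(2))
            traj: dict[int, str] = {}
            for day in spec.days:
                base = templates[sid].copy()
                dom, sec = (dominants[state], dominants[1 - state])
                base[f_index[dom]] = config.infant_dominant_mass
                base[f_index[sec]] = config.infant_secondary_mass
                base = base / base.sum()
                traj[day] = dom
                p = _dirichlet_on_support(rng, base, config.concentration)
                depth = _lognormal_depth(rng, config.depth_mean, config.depth_sigma)
                rows.append(rng.multinomial(depth, p))
                sample_ids.append(f"{sid}_d{day:02d}")
                meta_rows.append(
                    {"sample_id": f"{sid}_d{day:02d}", "subject_id": sid, "day": day,
                     "cohort": "family", "feeding": spec.feeding}
                )
                if rng.random() < config.infant_switch_prob:
                    state = 1 - state
            trajectory[sid] = traj
        else:
            for day in spec.days:
                p = _dirichlet_on_support(rng, bases[sid], config.concentration)
                depth = _lognormal_depth(rng, config.depth_mean, config.depth_sigma)
                rows.append(rng.multinomial(depth, p))
                sample_ids.append(f"{sid}_d{day:02d}")
                meta_rows.append(
                    {"sample_id": f"{sid}_d{day:02d}", "subject_id": sid, "day": day,
                     "cohort": "family", "feeding": spec.feeding}
                )

    data = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=pd.Index(sample_ids, name="Group"),
        columns=features,
    )
    table = CountTable(data)
    meta_df = pd.DataFrame(meta_rows).set_index("sample_id")
    meta_df["day"] = meta_df["day"].astype("Int64")
    meta = SampleMetadata(meta_df)
    truth = FamilyTruth(
        core_features=tuple(core),
        personal_features=personal,
        pool_features=tuple(pool),
        infant_dominants=dominants,
        infant_trajectory=trajectory,
        base_compositions=pd.DataFrame(bases, index=features).T,
        core_mass=config.core_mass,
    )
    return table, meta, truth


def generate_infant_series(config: FamilyConfig) -> CountTable:
    """Daily counts for the exclusively breastfed infant alone.

    The dominant taxon follows a two-state switching process: each day it
    flips with probability ``infant_switch_prob``.
    """
    infant_only = replace(
        config,
        subjects=tuple(
            s for s in config.subjects if s.feeding == "exclusively_breastfed"
        ),
    )
    if not infant_only.subjects:
        raise ValueError("config contains no exclusively breastfed subject")
    table, _, _ = generate_family(infant_only)
    return table


@dataclass
class CohortConfig:
    """Cross-sectional community cohort: one sample per member."""

    n_members: int = 155
    n_common: int = 4
    common_mass: float = 0.20
    n_pool: int = 100
    pool_inclusion_prob: float = 0.7
    pool_mass: float = 0.50
    n_personal: int = 8
    personal_mass: float = 0.30
    concentration: float = 300.0
    depth_mean: float = 5000.0
    depth_sigma: float = 0.3
    common_overlap_with_family_core: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        block = self.common_mass + self.pool_mass + self.personal_mass
        if not np.isclose(block, 1.0):
            raise ValueError(f"cohort masses must sum to 1, got {block:.4f}")
        if self.common_overlap_with_family_core > self.n_common:
            raise ValueError("overlap cannot exceed n_common")


@dataclass
class CohortTruth:
    common_features: tuple[str, ...]
    pool_features: tuple[str, ...]


def generate_cohort(
    config: CohortConfig, family_truth: FamilyTruth | None = None
) -> tuple[CountTable, SampleMetadata, CohortTruth]:
    """Simulate the community cohort with a small planted common feature set.

    When ``family_truth`` is supplied, ``common_overlap_with_family_core`` of
    the planted common features reuse family-core feature ids, so merged
    family+cohort tables share those taxa.
    """
    rng = as_rng(config.seed)
    overlap = 0
    common: list[str] = []
    if family_truth is not None:
        overlap = min(config.common_overlap_with_family_core, len(family_truth.core_features))
        common.extend(family_truth.core_features[:overlap])
    common.extend(f"OtuC{i:04d}" for i in range(1, config.n_common - overlap + 1))
    nxt = config.n_common - overlap + 1
    pool = [f"OtuC{i:04d}" for i in range(nxt, nxt + config.n_pool)]
    nxt += config.n_pool
    members = [f"aa{i:03d}" for i in range(1, config.n_members + 1)]
    personal = {}
    for m in members:
        personal[m] = [f"OtuC{i:04d}" for i in range(nxt, nxt + config.n_personal)]
        nxt += config.n_personal
    features = common + pool + [f for m in members for f in personal[m]]
    f_index = {f: i for i, f in enumerate(features)}

    rows, sample_ids, meta_rows = [], [], []
    for m in members:
        base = np.zeros(len(features))
        common_w = rng.dirichlet(np.full(config.n_common, 8.0))
        for f, w in zip(common, common_w):
            base[f_index[f]] = config.common_mass * w
        included = [f for f in pool if rng.random() < config.pool_inclusion_prob]
        if included:
            pool_w = rng.dirichlet(np.full(len(included), 2.0))
            for f, w in zip(included, pool_w):
                base[f_index[f]] = config.pool_mass * w
        pers_w = rng.dirichlet(np.full(config.n_personal, 3.0))
        for f, w in zip(personal[m], pers_w):
            base[f_index[f]] = config.personal_mass * w
        base = base / base.sum()
        p = _dirichlet_on_support(rng, base, config.concentration)
        depth = _lognormal_depth(rng, config.depth_mean, config.depth_sigma)
        rows.append(rng.multinomial(depth, p))
        sample_ids.append(f"{m}_s1")
        meta_rows.append(
            {"sample_id": f"{m}_s1", "subject_id": m, "day": pd.NA,
             "cohort": "community", "feeding": "adult"}
        )
    data = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=pd.Index(sample_ids, name="Group"),
        columns=features,
    )
    meta_df = pd.DataFrame(meta_rows).set_index("sample_id")
    meta_df["day"] = meta_df["day"].astype("Int64")
    return CountTable(data), SampleMetadata(meta_df), CohortTruth(tuple(common), tuple(pool))


# ---------------------------------------------------------------------------
# functional (metagenome-like) tables
# ---------------------------------------------------------------------------

@dataclass
class FunctionalConfig:
    """Paired KO-like and OPF-like tables plus planted protein families."""

    n_ko: int = 200
    ko_universal_fraction: float = 0.66
    ko_universal_mass: float = 0.75
    n_opf: int = 400
    opf_universal_fraction: float = 0.073
    opf_universal_mass: float = 0.50
    association: float = 0.8
    timepoints: tuple[int, ...] = (1, 15, 26)
    concentration: float = 200.0
    depth_mean: float = 2.5e6
    depth_sigma: float = 0.25
    n_protein_families: int = 20
    universal_family_fraction: float = 0.10
    family_size_range: tuple[int, int] = (1, 8)
    within_family_dist: tuple[float, float] = (0.05, 0.20)
    cross_family_dist: tuple[float, float] = (0.35, 0.70)
    cross_hit_prob: float = 0.10
    self_score_range: tuple[int, int] = (150, 400)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.association <= 1.0):
            raise ValueError("association must lie in [0, 1]")


@dataclass
class FunctionalTruth:
    universal_ko: tuple[str, ...]
    universal_opf: tuple[str, ...]
    universal_opf_fraction: float
    protein_families: tuple[tuple[str, ...], ...]
    orf_subject: dict[str, str]
    association: float


def _functional_table(
    rng: np.random.Generator,
    prefix: str,
    n_features: int,
    universal_fraction: float,
    universal_mass: float,
    subjects: list[str],
    samples: list[tuple[str, str]],  # (sample_id, subject_id)
    association: float,
    concentration: float,
    depth_mean: float,
    depth_sigma: float,
    tax_counts: pd.DataFrame | None,
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    n_universal = max(1, int(round(universal_fraction * n_features)))
    features = [f"{prefix}{i:05d}" for i in range(1, n_features + 1)]
    universal = features[:n_universal]
    specific = features[n_universal:]
    if association == 1.0 and tax_counts is not None:
        # limiting contract: functional counts reproduce the taxonomic table
        # exactly (features renamed), so distance matrices coincide
        mapped = tax_counts.copy()
        mapped.columns = [f"{prefix}{i + 1:05d}" for i in range(tax_counts.shape[1])]
        return mapped, tuple(mapped.columns[:n_universal])

    # assign each specific feature to a proper, non-empty subject subset
    holders: dict[str, list[str]] = {}
    n_subj = len(subjects)
    for feat in specific:
        size = int(rng.integers(1, n_subj))  # 1 .. n_subj-1
        chosen = list(rng.choice(n_subj, size=size, replace=False))
        holders[feat] = [subjects[i] for i in chosen]

    # subject signatures over their present features; association blends the
    # signature with a global profile shared by everyone
    global_universal = rng.dirichlet(np.full(n_universal, 5.0))
    bases: dict[str, np.ndarray] = {}
    for subject in subjects:
        base = np.zeros(n_features)
        uni_w = rng.dirichlet(np.full(n_universal, 2.0))
        blended = association * uni_w + (1 - association) * global_universal
        base[:n_universal] = universal_mass * blended
        present = [i for i, f in enumerate(specific) if subject in holders[f]]
        if present:
            spec_w = rng.dirichlet(np.full(len(present), 2.0))
            for i, w in zip(present, spec_w):
                base[n_universal + i] = association * (1 - universal_mass) * w
        # leftover mass (weaker association => less subject-specific signal)
        # folds back onto the shared global profile
        base[:n_universal] += (1.0 - base.sum()) * global_universal
        bases[subject] = base / base.sum()

    rows = []
    for sample_id, subject in samples:
        p = _dirichlet_on_support(rng, bases[subject], concentration)
        depth = _lognormal_depth(rng, depth_mean, depth_sigma)
        rows.append(rng.multinomial(depth, p))
    df = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=pd.Index([s for s, _ in samples], name="Group"),
        columns=features,
    )
    return df, tuple(universal)


def generate_functional_tables(
    config: FunctionalConfig,
    family_table: CountTable,
    family_meta: SampleMetadata,
) -> tuple[CountTable, CountTable, PairwiseScoreSet, FunctionalTruth]:
    """KO-like and OPF-like count tables at the metagenome timepoints, plus a
    planted pairwise-score set whose true protein families sit below the
    clustering cutoff.

    Sample ids are shared with the 16S table (the same specimens were
    sequenced), so taxonomic and functional distance matrices can be
    compared directly.  ``association`` controls how strongly functional
    community structure tracks subject identity: 0 gives one global profile
    (no concordance signal), 1 reproduces the taxonomic table exactly in
    the functional namespace.
    """
    rng = as_rng(config.seed)
    subjects = [s for s in family_meta.subjects]
    samples: list[tuple[str, str]] = []
    for subject in subjects:
        for s in family_meta.samples_of(subject):
            if family_meta.day_of(s) in config.timepoints:
                samples.append((s, subject))
    if len(samples) < 3:
        raise ValueError("fewer than 3 metagenome samples; check timepoints")
    sample_ids = [s for s, _ in samples]
    tax_counts = family_table.data.loc[sample_ids]

    ko_df, universal_ko = _functional_table(
        rng, "K", config.n_ko, config.ko_universal_fraction, config.ko_universal_mass,
        subjects, samples, config.association, config.concentration,
        config.depth_mean, config.depth_sigma, tax_counts,
    )
    opf_df, universal_opf = _functional_table(
        rng, "OPF", config.n_opf, config.opf_universal_fraction,
        config.opf_universal_mass, subjects, samples, config.association,
        config.concentration, config.depth_mean, config.depth_sigma, tax_counts,
    )
    ko_table = CountTable(ko_df, label="ko")
    opf_table = CountTable(opf_df, label="opf")

    scores, families, orf_subject = _planted_score_set(rng, config, subjects)
    truth = FunctionalTruth(
        universal_ko=universal_ko,
        universal_opf=universal_opf,
        universal_opf_fraction=len(universal_opf) / config.n_opf,
        protein_families=families,
        orf_subject=orf_subject,
        association=config.association,
    )
    return ko_table, opf_table, scores, truth


def _planted_score_set(
    rng: np.random.Generator, config: FunctionalConfig, subjects: list[str]
) -> tuple[PairwiseScoreSet, tuple[tuple[str, ...], ...], dict[str, str]]:
    """Bitscores whose implied distances recover the planted families exactly.

    A ``universal_family_fraction`` of the planted families carries one ORF
    per subject (detected in every member); the rest draw their ORFs from a
    proper subject subset, so cluster-level sharing across all members
    recovers the planted fraction.
    """
    lo, hi = config.family_size_range
    n_universal = int(round(config.universal_family_fraction * config.n_protein_families))
    orf_ids: list[str] = []
    families: list[tuple[str, ...]] = []
    orf_subject: dict[str, str] = {}
    n = 0
    for fam_idx in range(config.n_protein_families):
        universal = fam_idx < n_universal
        if universal:
            size = max(int(rng.integers(lo, hi + 1)), len(subjects))
        else:
            size = int(rng.integers(lo, hi + 1))
        fam = tuple(f"Orf{n + i:04d}" for i in range(1, size + 1))
        families.append(fam)
        orf_ids.extend(fam)
        n += size
        if universal:
            # one ORF per subject first, extras at random
            for i, orf in enumerate(fam):
                if i < len(subjects):
                    orf_subject[orf] = subjects[i]
                else:
                    orf_subject[orf] = subjects[int(rng.integers(len(subjects)))]
        else:
            k = int(rng.integers(1, len(subjects))) if len(subjects) > 1 else 1
            subset = [subjects[i] for i in rng.choice(len(subjects), size=k, replace=False)]
            for orf in fam:
                orf_subject[orf] = subset[int(rng.integers(len(subset)))]
    s_lo, s_hi = config.self_score_range
    selfs = pd.Series(
        rng.integers(s_lo, s_hi + 1, size=len(orf_ids)).astype(float), index=orf_ids
    )

    hit_rows: list[tuple[str, str, float]] = []
    d_lo, d_hi = config.within_family_dist
    for fam in families:
        for i, a in enumerate(fam):
            for b in fam[i + 1 :]:
                d = rng.uniform(d_lo, d_hi)
                s_mean = (1.0 - d) * min(selfs[a], selfs[b])
                asym = rng.uniform(0.0, 0.05)
                hit_rows.append((a, b, s_mean * (1 + asym)))
                hit_rows.append((b, a, s_mean * (1 - asym)))
    c_lo, c_hi = config.cross_family_dist
    for fi, fam_a in enumerate(families):
        for fam_b in families[fi + 1 :]:
            for a in fam_a:
                for b in fam_b:
                    if rng.random() < config.cross_hit_prob:
                        d = rng.uniform(c_lo, c_hi)
                        hit_rows.append((a, b, (1.0 - d) * min(selfs[a], selfs[b])))
    hits = pd.DataFrame(hit_rows, columns=["query", "subject", "bitscore"])
    return PairwiseScoreSet(hits, selfs), tuple(families), orf_subject
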