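"""End-to-end orchestration: simulate -> rarefy -> diversity -> distances ->
core -> stability -> comparisons -> classify -> ordinate -> concordance -> OPF.

Every artifact is a plain-text TSV/JSON (plus phylip distance matrices and a
mothur list file); the manifest records the seed, the config hash and
library versions, and a rerun with the same config and seed reproduces
every tracked output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import top_feature_refit, train_individual_classifier
from .core import cohort_core, core_coverage, individual_core, shared_core, write_coresets
from .diversity import distance_matrix, rarefied_inverse_simpson
from .opf import average_neighbor, feature_sharing, opf_sharing, scores_to_distances
from .ordination import mantel, nmds
from .simulate import (
    CohortConfig,
    FamilyConfig,
    FunctionalConfig,
    generate_cohort,
    generate_family,
    generate_functional_tables,
)
from .stability import (
    group_similarity,
    stability_curve,
    stability_slope,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from .tables import RelAbundTable, merge_tables, rarefy, to_relabund, write_design, write_shared

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "report"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


@dataclass
class PipelineConfig:
    """All fixed parameters of one pipeline run."""

    otu_depth: int = 1827
    functional_depth: int = 1_207_904
    iters: int = 100
    functional_iters: int = 25
    abund_thresh: float = 0.0005
    prevalence_thresh: float = 0.95
    n_trees: int = 10_000
    top_k: int = 15
    opf_cutoff: float = 0.25
    nmds_dim: int = 2
    nmds_restarts: int = 20
    n_permutations: int = 999
    seed: int = 0
    family: FamilyConfig = field(default_factory=FamilyConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    functional: FunctionalConfig = field(default_factory=FunctionalConfig)

    def to_dict(self) -> dict:
        # JSON round-trip normalizes tuples to lists for hashing/serialization
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        fam = raw.pop("family", {})
        coh = raw.pop("cohort", {})
        fun = raw.pop("functional", {})
        if isinstance(fam, dict) and "subjects" in fam:
            from .simulate import SubjectSpec

            fam["subjects"] = tuple(
                SubjectSpec(s["subject_id"], s["feeding"], tuple(s.get("days", range(1, 27))))
                for s in fam["subjects"]
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(
            family=FamilyConfig(**fam) if isinstance(fam, dict) else fam,
            cohort=CohortConfig(**coh) if isinstance(coh, dict) else coh,
            functional=FunctionalConfig(**fun) if isinstance(fun, dict) else fun,
            **raw,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from the run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _write_json(obj, path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage and write all artifacts under ``out_dir``.

    A stage failure raises :class:`PipelineError` naming the stage; partial
    outputs are retained next to a ``FAILED`` marker file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    seeds = _spawn_seeds(config.seed, 12)
    (s_family, s_cohort, s_functional, s_div, s_dist, s_dist_all, s_core,
     s_classify, s_distko, s_distopf, s_nmds, s_mantel) = seeds
    try:
        # ---- simulate -----------------------------------------------------
        stage = "simulate"
        fam_cfg = dataclasses.replace(config.family, seed=s_family)
        table, meta, truth = generate_family(fam_cfg)
        coh_cfg = dataclasses.replace(config.cohort, seed=s_cohort)
        cohort_table, cohort_meta, cohort_truth = generate_cohort(coh_cfg, truth)
        write_shared(table, out / "family.shared")
        write_design(meta, out / "family.design")
        write_shared(cohort_table, out / "cohort.shared")
        write_design(cohort_meta, out / "cohort.design")
        _write_json(
            {
                "core_features": list(truth.core_features),
                "infant_dominants": list(truth.infant_dominants),
                "core_mass": truth.core_mass,
                "cohort_common_features": list(cohort_truth.common_features),
            },
            out / "truth.json",
        )
        family_subjects = list(meta.subjects)
        feeding = {s: meta.feeding_of(s) for s in family_subjects}
        non_infant = [s for s in family_subjects if feeding[s] != "exclusively_breastfed"]
        children = [s for s in family_subjects if feeding[s] == "weaned"]
        adults = [s for s in family_subjects if feeding[s] == "adult"]
        mother = "mother" if "mother" in adults else (adults[0] if adults else None)
        father = "father" if "father" in adults else (adults[1] if len(adults) > 1 else None)

        # ---- alpha diversity ---------------------------------------------
        stage = "diversity"
        div = rarefied_inverse_simpson(
            table, depth=config.otu_depth, iters=config.iters, seed=s_div
        )
        div_df = div.per_sample.rename_axis("sample_id").reset_index()
        div_df["subject_id"] = [meta.data.loc[s, "subject_id"] for s in div_df["sample_id"]]
        div_df.to_csv(out / "diversity.tsv", sep="\t", index=False, lineterminator="\n")

        # ---- distance matrices ---------------------------------------------
        stage = "distances"
        dist_family = distance_matrix(
            table, depth=config.otu_depth, iters=config.iters, seed=s_dist
        )
        dist_family.write_phylip(out / "thetayc_family.phylip")
        merged = merge_tables(table, cohort_table)
        merged_meta_df = pd.concat([meta.data, cohort_meta.data])
        from .tables import SampleMetadata

        merged_meta = SampleMetadata(merged_meta_df)
        dist_all = distance_matrix(
            merged, depth=config.otu_depth, iters=config.iters, seed=s_dist_all
        )
        dist_all.write_phylip(out / "thetayc_all.phylip")

        # ---- core microbiota -----------------------------------------------
        stage = "core"
        rng_core = np.random.default_rng(s_core)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fam_rar = rarefy(table, config.otu_depth, rng_core)
            fam_rel = to_relabund(fam_rar)
            coh_rar = rarefy(cohort_table, config.otu_depth, rng_core)
            coh_rel = to_relabund(coh_rar)
        cores = {
            s: individual_core(
                fam_rel, meta, s, config.abund_thresh, config.prevalence_thresh
            )
            for s in family_subjects
        }
        family_core = shared_core([cores[s] for s in non_infant])
        community_core = cohort_core(
            coh_rel, cohort_meta, "community", config.abund_thresh, config.prevalence_thresh
        )
        write_coresets(list(cores.values()) + [family_core, community_core], out / "cores.tsv")
        coverage_rows = []
        for s in family_subjects:
            coverage_rows.append(
                {
                    "subject_id": s,
                    "feeding": feeding[s],
                    "individual_core_size": len(cores[s]),
                    "family_core_coverage_pct": core_coverage(fam_rar, family_core, meta, s),
                }
            )
        cov_df = pd.DataFrame(coverage_rows)
        cov_df.to_csv(out / "core_coverage.tsv", sep="\t", index=False, lineterminator="\n")

        # ---- stability ------------------------------------------------------
        stage = "stability"
        curves = []
        rng_slope = np.random.default_rng(s_core + 1)
        for s in family_subjects:
            curve = stability_curve(dist_family, meta, s)
            slope, (lo, hi) = stability_slope(
                dist_family, meta, s, n_permutations=499, seed=rng_slope
            )
            block = curve.curve.assign(subject_id=s, slope=slope, slope_ci_low=lo, slope_ci_high=hi)
            curves.append(block)
        pd.concat(curves, ignore_index=True)[
            ["subject_id", "lag", "mean_similarity", "n_pairs", "slope", "slope_ci_low", "slope_ci_high"]
        ].to_csv(out / "stability.tsv", sep="\t", index=False, lineterminator="\n")

        # ---- group comparisons ---------------------------------------------
        stage = "comparisons"
        comp_values: dict[str, pd.Series] = {}
        comp_values["intra_individual"] = group_similarity(
            dist_family, meta, family_subjects, intra=True
        )
        if len(children) >= 2:
            comp_values["child_child"] = group_similarity(
                dist_family, meta, children, children
            )
        if mother:
            comp_values["child_mother"] = group_similarity(
                dist_family, meta, children, [mother]
            )
        if father:
            comp_values["child_father"] = group_similarity(
                dist_family, meta, children, [father]
            )
        if mother and father:
            comp_values["parent_parent"] = group_similarity(
                dist_family, meta, [mother, father], [mother, father]
            )
        comp_values["family_family"] = group_similarity(
            dist_all, merged_meta, family_subjects, family_subjects
        )
        surviving = set(dist_all.ids)
        cohort_members = [
            m for m in cohort_meta.subjects
            if any(s in surviving for s in cohort_meta.samples_of(m))
        ]
        comp_values["cohort_cohort"] = group_similarity(
            dist_all, merged_meta, cohort_members, cohort_members
        )
        rows = [
            {"comparison": label, "subject_id": subject, "mean_similarity": value}
            for label, series in comp_values.items()
            for subject, value in series.items()
        ]
        pd.DataFrame(rows).to_csv(
            out / "comparisons.tsv", sep="\t", index=False, lineterminator="\n"
        )
        tests = []
        if "child_child" in comp_values and "child_mother" in comp_values:
            stat, p = wilcoxon_rank_sum(
                comp_values["child_child"].to_numpy(), comp_values["child_mother"].to_numpy()
            )
            tests.append(("child_child_vs_child_mother", stat, p, False))
        if "child_child" in comp_values and "child_father" in comp_values:
            stat, p = wilcoxon_rank_sum(
                comp_values["child_child"].to_numpy(), comp_values["child_father"].to_numpy()
            )
            tests.append(("child_child_vs_child_father", stat, p, False))
        if "child_child" in comp_values and "parent_parent" in comp_values:
            stat, p = wilcoxon_rank_sum(
                comp_values["child_child"].to_numpy(), comp_values["parent_parent"].to_numpy()
            )
            tests.append(("child_child_vs_parent_parent", stat, p, False))
        if "child_mother" in comp_values and "child_father" in comp_values:
            stat, p = wilcoxon_signed_rank(
                comp_values["child_mother"].to_numpy(), comp_values["child_father"].to_numpy()
            )
            tests.append(("child_mother_vs_child_father_paired", stat, p, True))
        stat, p = wilcoxon_rank_sum(
            comp_values["family_family"].to_numpy(), comp_values["cohort_cohort"].to_numpy(),
            mode="normal_approx",
        )
        tests.append(("family_family_vs_cohort_cohort", stat, p, False))
        pd.DataFrame(tests, columns=["comparison", "statistic", "p_value", "paired"]).to_csv(
            out / "tests.tsv", sep="\t", index=False, lineterminator="\n"
        )

        # ---- classification -------------------------------------------------
        stage = "classification"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf_rel = to_relabund(rarefy(table, config.otu_depth, np.random.default_rng(s_classify)))
        labels = meta.data["subject_id"]
        full = train_individual_classifier(
            clf_rel, labels, n_trees=config.n_trees, seed=s_classify
        )
        refit = top_feature_refit(clf_rel, labels, full, k=config.top_k)
        _write_json(
            {
                "oob_error_full": full.oob_error,
                "oob_error_top_k": refit.oob_error,
                "top_k": config.top_k,
                "n_trees": config.n_trees,
                "top_features": refit.top_features(config.top_k),
                "per_subject_misclassified_full": full.per_subject_misclassified.to_dict(),
                "confusion_full": full.confusion.to_dict(),
            },
            out / "classifier.json",
        )

        # ---- functional tables, ordination, concordance ---------------------
        stage = "functional"
        fun_cfg = dataclasses.replace(config.functional, seed=s_functional)
        ko_table, opf_table, score_set, fun_truth = generate_functional_tables(
            fun_cfg, table, meta
        )
        write_shared(ko_table, out / "ko.shared")
        write_shared(opf_table, out / "opf.shared")
        mg_samples = list(ko_table.sample_ids)
        fun_depth = min(
            config.functional_depth, int(min(ko_table.depths.min(), opf_table.depths.min()))
        )
        dist_ko = distance_matrix(
            ko_table, depth=fun_depth, iters=config.functional_iters, seed=s_distko
        )
        dist_opf = distance_matrix(
            opf_table, depth=fun_depth, iters=config.functional_iters, seed=s_distopf
        )
        dist_otu_mg = dist_family.submatrix(mg_samples)

        stage = "ordination"
        ords = {}
        for name, dm in (("otu", dist_otu_mg), ("ko", dist_ko), ("opf", dist_opf)):
            result = nmds(
                dm, dim=config.nmds_dim, restarts=config.nmds_restarts, seed=s_nmds
            )
            ords[name] = result
            coords = pd.DataFrame(
                result.coordinates,
                index=list(result.ids),
                columns=[f"axis{i + 1}" for i in range(config.nmds_dim)],
            )
            coords.insert(0, "stress", result.stress)
            coords.rename_axis("sample_id").reset_index().to_csv(
                out / f"nmds_{name}.tsv", sep="\t", index=False, lineterminator="\n"
            )

        stage = "concordance"
        rng_mantel = np.random.default_rng(s_mantel)
        m_ko = mantel(dist_otu_mg, dist_ko, config.n_permutations, seed=rng_mantel)
        m_opf = mantel(dist_otu_mg, dist_opf, config.n_permutations, seed=rng_mantel)
        _write_json(
            {
                "otu_ko": {"r": m_ko.r, "p": m_ko.p, "method": m_ko.method},
                "otu_opf": {"r": m_opf.r, "p": m_opf.p, "method": m_opf.method},
                "stress": {name: o.stress for name, o in ords.items()},
                "n_permutations": config.n_permutations,
            },
            out / "concordance.json",
        )

        # ---- OPF clustering & sharing ---------------------------------------
        stage = "opf"
        sparse = scores_to_distances(score_set)
        assignment = average_neighbor(sparse, cutoff=config.opf_cutoff)
        assignment.write_list(out / "opf.list")
        sharing_rows = [
            {
                "table": "opf_clusters",
                "group": "all_members",
                "shared_fraction": opf_sharing(
                    assignment, fun_truth.orf_subject, family_subjects
                ),
            },
            {
                "table": "ko",
                "group": "all_members",
                "shared_fraction": feature_sharing(ko_table, meta, family_subjects),
            },
            {
                "table": "opf",
                "group": "all_members",
                "shared_fraction": feature_sharing(opf_table, meta, family_subjects),
            },
        ]
        if len(children) >= 2:
            sharing_rows.append(
                {
                    "table": "ko",
                    "group": "weaned_children",
                    "shared_fraction": feature_sharing(ko_table, meta, children),
                }
            )
            sharing_rows.append(
                {
                    "table": "opf",
                    "group": "weaned_children",
                    "shared_fraction": feature_sharing(opf_table, meta, children),
                }
            )
        pd.DataFrame(sharing_rows).to_csv(
            out / "sharing.tsv", sep="\t", index=False, lineterminator="\n"
        )

        # ---- manifest --------------------------------------------------------
        stage = "manifest"
        import sklearn
        import scipy

        _write_json(
            {
                "famgut_version": __version__,
                "numpy_version": np.__version__,
                "pandas_version": pd.__version__,
                "scipy_version": scipy.__version__,
                "sklearn_version": sklearn.__version__,
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "config": config.to_dict(),
                "artifacts": sorted(
                    p.name for p in out.iterdir() if p.is_file() and p.name != "FAILED"
                ),
            },
            out / "manifest.json",
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n", encoding="utf-8")
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return out


def report(out_dir) -> str:
    """Human-readable summary of a finished pipeline run."""
    out = Path(out_dir)
    lines = ["famgut pipeline summary", "=" * 24]
    cov = pd.read_csv(out / "core_coverage.tsv", sep="\t")
    truth = json.loads((out / "truth.json").read_text())
    lines.append(f"family core size: {len(truth['core_features'])} OTUs")
    lines.append("individual core sizes:")
    for _, row in cov.iterrows():
        lines.append(
            f"  {row['subject_id']:<10s} ({row['feeding']}): "
            f"{int(row['individual_core_size'])} OTUs, family-core coverage "
            f"{row['family_core_coverage_pct']:.1f}%"
        )
    non_infant = cov[cov["feeding"] != "exclusively_breastfed"]
    lines.append(
        "family-core coverage (non-infant members): "
        f"{non_infant['family_core_coverage_pct'].min():.1f}-"
        f"{non_infant['family_core_coverage_pct'].max():.1f}%"
    )
    clf = json.loads((out / "classifier.json").read_text())
    lines.append(
        f"random forest OOB error: {100 * clf['oob_error_full']:.1f}% (all features), "
        f"{100 * clf['oob_error_top_k']:.1f}% (top {clf['top_k']})"
    )
    conc = json.loads((out / "concordance.json").read_text())
    lines.append(
        "NMDS stress: "
        + ", ".join(f"{k}={v:.3f}" for k, v in sorted(conc["stress"].items()))
    )
    lines.append(
        f"Mantel concordance: OTU-KO r={conc['otu_ko']['r']:.2f} "
        f"(p={conc['otu_ko']['p']:.3f}), OTU-OPF r={conc['otu_opf']['r']:.2f} "
        f"(p={conc['otu_opf']['p']:.3f})"
    )
    sharing = pd.read_csv(out / "sharing.tsv", sep="\t")
    for _, row in sharing.iterrows():
        lines.append(
            f"shared {row['table']} ({row['group']}): {100 * row['shared_fraction']:.1f}%"
        )
    comp = pd.read_csv(out / "comparisons.tsv", sep="\t")
    for label, block in comp.groupby("comparison"):
        lines.append(
            f"median similarity [{label}]: {block['mean_similarity'].median():.2f} "
            f"(n={len(block)})"
        )
    tests = pd.read_csv(out / "tests.tsv", sep="\t")
    for _, row in tests.iterrows():
        lines.append(f"test {row['comparison']}: p={row['p_value']:.3f}")
    return "\n".join(lines) + "\n"
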