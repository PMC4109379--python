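import warnings

import numpy as np
import pandas as pd
import pytest

from famgut import (
    CohortConfig,
    FamilyConfig,
    FunctionalConfig,
    average_neighbor,
    cohort_core,
    distance_matrix,
    generate_cohort,
    generate_family,
    generate_functional_tables,
    generate_infant_series,
    mantel,
    rarefied_inverse_simpson,
    scores_to_distances,
    to_relabund,
)
from famgut.simulate import SubjectSpec


class TestFamilyGenerator:
    def test_bit_reproducible(self):
        a, _, _ = generate_family(FamilyConfig(seed=3))
        b, _, _ = generate_family(FamilyConfig(seed=3))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_metadata_matches_table(self, family):
        table, meta, _ = family
        assert set(table.sample_ids) == set(meta.sample_ids)
        assert len(meta.subjects) == 8
        for subject in meta.subjects:
            assert len(meta.samples_of(subject)) == 26

    def test_diversity_ordering_infant_toddler_weaned(self, family):
        table, meta, _ = family
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = rarefied_inverse_simpson(table, depth=1827, iters=5, seed=0)
        by_subject = rep.per_sample.groupby(
            meta.data.loc[list(rep.per_sample.index), "subject_id"].to_numpy()
        ).mean()
        weaned_mean = by_subject[["child3", "child4", "child5", "child6"]].mean()
        assert by_subject["infant"] < by_subject["toddler"] < weaned_mean

    def test_high_concentration_limit_is_stable(self):
        # without overdispersion, day-to-day dissimilarity reduces to
        # multinomial sampling noise, which deep subsampling drives to ~0
        cfg = FamilyConfig(
            subjects=(SubjectSpec("s1", "weaned", tuple(range(1, 11))),),
            concentration=1e7,
            depth_mean=60_000.0,
            depth_sigma=0.05,
            seed=0,
        )
        table, meta, _ = generate_family(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dm = distance_matrix(table, depth=40_000, iters=3, seed=1)
        assert dm.condensed().max() < 0.01

    def test_inconsistent_masses_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FamilyConfig(core_mass=0.9)


class TestInfantSeries:
    def _dominant_per_day(self, table, dominants):
        share = table.data[list(dominants)].div(table.depths, axis=0)
        return share.idxmax(axis=1)

    def test_no_switching_keeps_one_dominant(self):
        cfg = FamilyConfig(infant_switch_prob=0.0, seed=1)
        table = generate_infant_series(cfg)
        _, _, truth = generate_family(
            FamilyConfig(
                infant_switch_prob=0.0, seed=1,
                subjects=tuple(s for s in cfg.subjects if s.feeding == "exclusively_breastfed"),
            )
        )
        dominant = self._dominant_per_day(table, truth.infant_dominants)
        assert dominant.nunique() == 1

    def test_certain_switching_alternates_daily(self):
        subjects = tuple(
            s for s in FamilyConfig().subjects if s.feeding == "exclusively_breastfed"
        )
        cfg = FamilyConfig(infant_switch_prob=1.0, seed=2, subjects=subjects)
        table = generate_infant_series(cfg)
        _, _, truth = generate_family(cfg)
        dominant = self._dominant_per_day(table, truth.infant_dominants).to_numpy()
        assert all(dominant[i] != dominant[i + 1] for i in range(len(dominant) - 1))

    def test_flip_frequency_tracks_switch_probability(self):
        subjects = (SubjectSpec("infant", "exclusively_breastfed", tuple(range(1, 301))),)
        cfg = FamilyConfig(infant_switch_prob=0.3, seed=3, subjects=subjects)
        _, _, truth = generate_family(cfg)
        traj = truth.infant_trajectory["infant"]
        states = [traj[d] for d in sorted(traj)]
        flips = np.mean([states[i] != states[i + 1] for i in range(len(states) - 1)])
        assert flips == pytest.approx(0.3, abs=0.08)  # ~3 SE at n=299


class TestCohortGenerator:
    def test_member_count_and_one_sample_each(self):
        table, meta, _ = generate_cohort(CohortConfig(n_members=25, seed=4))
        assert len(meta.subjects) == 25
        assert table.shape[0] == 25

    def test_planted_common_features_recovered(self):
        table, meta, truth = generate_cohort(CohortConfig(n_members=40, seed=5))
        core = cohort_core(to_relabund(table), meta)
        assert core.feature_ids == frozenset(truth.common_features)

    def test_overlap_with_family_core_is_configurable(self, family):
        _, _, fam_truth = family
        _, _, truth = generate_cohort(
            CohortConfig(n_members=10, common_overlap_with_family_core=3, seed=6), fam_truth
        )
        overlap = set(truth.common_features) & set(fam_truth.core_features)
        assert len(overlap) == 3


class TestFunctionalGenerator:
    def test_full_association_reproduces_taxonomic_distances(self, family):
        table, meta, _ = family
        ko, _, _, _ = generate_functional_tables(
            FunctionalConfig(association=1.0, seed=7), table, meta
        )
        depth = int(min(table.depths.min(), ko.depths.min()))
        d_tax = distance_matrix(
            table.subset_samples(list(ko.sample_ids)), depth, iters=2, seed=8
        )
        d_ko = distance_matrix(ko, depth, iters=2, seed=8)
        res = mantel(d_tax, d_ko, n_permutations=99, seed=9)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_zero_association_gives_no_concordance(self, family, family_dist):
        table, meta, _ = family
        ko, _, _, _ = generate_functional_tables(
            FunctionalConfig(association=0.0, seed=10), table, meta
        )
        d_ko = distance_matrix(ko, int(ko.depths.min()), iters=2, seed=11)
        d_tax = family_dist.submatrix(list(ko.sample_ids))
        res = mantel(d_tax, d_ko, n_permutations=199, seed=12)
        assert abs(res.r) < 0.25

    def test_default_association_gives_concordance_signal(self, family, family_dist):
        table, meta, _ = family
        ko, opf, _, _ = generate_functional_tables(FunctionalConfig(seed=13), table, meta)
        d_ko = distance_matrix(ko, int(ko.depths.min()), iters=2, seed=14)
        d_tax = family_dist.submatrix(list(ko.sample_ids))
        res = mantel(d_tax, d_ko, n_permutations=199, seed=15)
        assert res.r > 0.3
        assert res.p <= 0.05

    def test_planted_protein_families_recovered(self, family):
        table, meta, _ = family
        _, _, scores, truth = generate_functional_tables(
            FunctionalConfig(seed=16), table, meta
        )
        assignment = average_neighbor(scores_to_distances(scores), cutoff=0.25)
        ours = {frozenset(g) for g in assignment.clusters()}
        assert ours == {frozenset(f) for f in truth.protein_families}

    def test_universal_family_fraction_recovered_by_sharing(self, family):
        from famgut import opf_sharing

        table, meta, _ = family
        cfg = FunctionalConfig(universal_family_fraction=0.3, n_protein_families=20, seed=17)
        _, _, scores, truth = generate_functional_tables(cfg, table, meta)
        assignment = average_neighbor(scores_to_distances(scores), cutoff=0.25)
        shared = opf_sharing(assignment, truth.orf_subject, list(meta.subjects))
        assert shared == pytest.approx(0.3, abs=1e-12)

    def test_ko_tables_more_shared_than_opf_tables(self, family):
        from famgut import feature_sharing

        table, meta, _ = family
        ko, opf, _, _ = generate_functional_tables(FunctionalConfig(seed=18), table, meta)
        subjects = list(meta.subjects)
        assert feature_sharing(ko, meta, subjects) > feature_sharing(opf, meta, subjects)
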