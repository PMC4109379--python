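import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famgut import (
    CoreSet,
    CountTable,
    cohort_core,
    core_coverage,
    individual_core,
    shared_core,
)
from famgut.tables import RelAbundTable, SampleMetadata


def _meta(subjects):
    rows = []
    for subject, n in subjects.items():
        for day in range(1, n + 1):
            rows.append(
                {"sample_id": f"{subject}_d{day}", "subject_id": subject,
                 "day": day, "cohort": "family", "feeding": "weaned"}
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    df["day"] = df["day"].astype("Int64")
    return SampleMetadata(df)


def _rel_with_abundances(subject, values, filler="zzz_filler"):
    """One feature ('feat') at given per-sample abundances; filler absorbs the rest."""
    idx = [f"{subject}_d{i + 1}" for i in range(len(values))]
    data = pd.DataFrame({"feat": values, filler: [1 - v for v in values]},
                        index=pd.Index(idx, name="Group"))
    return RelAbundTable(data)


class TestIndividualCore:
    def test_25_of_26_meets_95pct(self):
        values = [0.01] * 25 + [0.0]
        rel = _rel_with_abundances("p", values)
        core = individual_core(rel, _meta({"p": 26}), "p")
        assert "feat" in core.feature_ids  # 25/26 = 0.9615 >= 0.95

    def test_24_of_26_misses_95pct(self):
        values = [0.01] * 24 + [0.0, 0.0]
        rel = _rel_with_abundances("p", values)
        core = individual_core(rel, _meta({"p": 26}), "p")
        assert "feat" not in core.feature_ids  # 24/26 = 0.923 < 0.95

    def test_exactly_at_abundance_floor_is_excluded(self):
        rel = _rel_with_abundances("p", [0.0005] * 26)
        core = individual_core(rel, _meta({"p": 26}), "p")
        assert "feat" not in core.feature_ids  # "over" is strict

    def test_just_above_floor_is_included(self):
        rel = _rel_with_abundances("p", [0.00051] * 26)
        core = individual_core(rel, _meta({"p": 26}), "p")
        assert "feat" in core.feature_ids

    def test_unknown_subject_rejected(self):
        rel = _rel_with_abundances("p", [0.01] * 3)
        with pytest.raises(KeyError, match="ghost"):
            individual_core(rel, _meta({"p": 3}), "ghost")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_both_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.dirichlet(np.ones(8), size=10)
        rel = RelAbundTable(
            pd.DataFrame(raw, index=pd.Index([f"p_d{i + 1}" for i in range(10)], name="Group"),
                         columns=[f"f{j}" for j in range(8)])
        )
        meta = _meta({"p": 10})
        loose = individual_core(rel, meta, "p", abund_thresh=0.01, prevalence_thresh=0.5)
        tighter_abund = individual_core(rel, meta, "p", abund_thresh=0.05, prevalence_thresh=0.5)
        tighter_prev = individual_core(rel, meta, "p", abund_thresh=0.01, prevalence_thresh=0.9)
        assert tighter_abund.feature_ids <= loose.feature_ids
        assert tighter_prev.feature_ids <= loose.feature_ids


class TestSharedCore:
    def _core(self, feats, scope):
        return CoreSet(frozenset(feats), 0.0005, 0.95, scope)

    def test_disjoint_cores_intersect_to_empty(self):
        out = shared_core([self._core("ab", "x"), self._core("cd", "y")])
        assert out.feature_ids == frozenset()

    def test_identical_cores_unchanged(self):
        out = shared_core([self._core("abc", "x"), self._core("abc", "y")])
        assert out.feature_ids == frozenset("abc")

    def test_subset_of_every_input(self):
        cores = [self._core("abcd", "x"), self._core("bcde", "y"), self._core("bcf", "z")]
        out = shared_core(cores)
        for c in cores:
            assert out.feature_ids <= c.feature_ids

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            shared_core([self._core("ab", "x")])

    def test_planted_family_core_recovered(self, family, family_rel):
        table, meta, truth = family
        subjects = [s for s in meta.subjects if meta.feeding_of(s) != "exclusively_breastfed"]
        cores = [individual_core(family_rel, meta, s) for s in subjects]
        fam_core = shared_core(cores)
        assert fam_core.feature_ids == frozenset(truth.core_features)


class TestCoverage:
    def _table(self):
        data = pd.DataFrame(
            [[60, 30, 10], [50, 25, 25]],
            index=pd.Index(["p_d1", "p_d2"], name="Group"), columns=["a", "b", "c"],
        )
        return CountTable(data)

    def test_all_features_is_100(self):
        core = CoreSet(frozenset("abc"), 0.0005, 0.95, "p")
        assert core_coverage(self._table(), core, _meta({"p": 2}), "p") == 100.0

    def test_empty_core_is_0(self):
        core = CoreSet(frozenset(), 0.0005, 0.95, "p")
        assert core_coverage(self._table(), core, _meta({"p": 2}), "p") == 0.0

    def test_monotone_in_core_size(self):
        meta = _meta({"p": 2})
        small = CoreSet(frozenset("a"), 0.0005, 0.95, "p")
        large = CoreSet(frozenset("ab"), 0.0005, 0.95, "p")
        assert core_coverage(self._table(), small, meta, "p") <= core_coverage(
            self._table(), large, meta, "p"
        )

    def test_planted_core_mass_recovered(self, family, family_rel):
        table, meta, truth = family
        core = CoreSet(frozenset(truth.core_features), 0.0005, 0.95, "family")
        for subject in meta.subjects:
            if meta.feeding_of(subject) in ("weaned", "adult"):
                cov = core_coverage(table, core, meta, subject)
                assert cov == pytest.approx(100 * truth.core_mass, abs=5.0)


class TestCohortCore:
    def _cohort(self, values_by_member):
        rows, meta_rows = [], []
        for member, vals in values_by_member.items():
            rows.append(vals)
            meta_rows.append(
                {"sample_id": f"{member}_s1", "subject_id": member, "day": pd.NA,
                 "cohort": "community", "feeding": "adult"}
            )
        df = pd.DataFrame(
            rows, index=pd.Index([f"{m}_s1" for m in values_by_member], name="Group"),
            columns=[f"f{j}" for j in range(len(rows[0]))],
        )
        meta_df = pd.DataFrame(meta_rows).set_index("sample_id")
        meta_df["day"] = meta_df["day"].astype("Int64")
        return RelAbundTable(df), SampleMetadata(meta_df)

    def test_feature_in_all_members_kept(self):
        rel, meta = self._cohort({"m1": [0.5, 0.5], "m2": [0.6, 0.4]})
        core = cohort_core(rel, meta, member_prevalence=0.95)
        assert core.feature_ids == frozenset({"f0", "f1"})

    def test_feature_in_half_the_members_dropped(self):
        rel, meta = self._cohort({"m1": [1.0, 0.0], "m2": [0.5, 0.5]})
        core = cohort_core(rel, meta, member_prevalence=0.95)
        assert core.feature_ids == frozenset({"f0"})

    def test_planted_common_features_recovered(self):
        from famgut import CohortConfig, generate_cohort, to_relabund

        table, meta, truth = generate_cohort(CohortConfig(n_members=40, seed=5))
        rel = to_relabund(table)
        core = cohort_core(rel, meta)
        assert core.feature_ids == frozenset(truth.common_features)
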