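import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famgut import CountTable, merge_tables, rarefy, read_design, read_shared, to_relabund, write_shared
from famgut.tables import SharedFormatError


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestSharedIO:
    def test_round_trip_identity(self, tiny_table, tmp_path):
        path = tmp_path / "t.shared"
        write_shared(tiny_table, path)
        back = read_shared(path)
        pd.testing.assert_frame_equal(back.data, tiny_table.data)
        # writing the parsed table reproduces the file byte for byte
        path2 = tmp_path / "t2.shared"
        write_shared(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_depths_are_row_sums(self, tiny_table, tmp_path):
        path = tmp_path / "t.shared"
        write_shared(tiny_table, path)
        table = read_shared(path)
        assert table.shape == (2, 3)
        assert table.depths.tolist() == [10, 10]

    def test_numotus_mismatch_is_format_error(self, tmp_path):
        p = _write(
            tmp_path, "bad.shared",
            "label\tGroup\tnumOtus\tOtu1\tOtu2\tOtu3\tOtu4\n0.03\ts1\t5\t1\t2\t3\t4\n",
        )
        with pytest.raises(SharedFormatError, match="numOtus=5"):
            read_shared(p)

    def test_malformed_header(self, tmp_path):
        p = _write(tmp_path, "bad.shared", "foo\tbar\n0.03\ts1\t1\t2\n")
        with pytest.raises(SharedFormatError, match="header"):
            read_shared(p)

    def test_non_integer_cell_names_row_and_column(self, tmp_path):
        p = _write(
            tmp_path, "bad.shared",
            "label\tGroup\tnumOtus\tOtu1\tOtu2\n0.03\ts1\t2\t1\t2.5\n",
        )
        with pytest.raises(ValueError, match="'s1'.*'Otu2'"):
            read_shared(p)

    def test_negative_cell(self, tmp_path):
        p = _write(
            tmp_path, "bad.shared",
            "label\tGroup\tnumOtus\tOtu1\tOtu2\n0.03\ts1\t2\t1\t-2\n",
        )
        with pytest.raises(ValueError, match="negative"):
            read_shared(p)

    def test_duplicate_group_strict(self, tmp_path):
        text = (
            "label\tGroup\tnumOtus\tOtu1\n"
            "0.03\ts1\t1\t5\n0.03\ts1\t1\t6\n"
        )
        p = _write(tmp_path, "dup.shared", text)
        with pytest.raises(SharedFormatError, match="duplicate Group"):
            read_shared(p, strict=True)
        with pytest.warns(UserWarning, match="duplicate Group"):
            table = read_shared(p, strict=False)
        assert table.data.loc["s1", "Otu1"] == 5

    def test_empty_feature_set(self, tmp_path):
        table = CountTable(
            pd.DataFrame(index=pd.Index(["s1"], name="Group"), columns=[], dtype=np.int64)
        )
        path = tmp_path / "empty.shared"
        write_shared(table, path)
        assert path.read_text().splitlines()[1] == "0.03\ts1\t0"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_property_on_random_tables(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        n_s, n_f = int(rng.integers(1, 6)), int(rng.integers(1, 8))
        data = pd.DataFrame(
            rng.integers(0, 50, size=(n_s, n_f)),
            index=pd.Index([f"s{i}" for i in range(n_s)], name="Group"),
            columns=[f"Otu{j:03d}" for j in range(n_f)],
        )
        table = CountTable(data)
        path = tmp_path_factory.mktemp("rt") / "x.shared"
        write_shared(table, path)
        pd.testing.assert_frame_equal(read_shared(path).data, table.data)


class TestDesign:
    DESIGN = (
        "sample_id\tsubject_id\tday\tcohort\tfeeding\n"
        + "\n".join(
            f"p{i}_d1\tp{i}\t1\tfamily\tweaned" for i in range(1, 9)
        )
        + "\n"
    )

    def test_eight_subjects(self, tmp_path):
        meta = read_design(_write(tmp_path, "d.tsv", self.DESIGN))
        assert len(meta.subjects) == 8

    def test_duplicate_subject_day_rejected(self, tmp_path):
        text = (
            "sample_id\tsubject_id\tday\tcohort\tfeeding\n"
            "a\tp1\t1\tfamily\tweaned\nb\tp1\t1\tfamily\tweaned\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_design(_write(tmp_path, "d.tsv", text))

    def test_unknown_feeding_rejected(self, tmp_path):
        text = (
            "sample_id\tsubject_id\tday\tcohort\tfeeding\n"
            "a\tp1\t1\tfamily\tvegan\n"
        )
        with pytest.raises(ValueError, match="feeding"):
            read_design(_write(tmp_path, "d.tsv", text))

    def test_community_rows_may_lack_day(self, tmp_path):
        text = (
            "sample_id\tsubject_id\tday\tcohort\tfeeding\n"
            "a\tp1\t1\tfamily\tweaned\nb\tc1\t\tcommunity\tadult\n"
        )
        meta = read_design(_write(tmp_path, "d.tsv", text))
        assert meta.subjects_in_cohort("community") == ("c1",)
        with pytest.raises(ValueError, match="no collection day"):
            meta.day_of("b")


class TestRarefy:
    def test_identity_at_exact_depth(self, tiny_table):
        out = rarefy(tiny_table, 10, seed=0)
        pd.testing.assert_frame_equal(out.data, tiny_table.data)

    def test_rows_sum_to_depth_and_never_exceed_cells(self, rng):
        data = pd.DataFrame(
            rng.integers(0, 200, size=(6, 10)) + 1,
            index=pd.Index([f"s{i}" for i in range(6)], name="Group"),
            columns=[f"f{j}" for j in range(10)],
        )
        table = CountTable(data)
        out = rarefy(table, 100, seed=1)
        assert (out.depths == 100).all()
        assert (out.data.to_numpy() <= table.data.loc[out.data.index].to_numpy()).all()

    def test_shallow_samples_dropped_with_warning(self, tiny_table):
        deep = tiny_table.data.copy()
        deep.loc["s1"] = [500, 300, 200]
        table = CountTable(deep)
        with pytest.warns(UserWarning, match="dropping 1 sample"):
            out = rarefy(table, 100, seed=0)
        assert out.sample_ids == ("s1",)

    def test_nonpositive_depth_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="depth"):
            rarefy(tiny_table, 0)

    def test_hypergeometric_marginal(self):
        # subsampling (90, 10) to depth 10: E[count of feature 1] = 9
        table = CountTable(
            pd.DataFrame([[90, 10]], index=pd.Index(["s"], name="Group"), columns=["a", "b"])
        )
        rng = np.random.default_rng(3)
        draws = [rarefy(table, 10, rng).data.loc["s", "a"] for _ in range(2000)]
        mean = np.mean(draws)
        # SE of the mean ~ sqrt(Var_hypergeom)/sqrt(2000) ~ 0.02
        assert abs(mean - 9.0) < 0.07

    def test_deterministic_given_seed(self, rng):
        data = pd.DataFrame(
            rng.integers(1, 100, size=(4, 8)),
            index=pd.Index(list("abcd"), name="Group"),
            columns=[f"f{j}" for j in range(8)],
        )
        table = CountTable(data)
        a = rarefy(table, 50, seed=9)
        b = rarefy(table, 50, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestRelAbund:
    def test_hand_case(self):
        table = CountTable(
            pd.DataFrame([[1, 1], [3, 1]], index=pd.Index(["x", "y"], name="Group"),
                         columns=["a", "b"])
        )
        rel = to_relabund(table)
        assert rel.data.loc["x"].tolist() == [0.5, 0.5]
        assert rel.data.loc["y"].tolist() == [0.75, 0.25]

    def test_zero_row_flagged_and_excluded(self):
        table = CountTable(
            pd.DataFrame([[1, 1], [0, 0]], index=pd.Index(["x", "y"], name="Group"),
                         columns=["a", "b"])
        )
        with pytest.warns(UserWarning, match="zero-depth"):
            rel = to_relabund(table)
        assert rel.dropped == ("y",)
        assert rel.sample_ids == ("x",)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rows_sum_to_one_after_rarefaction(self, seed):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            rng.integers(1, 40, size=(3, 6)),
            index=pd.Index(["s1", "s2", "s3"], name="Group"),
            columns=[f"f{j}" for j in range(6)],
        )
        table = CountTable(data)
        depth = int(table.depths.min())
        rel = to_relabund(rarefy(table, depth, seed=seed))
        assert np.allclose(rel.data.sum(axis=1), 1.0, atol=1e-12)


def test_merge_tables_union_and_overlap_error(tiny_table):
    other = CountTable(
        pd.DataFrame([[4]], index=pd.Index(["s3"], name="Group"), columns=["Otu009"])
    )
    merged = merge_tables(tiny_table, other)
    assert merged.shape == (3, 4)
    assert merged.data.loc["s3", "Otu001"] == 0
    assert merged.data.loc["s1", "Otu009"] == 0
    with pytest.raises(ValueError, match="both tables"):
        merge_tables(tiny_table, tiny_table)


def test_count_table_invariants():
    idx = pd.Index(["s1", "s1"], name="Group")
    with pytest.raises(ValueError, match="duplicate sample"):
        CountTable(pd.DataFrame([[1], [2]], index=idx, columns=["a"]))
    with pytest.raises(ValueError, match="non-negative"):
        CountTable(pd.DataFrame([[-1]], index=pd.Index(["s1"], name="Group"), columns=["a"]))
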