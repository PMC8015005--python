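import numpy as np
import pandas as pd
import pytest

from polystest import (
    ComparisonSpec,
    Design,
    ExpressionMatrix,
    filter_min_observed,
    load_matrix,
    log2_transform,
    mean_log_ratio,
    median_normalize,
    sum_technical_replicates,
    write_matrix,
)

from conftest import make_matrix


DESIGN = {"A": ["a1", "a2"], "B": ["b1", "b2"]}


def write_tsv(path, text):
    path.write_text(text)
    return path


class TestLoadMatrix:
    def test_empty_cell_parses_as_missing(self, tmp_path):
        f = write_tsv(
            tmp_path / "m.tsv",
            "id\ta1\ta2\tb1\tb2\np1\t1\t2\t3\t4\np2\t5\t\t7\t8\np3\t9\t10\t11\t12\n",
        )
        m = load_matrix(f, DESIGN)
        assert int(np.isnan(m.values).sum()) == 1
        assert np.isnan(m.values[1, 1])

    def test_na_tokens_parse_as_missing(self, tmp_path):
        f = write_tsv(
            tmp_path / "m.tsv",
            "id\ta1\ta2\tb1\tb2\np1\t1\tNaN\t3\t4\np2\t5\t6\tNA\tnot_a_number\n",
        )
        m = load_matrix(f, DESIGN)
        assert int(np.isnan(m.values).sum()) == 3
        assert np.isfinite(m.values[0, [0, 2, 3]]).all()

    def test_missing_design_column_errors(self, tmp_path):
        f = write_tsv(tmp_path / "m.tsv", "id\ta1\ta2\tb1\np1\t1\t2\t3\n")
        with pytest.raises(ValueError, match="b2"):
            load_matrix(f, DESIGN)

    def test_duplicate_feature_ids_named_in_error(self, tmp_path):
        f = write_tsv(
            tmp_path / "m.tsv",
            "id\ta1\ta2\tb1\tb2\npX\t1\t2\t3\t4\npX\t5\t6\t7\t8\n",
        )
        with pytest.raises(ValueError, match="pX"):
            load_matrix(f, DESIGN)

    @pytest.mark.parametrize("ext", ["tsv", "csv"])
    def test_round_trip_preserves_values_and_missingness(self, tmp_path, ext):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((20, 4))
        vals[rng.random((20, 4)) < 0.25] = np.nan
        m = make_matrix(vals, conditions=DESIGN)
        path = tmp_path / f"m.{ext}"
        write_matrix(m, path)
        m2 = load_matrix(path, DESIGN)
        assert m2.feature_ids == m.feature_ids
        np.testing.assert_array_equal(np.isnan(m2.values), np.isnan(vals))
        np.testing.assert_allclose(m2.values[~np.isnan(vals)], vals[~np.isnan(vals)])


class TestDesign:
    def test_gap_in_replicate_indices_rejected(self):
        with pytest.raises(ValueError, match="without gaps"):
            Design({"s1": ("A", 1), "s2": ("A", 3)})

    def test_paired_comparison_requires_equal_replicates(self):
        d = Design.from_conditions({"A": ["a1", "a2"], "B": ["b1", "b2", "b3"]})
        with pytest.raises(ValueError, match="equal replicate"):
            ComparisonSpec("A", "B", paired=True).validate(d)

    def test_infinite_cells_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            make_matrix([[1.0, np.inf, 2.0, 3.0]])


class TestTechnicalReplicates:
    def test_sum_ignores_missing_and_keeps_all_missing(self):
        vals = [[2.0, 4.0, np.nan, 1.0, 1.0, 1.0], [np.nan, np.nan, np.nan, 2.0, 2.0, 2.0]]
        labels = [f"a{i}" for i in range(1, 7)]
        m = make_matrix(vals, conditions={"A": labels[:3], "B": labels[3:]})
        groups = {labels[i]: ("gA" if i < 3 else "gB") for i in range(6)}
        out = sum_technical_replicates(m, groups)
        assert out.values.shape == (2, 2)
        assert out.values[0, 0] == 6.0
        assert np.isnan(out.values[1, 0])
        assert out.values[1, 1] == 6.0

    def test_unmapped_sample_errors(self, toy_matrix):
        with pytest.raises(ValueError, match="without a technical-replicate group"):
            sum_technical_replicates(toy_matrix, {"A_1": "g"})


class TestTransforms:
    def test_log2_known_points_and_zero_handling(self):
        m = make_matrix([[8.0, 1.0, 0.0, 4.0]])
        out = log2_transform(m)
        assert out.values[0, 0] == 3.0
        assert out.values[0, 1] == 0.0
        assert np.isnan(out.values[0, 2])
        with pytest.raises(ValueError):
            log2_transform(m, on_nonpositive="error")

    def test_median_normalize_shifts_and_ignores_missing(self):
        m = make_matrix([[1.0, 1.0, 0.0, 1.0], [2.0, np.nan, 0.0, 2.0], [3.0, 3.0, 0.0, 3.0]])
        out = median_normalize(m)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])
        # column with observed (1, missing, 3): median of observed is 2
        np.testing.assert_allclose(out.values[[0, 2], 1], [-1.0, 1.0])
        assert np.isnan(out.values[1, 1])
        # already-centred column unchanged
        np.testing.assert_allclose(out.values[:, 2], [0.0, 0.0, 0.0])

    def test_median_normalize_idempotent(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((30, 6)) + 3.0
        vals[rng.random((30, 6)) < 0.2] = np.nan
        m = median_normalize(make_matrix(vals))
        again = median_normalize(m)
        np.testing.assert_allclose(
            again.values[~np.isnan(vals)], m.values[~np.isnan(vals)], atol=1e-12
        )
        assert np.nanmax(np.abs(np.nanmedian(m.values, axis=0))) < 1e-12

    def test_all_missing_column_errors(self):
        with pytest.raises(ValueError, match="no observed values"):
            median_normalize(make_matrix([[np.nan, 1.0, 2.0, 3.0]]))


class TestFilter:
    def test_min_observed_threshold(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((10, 18))
        vals[0, 5:] = np.nan  # 5 observed of 18 -> removed at min_total=6
        labels = [f"s{i}" for i in range(18)]
        m = make_matrix(vals, conditions={"A": labels[:9], "B": labels[9:]})
        out = filter_min_observed(m, 6)
        assert "f1" not in out.feature_ids
        assert out.n_features == 9

    def test_noop_and_order_preserved(self, toy_matrix):
        out = filter_min_observed(toy_matrix, 0)
        assert out.feature_ids == toy_matrix.feature_ids
        out2 = filter_min_observed(toy_matrix, 5)
        assert out2.feature_ids == [f for f, k in zip(
            toy_matrix.feature_ids, (~np.isnan(toy_matrix.values)).sum(axis=1) >= 5) if k]

    def test_monotone_in_min_total(self, toy_matrix):
        kept = [set(filter_min_observed(toy_matrix, k).feature_ids) for k in range(7)]
        for lo, hi in zip(kept, kept[1:]):
            assert hi <= lo

    def test_meta_filter(self):
        meta = pd.DataFrame({"peptides": [1, 2, 5]}, index=["f1", "f2", "f3"])
        m = make_matrix(np.ones((3, 4)), meta=meta)
        out = filter_min_observed(m, 0, min_meta=("peptides", 2))
        assert out.feature_ids == ["f2", "f3"]


class TestMeanLogRatio:
    def test_unpaired_difference_of_means(self):
        m = make_matrix([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]])
        np.testing.assert_allclose(mean_log_ratio(m, ComparisonSpec("A", "B")), [1.0])

    def test_all_missing_side_is_undefined(self):
        m = make_matrix([[np.nan, np.nan, np.nan, 1.0, 2.0, 3.0]])
        assert np.isnan(mean_log_ratio(m, ComparisonSpec("A", "B"))[0])

    def test_paired_uses_complete_pairs_only(self):
        m = make_matrix([[1.0, 2.0, np.nan, 2.0, 4.0, 5.0]])
        out = mean_log_ratio(m, ComparisonSpec("A", "B", paired=True))
        np.testing.assert_allclose(out, [1.5])

    def test_antisymmetric_under_condition_swap(self, toy_matrix):
        fwd = mean_log_ratio(toy_matrix, ComparisonSpec("A", "B"))
        rev = mean_log_ratio(toy_matrix, ComparisonSpec("B", "A"))
        both = np.isfinite(fwd) & np.isfinite(rev)
        np.testing.assert_allclose(fwd[both], -rev[both], atol=1e-12)
        assert (np.isnan(fwd) == np.isnan(rev)).all()
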