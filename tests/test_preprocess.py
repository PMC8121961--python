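"""Ingestion and preprocessing: trimming, reversal, standardization, WIM/WISD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import slodr
from slodr.matrix import ScoreMatrix, ScoreMatrixError


def _matrix(values, ids=None, cols=None) -> ScoreMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ids = ids or [f"p{i}" for i in range(n)]
    cols = cols or [f"m{j}" for j in range(p)]
    return ScoreMatrix(pd.DataFrame(values, index=pd.Index(ids, name="person_id"), columns=cols))


class TestReadWrite:
    def test_round_trip_preserves_matrix(self, toy_matrix, tmp_path):
        path = tmp_path / "scores.csv"
        slodr.write_scores(toy_matrix, path)
        back = slodr.read_scores(path)
        pd.testing.assert_frame_equal(back.data, toy_matrix.data)

    def test_blank_cell_becomes_missing(self, tmp_path):
        path = tmp_path / "gap.csv"
        path.write_text("person_id,m1,m2,m3\na,1,2,3\nb,4,,6\nc,7,8,9\nd,1,1,1\n")
        m = slodr.read_scores(path)
        assert m.data.isna().sum().sum() == 1
        assert np.isnan(m.data.loc["b", "m2"])

    def test_duplicate_id_error_names_id(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("person_id,m1,m2,m3\nx,1,2,3\nx,4,5,6\n")
        with pytest.raises(ScoreMatrixError, match="x"):
            slodr.read_scores(path)

    def test_non_numeric_cell_error_names_location(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("person_id,m1,m2,m3\na,1,2,3\nb,4,oops,6\n")
        with pytest.raises(ScoreMatrixError, match="m2"):
            slodr.read_scores(path)

    def test_too_few_measures_rejected(self, tmp_path):
        path = tmp_path / "narrow.csv"
        path.write_text("person_id,m1,m2\na,1,2\nb,3,4\n")
        with pytest.raises(ScoreMatrixError, match="3 measures"):
            slodr.read_scores(path)


class TestReverseScores:
    def test_negates_only_listed_columns(self, toy_matrix):
        out = slodr.reverse_scores(toy_matrix, ["m1"])
        assert np.array_equal(out.data["m1"], -toy_matrix.data["m1"])
        assert np.array_equal(out.data["m2"], toy_matrix.data["m2"])

    def test_involution(self, toy_matrix):
        twice = slodr.reverse_scores(
            slodr.reverse_scores(toy_matrix, ["m1", "m3"]), ["m1", "m3"]
        )
        pd.testing.assert_frame_equal(twice.data, toy_matrix.data)

    def test_preserves_sd_and_flips_skewness(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.exponential(size=(200, 3)))
        out = slodr.reverse_scores(m, ["m0"])
        assert out.data["m0"].std() == pytest.approx(m.data["m0"].std())
        assert stats.skew(out.data["m0"]) == pytest.approx(-stats.skew(m.data["m0"]))

    def test_unknown_column(self, toy_matrix):
        with pytest.raises(ScoreMatrixError, match="nope"):
            slodr.reverse_scores(toy_matrix, ["nope"])


class TestTimesToSpeed:
    def test_distance_over_time(self):
        m = _matrix([[10.0, 300.0, 1.0], [12.5, 250.0, 2.0]], cols=["r100", "r1500", "other"])
        out = slodr.times_to_speed(m, {"r100": 100.0, "r1500": 1500.0})
        assert out.data["r100"].tolist() == [10.0, 8.0]
        assert out.data["r1500"].tolist() == [5.0, 6.0]
        assert out.data["other"].tolist() == [1.0, 2.0]

    def test_non_positive_time_error_names_row(self):
        m = _matrix([[10.0, 1, 1], [0.0, 1, 1]], ids=["a", "b"], cols=["t", "x", "y"])
        with pytest.raises(ScoreMatrixError, match="b"):
            slodr.times_to_speed(m, {"t": 100.0})


class TestPercentileTrim:
    def test_trim_count_near_expected_rate(self):
        rng = np.random.default_rng(42)
        m = _matrix(rng.standard_normal((250, 4)))  # 1000 pooled cells
        _, deleted = slodr.percentile_trim(m, 1, 99)
        # binomial(1000, 0.02) 99% interval
        assert 9 <= deleted <= 32

    def test_full_range_deletes_nothing(self, toy_matrix):
        out, deleted = slodr.percentile_trim(toy_matrix, 0, 100)
        assert deleted == 0
        pd.testing.assert_frame_equal(out.data, toy_matrix.data)

    def test_matches_brute_force_on_uniform_integers(self):
        vals = np.arange(1, 101, dtype=float).reshape(25, 4)
        m = _matrix(vals)
        out, deleted = slodr.percentile_trim(m, 1, 99)
        lo, hi = np.percentile(vals.ravel(), [1, 99])
        expected = ((vals < lo) | (vals > hi))
        assert deleted == expected.sum()
        assert np.array_equal(np.isnan(out.values), expected)

    def test_degenerate_data_is_noop(self):
        m = _matrix(np.ones((10, 3)))
        out, deleted = slodr.percentile_trim(m, 1, 99)
        assert deleted == 0
        assert not out.data.isna().any().any()

    def test_per_column_mode_uses_column_bounds(self):
        rng = np.random.default_rng(3)
        vals = np.column_stack([rng.normal(0, 1, 200), rng.normal(100, 1, 200), rng.normal(0, 1, 200)])
        m = _matrix(vals)
        pooled, _ = slodr.percentile_trim(m, 5, 95)
        per_col, _ = slodr.percentile_trim(m, 5, 95, per_column=True)
        # pooled bounds straddle the offset column, so different cells go
        assert not np.array_equal(np.isnan(pooled.values), np.isnan(per_col.values))
        # pooled trimming never touches the upper tail of the centred column
        upper = vals[:, 0] > np.median(vals[:, 0])
        assert not np.isnan(pooled.values[upper, 0]).any()
        assert np.isnan(per_col.values[:, 0]).any()


class TestCompleteCases:
    def test_removes_rows_with_any_gap(self):
        vals = np.ones((5, 3))
        vals[1, 0] = np.nan
        vals[3, 2] = np.nan
        out, removed = slodr.complete_cases(_matrix(vals))
        assert removed == 2
        assert out.n_persons == 3
        assert not out.data.isna().any().any()

    def test_identity_when_complete(self, toy_matrix):
        out, removed = slodr.complete_cases(toy_matrix)
        assert removed == 0
        pd.testing.assert_frame_equal(out.data, toy_matrix.data)

    def test_all_rows_incomplete_is_error(self):
        vals = np.full((3, 3), np.nan)
        with pytest.raises(ScoreMatrixError, match="every row"):
            slodr.complete_cases(_matrix(vals))


class TestStandardize:
    def test_hand_computed_column(self):
        m = _matrix(np.column_stack([[1.0, 2.0, 3.0], [5.0, 5.0, 8.0], [0.0, 1.0, 5.0]]))
        out = slodr.standardize(m)
        assert out.standardized
        np.testing.assert_allclose(out.data["m0"], [-1.0, 0.0, 1.0])

    def test_idempotent(self, std_null):
        again = slodr.standardize(std_null)
        np.testing.assert_allclose(again.values, std_null.values, atol=1e-12)

    def test_constant_column_error_names_column(self):
        vals = np.random.default_rng(0).normal(size=(10, 3))
        vals[:, 1] = 7.0
        with pytest.raises(ScoreMatrixError, match="m1"):
            slodr.standardize(_matrix(vals))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_idempotence_property(self, seed):
        rng = np.random.default_rng(seed)
        m = _matrix(rng.normal(size=(20, 4)) * rng.uniform(0.5, 5, size=4))
        once = slodr.standardize(m)
        twice = slodr.standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)


class TestWimWisd:
    def test_hand_computation(self):
        m = _matrix([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]], ids=["a", "b"])
        prof = slodr.wim_wisd(m)
        assert prof.loc["a", "wim"] == pytest.approx(2.0)
        assert prof.loc["a", "wisd"] == pytest.approx(1.0)
        assert prof.loc["b", "wisd"] == 0.0

    def test_equal_shift_moves_wim_not_wisd(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(50, 5))
        base = slodr.wim_wisd(_matrix(vals))
        shifted = slodr.wim_wisd(_matrix(vals + 3.5))
        np.testing.assert_allclose(shifted["wim"], base["wim"] + 3.5)
        np.testing.assert_allclose(shifted["wisd"], base["wisd"])

    def test_requires_complete_matrix(self):
        vals = np.ones((4, 3))
        vals[0, 0] = np.nan
        with pytest.raises(ScoreMatrixError, match="complete"):
            slodr.wim_wisd(_matrix(vals))
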