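"""Expression-matrix reading, normalization, intensity filtering and summarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirpair import (
    condition_geometric_means,
    filter_low_intensity,
    normalize_pm_only,
    read_expression_table,
)
from mirpair.expression import ExpressionMatrix


def _write_table(tmp_path, frame, name="expr.tsv"):
    path = tmp_path / name
    frame.to_csv(path, sep="\t", index_label="transcript")
    return path


class TestReadExpressionTable:
    def test_round_trip_identity(self, tmp_path, design, small_matrix):
        path = _write_table(tmp_path, small_matrix.values)
        matrix = read_expression_table(path, design, "mrna")
        assert matrix.values.shape == (3, 18)
        pd.testing.assert_frame_equal(matrix.values, small_matrix.values, check_names=False)

    def test_missing_sample_named_in_error(self, tmp_path, design, small_matrix):
        frame = small_matrix.values.drop(columns=["LH4_r2"])
        path = _write_table(tmp_path, frame)
        with pytest.raises(ValueError, match="LH4_r2"):
            read_expression_table(path, design, "mrna")

    def test_negative_cell_reported_with_coordinates(self, tmp_path, design, small_matrix):
        frame = small_matrix.values.copy()
        frame.loc["t2", "LH1_r1"] = -4.0
        path = _write_table(tmp_path, frame)
        with pytest.raises(ValueError, match="t2.*LH1_r1"):
            read_expression_table(path, design, "mrna")

    def test_non_numeric_cell_reported_with_coordinates(self, tmp_path, design, small_matrix):
        frame = small_matrix.values.astype(object)
        frame.loc["t3", "LH8_r3"] = "oops"
        path = _write_table(tmp_path, frame)
        with pytest.raises(ValueError, match="t3.*LH8_r3"):
            read_expression_table(path, design, "mrna")

    def test_duplicate_transcript_rejected(self, tmp_path, design, small_matrix):
        frame = pd.concat([small_matrix.values, small_matrix.values.iloc[[0]]])
        path = _write_table(tmp_path, frame)
        with pytest.raises(ValueError, match="duplicate"):
            read_expression_table(path, design, "mrna")


class TestNormalizePmOnly:
    def test_constant_sample_becomes_target(self, design):
        values = pd.DataFrame(
            {s: [7.0, 7.0, 7.0] for s in design.samples}, index=["a", "b", "c"]
        )
        matrix = ExpressionMatrix(values, "mrna")
        out = normalize_pm_only(matrix, target=100.0, trim_fraction=0.02)
        assert np.allclose(out.values.to_numpy(), 100.0)

    def test_idempotent_when_already_at_target(self, design):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.uniform(1, 50, size=(30, 18)),
            index=[f"t{i}" for i in range(30)],
            columns=design.samples,
        )
        once = normalize_pm_only(ExpressionMatrix(values, "mrna"), 100.0, 0.02)
        twice = normalize_pm_only(once, 100.0, 0.02)
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy(), rtol=1e-12)

    def test_scale_factor_matches_direct_trimmed_mean(self, design):
        # one sample holding 1..100; independent trimmed mean: sort, drop 2 each side
        col = np.arange(1.0, 101.0)
        direct = np.sort(col)[2:-2].mean()
        values = pd.DataFrame({design.samples[0]: col})
        matrix = ExpressionMatrix(values, "mrna")
        out = normalize_pm_only(matrix, target=500.0, trim_fraction=0.02)
        np.testing.assert_allclose(
            out.values.iloc[:, 0].to_numpy(), col * (500.0 / direct), rtol=1e-12
        )

    def test_preserves_within_sample_ratios(self, design):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            rng.uniform(0.5, 200, size=(40, 18)),
            index=[f"t{i}" for i in range(40)],
            columns=design.samples,
        )
        matrix = ExpressionMatrix(values, "mirna")
        out = normalize_pm_only(matrix, 100.0, 0.02)
        before = values.to_numpy()
        after = out.values.to_numpy()
        ratio_before = before[1:] / before[:-1]
        ratio_after = after[1:] / after[:-1]
        np.testing.assert_allclose(ratio_after, ratio_before, rtol=1e-12)

    def test_all_zero_sample_fatal(self, design):
        values = pd.DataFrame({s: [0.0, 0.0] for s in design.samples}, index=["a", "b"])
        with pytest.raises(ValueError, match="positive"):
            normalize_pm_only(ExpressionMatrix(values, "mrna"), 100.0, 0.02)


class TestFilterLowIntensity:
    @pytest.mark.parametrize(
        "row,kept",
        [
            ([9.9] * 18, False),  # strictly below everywhere
            ([10.0] + [0.0] * 17, True),  # max exactly at threshold is retained
            ([11.0] + [0.0] * 17, True),  # a single bright sample suffices
        ],
    )
    def test_max_rule(self, design, row, kept):
        values = pd.DataFrame([row], index=["t"], columns=design.samples)
        filtered, removed = filter_low_intensity(ExpressionMatrix(values, "mrna"), 10.0)
        assert ("t" in filtered.values.index) is kept
        assert ("t" in removed) is (not kept)


class TestConditionGeometricMeans:
    def test_known_triplets(self, design):
        rows = {
            "g1": [2.0, 4.0, 8.0] * 6,  # (2*4*8)^(1/3) = 4
            "g2": [5.0, 5.0, 5.0] * 6,  # identity on constants
        }
        values = pd.DataFrame.from_dict(rows, orient="index", columns=design.samples)
        profiles = condition_geometric_means(ExpressionMatrix(values, "mrna"), design)
        np.testing.assert_allclose(profiles.loc["g1"], 4.0, rtol=1e-12)
        np.testing.assert_allclose(profiles.loc["g2"], 5.0, rtol=1e-12)

    def test_floor_clips_zeros(self, design):
        values = pd.DataFrame(
            [[0.0, 4.0, 8.0] + [1.0] * 15], index=["g"], columns=design.samples
        )
        profiles = condition_geometric_means(
            ExpressionMatrix(values, "mrna"), design, floor=0.5
        )
        np.testing.assert_allclose(
            profiles.loc["g", design.conditions[0]], (0.5 * 4 * 8) ** (1 / 3), rtol=1e-12
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        scale=st.floats(min_value=1.0, max_value=1000),  # stay above the log floor
        base=st.lists(st.floats(min_value=0.6, max_value=1e4), min_size=3, max_size=3),
    )
    def test_scale_equivariance(self, design, scale, base):
        """Scaling one condition's replicates by c scales its geometric mean by c."""
        row = base * 6
        values = pd.DataFrame([row], index=["g"], columns=design.samples)
        ref = condition_geometric_means(ExpressionMatrix(values, "mrna"), design)
        scaled = values.copy()
        cond = design.conditions[2]
        scaled[design.samples_for(cond)] = values[design.samples_for(cond)] * scale
        out = condition_geometric_means(ExpressionMatrix(scaled, "mrna"), design)
        np.testing.assert_allclose(out.loc["g", cond], ref.loc["g", cond] * scale, rtol=1e-12)
        others = [c for c in design.conditions if c != cond]
        np.testing.assert_allclose(out.loc["g", others], ref.loc["g", others], rtol=1e-12)

    def test_filter_then_summarize_commutes_with_subsetting(self, design):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            rng.uniform(0, 100, size=(20, 18)),
            index=[f"t{i}" for i in range(20)],
            columns=design.samples,
        )
        matrix = ExpressionMatrix(values, "mrna")
        filtered, _ = filter_low_intensity(matrix, 10.0)
        whole = condition_geometric_means(filtered, design)
        subset_ids = [f"t{i}" for i in range(0, 20, 3)]
        sub_matrix = ExpressionMatrix(values.loc[subset_ids], "mrna")
        sub_filtered, _ = filter_low_intensity(sub_matrix, 10.0)
        sub = condition_geometric_means(sub_filtered, design)
        common = [t for t in subset_ids if t in whole.index]
        pd.testing.assert_frame_equal(whole.loc[common], sub.loc[common])
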