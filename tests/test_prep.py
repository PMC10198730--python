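"""Normalization, prefilter and DE-call/consensus logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circdeconv import (
    DECallSpec,
    DEResultTable,
    ExpressionMatrix,
    FilterSpec,
    ValidationError,
    call_de,
    counts_to_tpm,
    de_consensus,
    normalize_backsplice,
    prefilter,
)


def counts_matrix(values, ids=None, samples=None):
    values = np.atleast_2d(values)
    ids = ids or [f"t{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(ids, samples, values, "raw_counts")


class TestCountsToTpm:
    def test_closed_form_two_transcripts(self):
        m = counts_matrix([[10.0], [10.0]])
        tpm = counts_to_tpm(m, pd.Series({"t0": 1000.0, "t1": 2000.0}))
        # rates 0.01 and 0.005 → TPM (2/3, 1/3) × 10⁶
        assert tpm.values[:, 0] == pytest.approx([2e6 / 3, 1e6 / 3])

    def test_all_zero_sample_stays_zero(self):
        m = counts_matrix([[0.0], [0.0]])
        tpm = counts_to_tpm(m, pd.Series({"t0": 100.0, "t1": 100.0}))
        assert np.all(tpm.values == 0.0)

    def test_equal_counts_equal_lengths_split_evenly(self):
        m = counts_matrix([[7.0], [7.0]])
        tpm = counts_to_tpm(m, pd.Series({"t0": 500.0, "t1": 500.0}))
        assert tpm.values[:, 0] == pytest.approx([5e5, 5e5])

    def test_columns_sum_to_a_million(self):
        rng = np.random.default_rng(0)
        m = counts_matrix(rng.integers(0, 100, size=(20, 5)).astype(float))
        lengths = pd.Series(
            rng.uniform(200, 5000, size=20), index=m.transcript_ids
        )
        tpm = counts_to_tpm(m, lengths)
        assert tpm.values.sum(axis=0) == pytest.approx([1e6] * 5, rel=1e-9)

    def test_non_positive_length_rejected(self):
        m = counts_matrix([[1.0]])
        with pytest.raises(ValidationError, match="length"):
            counts_to_tpm(m, pd.Series({"t0": 0.0}))


class TestNormalizeBacksplice:
    def test_reads_per_million(self):
        m = counts_matrix([[10.0]])
        out = normalize_backsplice(m, pd.Series({"s0": 2e7}))
        assert out.values[0, 0] == pytest.approx(0.5)
        assert out.unit_label == "normalized_backspliced_reads"

    def test_doubling_depth_halves_values(self):
        m = counts_matrix([[10.0, 10.0]], samples=["s0", "s1"])
        out = normalize_backsplice(m, pd.Series({"s0": 1e7, "s1": 2e7}))
        assert out.values[0, 0] == pytest.approx(2 * out.values[0, 1])

    def test_non_positive_depth_rejected(self):
        m = counts_matrix([[1.0]])
        with pytest.raises(ValidationError, match="depth"):
            normalize_backsplice(m, pd.Series({"s0": 0.0}))


class TestPrefilter:
    def test_circ_rule_boundary_passes(self):
        # 1 of 4 samples ≥ 1 raw read → fraction 0.25 ≥ 0.15
        raw = counts_matrix([[1.0, 0.0, 0.0, 0.0]], ids=["c1"])
        norm = ExpressionMatrix(["c1"], raw.sample_ids,
                                [[0.05, 0.0, 0.0, 0.0]],
                                "normalized_backspliced_reads")
        kept = prefilter(norm, FilterSpec(1.0, 0.15), raw=raw, on_raw=True)
        assert kept == ["c1"]

    def test_gene_rule_boundary_passes(self):
        m = ExpressionMatrix(["g1"], ["a", "b", "c", "d"],
                             [[5.0, 5.0, 0.0, 0.0]], "TPM")
        assert prefilter(m, FilterSpec(5.0, 0.25)) == ["g1"]

    def test_value_below_threshold_dropped(self):
        m = ExpressionMatrix(["g1"], ["a", "b", "c", "d"],
                             [[4.9, 4.9, 4.9, 4.9]], "TPM")
        assert prefilter(m, FilterSpec(5.0, 0.25)) == []

    def test_exact_fraction_boundary_is_non_strict(self):
        # exactly 25% of samples at the threshold value → kept
        m = ExpressionMatrix(["g1"], ["a", "b", "c", "d"],
                             [[5.0, 0.0, 0.0, 0.0]], "TPM")
        assert prefilter(m, FilterSpec(5.0, 0.25)) == ["g1"]

    def test_shape_mismatch_rejected(self):
        m = ExpressionMatrix(["g1"], ["a"], [[1.0]], "TPM")
        raw = counts_matrix([[1.0, 1.0]], ids=["g1"], samples=["a", "b"])
        with pytest.raises(ValidationError, match="raw"):
            prefilter(m, FilterSpec(1.0, 0.5), raw=raw, on_raw=True)

    @settings(derandomize=True, max_examples=60)
    @given(
        seed=st.integers(0, 2**16),
        dv=st.floats(min_value=0, max_value=2),
        df=st.floats(min_value=0, max_value=0.4),
    )
    def test_monotone_in_both_thresholds(self, seed, dv, df):
        """Loosening either threshold never removes a kept transcript."""
        rng = np.random.default_rng(seed)
        m = ExpressionMatrix(
            [f"t{i}" for i in range(15)],
            [f"s{j}" for j in range(8)],
            rng.uniform(0, 10, size=(15, 8)),
            "TPM",
        )
        strict = set(prefilter(m, FilterSpec(3.0, 0.5)))
        loose = set(prefilter(
            m, FilterSpec(max(3.0 - dv, 1e-9), max(0.5 - df, 1e-9))
        ))
        assert strict <= loose


def de_table(rows, tool="edgeR"):
    df = pd.DataFrame(
        rows, columns=["transcript_id", "comparison_group", "log_fc", "p_value", "fdr"]
    )
    return DEResultTable(df, tool, fdr_required=False)


class TestCallDE:
    @pytest.mark.parametrize(
        "p, lfc, fdr, expected",
        [
            (0.04, 0.5, 0.10, "up"),      # all thresholds pass
            (0.04, -0.5, 0.10, "down"),
            (0.05, 0.5, 0.10, "none"),    # p boundary is strict
            (0.04, 0.0, 0.10, "none"),    # |logFC| boundary is strict
            (0.04, 0.5, 0.15, "up"),      # FDR boundary is non-strict
            (0.04, 0.5, 0.151, "none"),
        ],
    )
    def test_boundary_semantics(self, p, lfc, fdr, expected):
        t = de_table([("c", "MvP", lfc, p, fdr)])
        calls = call_de(t, DECallSpec())
        assert calls.loc[0, "status"] == expected

    def test_missing_fdr_never_de(self):
        t = de_table([("c", "MvP", 1.0, 0.01, np.nan)], tool="CircTest")
        assert call_de(t).loc[0, "status"] == "none"


class TestDEConsensus:
    def primary(self, status="up", group="MvP"):
        return pd.DataFrame(
            [("circ1", group, 1.0 if status == "up" else -1.0, status)],
            columns=["transcript_id", "comparison_group", "log_fc", "status"],
        )

    def test_ciriquant_concurs_on_group_and_direction(self):
        result = de_consensus(
            self.primary(),
            de_table([("circ1", "MvP", 0.8, 0.01, np.nan)], "CIRIquant"),
            de_table([("circ1", "MvP", 0.0, 0.2, np.nan)], "CircTest"),
        )
        assert result.loc[0, "validation"] == "ciriquant_only"

    def test_direction_mismatch_does_not_concur(self):
        result = de_consensus(
            self.primary(),
            de_table([("circ1", "MvP", -0.8, 0.01, np.nan)], "CIRIquant"),
            de_table([], "CircTest"),
        )
        assert result.loc[0, "validation"] == "none"

    def test_circtest_concurs_on_group_alone(self):
        result = de_consensus(
            self.primary(),
            de_table([], "CIRIquant"),
            de_table([("circ1", "MvP", 0.0, 0.01, np.nan)], "CircTest"),
        )
        assert result.loc[0, "validation"] == "circtest_only"

    def test_both_tools_concur(self):
        result = de_consensus(
            self.primary(),
            de_table([("circ1", "MvP", 2.0, 0.04, np.nan)], "CIRIquant"),
            de_table([("circ1", "MvP", 0.0, 0.04, np.nan)], "CircTest"),
        )
        assert result.loc[0, "validation"] == "both"

    def test_group_mismatch_does_not_concur(self):
        result = de_consensus(
            self.primary(group="MvP"),
            de_table([("circ1", "PvN", 0.8, 0.01, np.nan)], "CIRIquant"),
            de_table([("circ1", "MvN", 0.0, 0.01, np.nan)], "CircTest"),
        )
        assert result.loc[0, "validation"] == "none"

    def test_absent_transcript_treated_as_non_concurring(self):
        result = de_consensus(
            self.primary(), de_table([], "CIRIquant"), de_table([], "CircTest")
        )
        assert result.loc[0, "validation"] == "none"

    def test_non_de_primary_records_excluded(self):
        primary = pd.DataFrame(
            [("circ1", "MvP", 0.0, "none")],
            columns=["transcript_id", "comparison_group", "log_fc", "status"],
        )
        result = de_consensus(
            primary, de_table([], "CIRIquant"), de_table([], "CircTest")
        )
        assert result.empty
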