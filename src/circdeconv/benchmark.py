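"""Reconstruction benchmark: modeled bulk vs ground truth.

Modeled bulk is the matrix product of fitted cell-type coefficients and
cell-type proportions. Agreement is scored two ways: per transcript, a
simple linear regression of ground truth on modeled values across samples
(R² and the two-sided slope-test p-value, n−2 df); per sample, the Pearson
correlation across transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import ExpressionMatrix, ProportionMatrix, ValidationError
from .nnls import CoefficientMatrix

__all__ = [
    "reconstruct_bulk",
    "per_transcript_diagnostics",
    "per_sample_diagnostics",
    "summarize_diagnostics",
]


def reconstruct_bulk(
    coefficients: CoefficientMatrix,
    proportions: ProportionMatrix,
    unit_label: str = "normalized_backspliced_reads",
) -> ExpressionMatrix:
    """modeled[g, s] = Σ_c coefficients[g, c] × proportions[c, s]."""
    if coefficients.cell_types != proportions.cell_types:
        raise ValidationError(
            f"cell-type lists differ: {coefficients.cell_types} vs {proportions.cell_types}"
        )
    values = coefficients.coefficients @ proportions.fractions
    return ExpressionMatrix(
        list(coefficients.transcript_ids),
        list(proportions.sample_ids),
        values,
        unit_label,
    )


def _check_aligned(modeled: ExpressionMatrix, truth: ExpressionMatrix) -> None:
    if (
        modeled.transcript_ids != truth.transcript_ids
        or modeled.sample_ids != truth.sample_ids
    ):
        raise ValidationError("modeled and truth matrices are not aligned")


@dataclass
class FitDiagnostics:
    """Per-transcript regression diagnostics (truth on modeled).

    ``table`` columns: transcript_id, r_squared, p_value, slope, intercept,
    defined. A transcript is undefined when either series is constant or
    fewer than 3 samples are available; undefined rows carry NaN statistics
    and are excluded from medians downstream.
    """

    table: pd.DataFrame

    def defined(self) -> pd.DataFrame:
        return self.table[self.table["defined"]]

    def median_r_squared(self) -> float:
        d = self.defined()
        if d.empty:
            raise ValidationError("no transcript has defined diagnostics")
        return float(d["r_squared"].median())


@dataclass
class SampleDiagnostics:
    """Per-sample Pearson correlation across transcripts.

    ``table`` columns: sample_id, pearson_r, p_value, defined.
    """

    table: pd.DataFrame


def per_transcript_diagnostics(
    modeled: ExpressionMatrix, truth: ExpressionMatrix
) -> FitDiagnostics:
    """Regress ground truth on modeled expression for every transcript."""
    _check_aligned(modeled, truth)
    n = modeled.n_samples
    rows = []
    for g, tid in enumerate(modeled.transcript_ids):
        x = modeled.values[g]
        y = truth.values[g]
        if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((tid, np.nan, np.nan, np.nan, np.nan, False))
            continue
        res = stats.linregress(x, y)
        rows.append(
            (tid, res.rvalue**2, res.pvalue, res.slope, res.intercept, True)
        )
    return FitDiagnostics(
        pd.DataFrame(
            rows,
            columns=["transcript_id", "r_squared", "p_value", "slope", "intercept", "defined"],
        )
    )


def per_sample_diagnostics(
    modeled: ExpressionMatrix, truth: ExpressionMatrix
) -> SampleDiagnostics:
    """Pearson r (with two-sided test) between modeled and truth per sample."""
    _check_aligned(modeled, truth)
    rows = []
    for s, sid in enumerate(modeled.sample_ids):
        x = modeled.values[:, s]
        y = truth.values[:, s]
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((sid, np.nan, np.nan, False))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((sid, float(r), float(p), True))
    return SampleDiagnostics(
        pd.DataFrame(rows, columns=["sample_id", "pearson_r", "p_value", "defined"])
    )


def summarize_diagnostics(
    fit: FitDiagnostics, samples: SampleDiagnostics
) -> dict:
    """Min/mean/max summaries of defined R² and per-sample Pearson r."""
    d = fit.defined()["r_squared"]
    s = samples.table.loc[samples.table["defined"], "pearson_r"]

    def stats3(v):
        if v.empty:
            return {"min": None, "mean": None, "max": None}
        return {"min": float(v.min()), "mean": float(v.mean()), "max": float(v.max())}

    return {
        "n_transcripts": int(len(fit.table)),
        "n_defined_transcripts": int(len(d)),
        "r_squared": stats3(d),
        "n_samples": int(len(samples.table)),
        "pearson_r": stats3(s),
    }
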