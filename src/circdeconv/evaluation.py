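"""Recovery metrics against synthetic ground truth.

Used to score how well the deconvolution recovers known cell-type profiles:
per-transcript correlation between estimated and true coefficient rows, and
sensitivity/precision of consensus specificity calls against the true
single-cell-type labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrices import ValidationError
from .nnls import CoefficientMatrix

__all__ = ["coefficient_recovery_correlations", "specificity_confusion"]


def coefficient_recovery_correlations(
    estimated: CoefficientMatrix, truth: CoefficientMatrix
) -> pd.Series:
    """Pearson correlation between estimated and true coefficient rows.

    One value per transcript; NaN when either row is constant (e.g. an
    all-zero estimate for an undetectable transcript) — callers typically
    take the median over the defined entries.
    """
    if (
        estimated.transcript_ids != truth.transcript_ids
        or estimated.cell_types != truth.cell_types
    ):
        raise ValidationError("estimated and true coefficient matrices not aligned")
    out = np.full(len(estimated.transcript_ids), np.nan)
    for g in range(len(out)):
        a, b = estimated.coefficients[g], truth.coefficients[g]
        if np.ptp(a) > 0 and np.ptp(b) > 0:
            out[g] = np.corrcoef(a, b)[0, 1]
    return pd.Series(out, index=estimated.transcript_ids, name="recovery_correlation")


def specificity_confusion(
    consensus_calls: pd.DataFrame, true_labels: pd.Series
) -> dict:
    """Sensitivity/precision of consensus calls vs true specific labels.

    ``consensus_calls`` is a ``consensus`` output (transcript_id,
    shared_cell_type); ``true_labels`` maps every transcript to its true
    exclusive cell type or None. A call is a true positive only when the
    transcript is truly single-cell-type AND the called type matches.
    """
    called = dict(
        zip(consensus_calls["transcript_id"], consensus_calls["shared_cell_type"])
    )
    tp = fp = fn = 0
    for tid, label in true_labels.items():
        call = called.get(tid)
        if label is not None:
            if call == label:
                tp += 1
            else:
                fn += 1
                if call is not None:
                    fp += 1
        elif call is not None:
            fp += 1
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
    }
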