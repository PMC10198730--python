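"""Normalization, expression prefilters and differential-expression call logic.

Linear genes are worked with in TPM; circRNAs in backspliced reads normalized
against sequencing depth (reads per million). The DE machinery here does not
run any statistical test itself — it classifies and cross-validates result
tables produced by external tools (an edgeR-style primary test plus
CIRIquant- and CircTest-style parallel tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import DEResultTable, ExpressionMatrix, ValidationError

__all__ = [
    "FilterSpec",
    "DECallSpec",
    "GENE_FILTER",
    "CIRC_FILTER",
    "DEFAULT_DE_CALL",
    "counts_to_tpm",
    "normalize_backsplice",
    "prefilter",
    "call_de",
    "de_consensus",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Keep a transcript when ≥ ``min_sample_fraction`` of samples reach ``min_value``."""

    min_value: float
    min_sample_fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.min_sample_fraction <= 1:
            raise ValidationError("min_sample_fraction must be in (0, 1]")


#: Linear genes: ≥5 TPM in 25% of samples.
GENE_FILTER = FilterSpec(min_value=5.0, min_sample_fraction=0.25)
#: circRNAs: ≥1 backspliced read (raw) in 15% of samples.
CIRC_FILTER = FilterSpec(min_value=1.0, min_sample_fraction=0.15)


@dataclass(frozen=True)
class DECallSpec:
    """DE iff p < max_p AND |logFC| > min_abs_logfc AND FDR ≤ max_fdr.

    Note the asymmetric boundaries: p and |logFC| are strict, FDR is not.
    """

    max_p: float = 0.05
    min_abs_logfc: float = 0.0
    max_fdr: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.max_p <= 1 or not 0 <= self.max_fdr <= 1:
            raise ValidationError("max_p and max_fdr must lie in [0, 1]")
        if self.min_abs_logfc < 0:
            raise ValidationError("min_abs_logfc must be non-negative")


DEFAULT_DE_CALL = DECallSpec()


def counts_to_tpm(counts: ExpressionMatrix, lengths) -> ExpressionMatrix:
    """Convert raw counts to TPM given per-transcript effective lengths (bases).

    TPM_g = (count_g / length_g) / Σ_h (count_h / length_h) × 10⁶ per sample.
    A sample with all-zero counts stays all-zero (logged, not an error).
    """
    if counts.unit_label != "raw_counts":
        raise ValidationError(f"expected raw_counts input, got {counts.unit_label}")
    lengths = pd.Series(lengths, dtype=float)
    missing = [t for t in counts.transcript_ids if t not in lengths.index]
    if missing:
        raise ValidationError(f"missing length for transcript(s): {missing[:5]}")
    lvec = lengths.loc[counts.transcript_ids].to_numpy()
    if np.any(lvec <= 0):
        bad = counts.transcript_ids[int(np.argmax(lvec <= 0))]
        raise ValidationError(f"non-positive length for transcript {bad!r}")
    rates = counts.values / lvec[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.info(
            "all-zero sample(s) left at zero TPM: %s",
            [counts.sample_ids[i] for i in np.flatnonzero(zero)],
        )
    safe = np.where(zero, 1.0, totals)
    tpm = rates / safe * 1e6
    return ExpressionMatrix(
        list(counts.transcript_ids), list(counts.sample_ids), tpm, "TPM"
    )


def normalize_backsplice(counts: ExpressionMatrix, depths) -> ExpressionMatrix:
    """Normalize backspliced read counts against sequencing depth.

    value = count / total_reads × 10⁶ (reads per million sequenced reads).
    """
    if counts.unit_label != "raw_counts":
        raise ValidationError(f"expected raw_counts input, got {counts.unit_label}")
    depths = pd.Series(depths, dtype=float)
    missing = [s for s in counts.sample_ids if s not in depths.index]
    if missing:
        raise ValidationError(f"missing depth for sample(s): {missing[:5]}")
    dvec = depths.loc[counts.sample_ids].to_numpy()
    if np.any(dvec <= 0):
        bad = counts.sample_ids[int(np.argmax(dvec <= 0))]
        raise ValidationError(f"non-positive sequencing depth for sample {bad!r}")
    return ExpressionMatrix(
        list(counts.transcript_ids),
        list(counts.sample_ids),
        counts.values / dvec[None, :] * 1e6,
        "normalized_backspliced_reads",
    )


def prefilter(
    m: ExpressionMatrix,
    spec: FilterSpec,
    raw: ExpressionMatrix | None = None,
    on_raw: bool = False,
) -> list[str]:
    """Return transcript ids passing the expression prefilter.

    A transcript is kept iff the fraction of samples with value ≥
    ``spec.min_value`` is ≥ ``spec.min_sample_fraction`` (both bounds
    non-strict). With ``on_raw`` the thresholding is evaluated on the raw
    count matrix (the circRNA rule counts raw backspliced reads) while the
    returned ids refer to ``m``.
    """
    values = m.values
    if on_raw:
        if raw is None:
            raise ValidationError("on_raw=True requires the raw count matrix")
        if raw.values.shape != m.values.shape or raw.transcript_ids != m.transcript_ids:
            raise ValidationError("raw matrix shape/ids do not match the input matrix")
        values = raw.values
    frac = (values >= spec.min_value).mean(axis=1)
    keep = frac >= spec.min_sample_fraction
    return [t for t, k in zip(m.transcript_ids, keep) if k]


def call_de(table: DEResultTable, spec: DECallSpec = DEFAULT_DE_CALL) -> pd.DataFrame:
    """Classify each record as up / down / none per comparison group.

    Boundary semantics are deliberately asymmetric: p < max_p (strict),
    |logFC| > min_abs_logfc (strict), FDR ≤ max_fdr (non-strict). A record
    whose FDR is NaN can never be DE under a finite max_fdr.
    """
    df = table.records.copy()
    de = (
        (df["p_value"] < spec.max_p)
        & (df["log_fc"].abs() > spec.min_abs_logfc)
        & (df["fdr"] <= spec.max_fdr)
    )
    status = np.where(~de, "none", np.where(df["log_fc"] > 0, "up", "down"))
    out = df[["transcript_id", "comparison_group", "log_fc"]].copy()
    out["status"] = status
    return out


def _direction_lookup(table: DEResultTable, alpha: float) -> dict:
    """(transcript, group) → sign(logFC) for records with p < alpha."""
    df = table.records
    sig = df[df["p_value"] < alpha]
    return {
        (r.transcript_id, r.comparison_group): np.sign(r.log_fc)
        for r in sig.itertuples()
    }


def de_consensus(
    primary_calls: pd.DataFrame,
    ciriquant: DEResultTable,
    circtest: DEResultTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cross-tool validation of primary DE calls.

    A CIRIquant-style test concurs when it is significant (p < alpha) in the
    same comparison group with the same direction; a CircTest-style test
    concurs on group alone (its statistic has no signed fold change on the
    same scale). Each primary DE call is labelled ``both``,
    ``ciriquant_only``, ``circtest_only`` or ``none``. Transcripts absent
    from a secondary table simply do not concur.
    """
    ciri = _direction_lookup(ciriquant, alpha)
    circ = _direction_lookup(circtest, alpha)
    rows = []
    de_calls = primary_calls[primary_calls["status"] != "none"]
    for r in de_calls.itertuples():
        key = (r.transcript_id, r.comparison_group)
        direction = 1.0 if r.status == "up" else -1.0
        ciri_ok = key in ciri and ciri[key] == direction
        circ_ok = key in circ
        if ciri_ok and circ_ok:
            validation = "both"
        elif ciri_ok:
            validation = "ciriquant_only"
        elif circ_ok:
            validation = "circtest_only"
        else:
            validation = "none"
        rows.append(
            (r.transcript_id, r.comparison_group, r.status, validation)
        )
    return pd.DataFrame(
        rows, columns=["transcript_id", "comparison_group", "status", "validation"]
    )
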