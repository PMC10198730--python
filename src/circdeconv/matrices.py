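"""Validated tabular containers for expression, proportion and DE-result data.

All on-disk formats are tab-separated UTF-8 with a mandatory header row.
Expression matrices are transcripts × samples; proportion tables are accepted
in the orientation cell-fraction tools emit (samples as rows) and transposed
into the internal cell types × samples layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "ProportionMatrix",
    "DEResultTable",
    "EXPRESSION_UNITS",
    "COMPARISON_GROUPS",
    "DE_SOURCE_TOOLS",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_proportions",
    "write_proportions",
    "read_de_table",
    "write_de_table",
]

EXPRESSION_UNITS = ("TPM", "normalized_backspliced_reads", "raw_counts")
COMPARISON_GROUPS = ("PvN", "MvN", "MvP")
DE_SOURCE_TOOLS = ("edgeR", "CIRIquant", "CircTest")

#: Diagnostic columns that cell-fraction tools append after the per-cell-type
#: fractions; dropped on read unless the caller overrides the list.
DEFAULT_PROPORTION_DROP_COLUMNS = (
    "P-value",
    "Pvalue",
    "Correlation",
    "RMSE",
    "Absolute score",
    "Absolute score (sig.score)",
)

PROPORTION_SUM_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Non-negative transcripts × samples expression values.

    Parameters
    ----------
    transcript_ids, sample_ids
        Ordered, unique identifiers for the rows and columns.
    values
        Float array of shape ``(len(transcript_ids), len(sample_ids))``;
        every entry must be finite and non-negative.
    unit_label
        One of :data:`EXPRESSION_UNITS`.
    """

    transcript_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit_label: str

    def __post_init__(self) -> None:
        self.transcript_ids = [str(t) for t in self.transcript_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.unit_label not in EXPRESSION_UNITS:
            raise ValidationError(
                f"unknown unit_label {self.unit_label!r}; expected one of {EXPRESSION_UNITS}"
            )
        _check_unique(self.transcript_ids, "transcript")
        _check_unique(self.sample_ids, "sample")
        expected = (len(self.transcript_ids), len(self.sample_ids))
        if self.values.shape != expected:
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with identifiers {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at transcript {self.transcript_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value {self.values[r, c]} at transcript "
                f"{self.transcript_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.transcript_ids, columns=self.sample_ids
        )

    def subset(self, transcript_ids: list[str]) -> "ExpressionMatrix":
        """Row subset in the given order; unknown ids raise."""
        index = {t: i for i, t in enumerate(self.transcript_ids)}
        try:
            rows = [index[t] for t in transcript_ids]
        except KeyError as e:  # pragma: no cover - message path
            raise ValidationError(f"unknown transcript id {e.args[0]!r}") from None
        return ExpressionMatrix(
            list(transcript_ids), list(self.sample_ids),
            self.values[rows, :], self.unit_label,
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.transcript_ids == other.transcript_ids
            and self.sample_ids == other.sample_ids
            and self.unit_label == other.unit_label
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ProportionMatrix:
    """Cell types × samples composition fractions; each column sums to 1."""

    cell_types: list[str]
    sample_ids: list[str]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.cell_types = [str(c) for c in self.cell_types]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.fractions = np.asarray(self.fractions, dtype=float)
        _check_unique(self.cell_types, "cell type")
        _check_unique(self.sample_ids, "sample")
        expected = (len(self.cell_types), len(self.sample_ids))
        if self.fractions.shape != expected:
            raise ValidationError(
                f"fractions shape {self.fractions.shape} inconsistent with {expected}"
            )
        if np.any(~np.isfinite(self.fractions)) or np.any(self.fractions < 0) or np.any(
            self.fractions > 1
        ):
            raise ValidationError("fractions must all lie in [0, 1]")
        sums = self.fractions.sum(axis=0)
        bad = np.abs(sums - 1.0) > PROPORTION_SUM_TOL
        if np.any(bad):
            s = int(np.argmax(bad))
            raise ValidationError(
                f"sample {self.sample_ids[s]!r} fractions sum to {sums[s]:.8f}, "
                f"not 1 within {PROPORTION_SUM_TOL}"
            )

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fractions, index=self.cell_types, columns=self.sample_ids
        )

    def reorder_samples(self, sample_ids: list[str]) -> "ProportionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            cols = [index[s] for s in sample_ids]
        except KeyError as e:
            raise ValidationError(f"unknown sample id {e.args[0]!r}") from None
        return ProportionMatrix(
            list(self.cell_types), list(sample_ids), self.fractions[:, cols]
        )


DE_TABLE_COLUMNS = ["transcript_id", "comparison_group", "log_fc", "p_value", "fdr"]


@dataclass
class DEResultTable:
    """Per-transcript differential-expression statistics from one tool.

    ``records`` has columns ``transcript_id, comparison_group, log_fc,
    p_value, fdr`` (``fdr`` may be NaN for tools that report none);
    ``source_tool`` tags the producing pipeline.
    """

    records: pd.DataFrame
    source_tool: str
    fdr_required: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.source_tool not in DE_SOURCE_TOOLS:
            raise ValidationError(
                f"unknown source_tool {self.source_tool!r}; expected one of {DE_SOURCE_TOOLS}"
            )
        df = pd.DataFrame(self.records, columns=DE_TABLE_COLUMNS).copy()
        df["transcript_id"] = df["transcript_id"].astype(str)
        for col in ("log_fc", "p_value", "fdr"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        bad_group = ~df["comparison_group"].isin(COMPARISON_GROUPS)
        if bad_group.any():
            raise ValidationError(
                f"unknown comparison group {df.loc[bad_group, 'comparison_group'].iloc[0]!r}; "
                f"expected one of {COMPARISON_GROUPS}"
            )
        if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
            raise ValidationError("p_value outside [0, 1]")
        fdr = df["fdr"]
        if self.fdr_required and fdr.isna().any():
            raise ValidationError(f"{self.source_tool} table is missing FDR values")
        if ((fdr < 0) | (fdr > 1)).any():
            raise ValidationError("fdr outside [0, 1]")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Readers / writers (tab-separated UTF-8, mandatory header)
# ---------------------------------------------------------------------------

def read_expression_matrix(path, unit_label: str) -> ExpressionMatrix:
    """Read a transcripts × samples TSV (first column transcript id)."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str},
                     float_precision="round_trip")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as e:
        raise ValidationError(f"non-numeric expression value in {path}: {e}") from None
    return ExpressionMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], values, unit_label
    )


#: %.17g prints the shortest-or-full form that reparses to the same double,
#: keeping write→read exact and the written form canonical.
FLOAT_FORMAT = "%.17g"


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    df = m.to_frame()
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_proportions(
    path,
    renormalize: bool = False,
    drop_columns=DEFAULT_PROPORTION_DROP_COLUMNS,
) -> ProportionMatrix:
    """Read a samples × cell-types fraction table, transposing internally.

    Diagnostic columns listed in ``drop_columns`` are discarded. With
    ``renormalize`` each sample's fractions are divided by their sum;
    otherwise a sum off 1 beyond tolerance is an error.
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0,
                     float_precision="round_trip")
    df = df.drop(columns=[c for c in drop_columns if c in df.columns])
    fractions = df.to_numpy(dtype=float).T  # cell types × samples
    if np.any(fractions < 0):
        raise ValidationError(f"negative fraction in {path}")
    if renormalize:
        sums = fractions.sum(axis=0)
        if np.any(sums <= 0):
            raise ValidationError(f"sample with non-positive fraction sum in {path}")
        fractions = fractions / sums
    return ProportionMatrix(
        [str(c) for c in df.columns], [str(i) for i in df.index], fractions
    )


def write_proportions(p: ProportionMatrix, path) -> None:
    """Write in the samples-as-rows orientation (the one `read_proportions` expects)."""
    df = p.to_frame().T
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


_DE_FILE_COLUMNS = {"id": "transcript_id", "group": "comparison_group",
                    "logFC": "log_fc", "pvalue": "p_value", "fdr": "fdr"}


def read_de_table(path, source_tool: str) -> DEResultTable:
    """Read a DE result TSV with columns id, group, logFC, pvalue[, fdr]."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={"id": str},
                     float_precision="round_trip")
    missing = [c for c in ("id", "group", "logFC", "pvalue") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path} missing required column(s): {missing}")
    if "fdr" not in df.columns:
        df["fdr"] = np.nan
    df = df.rename(columns=_DE_FILE_COLUMNS)[DE_TABLE_COLUMNS]
    return DEResultTable(df, source_tool, fdr_required=source_tool == "edgeR")


def write_de_table(t: DEResultTable, path) -> None:
    inverse = {v: k for k, v in _DE_FILE_COLUMNS.items()}
    t.records.rename(columns=inverse).to_csv(path, sep="\t", index=False)
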