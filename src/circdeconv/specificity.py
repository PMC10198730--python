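"""Cell-type-specificity calls and cross-model consensus.

A transcript is called *exclusive* when exactly one cell type carries a
positive fitted coefficient, and *significant* when it additionally passes
two filters: its reconstruction-regression p-value is below alpha (strict),
and its R² exceeds the median R² of all transcripts in the run (strict).
Two independently trained models agree when both call a transcript
significant in cell types that map to the same label of a shared ontology —
e.g. macrophages count as myeloid cells, and fibroblasts/endothelial cells
as stromal cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .benchmark import FitDiagnostics
from .matrices import ValidationError
from .nnls import CoefficientMatrix

__all__ = [
    "call_exclusive",
    "apply_filters",
    "CellTypeMap",
    "COARSE_TME_MAP",
    "FINE_TME_MAP",
    "consensus",
]

#: Shared ontology used by the default maps.
SHARED_ONTOLOGY = ("T", "B", "epithelial", "mast", "myeloid", "stromal")


def call_exclusive(
    coefficients: CoefficientMatrix,
    zero_tol: float = 0.0,
    relative_tol: float = 0.0,
) -> pd.Series:
    """Per-transcript exclusive cell type, or None.

    A cell type counts as expressing the transcript when its coefficient
    exceeds ``max(zero_tol, relative_tol × row maximum)``. The defaults treat
    only exact active-set zeros as absent, which is the right semantics for
    coefficients from the bundled solver on noiseless data. For noisy fits a
    ``relative_tol`` of ~0.2 discards the small spurious coefficients NNLS
    leaks onto non-expressing cell types (see docs/methods.md).
    """
    out = []
    for row in coefficients.coefficients:
        threshold = max(zero_tol, relative_tol * row.max())
        positive = np.flatnonzero(row > threshold)
        out.append(coefficients.cell_types[positive[0]] if len(positive) == 1 else None)
    return pd.Series(
        out, index=coefficients.transcript_ids, name="exclusive_cell_type", dtype=object
    )


def apply_filters(
    calls: pd.Series, diagnostics: FitDiagnostics, alpha: float = 0.05
) -> pd.DataFrame:
    """Combine exclusivity with the p-value and median-R² filters.

    Returns one row per transcript with columns ``exclusive_cell_type,
    r_squared, p_value, passed_p_filter, passed_r2_filter, significant``.
    The R² threshold is the median over all transcripts with defined
    diagnostics *in this call* (strictly exceeded to pass); transcripts with
    undefined diagnostics fail both filters and can never be significant.
    """
    diag = diagnostics.table.set_index("transcript_id")
    missing = [t for t in calls.index if t not in diag.index]
    if missing:
        raise ValidationError(f"diagnostics missing for transcript(s): {missing[:5]}")
    diag = diag.loc[calls.index]
    median_r2 = diagnostics.median_r_squared()  # raises when nothing is defined
    defined = diag["defined"].to_numpy(dtype=bool)
    passed_p = defined & (diag["p_value"].to_numpy() < alpha)
    passed_r2 = defined & (diag["r_squared"].to_numpy() > median_r2)
    exclusive = calls.to_numpy(dtype=object)
    significant = passed_p & passed_r2 & (exclusive != None)  # noqa: E711
    return pd.DataFrame(
        {
            "exclusive_cell_type": exclusive,
            "r_squared": diag["r_squared"].to_numpy(),
            "p_value": diag["p_value"].to_numpy(),
            "passed_p_filter": passed_p,
            "passed_r2_filter": passed_r2,
            "significant": significant,
        },
        index=calls.index.rename("transcript_id"),
    )


@dataclass(frozen=True)
class CellTypeMap:
    """Mapping from one model's cell-type labels to a shared ontology."""

    name: str
    mapping: tuple[tuple[str, str], ...]

    def as_dict(self) -> dict[str, str]:
        return dict(self.mapping)

    def apply(self, cell_type: str) -> str:
        try:
            return self.as_dict()[cell_type]
        except KeyError:
            raise ValidationError(
                f"cell type {cell_type!r} is not mapped by {self.name!r}"
            ) from None

    @classmethod
    def from_dict(cls, name: str, mapping: dict[str, str]) -> "CellTypeMap":
        return cls(name, tuple(sorted(mapping.items())))

    @classmethod
    def from_yaml(cls, path) -> dict[str, "CellTypeMap"]:
        """Load ``{map_name: {model_type: shared_label, ...}, ...}``."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return {n: cls.from_dict(n, m) for n, m in raw.items()}


#: Identity map for a model annotated directly on the shared ontology.
COARSE_TME_MAP = CellTypeMap.from_dict(
    "coarse_tme", {t: t for t in SHARED_ONTOLOGY}
)
#: Map for a model with finer myeloid/stromal annotation: macrophages are a
#: subtype of myeloid cells; fibroblasts and endothelial cells are stromal.
FINE_TME_MAP = CellTypeMap.from_dict(
    "fine_tme",
    {
        "T": "T",
        "B": "B",
        "epithelial": "epithelial",
        "mast": "mast",
        "macrophage": "myeloid",
        "fibroblast": "stromal",
        "endothelial": "stromal",
    },
)


def consensus(
    calls_a: pd.DataFrame,
    map_a: CellTypeMap,
    calls_b: pd.DataFrame,
    map_b: CellTypeMap,
) -> pd.DataFrame:
    """Transcripts significant in both models with matching shared cell type.

    Input frames are ``apply_filters`` outputs. Returns columns
    ``transcript_id, shared_cell_type`` sorted by transcript id; symmetric
    in its two model arguments.
    """
    sig_a = calls_a[calls_a["significant"]]
    sig_b = calls_b[calls_b["significant"]]
    shared_a = {t: map_a.apply(ct) for t, ct in sig_a["exclusive_cell_type"].items()}
    shared_b = {t: map_b.apply(ct) for t, ct in sig_b["exclusive_cell_type"].items()}
    rows = [
        (t, shared_a[t])
        for t in sorted(set(shared_a) & set(shared_b))
        if shared_a[t] == shared_b[t]
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "shared_cell_type"])
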