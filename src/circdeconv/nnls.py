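"""Non-negative least squares by the Lawson–Hanson active-set algorithm,
and per-transcript cell-type deconvolution built on it.

The deconvolution model: each transcript's bulk expression across samples is
a non-negative linear combination of the samples' cell-type proportions,

    y_g ≈ Pᵀ β_g,   β_g ≥ 0,

where Pᵀ is the samples × cell-types proportion matrix and β_g the
transcript's cell-type-specific expression levels. NNLS is a convex problem;
the active-set algorithm terminates at the global optimum with *exact* zeros
on the constrained coordinates, which is what makes downstream
"expressed in exactly one cell type" calls well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrices import ExpressionMatrix, ProportionMatrix, ValidationError

__all__ = [
    "NNLSError",
    "NNLSSolution",
    "nnls_solve",
    "CoefficientMatrix",
    "fit_cell_type_expression",
]

logger = logging.getLogger(__name__)


class NNLSError(ValueError):
    """Invalid NNLS input or failed convergence."""


@dataclass
class NNLSSolution:
    """Solution of min ||Xβ − y||₂ s.t. β ≥ 0.

    ``active_set`` holds the indices pinned at the zero bound; entries of
    ``beta`` at those indices are exact floating-point zeros.
    """

    beta: np.ndarray
    residual_norm: float
    active_set: frozenset[int]
    iterations: int


def nnls_solve(
    X, y, tol: float = 1e-10, max_iter: int | None = None
) -> NNLSSolution:
    """Lawson–Hanson active-set solution of the NNLS problem.

    Parameters
    ----------
    X : (n, k) array
        Design matrix.
    y : (n,) array
        Response vector.
    tol
        KKT tolerance on the gradient, relative to the problem scale
        ``max(1, ‖Xᵀy‖_∞)``: a coordinate enters the passive set only while
        its (negated) gradient exceeds ``tol × scale``.
    max_iter
        Cap on passive-set insertions; defaults to ``3k``. Exceeding it
        raises (unreachable for well-posed inputs — the safeguard exists to
        surface degenerate instances rather than loop).

    Notes
    -----
    The anti-cycling safeguard is the standard one: the inner loop moves
    along the feasible segment toward the unconstrained subproblem solution
    and evicts every coordinate that hits zero, so each outer iteration
    strictly decreases the objective. Ties in the most-negative-gradient
    selection break toward the lowest index, making the output deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise NNLSError(f"X must be 2-D, got shape {X.shape}")
    n, k = X.shape
    if y.shape != (n,):
        raise NNLSError(f"y shape {y.shape} incompatible with X shape {X.shape}")
    if n < 1 or k < 1:
        raise NNLSError("X must have at least one row and one column")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise NNLSError("non-finite values in X or y")
    if max_iter is None:
        max_iter = 3 * k

    Xty = X.T @ y
    scale = max(1.0, float(np.abs(Xty).max()))
    gtol = tol * scale

    beta = np.zeros(k)
    passive = np.zeros(k, dtype=bool)
    iterations = 0

    while True:
        # Negated gradient of ½‖Xβ − y‖²: w = Xᵀ(y − Xβ)
        w = Xty - X.T @ (X @ beta)
        w_free = np.where(passive, -np.inf, w)
        j = int(np.argmax(w_free))  # argmax breaks ties toward lowest index
        if w_free[j] <= gtol:
            break  # KKT satisfied: optimum reached
        iterations += 1
        if iterations > max_iter:
            raise NNLSError(
                f"NNLS failed to converge within {max_iter} iterations "
                f"(n={n}, k={k}); instance may be degenerate"
            )
        passive[j] = True

        while True:
            idx = np.flatnonzero(passive)
            s_sub, *_ = np.linalg.lstsq(X[:, idx], y, rcond=None)
            if np.all(s_sub > 0):
                beta = np.zeros(k)
                beta[idx] = s_sub
                break
            # Step toward s along the feasible segment; evict zeros.
            s = np.zeros(k)
            s[idx] = s_sub
            shrink = idx[s_sub <= 0]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = beta[shrink] / (beta[shrink] - s[shrink])
            alpha = float(np.min(ratios))
            beta = beta + alpha * (s - beta)
            beta[shrink[ratios <= alpha + 1e-15]] = 0.0
            passive &= beta > 0
            if not passive.any():
                beta = np.zeros(k)
                break

    beta[~passive] = 0.0  # exact zeros on the active set
    residual = y - X @ beta
    return NNLSSolution(
        beta=beta,
        residual_norm=float(np.linalg.norm(residual)),
        active_set=frozenset(np.flatnonzero(~passive).tolist()),
        iterations=iterations,
    )


@dataclass
class CoefficientMatrix:
    """Transcripts × cell types non-negative expression estimates.

    Zero entries are exact active-set zeros when produced by
    :func:`fit_cell_type_expression`.
    """

    transcript_ids: list[str]
    cell_types: list[str]
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.transcript_ids = [str(t) for t in self.transcript_ids]
        self.cell_types = [str(c) for c in self.cell_types]
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        expected = (len(self.transcript_ids), len(self.cell_types))
        if self.coefficients.shape != expected:
            raise ValidationError(
                f"coefficients shape {self.coefficients.shape} inconsistent with {expected}"
            )
        if np.any(~np.isfinite(self.coefficients)) or np.any(self.coefficients < 0):
            raise ValidationError("coefficients must be finite and non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.coefficients, index=self.transcript_ids, columns=self.cell_types
        )

    def write(self, path) -> None:
        from .matrices import FLOAT_FORMAT

        df = self.to_frame()
        df.index.name = "transcript_id"
        df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)

    @classmethod
    def read(cls, path) -> "CoefficientMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", header=0, index_col=0,
                     float_precision="round_trip")
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
        )


def fit_cell_type_expression(
    bulk: ExpressionMatrix,
    proportions: ProportionMatrix,
    groups: dict[str, list[str]] | None = None,
    tol: float = 1e-10,
) -> CoefficientMatrix | dict[str, CoefficientMatrix]:
    """Per-transcript NNLS deconvolution of bulk expression.

    For every transcript g the regression ``y_g ≈ Pᵀ β_g, β_g ≥ 0`` is
    solved across samples, stacking the β_g into a transcripts × cell-types
    coefficient matrix. When ``groups`` maps labels to sample-id subsets, an
    independent fit is returned per group.

    All-zero transcripts yield all-zero coefficient rows (logged).
    """
    missing = [s for s in bulk.sample_ids if s not in set(proportions.sample_ids)]
    extra = [s for s in proportions.sample_ids if s not in set(bulk.sample_ids)]
    if missing or extra:
        raise ValidationError(
            f"sample ids differ between bulk and proportions "
            f"(missing from proportions: {missing[:3]}, extra: {extra[:3]})"
        )
    props = proportions.reorder_samples(bulk.sample_ids)

    if groups is not None:
        out = {}
        sample_index = {s: i for i, s in enumerate(bulk.sample_ids)}
        for label, sample_ids in groups.items():
            unknown = [s for s in sample_ids if s not in sample_index]
            if unknown:
                raise ValidationError(
                    f"group {label!r} references unknown sample(s) {unknown[:3]}"
                )
            cols = [sample_index[s] for s in sample_ids]
            sub_bulk = ExpressionMatrix(
                list(bulk.transcript_ids),
                list(sample_ids),
                bulk.values[:, cols],
                bulk.unit_label,
            )
            sub_props = props.reorder_samples(list(sample_ids))
            out[label] = fit_cell_type_expression(sub_bulk, sub_props, tol=tol)
        return out

    if bulk.n_samples < 2:
        raise ValidationError("deconvolution needs at least 2 samples")
    X = props.fractions.T  # samples × cell types
    coeffs = np.zeros((bulk.n_transcripts, props.n_cell_types))
    n_zero = 0
    for g in range(bulk.n_transcripts):
        y = bulk.values[g]
        if not y.any():
            n_zero += 1
            continue
        coeffs[g] = nnls_solve(X, y, tol=tol).beta
    if n_zero:
        logger.info("%d all-zero transcript(s) given all-zero coefficients", n_zero)
    return CoefficientMatrix(
        list(bulk.transcript_ids), list(props.cell_types), coeffs
    )
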