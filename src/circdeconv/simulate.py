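"""Synthetic bulk-mixture generator with known cell-type ground truth.

Emulates the statistical structure the deconvolution assumes: per-sample
cell-type proportions drawn from a Dirichlet, non-negative cell-type
expression profiles with a controllable fraction of single-cell-type
transcripts, and count noise (Poisson or negative-binomial) applied on the
raw-count scale and mapped back to the normalized scale.

Two abundance regimes matter. Linear genes live on a TPM-like scale whose
upper quartile of mean bulk expression is ≈1.7; circRNAs are ~400× lower
(normalized backspliced reads, upper quartile ≈0.004), which is what makes
their deconvolution hard: at realistic sequencing depth most circRNA
entries correspond to fractional expected read counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import (
    ExpressionMatrix,
    ProportionMatrix,
    ValidationError,
    read_expression_matrix,
    read_proportions,
    write_expression_matrix,
    write_proportions,
)
from .nnls import CoefficientMatrix

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate", "export_fixture", "load_fixture"]

#: Cell-type labels used when k matches the default tumor-microenvironment set.
DEFAULT_CELL_TYPES = ("T", "B", "epithelial", "mast", "myeloid", "stromal")

NOISE_MODELS = ("none", "poisson", "negative_binomial")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror the bulk cohort regime the pipeline targets: 30 samples,
    6 cell types, lognormal expression amplitudes putting the upper quartile
    of mean linear bulk at ≈1.7 TPM, a circRNA block scaled down 400×
    (``circ_abundance_scale``), negative-binomial count noise with dispersion
    0.1, and total sequencing depths of 20–60 million reads.
    """

    n_cell_types: int = 6
    n_samples: int = 30
    n_linear: int = 300
    n_circ: int = 300
    specific_fraction: float = 0.3
    dirichlet_alpha: tuple[float, ...] | None = None  # None → flat (all ones)
    circ_abundance_scale: float = 0.0025
    noise_model: str = "negative_binomial"
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (2e7, 6e7)
    seed: int = 0
    # Amplitude distribution (lognormal): specific transcripts get a larger
    # location so a single cell type carries the whole transcript's output.
    lognormal_mu_specific: float = 1.0
    lognormal_mu_shared: float = 0.0
    lognormal_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cell_types < 2:
            raise ValidationError("n_cell_types must be ≥ 2")
        if min(self.n_samples, self.n_linear + self.n_circ) < 1:
            raise ValidationError("empty simulation requested")
        if not 0 <= self.specific_fraction <= 1:
            raise ValidationError("specific_fraction must be in [0, 1]")
        if self.noise_model not in NOISE_MODELS:
            raise ValidationError(f"noise_model must be one of {NOISE_MODELS}")
        if self.nb_dispersion <= 0 or self.circ_abundance_scale <= 0:
            raise ValidationError("dispersion and abundance scale must be positive")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValidationError("library_size_range must be positive and ordered")
        if self.dirichlet_alpha is not None and len(self.dirichlet_alpha) != self.n_cell_types:
            raise ValidationError("dirichlet_alpha length must equal n_cell_types")

    @property
    def cell_types(self) -> list[str]:
        if self.n_cell_types == len(DEFAULT_CELL_TYPES):
            return list(DEFAULT_CELL_TYPES)
        return [f"CT{i + 1}" for i in range(self.n_cell_types)]


@dataclass
class SyntheticTruth:
    """Ground truth bundle: profiles, proportions, and noiseless/observed bulk.

    ``bulk_noiseless`` equals ``true_coefficients @ true_proportions``
    exactly; ``specific_labels`` maps each transcript to its single
    expressing cell type, or None for transcripts expressed everywhere.
    """

    config: SimulationConfig
    true_coefficients: CoefficientMatrix
    true_proportions: ProportionMatrix
    specific_labels: pd.Series
    bulk_noiseless: ExpressionMatrix
    bulk_observed: ExpressionMatrix
    library_sizes: pd.Series = field(repr=False, default=None)

    def linear_ids(self) -> list[str]:
        return self.true_coefficients.transcript_ids[: self.config.n_linear]

    def circ_ids(self) -> list[str]:
        return self.true_coefficients.transcript_ids[self.config.n_linear:]


def _draw_coefficients(cfg: SimulationConfig, rng: np.random.Generator):
    """Coefficient block plus per-transcript specific-cell-type labels."""
    n_total = cfg.n_linear + cfg.n_circ
    k = cfg.n_cell_types
    coeffs = np.zeros((n_total, k))
    labels = np.full(n_total, None, dtype=object)

    def fill_block(sl: slice, scale: float) -> None:
        n = sl.stop - sl.start
        if n == 0:
            return
        n_spec = int(round(cfg.specific_fraction * n))
        order = rng.permutation(n) + sl.start
        spec_rows, shared_rows = order[:n_spec], order[n_spec:]
        types = rng.integers(0, k, size=n_spec)
        amp = rng.lognormal(cfg.lognormal_mu_specific, cfg.lognormal_sigma, size=n_spec)
        coeffs[spec_rows, types] = amp * scale
        labels[spec_rows] = [cfg.cell_types[t] for t in types]
        coeffs[shared_rows, :] = (
            rng.lognormal(cfg.lognormal_mu_shared, cfg.lognormal_sigma, size=(len(shared_rows), k))
            * scale
        )

    fill_block(slice(0, cfg.n_linear), 1.0)
    fill_block(slice(cfg.n_linear, n_total), cfg.circ_abundance_scale)
    ids = [f"gene{i + 1:05d}" for i in range(cfg.n_linear)] + [
        f"circ{i + 1:05d}" for i in range(cfg.n_circ)
    ]
    return ids, coeffs, pd.Series(labels, index=ids, name="specific_cell_type")


def _apply_noise(
    noiseless: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Count noise on the raw scale, mapped back to the normalized scale.

    Expected counts are ``noiseless × depth/10⁶`` (per-million factor), so
    E[observed] = noiseless under both noise models.
    """
    lo, hi = cfg.library_size_range
    depths = rng.uniform(lo, hi, size=noiseless.shape[1])
    if cfg.noise_model == "none":
        return noiseless.copy(), depths
    factor = depths / 1e6
    mean_counts = noiseless * factor[None, :]
    if cfg.noise_model == "poisson":
        counts = rng.poisson(mean_counts)
    else:
        r = 1.0 / cfg.nb_dispersion
        # NB with mean m, variance m + m²·dispersion
        counts = rng.negative_binomial(r, r / (r + mean_counts))
    return counts / factor[None, :], depths


def simulate(config: SimulationConfig) -> SyntheticTruth:
    """Draw a complete synthetic study from ``config`` (reproducible by seed)."""
    if config.n_samples < config.n_cell_types:
        warnings.warn(
            f"n_samples ({config.n_samples}) < n_cell_types ({config.n_cell_types}): "
            "the per-transcript design matrix is underdetermined",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    alpha = (
        np.ones(config.n_cell_types)
        if config.dirichlet_alpha is None
        else np.asarray(config.dirichlet_alpha, dtype=float)
    )
    fractions = rng.dirichlet(alpha, size=config.n_samples).T  # k × n
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    proportions = ProportionMatrix(config.cell_types, sample_ids, fractions)

    ids, coeffs, labels = _draw_coefficients(config, rng)
    coeff_matrix = CoefficientMatrix(ids, config.cell_types, coeffs)
    noiseless = coeffs @ fractions
    observed, depths = _apply_noise(noiseless, config, rng)

    # The stacked matrix carries both blocks; the linear block is TPM-like
    # but the shared label keeps the container honest about its scale.
    unit = "normalized_backspliced_reads"
    return SyntheticTruth(
        config=config,
        true_coefficients=coeff_matrix,
        true_proportions=proportions,
        specific_labels=labels,
        bulk_noiseless=ExpressionMatrix(ids, sample_ids, noiseless, unit),
        bulk_observed=ExpressionMatrix(ids, sample_ids, observed, unit),
        library_sizes=pd.Series(depths, index=sample_ids, name="library_size"),
    )


def reobserve(truth: SyntheticTruth, seed: int) -> ExpressionMatrix:
    """A fresh noisy observation of the same noiseless bulk.

    Useful for building two independently observed "models" of one ground
    truth (the noise model and depth range come from the original config).
    """
    rng = np.random.default_rng(seed)
    observed, _ = _apply_noise(truth.bulk_noiseless.values, truth.config, rng)
    return ExpressionMatrix(
        list(truth.bulk_noiseless.transcript_ids),
        list(truth.bulk_noiseless.sample_ids),
        observed,
        truth.bulk_noiseless.unit_label,
    )


def resample_proportions(
    truth: SyntheticTruth, concentration: float, seed: int
) -> ProportionMatrix:
    """Dirichlet-resampled proportions centred on the truth.

    Emulates estimation error in an upstream cell-fraction tool: each
    sample's fractions are redrawn from Dirichlet(concentration × p + ε).
    Larger ``concentration`` → smaller perturbation.
    """
    rng = np.random.default_rng(seed)
    p = truth.true_proportions.fractions
    out = np.empty_like(p)
    for s in range(p.shape[1]):
        out[:, s] = rng.dirichlet(concentration * p[:, s] + 1e-9)
    return ProportionMatrix(
        list(truth.true_proportions.cell_types),
        list(truth.true_proportions.sample_ids),
        out,
    )


_FIXTURE_FILES = {
    "observed": "bulk_observed.tsv",
    "noiseless": "bulk_noiseless.tsv",
    "proportions": "proportions.tsv",
    "coefficients": "true_coefficients.tsv",
    "labels": "specific_labels.tsv",
}


def export_fixture(truth: SyntheticTruth, directory) -> dict[str, Path]:
    """Write all truth tables as TSVs; read-back reproduces the objects."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {k: d / v for k, v in _FIXTURE_FILES.items()}
    write_expression_matrix(truth.bulk_observed, paths["observed"])
    write_expression_matrix(truth.bulk_noiseless, paths["noiseless"])
    write_proportions(truth.true_proportions, paths["proportions"])
    truth.true_coefficients.write(paths["coefficients"])
    labels = truth.specific_labels.fillna("").rename("specific_cell_type")
    labels.index.name = "transcript_id"
    labels.to_frame().to_csv(paths["labels"], sep="\t")
    return paths


def load_fixture(directory) -> dict:
    """Read back a fixture directory written by :func:`export_fixture`."""
    d = Path(directory)
    labels = pd.read_csv(
        d / _FIXTURE_FILES["labels"], sep="\t", index_col=0, dtype=str
    )["specific_cell_type"].replace("", np.nan).where(lambda s: s.notna(), None)
    return {
        "bulk_observed": read_expression_matrix(
            d / _FIXTURE_FILES["observed"], "normalized_backspliced_reads"
        ),
        "bulk_noiseless": read_expression_matrix(
            d / _FIXTURE_FILES["noiseless"], "normalized_backspliced_reads"
        ),
        "proportions": read_proportions(d / _FIXTURE_FILES["proportions"]),
        "coefficients": CoefficientMatrix.read(d / _FIXTURE_FILES["coefficients"]),
        "specific_labels": labels,
    }
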