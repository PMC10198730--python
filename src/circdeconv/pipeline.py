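"""End-to-end orchestration: simulate/load → fit → benchmark → specificity → consensus.

Every stage's output is persisted as a TSV so any stage can be re-run from
files alone; a JSON manifest records counts and file paths. All randomness
derives from one top-level seed via fixed per-stage offsets.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

from .benchmark import (
    per_sample_diagnostics,
    per_transcript_diagnostics,
    reconstruct_bulk,
    summarize_diagnostics,
)
from .matrices import (
    ExpressionMatrix,
    ValidationError,
    read_expression_matrix,
    read_proportions,
)
from .nnls import fit_cell_type_expression
from .simulate import SimulationConfig, export_fixture, reobserve, simulate
from .specificity import CellTypeMap, apply_filters, call_exclusive, consensus

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as e:
        raise PipelineError(f"stage {name!r} failed: {e}") from e
    logger.info("stage %s: done", name)


@dataclass
class RunConfig:
    """Configuration for one end-to-end run.

    Exactly one of ``simulation`` or (``expr_path`` + ``proportions_paths``)
    must be supplied. ``proportions_paths`` maps a model label to that
    model's proportion table; with a simulation, the two models are two
    independent noisy observations of the same ground truth fitted against
    the true proportions.
    """

    out_dir: str | Path
    seed: int = 0
    simulation: SimulationConfig | None = None
    expr_path: str | Path | None = None
    expr_unit: str = "normalized_backspliced_reads"
    proportions_paths: dict[str, str | Path] = field(default_factory=dict)
    renormalize_proportions: bool = False
    cell_type_maps: dict[str, CellTypeMap] = field(default_factory=dict)
    alpha: float = 0.05
    relative_tol: float = 0.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        sim = self.simulation is not None
        files = self.expr_path is not None or bool(self.proportions_paths)
        if sim == files:
            raise ValidationError(
                "supply exactly one of: a SimulationConfig, or expression + proportion paths"
            )
        if not sim:
            if self.expr_path is None:
                raise ValidationError("expr_path is required for a file-based run")
            if not self.proportions_paths:
                raise ValidationError(
                    "at least one model's proportions path is required"
                )


def _identity_map(label: str, cell_types) -> CellTypeMap:
    return CellTypeMap.from_dict(label, {c: c for c in cell_types})


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return the manifest (also written to summary.json)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "models": {}, "outputs": {}}

    # --- assemble per-model inputs: (observed bulk, proportions) ----------
    models: dict[str, tuple[ExpressionMatrix, object]] = {}
    truth = None
    if config.simulation is not None:
        with _stage("simulate"):
            truth = simulate(
                SimulationConfig(
                    **{**config.simulation.__dict__, "seed": config.seed}
                )
            )
            fixture_dir = out / "fixture"
            export_fixture(truth, fixture_dir)
            manifest["outputs"]["fixture"] = str(fixture_dir)
            second = reobserve(truth, seed=config.seed + 1_000_003)
            models["model_A"] = (truth.bulk_observed, truth.true_proportions)
            models["model_B"] = (second, truth.true_proportions)
    else:
        with _stage("load"):
            bulk = read_expression_matrix(config.expr_path, config.expr_unit)
            for label, ppath in config.proportions_paths.items():
                try:
                    props = read_proportions(
                        ppath, renormalize=config.renormalize_proportions
                    )
                except FileNotFoundError:
                    raise ValidationError(
                        f"model {label!r}: proportions file not found: {ppath}"
                    ) from None
                models[label] = (bulk, props)

    # --- per-model fit, benchmark, specificity ----------------------------
    per_model_calls: dict[str, object] = {}
    maps: dict[str, CellTypeMap] = {}
    for label, (bulk, props) in models.items():
        mdir = out / label
        mdir.mkdir(exist_ok=True)
        with _stage(f"deconvolve[{label}]"):
            coeff = fit_cell_type_expression(bulk, props)
            coeff.write(mdir / "coefficients.tsv")
        with _stage(f"benchmark[{label}]"):
            modeled = reconstruct_bulk(coeff, props, unit_label=bulk.unit_label)
            fit_diag = per_transcript_diagnostics(modeled, bulk)
            samp_diag = per_sample_diagnostics(modeled, bulk)
            fit_diag.table.to_csv(
                mdir / "per_transcript_diagnostics.tsv", sep="\t", index=False
            )
            samp_diag.table.to_csv(
                mdir / "per_sample_diagnostics.tsv", sep="\t", index=False
            )
            summary = summarize_diagnostics(fit_diag, samp_diag)
        with _stage(f"specificity[{label}]"):
            exclusive = call_exclusive(coeff, relative_tol=config.relative_tol)
            calls = apply_filters(exclusive, fit_diag, alpha=config.alpha)
            calls.to_csv(mdir / "specificity.tsv", sep="\t")
        per_model_calls[label] = calls
        maps[label] = config.cell_type_maps.get(
            label, _identity_map(label, props.cell_types)
        )
        manifest["models"][label] = {
            "n_transcripts": bulk.n_transcripts,
            "n_samples": bulk.n_samples,
            "n_exclusive": int(calls["exclusive_cell_type"].notna().sum()),
            "n_significant": int(calls["significant"].sum()),
            "benchmark": summary,
            "outputs": str(mdir),
        }

    # --- cross-model consensus --------------------------------------------
    if len(models) == 2:
        with _stage("consensus"):
            (la, ca), (lb, cb) = per_model_calls.items()
            cons = consensus(ca, maps[la], cb, maps[lb])
            cons.to_csv(out / "consensus.tsv", sep="\t", index=False)
            manifest["n_consensus"] = int(len(cons))
            manifest["outputs"]["consensus"] = str(out / "consensus.tsv")

    with _stage("report"):
        with open(out / "summary.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
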