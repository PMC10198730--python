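# circdeconv

Cell-type-specific circRNA expression from bulk RNA-seq, by per-transcript
non-negative least squares (NNLS) deconvolution against cell-type
proportions — with reconstruction-based benchmarking, a two-filter
significance rule, and cross-model consensus calling of cell-type-specific
transcripts.

## The problem

Circular RNAs (circRNAs) are covalently closed transcripts identified and
quantified by their backsplice junctions. In bulk tumor RNA-seq, a sample is
a mixture of cell types (T, B, epithelial, mast, myeloid, stromal, …), so a
circRNA's bulk signal says nothing about *which* cell type expresses it —
and circRNAs are far too lowly expressed for routine single-cell protocols
to resolve. Given per-sample cell-type proportions (from an upstream
cell-fraction tool such as CIBERSORT), the expression of each transcript can
instead be decomposed computationally.

## The model

For transcript *g* with bulk expression **y**<sub>g</sub> across *n*
samples, and a cell-types × samples proportion matrix **p**:

&nbsp;&nbsp;&nbsp;&nbsp;**y**<sub>g</sub> ≈ **p**ᵀ **β**<sub>g</sub>,&nbsp;&nbsp;**β**<sub>g</sub> ≥ 0

solved exactly by the Lawson–Hanson active-set algorithm (implemented here
from scratch; coefficients constrained at zero are *exact* zeros). Stacking
the **β**<sub>g</sub> gives the transcripts × cell-types coefficient matrix
**B** (linear genes) or **C** (circRNAs). The fit is evaluated by
reconstructing modeled bulk **L** = **B p** (or **N** = **C p**) and scoring
per-transcript R²/p (linear regression across samples) and per-sample
Pearson r (across transcripts).

A transcript is called **cell-type specific** when exactly one cell type
carries positive expression and the fit passes two filters: p < 0.05 and
R² above the median R² of the run. Two independently trained models must
agree on the (ontology-mapped) cell type — macrophages count as myeloid
cells; fibroblasts and endothelial cells count as stromal — for a
**consensus** call.

The package also implements the surrounding plumbing: TPM and
depth-normalization, the expression prefilters (≥5 TPM in 25% of samples
for genes; ≥1 backspliced read in 15% for circRNAs), DE-call thresholds
(p < 0.05, |logFC| > 0, FDR ≤ 0.15) with cross-tool validation logic,
1-bp-adjusted backsplice-junction set comparison across database coordinate
dialects, and a seeded synthetic-cohort generator with known ground truth.

## Worked example

```sh
python examples/01_simulate_and_deconvolve.py
```

```
cohort: 400 transcripts × 30 samples, cell types: T, B, epithelial, mast, myeloid, stromal
median recovery correlation, linear genes: 0.959
median recovery correlation, circRNAs:     0.224
```

The generator drew a 30-sample cohort with Dirichlet proportions and
negative-binomial count noise; the NNLS fit recovers the known cell-type
profile of a typical linear gene almost perfectly (r ≈ 0.96), while the
circRNA block — simulated ~400× lower in abundance, matching the gap
observed between gene TPM and normalized backspliced reads in real
cohorts — is much harder to recover (r ≈ 0.22) at the same depth. The other
`examples/` scripts walk through reconstruction benchmarking, the
specificity + consensus calls, junction-dialect comparison, and the
prefilter/DE-consensus logic, one capability each.

Everything is also reachable from the shell via the `circdeconv` CLI
(`simulate`, `normalize`, `prefilter`, `de-call`, `de-consensus`,
`deconvolve`, `benchmark`, `specificity`, `consensus`, `junctions-compare`,
`run`).

## Layout

- `src/circdeconv/` — the library (`matrices`, `junctions`, `prep`,
  `simulate`, `nnls`, `benchmark`, `specificity`, `evaluation`,
  `pipeline`, `cli`)
- `examples/` — one short narrative script per capability
- `docs/methods.md` — model, assumptions, parameter choices, limitations
- `tests/` — pytest suite, including the end-to-end property tests
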