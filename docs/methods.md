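# Methods

## Deconvolution model

Each transcript's bulk expression across samples is modeled as a
non-negative mixture of the samples' cell-type composition:
for transcript *g*, `y_g ≈ Pᵀ β_g` with `β_g ≥ 0`, where `Pᵀ` is the
samples × cell-types proportion matrix (each sample's fractions sum to 1)
and `β_g` is the transcript's cell-type-specific expression level vector.
There is **no intercept**: bulk expression is assumed to be exactly a
proportion-weighted average of cell-type expression, so a transcript
expressed nowhere is expected at zero. The same proportion matrix serves
linear genes and circRNAs — proportions are estimated upstream from linear
genes (or simulated) and reused for the circRNA block.

The regression runs **per transcript across samples**. This is the only
orientation consistent with the reconstruction algebra `L = B·p`
(transcripts × samples = [transcripts × cell types] · [cell types ×
samples]); a per-sample fit would estimate one coefficient vector per
sample and could not be multiplied back against `p`. An optional `groups`
argument fits disjoint sample subsets (e.g. tissue groups) independently.

### Solver

NNLS is solved by a from-scratch Lawson–Hanson active-set implementation
(`nnls_solve`). Properties that matter downstream:

- **Exact zeros.** Coefficients on the active set are assigned `0.0`
  exactly, which makes "expressed in exactly one cell type" a well-defined
  predicate rather than a thresholding choice.
- **Global optimum.** NNLS is convex; the active-set method terminates at
  the KKT point. The suite verifies the objective against brute-force
  support enumeration (all 2^k supports, unconstrained LS on each, best
  feasible kept) and against an independent library implementation.
- **Determinism.** Ties in the most-negative-gradient selection break
  toward the lowest index.
- **Tolerances.** The KKT gradient tolerance is `tol × max(1, ‖Xᵀy‖∞)`
  with `tol = 1e-10`, i.e. relative to the problem scale, so fits behave
  identically for TPM-scale and normalized-backsplice-scale inputs. The
  outer-iteration cap is `3k` (k = number of cell types); exceeding it
  raises rather than looping — unreachable for the well-posed designs
  produced by proportion matrices.
- All-zero transcripts short-circuit to all-zero coefficient rows.

## Reconstruction benchmark

Modeled bulk is `B·p`. Two diagnostics:

- **Per transcript**: simple linear regression of ground-truth on modeled
  values across samples; R² (the squared Pearson correlation) and the
  two-sided t-test on the slope with n−2 df. Regression direction does not
  affect R² or that p-value; truth-on-modeled is fixed so reported slopes
  are deterministic. A transcript is **undefined** when either series is
  constant or n < 3; undefined transcripts are excluded from medians and
  can never be called specific.
- **Per sample**: Pearson r across transcripts, with its two-sided test.

## Specificity calls and consensus

A transcript is *exclusive* when exactly one cell type's coefficient
exceeds `max(zero_tol, relative_tol × row max)`:

- `zero_tol = 0` (default): only exact active-set zeros count as absent —
  the right semantics for noiseless data and for deciding support
  structure.
- `relative_tol`: under count noise, NNLS leaks small positive
  coefficients onto non-expressing cell types, so exact-zero support is
  not identifiable; the noisy-regime analyses use `relative_tol = 0.2`,
  i.e. a cell type contributing less than 20% of the transcript's dominant
  coefficient is treated as numerical leakage. The two-model consensus and
  the two significance filters then remove most of the remaining false
  exclusives (measured operating characteristics: see
  `scripts/acceptance.py` output).

*Significant* additionally requires p < 0.05 (strict) and R² strictly
greater than the median R² over all transcripts with defined diagnostics in
the same run — the median is computed within the transcript class being
analyzed (a circRNA run's median comes from circRNAs only). The p-value
used is the reconstruction-regression p-value, the only per-transcript test
the benchmark defines.

*Consensus* requires significance in both models with cell types mapping to
the same shared ontology label. The shipped maps follow the standard tumor
microenvironment merges: macrophages ⊂ myeloid; fibroblasts, endothelial ⊂
stromal. Maps are YAML-overridable; an unmapped cell type in a significant
call is an error, not a silent drop.

## Prefilters, DE calls, cross-tool validation

- Prefilter: keep a transcript when ≥ `min_sample_fraction` of samples
  (non-strict) reach `min_value` (non-strict). Defaults: genes ≥5 TPM in
  25% of samples; circRNAs ≥1 **raw** backspliced read in 15% of samples
  (the circRNA rule thresholds raw counts even when the analysis matrix is
  normalized). Fractions are evaluated over all samples passed in.
- DE call (from an external edgeR-style table): p < 0.05 (strict),
  |logFC| > 0 (strict), FDR ≤ 0.15 (non-strict). The statistical tests
  themselves are not reimplemented; only their result tables are consumed.
- Cross-tool validation: a CIRIquant-style record concurs at p < 0.05 in
  the same comparison group (PvN/MvN/MvP) and direction; a CircTest-style
  record concurs on group alone (its test statistic carries no comparable
  signed fold change). Transcripts absent from a secondary table simply do
  not concur.

## Junction conventions

Canonical internal convention is BED-style 0-based half-open, matching the
BED output of chimeric-alignment extraction. Junction identity is the bare
`(chrom, start, end)` pair — most databases characterize circRNAs only by
backsplice coordinates — with strand matching off by default. Per-source
dialects (`start_basis` ∈ {0, 1}, `end_inclusive`) implement the 1-bp
adjustments needed across databases; the built-in registry entries for
specific databases are documented best guesses and are YAML-overridable.
Normalization is exact integer arithmetic, idempotent, and invertible
through every dialect.

## Synthetic cohorts

The generator emulates the statistical structure the deconvolution assumes:

- **Proportions**: per sample from Dirichlet(α), default α = 1 (flat) over
  k = 6 cell types labeled T, B, epithelial, mast, myeloid, stromal;
  n = 30 samples by default.
- **Profiles**: a `specific_fraction` (default 0.3) of transcripts get a
  single positive coefficient (cell type uniform at random), amplitude
  lognormal(µ = 1, σ = 1); the rest are positive in all cell types,
  entries lognormal(0, 1). These amplitudes put the upper quartile of mean
  noiseless bulk at ≈ 1.7 on the linear (TPM-like) scale.
- **Abundance regimes**: the circRNA block is scaled by
  `circ_abundance_scale` (default 0.0025, i.e. ≈ 400× below the gene
  scale), reproducing the observed gap between gene TPM (upper quartile
  ≈ 1.68) and normalized backspliced reads (≈ 0.004). At realistic depth
  this puts most circRNA entries at fractional expected read counts —
  which is precisely what makes circRNA deconvolution hard, and what the
  degradation analyses measure.
- **Noise**: expected raw counts are `bulk × depth/10⁶` with per-sample
  depths uniform in 20–60 million reads; counts drawn Poisson or
  negative-binomial (mean m, variance m + φm², default dispersion
  φ = 0.1 — a typical bulk RNA-seq value), then mapped back to the
  normalized scale, so E[observed] = noiseless under both models.
  `noise_model="none"` returns the exact mixture.
- Everything derives from one `numpy` Generator seeded by `seed`;
  `reobserve` redraws only the noise for a fixed truth (used to build two
  independently observed "models" of the same cohort), and
  `resample_proportions` perturbs proportions Dirichlet-style to emulate
  upstream estimation error.

What the generator does **not** emulate: real signature-matrix /
cell-fraction estimation error structure (only the simple Dirichlet
resampling knob), correlated transcripts, isoform structure, batch
effects, zero-inflation beyond what NB at low means produces, or
library-preparation biases. Passing recovery tests on these cohorts shows
the estimator is correct *under its own model assumptions*; it does not
certify performance on real cohorts where proportions are themselves
estimates.

## Problem sizes and numerical choices

The end-to-end stochastic analyses use 300 transcripts × 30 samples × 6
cell types × 10 seed replicates per abundance regime — large enough for
stable operating characteristics, small enough that the full suite and the
acceptance script each run in seconds. Tabular I/O is tab-separated UTF-8
with `%.17g` floats and round-trip-exact parsing, so write→read is
bit-exact and repeated runs with the same seed produce byte-identical
outputs. Proportion columns must sum to 1 within 1e-6 (renormalization
available on read); expression matrices admit no negatives and no missing
values — absent measurements must be encoded as 0 upstream.

## Known limitations

- Proportions are consumed, never estimated: the package deliberately
  contains no signature-matrix construction or cell-fraction regression.
- The exclusivity call under noise depends on `relative_tol`; 0.2 is a
  pragmatic default measured to balance sensitivity and precision on
  synthetic cohorts, not a universal constant.
- Consensus sensitivity is bounded by the R²-above-median filter: a
  truly specific transcript whose fit lands below the run median is
  unrecoverable by design.
- At the real circRNA abundance regime, most transcripts' profiles are
  not recoverable at typical depth; the pipeline reports them as
  undefined/insignificant rather than guessing.
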