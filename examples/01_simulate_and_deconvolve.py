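"""Simulate a bulk cohort with known cell-type profiles and deconvolve it.

Builds a 30-sample, 6-cell-type synthetic cohort with negative-binomial
count noise, fits per-transcript NNLS coefficients against the true
proportions, and reports how well the known profiles are recovered.
"""

from circdeconv import (
    SimulationConfig,
    coefficient_recovery_correlations,
    fit_cell_type_expression,
    simulate,
)

truth = simulate(SimulationConfig(n_linear=200, n_circ=200, seed=42))
print(f"cohort: {truth.bulk_observed.n_transcripts} transcripts × "
      f"{truth.bulk_observed.n_samples} samples, "
      f"cell types: {', '.join(truth.true_proportions.cell_types)}")

fitted = fit_cell_type_expression(truth.bulk_observed, truth.true_proportions)
recovery = coefficient_recovery_correlations(fitted, truth.true_coefficients)

linear = recovery.loc[truth.linear_ids()]
circ = recovery.loc[truth.circ_ids()]
print(f"median recovery correlation, linear genes: {linear.median():.3f}")
print(f"median recovery correlation, circRNAs:     {circ.median():.3f}")
print("-> each value is the Pearson correlation between a transcript's")
print("   estimated and true cell-type expression profile; the circRNA block")
print("   sits ~400x lower in abundance, so its profiles are recovered far")
print("   less faithfully from the same sequencing depth.")
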