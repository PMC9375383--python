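"""Low-expression filtering, TMM factors and the arcsinh transform.

The filter keeps genes with >= 2 cpm (or >= 1 TPM) in at least 9 of the
19 samples; TMM factors put samples on a common scale; the arcsinh
ln(x + sqrt(x^2 + 1)) of normalized cpm stabilizes the variance before
any correlation is computed.
"""

import cocnet as cn

config = cn.SimConfig(n_genes_oocyte=400, n_genes_cumulus=400, seed=7)
experiment, _ = cn.simulate_paired_experiment(config)

kept = cn.filter_low_expression(experiment.oocyte, cpm_min=2, tpm_min=1,
                                min_samples=9)
print(f"filter: {experiment.oocyte.n_genes} genes in, {kept.n_genes} kept")

factors = cn.tmm_factors(kept)
print(f"TMM reference sample: {factors.reference_sample}")
print(f"factor range: {factors.factors.min():.3f} .. {factors.factors.max():.3f} "
      f"(product {factors.factors.prod():.6f})")

transformed = cn.asinh_transform(kept, factors)
print(f"transformed value range: {transformed.values.min().min():.3f} .. "
      f"{transformed.values.max().max():.3f}")
# Factors hover near 1 because the simulated depth spread is moderate;
# their product is exactly 1 by construction.  Transformed values are
# ~ln(2*cpm) for large cpm and exactly 0 for zero counts.
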