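"""Generate a synthetic paired COC experiment and inspect its structure.

Draws 9 BCB-positive and 10 BCB-negative cumulus-oocyte pairs with three
planted cross-compartment edges and one 4-fold cumulus DE gene, then
writes the fixture as plain TSV files.
"""

import numpy as np

import cocnet as cn

config = cn.SimConfig(
    n_genes_oocyte=300,
    n_genes_cumulus=300,
    baseline_log_mean_range=(np.log(50), np.log(500)),
    dispersion_range=(0.05, 0.2),
    planted_edges=[(0, 0, 0.97, "all"), (1, 1, 0.99, "pos_only"), (2, 2, 0.95, "all")],
    de_genes=[(10, 2.0)],
    seed=42,
)
experiment, truth = cn.simulate_paired_experiment(config)
paths = cn.write_fixture(experiment, truth, "coc_fixture")

print(f"pairs: {experiment.n_pairs}  groups: {experiment.group_sizes()}")
print(f"oocyte matrix: {experiment.oocyte.counts.shape}, "
      f"cumulus matrix: {experiment.cumulus.counts.shape}")
print(f"planted edges: {[(e.oocyte, e.cumulus, e.rho, e.scope) for e in truth.all_edges]}")
print(f"library sizes (oocyte): "
      f"{experiment.oocyte.library_sizes().describe()[['min', 'max']].to_dict()}")
print(f"fixture files: {sorted(p.name for p in paths.values())}")
# The two compartments are linked only through the planted edges; the
# library-size spread is what TMM normalization will remove downstream.
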