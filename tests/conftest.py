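import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cocnet as cn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def small_counts() -> cn.CountMatrix:
    """4 genes x 3 samples with known totals (100, 200, 400)."""
    counts = pd.DataFrame(
        [[10, 20, 40], [20, 40, 80], [30, 60, 120], [40, 80, 160]],
        index=["g1", "g2", "g3", "g4"],
        columns=["s1", "s2", "s3"],
    )
    lengths = pd.Series([1000, 1000, 2000, 500], index=counts.index)
    return cn.CountMatrix(counts=counts, compartment="oocyte", gene_lengths=lengths)


def expressed_sim_config(**overrides) -> cn.SimConfig:
    """A simulation preset emulating post-filter data: moderate-to-high
    expression so zero counts (and their correlation leverage) are rare."""
    params = dict(
        baseline_log_mean_range=(np.log(50.0), np.log(500.0)),
        dispersion_range=(0.05, 0.2),
    )
    params.update(overrides)
    return cn.SimConfig(**params)


@pytest.fixture
def small_experiment():
    """19-pair experiment, 60+60 well-expressed genes, 2 strong planted
    edges (one 'all', one 'pos_only') and one 4-fold cumulus DE gene."""
    cfg = expressed_sim_config(
        n_genes_oocyte=60,
        n_genes_cumulus=60,
        planted_edges=[(0, 0, 0.97, "all"), (1, 1, 0.99, "pos_only")],
        de_genes=[(5, 2.0)],
        seed=11,
    )
    exp, truth = cn.simulate_paired_experiment(cfg)
    return exp, truth


@pytest.fixture
def small_transformed(small_experiment):
    exp, truth = small_experiment
    f_o = cn.tmm_factors(exp.oocyte)
    f_c = cn.tmm_factors(exp.cumulus)
    return (
        cn.asinh_transform(exp.oocyte, f_o),
        cn.asinh_transform(exp.cumulus, f_c),
        exp,
        truth,
    )
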