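"""Paired Pearson matrices, the permutation null, eFDR curves and
threshold selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cocnet as cn
from cocnet.coexpression import CrossCorrelationMatrix, NullSummary

from conftest import expressed_sim_config


def toy_transformed(values, compartment, prefix):
    values = np.asarray(values, dtype=float)
    return cn.TransformedMatrix(
        values=pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(values.shape[0])],
            columns=[f"P{j+1:02d}_{compartment}" for j in range(values.shape[1])],
        ),
        compartment=compartment,
    )


def toy_pairing(n, n_pos=None):
    groups = ["BCB_pos"] * (n_pos if n_pos is not None else n)
    groups += ["BCB_neg"] * (n - len(groups))
    return pd.DataFrame(
        {
            "oocyte_sample": [f"P{j+1:02d}_oocyte" for j in range(n)],
            "cumulus_sample": [f"P{j+1:02d}_cumulus" for j in range(n)],
            "group": groups,
        },
        index=pd.Index([f"P{j+1:02d}" for j in range(n)], name="pair_id"),
    )


class TestPairedPearson:
    def test_affine_copy_gives_r_one(self):
        base = np.array([[1.0, 2.0, 5.0, 3.0, 8.0]])
        o = toy_transformed(base, "oocyte", "OG")
        c = toy_transformed(3.0 * base + 2.0, "cumulus", "CG")
        ccm = cn.paired_pearson(o, c, toy_pairing(5))
        assert ccm.r[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_row_is_flagged_undefined(self):
        o = toy_transformed([[2.0, 2.0, 2.0, 2.0]], "oocyte", "OG")
        c = toy_transformed([[1.0, 2.0, 3.0, 4.0]], "cumulus", "CG")
        ccm = cn.paired_pearson(o, c, toy_pairing(4))
        assert np.isnan(ccm.r[0, 0])
        assert ccm.n_finite == 0

    def test_matches_two_vector_oracle_and_block_invariance(self):
        rng = np.random.default_rng(5)
        o = toy_transformed(rng.normal(size=(40, 19)), "oocyte", "OG")
        c = toy_transformed(rng.normal(size=(30, 19)), "cumulus", "CG")
        pairing = toy_pairing(19)
        ccm = cn.paired_pearson(o, c, pairing, block_size=7)
        ccm_big = cn.paired_pearson(o, c, pairing, block_size=10_000)
        np.testing.assert_array_equal(ccm.r, ccm_big.r)
        for i, j in rng.integers(0, 30, size=(50, 2)):
            expected = np.corrcoef(
                o.values.to_numpy()[i], c.values.to_numpy()[j])[0, 1]
            assert ccm.r[i, j] == pytest.approx(expected, abs=1e-12)

    def test_swapping_compartments_transposes(self):
        rng = np.random.default_rng(6)
        o = toy_transformed(rng.normal(size=(10, 8)), "oocyte", "OG")
        c = toy_transformed(rng.normal(size=(12, 8)), "cumulus", "CG")
        pairing = toy_pairing(8)
        swapped = pairing.rename(columns={
            "oocyte_sample": "cumulus_sample", "cumulus_sample": "oocyte_sample"})
        forward = cn.paired_pearson(o, c, pairing)
        backward = cn.paired_pearson(c, o, swapped)
        np.testing.assert_allclose(forward.r, backward.r.T, atol=1e-15)

    def test_group_scope_restricts_pairs(self):
        rng = np.random.default_rng(7)
        o = toy_transformed(rng.normal(size=(5, 19)), "oocyte", "OG")
        c = toy_transformed(rng.normal(size=(5, 19)), "cumulus", "CG")
        ccm = cn.paired_pearson(o, c, toy_pairing(19, n_pos=9), scope="BCB_pos")
        assert ccm.n_pairs == 9

    def test_fewer_than_three_pairs_is_an_error(self):
        o = toy_transformed([[1.0, 2.0]], "oocyte", "OG")
        c = toy_transformed([[1.0, 2.0]], "cumulus", "CG")
        with pytest.raises(ValueError, match=">= 3"):
            cn.paired_pearson(o, c, toy_pairing(2))

    def test_mismatched_pairing_is_an_error(self):
        o = toy_transformed(np.zeros((2, 4)), "oocyte", "OG")
        c = toy_transformed(np.zeros((2, 4)), "cumulus", "CG")
        pairing = toy_pairing(4)
        pairing.loc["P01", "oocyte_sample"] = "missing_sample"
        with pytest.raises(ValueError, match="absent"):
            cn.paired_pearson(o, c, pairing)

    def test_planted_edges_separate_from_null_background(self):
        """Planted copula edges at rho=0.9 exceed the 99.9th percentile of
        the unplanted entries in nearly every seed, and entries match the
        naive oracle."""
        wins, n_seeds = 0, 20
        for seed in range(n_seeds):
            cfg = expressed_sim_config(
                n_genes_oocyte=200, n_genes_cumulus=200,
                planted_edges=[(i, i, 0.9, "all") for i in range(5)], seed=seed)
            exp, _ = cn.simulate_paired_experiment(cfg)
            o = cn.asinh_transform(exp.oocyte, cn.tmm_factors(exp.oocyte))
            c = cn.asinh_transform(exp.cumulus, cn.tmm_factors(exp.cumulus))
            ccm = cn.paired_pearson(o, c, exp.pairing)
            planted = np.diag(ccm.r[:5, :5])
            mask = np.ones_like(ccm.r, dtype=bool)
            mask[range(5), range(5)] = False
            background = ccm.r[mask]
            wins += (planted > np.quantile(background, 0.999)).all()
        assert wins >= n_seeds - 1


class TestPermutationNull:
    @pytest.fixture()
    def small_null_inputs(self):
        rng = np.random.default_rng(8)
        o = toy_transformed(rng.normal(size=(20, 10)), "oocyte", "OG")
        c = toy_transformed(rng.normal(size=(20, 10)), "cumulus", "CG")
        return o, c, toy_pairing(10)

    def test_identity_permutation_reproduces_observed(self, small_null_inputs):
        o, c, pairing = small_null_inputs
        grid = cn.default_threshold_grid()
        null = cn.permutation_null(o, c, pairing, B=10, seed=1,
                                   thresholds=grid, identity_first=True)
        observed = cn.paired_pearson(o, c, pairing)
        curve = cn.efdr_curve(observed, null)
        np.testing.assert_array_equal(null.counts[0], curve.observed_counts)

    def test_stream_stability_when_B_grows(self, small_null_inputs):
        o, c, pairing = small_null_inputs
        a = cn.permutation_null(o, c, pairing, B=15, seed=9)
        b = cn.permutation_null(o, c, pairing, B=30, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts[:15])

    def test_exhaustive_mode_enumerates_all_pairings(self):
        rng = np.random.default_rng(10)
        o = toy_transformed(rng.normal(size=(4, 4)), "oocyte", "OG")
        c = toy_transformed(rng.normal(size=(4, 4)), "cumulus", "CG")
        null = cn.permutation_null(o, c, toy_pairing(4), exhaustive=True)
        assert null.n_permutations == 24

    def test_null_distribution_matches_observed_under_the_null(self):
        """With no planted coupling, the pooled permutation-null r and the
        observed r are draws from the same distribution (two-sample KS)."""
        cfg = expressed_sim_config(n_genes_oocyte=100, n_genes_cumulus=100, seed=12)
        exp, _ = cn.simulate_paired_experiment(cfg)
        o = cn.asinh_transform(exp.oocyte, cn.tmm_factors(exp.oocyte))
        c = cn.asinh_transform(exp.cumulus, cn.tmm_factors(exp.cumulus))
        observed = cn.paired_pearson(o, c, exp.pairing)
        null = cn.permutation_null(o, c, exp.pairing, B=20, seed=13)
        ks = stats.ks_2samp(
            observed.r[observed.finite_mask].ravel(), null.pooled_r)
        assert ks.pvalue > 0.01

    def test_group_scope_shuffles_within_group(self, small_null_inputs):
        o, c, _ = small_null_inputs
        pairing = toy_pairing(10, n_pos=5)
        null = cn.permutation_null(o, c, pairing, scope="BCB_pos", B=10, seed=2)
        # 5 in-scope pairs -> 20*20 comparisons per permutation
        assert (null.n_comparisons == 400).all()


class TestEfdrCurveAndThreshold:
    def make_curve(self, observed_r, null_counts, thresholds):
        """Assemble an EFDRCurve from hand-built pieces."""
        g = len(observed_r)
        ccm = CrossCorrelationMatrix(
            r=np.asarray(observed_r, dtype=float).reshape(1, -1),
            oocyte_gene_ids=pd.Index(["o0"]),
            cumulus_gene_ids=pd.Index([f"c{i}" for i in range(g)]),
            n_pairs=10, scope="all")
        null = NullSummary(
            thresholds=np.asarray(thresholds, dtype=float),
            counts=np.asarray(null_counts, dtype=np.int64),
            n_comparisons=np.full(len(null_counts), g),
            pooled_r=np.zeros(1), n_permutations=len(null_counts),
            seed=0, signed=True, scope="all")
        return cn.efdr_curve(ccm, null), ccm

    def test_efdr_arithmetic(self):
        # 100 observed entries >= 0.5; null mean exactly 1
        observed = np.linspace(0.5, 0.99, 100)
        null_counts = [[1]] * 10
        curve, _ = self.make_curve(observed, null_counts, [0.5])
        assert curve.efdr[0] == pytest.approx(0.01)

    def test_no_observed_entries_means_undefined(self):
        curve, _ = self.make_curve([0.3, 0.4], [[0], [0]], [0.9])
        assert np.isnan(curve.efdr[0])
        assert curve.observed_counts[0] == 0

    def test_zero_null_count_reports_upper_bound(self):
        curve, _ = self.make_curve([0.95, 0.2], [[0], [0]], [0.9])
        assert curve.is_upper_bound[0]
        assert curve.efdr[0] == pytest.approx(1.0 / 4.0)  # 2 perms x 2 entries

    def test_counts_non_increasing_in_threshold(self, small_experiment):
        exp, _ = small_experiment
        o = cn.asinh_transform(exp.oocyte, cn.tmm_factors(exp.oocyte))
        c = cn.asinh_transform(exp.cumulus, cn.tmm_factors(exp.cumulus))
        observed = cn.paired_pearson(o, c, exp.pairing)
        null = cn.permutation_null(o, c, exp.pairing, B=10, seed=3)
        curve = cn.efdr_curve(observed, null)
        assert (np.diff(curve.observed_counts) <= 0).all()
        assert (np.diff(curve.null_mean_counts) <= 0).all()

    def test_choose_threshold_lookup(self):
        # efdr ladder (0.1, 1e-3, <1e-7) at thresholds (0.5, 0.8, 0.99)
        observed = [0.55] * 1000 + [0.85] * 1000 + [0.995] * 1000
        null_counts = [[300, 2, 0]] * 40_000  # B large: zero-null bound < 1e-7
        curve, _ = self.make_curve(observed, null_counts, [0.5, 0.8, 0.99])
        np.testing.assert_allclose(curve.efdr, [0.1, 1e-3, 1 / 120e6])
        assert cn.choose_threshold(curve, 1e-7) == pytest.approx(0.99)
        assert cn.choose_threshold(curve, 1e-2) == pytest.approx(0.8)
        assert cn.choose_threshold(curve, 1.0) == pytest.approx(0.5)

    def test_choose_threshold_unattainable_sentinel(self):
        curve, _ = self.make_curve([0.55], [[1]] * 10, [0.5])
        assert cn.choose_threshold(curve, 1e-7) is None

    def test_choose_threshold_rejects_bad_alpha(self):
        curve, _ = self.make_curve([0.55], [[1]] * 10, [0.5])
        with pytest.raises(ValueError):
            cn.choose_threshold(curve, 0.0)

    def test_threshold_monotone_in_alpha_on_null_data(self):
        cfg = expressed_sim_config(
            n_pairs_pos=9, n_pairs_neg=0, n_genes_oocyte=60,
            n_genes_cumulus=60, seed=14)
        exp, _ = cn.simulate_paired_experiment(cfg)
        o = cn.asinh_transform(exp.oocyte, cn.tmm_factors(exp.oocyte))
        c = cn.asinh_transform(exp.cumulus, cn.tmm_factors(exp.cumulus))
        observed = cn.paired_pearson(o, c, exp.pairing)
        null = cn.permutation_null(o, c, exp.pairing, B=50, seed=15)
        curve = cn.efdr_curve(observed, null)
        chosen = [cn.choose_threshold(curve, a) for a in (1e-1, 1e-3, 1e-5)]
        numeric = [t if t is not None else np.inf for t in chosen]
        assert numeric == sorted(numeric)

    def test_regularized_curve_is_monotone(self, small_experiment):
        exp, _ = small_experiment
        o = cn.asinh_transform(exp.oocyte, cn.tmm_factors(exp.oocyte))
        c = cn.asinh_transform(exp.cumulus, cn.tmm_factors(exp.cumulus))
        observed = cn.paired_pearson(o, c, exp.pairing)
        null = cn.permutation_null(o, c, exp.pairing, B=10, seed=4)
        curve = cn.efdr_curve(observed, null, regularize=True)
        vals = curve.efdr[np.isfinite(curve.efdr)]
        assert (np.diff(vals) <= 1e-12).all()


class TestEdgesAtThreshold:
    @pytest.fixture()
    def ccm(self):
        rng = np.random.default_rng(16)
        o = toy_transformed(np.abs(rng.normal(size=(6, 8))), "oocyte", "OG")
        values = o.values.to_numpy() + 0.05 * rng.normal(size=(6, 8))
        c = toy_transformed(values, "cumulus", "CG")
        return cn.paired_pearson(o, c, toy_pairing(8))

    def test_zero_threshold_returns_every_nonnegative_pair(self, ccm):
        edges = cn.edges_at_threshold(ccm, 0.0)
        assert len(edges) == int((ccm.r[ccm.finite_mask] >= 0).sum())

    def test_nesting_over_grid(self, ccm):
        previous = None
        for t in (0.0, 0.3, 0.6, 0.9):
            edges = set(map(tuple, cn.edges_at_threshold(
                ccm, t)[["oocyte_gene", "cumulus_gene"]].to_numpy()))
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_sorted_descending_with_lexicographic_ties(self, ccm):
        edges = cn.edges_at_threshold(ccm, 0.0)
        r = edges["r"].to_numpy()
        assert (np.diff(r) <= 1e-15).all()

    def test_absolute_mode_includes_negative_edges(self):
        base = np.array([[1.0, 2.0, 5.0, 3.0, 8.0]])
        o = toy_transformed(base, "oocyte", "OG")
        c = toy_transformed(-base, "cumulus", "CG")
        ccm = cn.paired_pearson(o, c, toy_pairing(5))
        assert len(cn.edges_at_threshold(ccm, 0.9, signed=True)) == 0
        assert len(cn.edges_at_threshold(ccm, 0.9, signed=False)) == 1
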