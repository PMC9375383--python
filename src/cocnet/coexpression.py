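"""Cross-compartment co-expression: paired Pearson correlation matrices,
a permutation null obtained by breaking the oocyte-cumulus pairing, and
empirical-FDR calibration of edge thresholds.

The empirical FDR at a correlation threshold t is

    eFDR(t) = E_perm[# null pairs with r >= t] / (# observed pairs with r >= t),

where the null re-pairs cumulus samples with oocyte samples by shuffling
pair labels (within the group when a group scope is analysed), preserving
each compartment's own gene-gene covariance while destroying any
cross-compartment coupling.  When no permuted value reaches t the eFDR is
known only to be below 1/(number of null comparisons); that upper bound is
reported and used conservatively when choosing thresholds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ALL, PairedExperiment, TransformedMatrix

__all__ = [
    "CrossCorrelationMatrix",
    "NullSummary",
    "EFDRCurve",
    "default_threshold_grid",
    "paired_pearson",
    "permutation_null",
    "efdr_curve",
    "choose_threshold",
    "edges_at_threshold",
]


def default_threshold_grid(step: float = 0.002) -> np.ndarray:
    """Ascending grid 0, step, ..., <1 (default 0 .. 0.998 by 0.002)."""
    n = math.ceil(1.0 / step)
    return np.round(np.arange(n) * step, 10)


@dataclass
class CrossCorrelationMatrix:
    """Oocyte-gene x cumulus-gene Pearson coefficients across COC pairs.

    Entries for genes with zero variance across the used pairs are NaN
    (flagged undefined), never silent zeros.
    """

    r: np.ndarray
    oocyte_gene_ids: pd.Index
    cumulus_gene_ids: pd.Index
    n_pairs: int
    scope: str

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.r)

    @property
    def n_finite(self) -> int:
        return int(self.finite_mask.sum())


@dataclass
class NullSummary:
    """Per-permutation exceedance counts over a threshold grid.

    ``counts[b, k]`` is the number of finite null correlations >= the k-th
    grid threshold in permutation b; ``n_comparisons[b]`` the number of
    finite null entries of that permutation.  ``pooled_r`` is a seeded
    subsample of null coefficients for distributional diagnostics.
    """

    thresholds: np.ndarray
    counts: np.ndarray
    n_comparisons: np.ndarray
    pooled_r: np.ndarray
    n_permutations: int
    seed: int
    signed: bool
    scope: str

    @property
    def mean_counts(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def total_comparisons(self) -> int:
        return int(self.n_comparisons.sum())


@dataclass
class EFDRCurve:
    """Observed and expected-null edge counts on a threshold grid.

    ``efdr`` holds E[null count]/observed count; where the null count is
    zero the entry is the upper bound 1/(total null comparisons) and the
    matching ``is_upper_bound`` flag is set.  Thresholds with zero observed
    count have NaN eFDR (undefined, no division).
    """

    thresholds: np.ndarray
    observed_counts: np.ndarray
    null_mean_counts: np.ndarray
    efdr: np.ndarray
    is_upper_bound: np.ndarray
    n_permutations: int
    seed: int
    regularized: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "observed_count": self.observed_counts,
            "null_mean_count": self.null_mean_counts,
            "efdr": self.efdr,
            "efdr_is_upper_bound": self.is_upper_bound,
        })


def _standardized_rows(values: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm; zero-variance rows become NaN."""
    x = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(norms > 0, x / norms, np.nan)
    return x


def _scope_columns(
    o: TransformedMatrix,
    c: TransformedMatrix,
    pairing: pd.DataFrame | PairedExperiment,
    scope: str,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairing, PairedExperiment):
        pairing = pairing.pairing
    if scope != ALL:
        pairing = pairing[pairing["group"] == scope]
    if len(pairing) < 3:
        raise ValueError(
            f"scope {scope!r} has {len(pairing)} pairs; Pearson needs >= 3")
    missing_o = set(pairing["oocyte_sample"]) - set(o.sample_ids)
    missing_c = set(pairing["cumulus_sample"]) - set(c.sample_ids)
    if missing_o or missing_c:
        raise ValueError(
            f"pairing references samples absent from the matrices: "
            f"{sorted(missing_o | missing_c)}")
    o_vals = o.values[list(pairing["oocyte_sample"])].to_numpy(dtype=float)
    c_vals = c.values[list(pairing["cumulus_sample"])].to_numpy(dtype=float)
    return o_vals, c_vals


def paired_pearson(
    o: TransformedMatrix,
    c: TransformedMatrix,
    pairing: pd.DataFrame | PairedExperiment,
    scope: str = ALL,
    block_size: int = 2048,
) -> CrossCorrelationMatrix:
    """Pearson coefficient of every (oocyte gene, cumulus gene) pair
    across the COC pairs in *scope*.

    Computed in blocks of ``block_size`` oocyte genes so the working set
    stays bounded on full-size matrices; the result is independent of the
    block size.
    """
    o_vals, c_vals = _scope_columns(o, c, pairing, scope)
    zo = _standardized_rows(o_vals)
    zc = _standardized_rows(c_vals)
    r = np.empty((zo.shape[0], zc.shape[0]))
    for start in range(0, zo.shape[0], block_size):
        stop = min(start + block_size, zo.shape[0])
        r[start:stop] = np.clip(zo[start:stop] @ zc.T, -1.0, 1.0)
    return CrossCorrelationMatrix(
        r=r,
        oocyte_gene_ids=o.gene_ids,
        cumulus_gene_ids=c.gene_ids,
        n_pairs=o_vals.shape[1],
        scope=scope,
    )


def _exceedance_counts(
    r_finite: np.ndarray, thresholds: np.ndarray, signed: bool
) -> np.ndarray:
    vals = r_finite if signed else np.abs(r_finite)
    vals = np.sort(vals)
    return vals.size - np.searchsorted(vals, thresholds, side="left")


def permutation_null(
    o: TransformedMatrix,
    c: TransformedMatrix,
    pairing: pd.DataFrame | PairedExperiment,
    scope: str = ALL,
    B: int = 100,
    seed: int = 0,
    thresholds: np.ndarray | None = None,
    signed: bool = True,
    identity_first: bool = False,
    exhaustive: bool = False,
    pooled_cap: int = 100_000,
) -> NullSummary:
    """Null exceedance counts from random re-pairings of the compartments.

    Each permutation shuffles which cumulus sample is paired with which
    oocyte sample (within *scope*), recomputes the full cross-correlation
    matrix, and records counts above each grid threshold.  Permutation b is
    drawn from its own seeded substream, so enlarging B leaves earlier
    permutations unchanged.  ``identity_first`` injects the identity
    re-pairing as permutation 0 (diagnostic: it reproduces the observed
    counts).  ``exhaustive`` enumerates all n! re-pairings instead (meant
    for n <= 8; B is ignored).
    """
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=float)
    o_vals, c_vals = _scope_columns(o, c, pairing, scope)
    n = o_vals.shape[1]

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to n <= 8 pairs")
        perms = [np.array(p) for p in itertools.permutations(range(n))]
    else:
        if B < 10:
            raise ValueError("need at least 10 permutations")
        perms = None

    zo = _standardized_rows(o_vals)
    zc = _standardized_rows(c_vals)
    n_perms = len(perms) if exhaustive else B
    counts = np.empty((n_perms, thresholds.size), dtype=np.int64)
    n_comparisons = np.empty(n_perms, dtype=np.int64)
    per_perm_cap = max(1, pooled_cap // n_perms)
    pooled = []
    for b in range(n_perms):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(b,)))
        if exhaustive:
            perm = perms[b]
        elif identity_first and b == 0:
            perm = np.arange(n)
        else:
            perm = rng.permutation(n)
        # permuting the sample axis permutes coordinates of each already
        # standardized cumulus row, so the shuffle acts on zc columns
        r = np.clip(zo @ zc[:, perm].T, -1.0, 1.0)
        finite = r[np.isfinite(r)]
        counts[b] = _exceedance_counts(finite, thresholds, signed)
        n_comparisons[b] = finite.size
        if finite.size:
            take = min(per_perm_cap, finite.size)
            pooled.append(rng.choice(finite, size=take, replace=False))
    pooled_r = np.concatenate(pooled) if pooled else np.empty(0)
    return NullSummary(
        thresholds=thresholds,
        counts=counts,
        n_comparisons=n_comparisons,
        pooled_r=pooled_r,
        n_permutations=n_perms,
        seed=seed,
        signed=signed,
        scope=scope,
    )


def efdr_curve(
    observed: CrossCorrelationMatrix,
    null: NullSummary,
    thresholds: np.ndarray | None = None,
    regularize: bool = False,
) -> EFDRCurve:
    """Empirical FDR across a threshold grid.

    ``regularize`` applies the running minimum from high thresholds
    downward, enforcing monotone eFDR (off by default: combined with the
    zero-null upper-bound convention a running minimum would propagate the
    smallest bound to every lower threshold).
    """
    if observed.r.size == 0:
        raise ValueError("empty observed correlation matrix")
    if thresholds is None:
        thresholds = null.thresholds
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0 or thresholds.min() < 0 or thresholds.max() >= 1:
        raise ValueError("thresholds must lie in [0, 1)")
    if not np.array_equal(thresholds, null.thresholds):
        raise ValueError("threshold grid differs from the null summary grid")

    finite = observed.r[observed.finite_mask]
    observed_counts = _exceedance_counts(finite, thresholds, null.signed)
    null_mean = null.mean_counts.astype(float)
    total_null = null.total_comparisons

    efdr = np.full(thresholds.size, np.nan)
    upper = np.zeros(thresholds.size, dtype=bool)
    has_obs = observed_counts > 0
    zero_null = null_mean == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        efdr[has_obs] = null_mean[has_obs] / observed_counts[has_obs]
    bound = 1.0 / total_null if total_null else np.nan
    efdr[has_obs & zero_null] = bound
    upper[has_obs & zero_null] = True

    if regularize:
        # running minimum from the highest threshold downward
        rev = efdr[::-1].copy()
        rev_filled = np.where(np.isnan(rev), np.inf, rev)
        rev_min = np.minimum.accumulate(rev_filled)
        efdr = np.where(np.isnan(efdr), np.nan, rev_min[::-1])

    return EFDRCurve(
        thresholds=thresholds,
        observed_counts=observed_counts,
        null_mean_counts=null_mean,
        efdr=efdr,
        is_upper_bound=upper,
        n_permutations=null.n_permutations,
        seed=null.seed,
        regularized=regularize,
    )


def choose_threshold(curve: EFDRCurve, alpha: float) -> float | None:
    """Smallest grid threshold whose eFDR is below ``alpha``.

    Returns ``None`` when no threshold qualifies (unattainable — e.g.
    alpha below 1/(number of null comparisons), which no permutation
    experiment of that size can certify).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    ok = np.isfinite(curve.efdr) & (curve.efdr < alpha) & (curve.observed_counts > 0)
    if not ok.any():
        return None
    return float(curve.thresholds[np.argmax(ok)])


def edges_at_threshold(
    observed: CrossCorrelationMatrix,
    t: float,
    signed: bool = True,
) -> pd.DataFrame:
    """All gene pairs with finite r >= t (|r| >= t in absolute mode).

    Sorted by descending r with a deterministic lexicographic tie-break on
    (oocyte id, cumulus id).  Columns: ``oocyte_gene``, ``cumulus_gene``,
    ``r``, ``threshold``, ``scope``.
    """
    if not 0 <= t < 1:
        raise ValueError("threshold must lie in [0, 1)")
    vals = observed.r if signed else np.abs(observed.r)
    with np.errstate(invalid="ignore"):
        oi, ci = np.nonzero(np.isfinite(observed.r) & (vals >= t))
    frame = pd.DataFrame({
        "oocyte_gene": observed.oocyte_gene_ids[oi],
        "cumulus_gene": observed.cumulus_gene_ids[ci],
        "r": observed.r[oi, ci],
        "threshold": t,
        "scope": observed.scope,
    })
    frame = frame.sort_values(
        ["r", "oocyte_gene", "cumulus_gene"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return frame
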