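"""Count-level preprocessing: cpm/TPM, low-expression filtering, TMM
normalization and the arcsinh transform feeding co-expression.

The normalization convention used throughout the package: the TMM factor
``f_j`` multiplies raw counts onto a common abundance scale (it absorbs both
sequencing depth and composition bias), factors are rescaled to product 1,
and the effective library size is ``geomean(totals) / f_j``.  cpm computed
on effective library sizes therefore equalises a pure depth difference
exactly (two samples where one is an entrywise doubling of the other get
factors sqrt(2) and 1/sqrt(2) and identical normalized abundances).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .types import CountMatrix, NormalizationFactors, TransformedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "cpm",
    "tpm",
    "filter_low_expression",
    "tmm_factors",
    "asinh_transform",
]


def cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million: count / library size x 1e6, per sample."""
    totals = matrix.library_sizes()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return matrix.counts / totals * 1e6


def tpm(matrix: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalized rate / rate total x 1e6."""
    if matrix.gene_lengths is None:
        raise ValueError("tpm requires gene_lengths")
    rates = matrix.counts.div(matrix.gene_lengths, axis=0)
    rate_totals = rates.sum(axis=0)
    zero = rate_totals[rate_totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return rates / rate_totals * 1e6


def filter_low_expression(
    matrix: CountMatrix,
    cpm_min: float = 2.0,
    tpm_min: float = 1.0,
    min_samples: int = 9,
    combine: str = "or",
) -> CountMatrix:
    """Remove lowly expressed genes.

    A gene is retained when it reaches ``cpm_min`` cpm in at least
    ``min_samples`` samples, or (when gene lengths are available) reaches
    ``tpm_min`` TPM in at least ``min_samples`` samples.  With the default
    ``min_samples=9`` on 19 samples this removes genes expressed in eight
    or fewer samples.  ``combine`` selects whether the cpm and TPM criteria
    are alternatives (``"or"``, default) or must both hold (``"and"``).
    """
    if min_samples > matrix.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {matrix.n_samples} samples"
        )
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")

    keep_cpm = (cpm(matrix) >= cpm_min).sum(axis=1) >= min_samples
    if matrix.gene_lengths is not None:
        keep_tpm = (tpm(matrix) >= tpm_min).sum(axis=1) >= min_samples
        keep = (keep_cpm | keep_tpm) if combine == "or" else (keep_cpm & keep_tpm)
    else:
        keep = keep_cpm

    kept = matrix.subset_genes(matrix.gene_ids[keep])
    logger.info(
        "%s filter: %d genes in, %d retained, %d removed",
        matrix.compartment, matrix.n_genes, kept.n_genes, matrix.n_genes - kept.n_genes,
    )
    return kept


def _choose_reference(cpm_values: pd.DataFrame) -> str:
    """Sample whose 75th-percentile cpm is closest to the mean of those
    percentiles (first sample on ties)."""
    q75 = cpm_values.quantile(0.75, axis=0)
    return (q75 - q75.mean()).abs().idxmin()


def tmm_factors(
    matrix: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed mean of M-values scaling factors.

    For each sample against the reference, using genes with nonzero counts
    in both, ``M_g = log2(y_ref / y_g)`` and ``A_g`` is the mean log2 count;
    genes inside the central ``1 - 2*trim`` quantile range of both M and A
    contribute a precision-weighted mean of M, and the factor is ``2`` to
    that mean.  Factors are rescaled so their product is 1.  Computing M on
    the raw-count scale makes the factor absorb sequencing depth: the
    effective library size is ``geomean(totals) / f_j``.
    """
    if matrix.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    totals = matrix.library_sizes().astype(float)
    if (totals == 0).any():
        raise ValueError("zero-total sample")

    ref = _choose_reference(cpm(matrix))
    y = matrix.counts.to_numpy(dtype=float)
    sample_ids = list(matrix.sample_ids)
    y_ref = y[:, sample_ids.index(ref)]
    n_ref = totals[ref]

    log_factors = {}
    for j, sid in enumerate(sample_ids):
        if sid == ref:
            log_factors[sid] = 0.0
            continue
        y_j = y[:, j]
        both = (y_j > 0) & (y_ref > 0)
        if not both.any():
            raise ValueError(f"sample {sid!r} shares no expressed gene with reference {ref!r}")
        m = np.log2(y_ref[both] / y_j[both])
        a = 0.5 * (np.log2(y_ref[both]) + np.log2(y_j[both]))
        lo_m, hi_m = np.quantile(m, [trim_m, 1.0 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1.0 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() < 10:
            warnings.warn(
                f"fewer than 10 genes survive TMM trimming for sample {sid!r}; "
                "falling back to the untrimmed mean",
                RuntimeWarning,
            )
            keep = np.ones_like(keep)
        n_j = totals[sid]
        yk_j, yk_ref = y_j[both][keep], y_ref[both][keep]
        w = (n_j - yk_j) / (n_j * yk_j) + (n_ref - yk_ref) / (n_ref * yk_ref)
        mk = m[keep]
        if w.sum() <= 0:  # degenerate: identical saturated counts
            log_factors[sid] = float(mk.mean())
        else:
            log_factors[sid] = float(np.average(mk, weights=w))

    f = pd.Series({sid: 2.0 ** log_factors[sid] for sid in sample_ids})
    f = f / np.exp(np.log(f).mean())  # rescale: product of factors = 1
    return NormalizationFactors(
        factors=f, reference_sample=ref, trim_m=trim_m, trim_a=trim_a,
        library_sizes=matrix.library_sizes(),
    )


def asinh_transform(
    matrix: CountMatrix, factors: NormalizationFactors
) -> TransformedMatrix:
    """arcsinh transform ``ln(x + sqrt(x^2 + 1))`` of normalized cpm.

    ``x`` is cpm computed on the effective library size (geomean of totals
    divided by the TMM factor).  The transform is strictly increasing,
    maps 0 to exactly 0, and is variance-stabilizing for overdispersed
    counts, which keeps Pearson correlations across COC pairs from being
    dominated by a few high-abundance genes.
    """
    if set(factors.sample_ids) != set(matrix.sample_ids):
        raise ValueError("factors not aligned to samples")
    eff = factors.effective_library_sizes().reindex(matrix.sample_ids)
    x = matrix.counts / eff * 1e6
    return TransformedMatrix(
        values=pd.DataFrame(
            np.arcsinh(x.to_numpy()), index=matrix.gene_ids, columns=matrix.sample_ids
        ),
        compartment=matrix.compartment,
    )
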