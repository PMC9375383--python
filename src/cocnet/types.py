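"""Core data containers for the paired cumulus-oocyte complex analysis.

The sampling unit throughout is a COC *pair*: one oocyte and the pooled
cumulus cells that surrounded it, labelled by the BCB staining outcome of
the oocyte (``BCB_pos`` / ``BCB_neg``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OOCYTE = "oocyte"
CUMULUS = "cumulus"
COMPARTMENTS = (OOCYTE, CUMULUS)

BCB_POS = "BCB_pos"
BCB_NEG = "BCB_neg"
GROUPS = (BCB_POS, BCB_NEG)

#: scope value meaning "use every pair regardless of group"
ALL = "all"


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix for one compartment.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, genes as rows (index = gene ids),
        samples as columns.
    compartment
        Either ``"oocyte"`` or ``"cumulus"``.
    gene_lengths
        Optional per-gene lengths in bp (Series aligned to ``counts.index``),
        required only for the TPM route of the low-expression filter.
    """

    counts: pd.DataFrame
    compartment: str
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.counts.to_numpy()
        if values.size and values.min() < 0:
            raise ValueError("negative counts")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
            if self.gene_lengths.isna().any():
                raise ValueError("gene_lengths missing for some genes")
            if (self.gene_lengths <= 0).any():
                raise ValueError("gene_lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        lengths = None
        if self.gene_lengths is not None:
            lengths = self.gene_lengths.loc[gene_ids]
        return CountMatrix(self.counts.loc[gene_ids], self.compartment, lengths)


@dataclass
class PairedExperiment:
    """Oocyte and cumulus count matrices joined by a COC pairing.

    ``pairing`` is a DataFrame indexed by pair id with columns
    ``oocyte_sample``, ``cumulus_sample`` and ``group``.
    """

    oocyte: CountMatrix
    cumulus: CountMatrix
    pairing: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"oocyte_sample", "cumulus_sample", "group"}
        missing = required - set(self.pairing.columns)
        if missing:
            raise ValueError(f"pairing is missing columns {sorted(missing)}")
        if self.pairing.index.has_duplicates:
            raise ValueError("duplicate pair ids")
        for col, cm in (("oocyte_sample", self.oocyte), ("cumulus_sample", self.cumulus)):
            samples = self.pairing[col]
            if samples.duplicated().any():
                raise ValueError(f"a sample appears in more than one pair ({col})")
            unknown = set(samples) - set(cm.sample_ids)
            if unknown:
                raise ValueError(f"pairing references unknown {col} {sorted(unknown)}")
        bad = set(self.pairing["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")

    @property
    def pair_ids(self) -> pd.Index:
        return self.pairing.index

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    def pairs_in_scope(self, scope: str) -> pd.DataFrame:
        """Rows of ``pairing`` belonging to *scope* (a group label or ``"all"``)."""
        if scope == ALL:
            return self.pairing
        if scope not in GROUPS:
            raise ValueError(f"unknown scope {scope!r}")
        return self.pairing[self.pairing["group"] == scope]

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.pairing["group"] == g).sum()) for g in GROUPS}


@dataclass
class NormalizationFactors:
    """TMM scaling factors for one count matrix.

    ``factors`` multiply raw counts onto a common abundance scale; the
    corresponding effective library size is ``geomean(totals) / factor``,
    so a sample sequenced twice as deep gets twice the effective library.
    The factors are rescaled so that their product is exactly 1.
    """

    factors: pd.Series
    reference_sample: str
    trim_m: float
    trim_a: float
    library_sizes: pd.Series = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")

    @property
    def sample_ids(self) -> pd.Index:
        return self.factors.index

    def effective_library_sizes(self) -> pd.Series:
        """Per-sample effective library size: geomean(N) / f_j."""
        n = self.library_sizes.astype(float)
        geomean = float(np.exp(np.log(n).mean()))
        return geomean / self.factors


@dataclass
class TransformedMatrix:
    """arcsinh-transformed, TMM-normalized abundances for one compartment.

    Entries are ``ln(x + sqrt(x^2 + 1))`` of cpm computed on effective
    library sizes; zero abundance maps to exactly zero.  The ``transformed``
    flag guards against applying the transform twice.
    """

    values: pd.DataFrame
    compartment: str
    transformed: bool = True

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns
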