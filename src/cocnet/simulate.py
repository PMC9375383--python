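"""Synthetic paired oocyte/cumulus count generator.

Emulates the data structure of the COC study: 9 BCB-positive and 10
BCB-negative pairs by default, negative-binomial counts with log-normal
library-size heterogeneity, cross-compartment gene pairs coupled through a
Gaussian copula (so NB margins are preserved exactly), optionally only
within one BCB group, and cumulus-only differentially expressed genes.

Correlation is planted on the latent Gaussian scale; the realized Pearson
coefficient of the transformed counts is attenuated below the nominal rho,
so tests compare against brute-force realized values, never the nominal.

Randomness is organized as one counter-based substream per gene
(``SeedSequence(seed, spawn_key=(stream, gene))``), so enlarging a config
by appending genes never perturbs the counts of earlier genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .types import BCB_NEG, BCB_POS, CUMULUS, OOCYTE, CountMatrix, PairedExperiment

__all__ = [
    "PlantedEdge",
    "DEGene",
    "SimConfig",
    "SimTruth",
    "nb_copula_pair",
    "simulate_paired_experiment",
    "write_fixture",
]

SCOPES = ("all", "pos_only", "neg_only")

# substream roles
_LIBSIZE, _OOCYTE, _CUMULUS = 0, 1, 2


class PlantedEdge(NamedTuple):
    """A cross-compartment gene pair coupled at latent correlation ``rho``.

    ``scope`` restricts the coupling to one BCB group (``pos_only`` /
    ``neg_only``); outside the scope the two genes are independent.
    """

    oocyte: int
    cumulus: int
    rho: float
    scope: str = "all"


class DEGene(NamedTuple):
    """A cumulus gene whose mean is shifted by ``2**log2fc`` in the
    BCB-positive group."""

    cumulus: int
    log2fc: float


@dataclass
class SimConfig:
    """Generative settings for one synthetic paired experiment.

    Defaults mirror the study design: 9 + 10 COC pairs; per-gene expected
    counts log-uniform between ~5 and ~500; NB dispersion phi (variance =
    mu + phi mu^2) uniform on 0.05-0.3, a generic moderately overdispersed
    range; library-size factors log-normal with sigma 0.25.
    """

    n_pairs_pos: int = 9
    n_pairs_neg: int = 10
    n_genes_oocyte: int = 2000
    n_genes_cumulus: int = 2000
    baseline_log_mean_range: tuple[float, float] = (np.log(5.0), np.log(500.0))
    dispersion_range: tuple[float, float] = (0.05, 0.3)
    libsize_log_sd: float = 0.25
    planted_edges: Sequence[PlantedEdge] = field(default_factory=tuple)
    de_genes: Sequence[DEGene] = field(default_factory=tuple)
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_edges = tuple(PlantedEdge(*e) for e in self.planted_edges)
        self.de_genes = tuple(DEGene(*d) for d in self.de_genes)
        if self.n_pairs_pos + self.n_pairs_neg < 3:
            raise ValueError("need at least 3 pairs for a Pearson coefficient")
        if self.n_pairs_pos < 0 or self.n_pairs_neg < 0:
            raise ValueError("negative pair count")
        if self.libsize_log_sd < 0:
            raise ValueError("libsize_log_sd must be nonnegative")
        lo, hi = self.baseline_log_mean_range
        if not lo <= hi:
            raise ValueError("invalid baseline_log_mean_range")
        lo, hi = self.dispersion_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid dispersion_range")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid gene_length_range")
        seen_pairs: set[tuple[int, int]] = set()
        seen_cumulus: set[int] = set()
        for e in self.planted_edges:
            if not -1.0 < e.rho < 1.0:
                raise ValueError(f"edge rho {e.rho} outside (-1, 1)")
            if e.scope not in SCOPES:
                raise ValueError(f"unknown edge scope {e.scope!r}")
            if not (0 <= e.oocyte < self.n_genes_oocyte):
                raise ValueError(f"oocyte gene index {e.oocyte} out of range")
            if not (0 <= e.cumulus < self.n_genes_cumulus):
                raise ValueError(f"cumulus gene index {e.cumulus} out of range")
            if (e.oocyte, e.cumulus) in seen_pairs:
                raise ValueError(f"duplicate planted edge {(e.oocyte, e.cumulus)}")
            seen_pairs.add((e.oocyte, e.cumulus))
            if e.cumulus in seen_cumulus:
                raise ValueError(
                    f"cumulus gene {e.cumulus} appears in more than one edge; "
                    "one latent substream per gene admits a single coupling"
                )
            seen_cumulus.add(e.cumulus)
        for d in self.de_genes:
            if not (0 <= d.cumulus < self.n_genes_cumulus):
                raise ValueError(f"DE cumulus gene index {d.cumulus} out of range")

    @property
    def n_pairs(self) -> int:
        return self.n_pairs_pos + self.n_pairs_neg


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment, for downstream evaluation."""

    edges_all: tuple[PlantedEdge, ...]
    edges_pos_only: tuple[PlantedEdge, ...]
    edges_neg_only: tuple[PlantedEdge, ...]
    de_genes: tuple[DEGene, ...]
    realized_libsizes: pd.Series
    seed: int

    @property
    def all_edges(self) -> tuple[PlantedEdge, ...]:
        return self.edges_all + self.edges_pos_only + self.edges_neg_only

    def edge_gene_ids(self) -> list[tuple[str, str]]:
        return [(_gene_id(OOCYTE, e.oocyte), _gene_id(CUMULUS, e.cumulus))
                for e in self.all_edges]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _nb_ppf(u: np.ndarray, mu: np.ndarray, phi: float | np.ndarray) -> np.ndarray:
    """NB quantile function parameterized by mean and dispersion.

    phi = 0 degenerates to Poisson (variance = mean).
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("NB mean must be positive")
    if np.any(np.asarray(phi) < 0):
        raise ValueError("dispersion must be nonnegative")
    u = np.clip(u, 0.0, 1.0 - 1e-16)  # guard the ppf against u == 1.0
    if np.all(np.asarray(phi) < 1e-12):
        return stats.poisson.ppf(u, mu).astype(np.int64)
    r = 1.0 / np.asarray(phi, dtype=float)
    p = r / (r + mu)
    return stats.nbinom.ppf(u, r, p).astype(np.int64)


def nb_copula_pair(
    mu1: float,
    phi1: float,
    mu2: float,
    phi2: float,
    rho: float,
    n: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two NB count vectors coupled by a Gaussian copula.

    A latent bivariate standard normal with correlation ``rho`` is mapped
    through the normal CDF and the NB quantile function with margins
    ``(mu_i, phi_i)``; the margins are exact NB, the count-scale Pearson
    coefficient is an attenuated image of ``rho``.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho {rho} outside (-1, 1)")
    if mu1 <= 0 or mu2 <= 0:
        raise ValueError("NB means must be positive")
    if phi1 < 0 or phi2 < 0:
        raise ValueError("dispersions must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed, 0)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    return _nb_ppf(ndtr(z1), mu1, phi1), _nb_ppf(ndtr(z2), mu2, phi2)


def _gene_id(compartment: str, index: int) -> str:
    prefix = "OG" if compartment == OOCYTE else "CG"
    return f"{prefix}{index:05d}"


def _sample_ids(compartment: str, pair_ids: Sequence[str]) -> list[str]:
    return [f"{p}_{compartment}" for p in pair_ids]


def simulate_paired_experiment(config: SimConfig) -> tuple[PairedExperiment, SimTruth]:
    """Generate a paired experiment plus its ground-truth record.

    Per gene: baseline mean ``exp(U(baseline_log_mean_range))``, dispersion
    ``U(dispersion_range)``, length ``U(gene_length_range)``; per sample a
    log-normal factor (median 1) multiplies every gene mean.  DE genes get
    their cumulus mean multiplied by ``2**log2fc`` in BCB-positive samples.
    Planted edges replace the cumulus gene's latent normal with
    ``rho z_oocyte + sqrt(1-rho^2) eps`` on the in-scope samples.
    """
    n = config.n_pairs
    seed = config.seed
    pair_ids = [f"P{i + 1:02d}" for i in range(n)]
    groups = np.array([BCB_POS] * config.n_pairs_pos + [BCB_NEG] * config.n_pairs_neg)
    pos_mask = groups == BCB_POS

    # library-size factors, one per sample per compartment, median 1
    rng_lib = _rng(seed, _LIBSIZE)
    s_oocyte = np.exp(config.libsize_log_sd * rng_lib.standard_normal(n))
    s_cumulus = np.exp(config.libsize_log_sd * rng_lib.standard_normal(n))

    scope_masks = {
        "all": np.ones(n, dtype=bool),
        "pos_only": pos_mask,
        "neg_only": ~pos_mask,
    }
    edge_by_cumulus = {e.cumulus: e for e in config.planted_edges}
    de_by_cumulus = {d.cumulus: d for d in config.de_genes}

    def gene_params(rng: np.random.Generator) -> tuple[float, float, int, np.ndarray]:
        lo, hi = config.baseline_log_mean_range
        mu = float(np.exp(rng.uniform(lo, hi)))
        phi = float(rng.uniform(*config.dispersion_range))
        length = int(rng.integers(config.gene_length_range[0],
                                  config.gene_length_range[1] + 1))
        z = rng.standard_normal(n)
        return mu, phi, length, z

    oocyte_counts = np.empty((config.n_genes_oocyte, n), dtype=np.int64)
    oocyte_lengths = np.empty(config.n_genes_oocyte, dtype=np.int64)
    oocyte_latent: dict[int, np.ndarray] = {}
    oocyte_edge_genes = {e.oocyte for e in config.planted_edges}
    for g in range(config.n_genes_oocyte):
        mu, phi, length, z = gene_params(_rng(seed, _OOCYTE, g))
        if g in oocyte_edge_genes:
            oocyte_latent[g] = z
        oocyte_lengths[g] = length
        oocyte_counts[g] = _nb_ppf(ndtr(z), mu * s_oocyte, phi)

    cumulus_counts = np.empty((config.n_genes_cumulus, n), dtype=np.int64)
    cumulus_lengths = np.empty(config.n_genes_cumulus, dtype=np.int64)
    for g in range(config.n_genes_cumulus):
        mu, phi, length, z = gene_params(_rng(seed, _CUMULUS, g))
        cumulus_lengths[g] = length
        edge = edge_by_cumulus.get(g)
        if edge is not None:
            mask = scope_masks[edge.scope]
            z = z.copy()
            z[mask] = (edge.rho * oocyte_latent[edge.oocyte][mask]
                       + np.sqrt(1.0 - edge.rho ** 2) * z[mask])
        mu_j = mu * s_cumulus
        de = de_by_cumulus.get(g)
        if de is not None:
            mu_j = np.where(pos_mask, mu_j * 2.0 ** de.log2fc, mu_j)
        cumulus_counts[g] = _nb_ppf(ndtr(z), mu_j, phi)

    def build(compartment, counts, lengths, n_genes) -> CountMatrix:
        gene_ids = [_gene_id(compartment, g) for g in range(n_genes)]
        samples = _sample_ids(compartment, pair_ids)
        return CountMatrix(
            counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
            compartment=compartment,
            gene_lengths=pd.Series(lengths, index=gene_ids),
        )

    oocyte = build(OOCYTE, oocyte_counts, oocyte_lengths, config.n_genes_oocyte)
    cumulus = build(CUMULUS, cumulus_counts, cumulus_lengths, config.n_genes_cumulus)
    pairing = pd.DataFrame(
        {
            "oocyte_sample": _sample_ids(OOCYTE, pair_ids),
            "cumulus_sample": _sample_ids(CUMULUS, pair_ids),
            "group": groups,
        },
        index=pd.Index(pair_ids, name="pair_id"),
    )
    experiment = PairedExperiment(oocyte=oocyte, cumulus=cumulus, pairing=pairing)

    truth = SimTruth(
        edges_all=tuple(e for e in config.planted_edges if e.scope == "all"),
        edges_pos_only=tuple(e for e in config.planted_edges if e.scope == "pos_only"),
        edges_neg_only=tuple(e for e in config.planted_edges if e.scope == "neg_only"),
        de_genes=config.de_genes,
        realized_libsizes=pd.concat(
            [oocyte.library_sizes(), cumulus.library_sizes()]
        ),
        seed=seed,
    )
    return experiment, truth


def write_fixture(experiment: PairedExperiment, truth: SimTruth, directory) -> dict:
    """Write a simulated experiment to plain-text TSV files.

    Produces per-compartment count tables (genes x samples), a sample sheet
    (sample_id, compartment, pair_id, group), a gene sheet (gene_id,
    compartment, length) and the truth record; reading the fixture back
    reproduces the matrices exactly.
    """
    from .io import write_experiment  # local import to avoid a cycle

    paths = write_experiment(experiment, directory)

    directory = Path(directory)
    rows = [
        {
            "kind": "edge",
            "oocyte_gene": _gene_id(OOCYTE, e.oocyte),
            "cumulus_gene": _gene_id(CUMULUS, e.cumulus),
            "rho": e.rho,
            "scope": e.scope,
            "log2fc": "",
        }
        for e in truth.all_edges
    ] + [
        {
            "kind": "de_gene",
            "oocyte_gene": "",
            "cumulus_gene": _gene_id(CUMULUS, d.cumulus),
            "rho": "",
            "scope": "",
            "log2fc": d.log2fc,
        }
        for d in truth.de_genes
    ]
    truth_path = directory / "truth.tsv"
    pd.DataFrame(rows, columns=["kind", "oocyte_gene", "cumulus_gene",
                                "rho", "scope", "log2fc"]).to_csv(
        truth_path, sep="\t", index=False
    )
    paths["truth"] = truth_path
    return paths
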