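"""Network-level summaries of the cross-compartment co-expression graph:
per-gene connectivity and hub calls, group-wise differential co-expression,
and the mirror-clustering concordance of independent sample clusterings in
the two compartments.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .coexpression import (
    CrossCorrelationMatrix,
    choose_threshold,
    edges_at_threshold,
    efdr_curve,
    paired_pearson,
    permutation_null,
)
from .types import CUMULUS, GROUPS, OOCYTE, PairedExperiment, TransformedMatrix

__all__ = [
    "connectivity",
    "DifferentialNetworkReport",
    "differential_coexpression",
    "MirrorClusterResult",
    "mirror_clustering",
    "chance_concordance",
]


def connectivity(edges: pd.DataFrame, hub_min: int = 10) -> pd.DataFrame:
    """Per-gene degree in the bipartite edge list.

    Returns one row per (gene, compartment) with ``degree``, ``share``
    (degree / total edges) and a ``hub`` flag for degree > ``hub_min``.
    The oocyte-side degrees and the cumulus-side degrees each sum to the
    number of edges (handshake identity).
    """
    if edges.empty:
        warnings.warn("empty edge list; connectivity table is empty", RuntimeWarning)
        return pd.DataFrame(columns=["gene_id", "compartment", "degree", "share", "hub"])
    total = len(edges)
    blocks = []
    for col, comp in (("oocyte_gene", OOCYTE), ("cumulus_gene", CUMULUS)):
        deg = edges[col].value_counts().sort_index()
        blocks.append(pd.DataFrame({
            "gene_id": deg.index,
            "compartment": comp,
            "degree": deg.to_numpy(),
            "share": deg.to_numpy() / total,
            "hub": deg.to_numpy() > hub_min,
        }))
    return (pd.concat(blocks, ignore_index=True)
            .sort_values(["compartment", "degree", "gene_id"],
                         ascending=[True, False, True])
            .reset_index(drop=True))


@dataclass
class DifferentialNetworkReport:
    """Edges called in one BCB group annotated with the other group's r.

    ``threshold`` is the group-specific correlation cutoff chosen at the
    common eFDR level (None when unattainable, in which case ``edges`` is
    empty and ``threshold_attainable`` False).
    """

    focal_group: str
    other_group: str
    alpha: float
    threshold: float | None
    threshold_attainable: bool
    edges: pd.DataFrame
    other_r_mean: float = math.nan
    other_r_min: float = math.nan
    other_r_max: float = math.nan
    gene_counts: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "focal_group": self.focal_group,
            "alpha": self.alpha,
            "threshold": self.threshold,
            "threshold_attainable": self.threshold_attainable,
            "n_edges": int(len(self.edges)),
            "other_r_mean": self.other_r_mean,
            "other_r_min": self.other_r_min,
            "other_r_max": self.other_r_max,
            **{f"n_{k}": v for k, v in self.gene_counts.items()},
        }


def differential_coexpression(
    o: TransformedMatrix,
    c: TransformedMatrix,
    pairing: pd.DataFrame | PairedExperiment,
    focal: str,
    alpha: float = 1e-7,
    B: int = 100,
    seed: int = 0,
    thresholds: np.ndarray | None = None,
    signed: bool = True,
) -> DifferentialNetworkReport:
    """Group-specific co-expression edges and their cross-group fate.

    Correlations are computed separately within the focal group's pairs;
    the focal threshold is chosen at the common eFDR level ``alpha`` from a
    within-group permutation null (group sizes preserved), so groups of
    different size get different r cutoffs.  Every called edge is annotated
    with the same gene pair's r in the other group, computed by the
    identical pair-restricted machinery.
    """
    if focal not in GROUPS:
        raise ValueError(f"unknown focal group {focal!r}")
    other = GROUPS[1 - GROUPS.index(focal)]

    observed = paired_pearson(o, c, pairing, scope=focal)
    null = permutation_null(
        o, c, pairing, scope=focal, B=B, seed=seed,
        thresholds=thresholds, signed=signed,
    )
    curve = efdr_curve(observed, null)
    t = choose_threshold(curve, alpha)
    if t is None:
        empty = pd.DataFrame(columns=[
            "oocyte_gene", "cumulus_gene", "r_focal", "threshold", "scope", "r_other"])
        return DifferentialNetworkReport(
            focal_group=focal, other_group=other, alpha=alpha,
            threshold=None, threshold_attainable=False, edges=empty,
        )

    edges = edges_at_threshold(observed, t, signed=signed)
    other_ccm = paired_pearson(o, c, pairing, scope=other)
    o_pos = pd.Index(other_ccm.oocyte_gene_ids).get_indexer(edges["oocyte_gene"])
    c_pos = pd.Index(other_ccm.cumulus_gene_ids).get_indexer(edges["cumulus_gene"])
    edges = edges.rename(columns={"r": "r_focal"})
    edges["r_other"] = other_ccm.r[o_pos, c_pos]

    gene_counts = {
        "oocyte_genes": int(edges["oocyte_gene"].nunique()),
        "cumulus_genes": int(edges["cumulus_gene"].nunique()),
    }
    finite_other = edges["r_other"].dropna()
    return DifferentialNetworkReport(
        focal_group=focal, other_group=other, alpha=alpha,
        threshold=t, threshold_attainable=True, edges=edges,
        other_r_mean=float(finite_other.mean()) if len(finite_other) else math.nan,
        other_r_min=float(finite_other.min()) if len(finite_other) else math.nan,
        other_r_max=float(finite_other.max()) if len(finite_other) else math.nan,
        gene_counts=gene_counts,
    )


@dataclass
class MirrorClusterResult:
    """Concordance of independent oocyte and cumulus sample clusterings."""

    oocyte_genes: list
    cumulus_genes: list
    linkage_method: str
    distance: str
    k: int
    pair_ids: list
    oocyte_labels: np.ndarray
    cumulus_labels: np.ndarray
    label_map: dict
    concordant: np.ndarray
    concordant_count: int

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)


def _correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between sample columns."""
    corr = np.corrcoef(profiles.T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d[d < 0] = 0.0
    return squareform(d, checks=False)


def _best_label_map(
    labels_a: np.ndarray, labels_b: np.ndarray, k: int
) -> tuple[dict, int]:
    """Map cluster labels of *a* onto labels of *b* maximizing agreement.

    Exhaustive over the k! label permutations (intended for k <= 6); ties
    resolved toward the lexicographically smallest assignment.
    """
    best_map, best_agree = None, -1
    for perm in itertools.permutations(range(1, k + 1)):
        mapping = {i + 1: perm[i] for i in range(k)}
        agree = int(np.sum([mapping[a] == b for a, b in zip(labels_a, labels_b)]))
        if agree > best_agree:
            best_map, best_agree = mapping, agree
    return best_map, best_agree


def mirror_clustering(
    o: TransformedMatrix,
    c: TransformedMatrix,
    pairing: pd.DataFrame | PairedExperiment,
    edges: pd.DataFrame,
    r_min: float = 0.992,
    linkage_method: str = "average",
    k: int = 2,
    scope: str = "BCB_pos",
) -> MirrorClusterResult:
    """Do the two compartments cluster their COC pairs the same way?

    The oocyte and cumulus gene sets of the edge subset with r >= ``r_min``
    are collected; the scope's samples are hierarchically clustered within
    each compartment independently (1 - Pearson distance between sample
    profiles restricted to the selected genes); each tree is cut at ``k``
    clusters, labels are matched across compartments by the assignment
    maximizing agreement, and a pair is concordant when its oocyte's
    cluster maps to its cumulus's cluster.
    """
    if k > 6:
        raise ValueError("exhaustive label matching is limited to k <= 6")
    r_col = "r_focal" if "r_focal" in edges.columns else "r"
    subset = edges[edges[r_col] >= r_min]
    if subset.empty:
        raise ValueError(f"no edges at r >= {r_min}")
    o_genes = sorted(subset["oocyte_gene"].unique())
    c_genes = sorted(subset["cumulus_gene"].unique())
    if len(o_genes) < 2 or len(c_genes) < 2:
        raise ValueError("fewer than 2 selected genes in a compartment")

    if isinstance(pairing, PairedExperiment):
        pairing = pairing.pairing
    if scope != "all":
        pairing = pairing[pairing["group"] == scope]
    if len(pairing) < 3:
        raise ValueError(f"scope {scope!r} has fewer than 3 pairs")
    pair_ids = list(pairing.index)

    def cluster(matrix: TransformedMatrix, genes, samples) -> np.ndarray:
        profiles = matrix.values.loc[genes, samples].to_numpy(dtype=float)
        if k == 1:
            return np.ones(len(samples), dtype=int)
        z = linkage(_correlation_distance(profiles), method=linkage_method)
        return fcluster(z, t=k, criterion="maxclust")

    o_labels = cluster(o, o_genes, list(pairing["oocyte_sample"]))
    c_labels = cluster(c, c_genes, list(pairing["cumulus_sample"]))
    k_eff = max(k, o_labels.max(), c_labels.max())
    label_map, _ = _best_label_map(o_labels, c_labels, k_eff)
    concordant = np.array([label_map[a] == b for a, b in zip(o_labels, c_labels)])
    return MirrorClusterResult(
        oocyte_genes=o_genes,
        cumulus_genes=c_genes,
        linkage_method=linkage_method,
        distance="1 - Pearson",
        k=k,
        pair_ids=pair_ids,
        oocyte_labels=o_labels,
        cumulus_labels=c_labels,
        label_map=label_map,
        concordant=concordant,
        concordant_count=int(concordant.sum()),
    )


def chance_concordance(sizes_a: tuple[int, ...], sizes_b: tuple[int, ...]) -> float:
    """Expected best-matched agreement of two independent random partitions.

    Exact enumeration: partition A is held fixed with cluster sizes
    ``sizes_a``; every arrangement of labels with sizes ``sizes_b`` over
    the same samples is enumerated, the best label matching is computed
    for each, and the mean agreement returned.  This is the chance level
    against which an observed mirror-clustering concordance is judged.
    Supports k = 2 (the default analysis cut).
    """
    if len(sizes_a) != 2 or len(sizes_b) != 2:
        raise ValueError("chance_concordance supports k = 2")
    n = sum(sizes_a)
    if sum(sizes_b) != n:
        raise ValueError("partitions cover different sample counts")
    labels_a = np.array([1] * sizes_a[0] + [2] * sizes_a[1])
    total, count = 0, 0
    for members in itertools.combinations(range(n), sizes_b[0]):
        labels_b = np.full(n, 2)
        labels_b[list(members)] = 1
        _, agree = _best_label_map(labels_a, labels_b, 2)
        total += agree
        count += 1
    return total / count
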