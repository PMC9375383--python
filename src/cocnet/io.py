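"""Readers and writers for the plain-text experiment layout.

An experiment directory holds:

- ``oocyte_counts.tsv`` / ``cumulus_counts.tsv`` — genes as rows (first
  column ``gene_id``), one column per sample;
- ``samples.tsv`` — columns ``sample_id``, ``compartment``, ``pair_id``,
  ``group`` (two rows per pair, one per compartment);
- ``genes.tsv`` — columns ``gene_id``, ``compartment``, ``length``.

MatrixMarket input is also accepted for counts (``.mtx`` with sidecar
``*_genes.txt`` / ``*_samples.txt`` id files, one id per line).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import COMPARTMENTS, CUMULUS, GROUPS, OOCYTE, CountMatrix, PairedExperiment

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_experiment",
    "write_experiment",
]


def write_count_table(matrix: CountMatrix, path) -> Path:
    path = Path(path)
    out = matrix.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    return path


def read_count_table(
    path, compartment: str, gene_lengths: pd.Series | None = None
) -> CountMatrix:
    """Read a counts table from TSV or MatrixMarket.

    TSV: first column gene ids, header row sample ids.  MatrixMarket: the
    ``.mtx`` file plus ``<stem>_genes.txt`` and ``<stem>_samples.txt``.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        m = scipy.io.mmread(path)
        if scipy.sparse.issparse(m):
            m = m.toarray()
        genes = (path.parent / f"{path.stem}_genes.txt").read_text().split()
        samples = (path.parent / f"{path.stem}_samples.txt").read_text().split()
        counts = pd.DataFrame(np.asarray(m, dtype=np.int64), index=genes, columns=samples)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts = counts.astype(np.int64)
        counts.index.name = None
    return CountMatrix(counts=counts, compartment=compartment, gene_lengths=gene_lengths)


def write_mtx(matrix: CountMatrix, path) -> Path:
    path = Path(path)
    scipy.io.mmwrite(path.with_suffix(".mtx"),
                     scipy.sparse.csr_matrix(matrix.counts.to_numpy()))
    (path.parent / f"{path.stem}_genes.txt").write_text(
        "\n".join(matrix.gene_ids) + "\n")
    (path.parent / f"{path.stem}_samples.txt").write_text(
        "\n".join(matrix.sample_ids) + "\n")
    return path.with_suffix(".mtx")


def write_experiment(experiment: PairedExperiment, directory) -> dict:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, cm in ((OOCYTE, experiment.oocyte), (CUMULUS, experiment.cumulus)):
        paths[f"{name}_counts"] = write_count_table(cm, directory / f"{name}_counts.tsv")

    sample_rows = []
    for pair_id, row in experiment.pairing.iterrows():
        sample_rows.append(
            {"sample_id": row["oocyte_sample"], "compartment": OOCYTE,
             "pair_id": pair_id, "group": row["group"]})
        sample_rows.append(
            {"sample_id": row["cumulus_sample"], "compartment": CUMULUS,
             "pair_id": pair_id, "group": row["group"]})
    paths["samples"] = directory / "samples.tsv"
    pd.DataFrame(sample_rows).to_csv(paths["samples"], sep="\t", index=False)

    gene_rows = []
    for name, cm in ((OOCYTE, experiment.oocyte), (CUMULUS, experiment.cumulus)):
        lengths = cm.gene_lengths
        for gid in cm.gene_ids:
            gene_rows.append({
                "gene_id": gid, "compartment": name,
                "length": "" if lengths is None else int(lengths.loc[gid]),
            })
    paths["genes"] = directory / "genes.tsv"
    pd.DataFrame(gene_rows).to_csv(paths["genes"], sep="\t", index=False)
    return paths


def _pairing_from_samples(samples: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "compartment", "pair_id", "group"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    bad = set(samples["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise ValueError(f"unknown compartments {sorted(bad)}")
    bad = set(samples["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown groups {sorted(bad)}")
    rows = {}
    for pair_id, block in samples.groupby("pair_id", sort=True):
        by_comp = {r["compartment"]: r for _, r in block.iterrows()}
        if set(by_comp) != set(COMPARTMENTS) or len(block) != 2:
            raise ValueError(
                f"pair {pair_id!r} must have exactly one oocyte and one cumulus sample")
        groups = set(block["group"])
        if len(groups) != 1:
            raise ValueError(f"pair {pair_id!r} has inconsistent group labels")
        rows[pair_id] = {
            "oocyte_sample": by_comp[OOCYTE]["sample_id"],
            "cumulus_sample": by_comp[CUMULUS]["sample_id"],
            "group": groups.pop(),
        }
    pairing = pd.DataFrame.from_dict(rows, orient="index")
    pairing.index.name = "pair_id"
    return pairing


def read_experiment(directory) -> PairedExperiment:
    """Read an experiment directory written by :func:`write_experiment`."""
    directory = Path(directory)
    samples = pd.read_csv(directory / "samples.tsv", sep="\t")
    pairing = _pairing_from_samples(samples)

    genes_path = directory / "genes.tsv"
    lengths_by_comp: dict[str, pd.Series | None] = {c: None for c in COMPARTMENTS}
    if genes_path.exists():
        genes = pd.read_csv(genes_path, sep="\t")
        for comp, block in genes.groupby("compartment"):
            lens = pd.to_numeric(block["length"], errors="coerce")
            if lens.notna().all():
                lengths_by_comp[comp] = pd.Series(
                    lens.to_numpy(dtype=np.int64), index=block["gene_id"].to_numpy())

    matrices = {}
    for comp in COMPARTMENTS:
        tsv = directory / f"{comp}_counts.tsv"
        mtx = directory / f"{comp}_counts.mtx"
        path = tsv if tsv.exists() else mtx
        if not path.exists():
            raise FileNotFoundError(f"no counts table for {comp} in {directory}")
        matrices[comp] = read_count_table(path, comp, lengths_by_comp[comp])
    return PairedExperiment(
        oocyte=matrices[OOCYTE], cumulus=matrices[CUMULUS], pairing=pairing)
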