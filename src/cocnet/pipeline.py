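"""End-to-end orchestration: filter -> TMM -> arcsinh transform ->
all-pairs co-expression with permutation eFDR -> group-wise differential
network -> mirror clustering -> per-compartment NB differential expression,
with every stage parameter echoed into a machine-readable run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import (
    choose_threshold,
    default_threshold_grid,
    edges_at_threshold,
    efdr_curve,
    paired_pearson,
    permutation_null,
)
from .counts import asinh_transform, filter_low_expression, tmm_factors
from .de import de_consensus
from .io import read_experiment
from .network import connectivity, differential_coexpression, mirror_clustering
from .simulate import DEGene, PlantedEdge, SimConfig, simulate_paired_experiment, write_fixture
from .types import BCB_NEG, BCB_POS, CUMULUS, OOCYTE, PairedExperiment

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class FilterParams:
    cpm_min: float = 2.0
    tpm_min: float = 1.0
    min_samples: int = 9
    combine: str = "or"


@dataclass
class CoexpressionParams:
    alpha: float = 1e-5
    permutations: int = 100
    seed: int = 7
    signed: bool = True
    grid_step: float = 0.002
    regularize: bool = False


@dataclass
class NetworkParams:
    alpha: float = 1e-7
    permutations: int = 100
    seed: int = 11
    hub_min: int = 10
    mirror_r_min: float = 0.992
    mirror_k: int = 2
    mirror_linkage: str = "average"
    mirror_scope: str = BCB_POS


@dataclass
class DEParams:
    fdr: float = 0.01
    shrink_weight: float = 0.3


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable to/from YAML."""

    input_dir: str | None = None
    sim: dict | None = None
    filter: FilterParams = field(default_factory=FilterParams)
    coexpression: CoexpressionParams = field(default_factory=CoexpressionParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    de: DEParams = field(default_factory=DEParams)
    out_dir: str = "coc_run"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.sim is None):
            raise ValueError("exactly one of input_dir or sim must be given")
        for name, cls in (("filter", FilterParams), ("coexpression", CoexpressionParams),
                          ("network", NetworkParams), ("de", DEParams)):
            value = getattr(self, name)
            if isinstance(value, dict):
                setattr(self, name, cls(**value))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _sim_config(payload: dict) -> SimConfig:
    payload = dict(payload)
    payload["planted_edges"] = [PlantedEdge(*e) for e in payload.get("planted_edges", [])]
    payload["de_genes"] = [DEGene(*d) for d in payload.get("de_genes", [])]
    for key in ("baseline_log_mean_range", "dispersion_range", "gene_length_range"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return SimConfig(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write artifacts under ``config.out_dir`` and return
    the run report (also written as ``report.json``).

    Any stage error aborts with the stage name; artifacts written by the
    failed run are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "timing_s": {},
    }

    def artifact(name: str) -> Path:
        path = out / name
        written.append(path)
        return path

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                report["timing_s"][name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    for path in written:
                        path.unlink(missing_ok=True)
                    raise PipelineError(name, exc) from exc
        return _Ctx()

    grid = default_threshold_grid(config.coexpression.grid_step)

    with stage("load"):
        if config.sim is not None:
            sim_cfg = _sim_config(config.sim)
            experiment, truth = simulate_paired_experiment(sim_cfg)
            paths = write_fixture(experiment, truth, out / "fixture")
            written.extend(paths.values())
            manifest = {k: _sha256(Path(p)) for k, p in paths.items()}
        else:
            experiment = read_experiment(config.input_dir)
            manifest = {
                p.name: _sha256(p)
                for p in sorted(Path(config.input_dir).glob("*.tsv"))
            }
        report["stages"]["load"] = {
            "n_pairs": experiment.n_pairs,
            "group_sizes": experiment.group_sizes(),
            "input_hashes": manifest,
        }

    with stage("filter"):
        fp = config.filter
        filtered = {}
        for comp, cm in ((OOCYTE, experiment.oocyte), (CUMULUS, experiment.cumulus)):
            kept = filter_low_expression(
                cm, cpm_min=fp.cpm_min, tpm_min=fp.tpm_min,
                min_samples=fp.min_samples, combine=fp.combine)
            filtered[comp] = kept
            report["stages"].setdefault("filter", {})[comp] = {
                "genes_in": cm.n_genes, "genes_kept": kept.n_genes,
            }
        experiment = PairedExperiment(
            oocyte=filtered[OOCYTE], cumulus=filtered[CUMULUS],
            pairing=experiment.pairing)

    with stage("normalize"):
        factors, transformed = {}, {}
        for comp, cm in ((OOCYTE, experiment.oocyte), (CUMULUS, experiment.cumulus)):
            f = tmm_factors(cm)
            factors[comp] = f
            transformed[comp] = asinh_transform(cm, f)
            f.factors.rename("tmm_factor").to_csv(
                artifact(f"{comp}_tmm_factors.tsv"), sep="\t")
            report["stages"].setdefault("normalize", {})[comp] = {
                "reference_sample": f.reference_sample,
                "factor_product": float(np.prod(f.factors)),
            }

    cx = config.coexpression
    with stage("coexpression"):
        observed = paired_pearson(
            transformed[OOCYTE], transformed[CUMULUS], experiment.pairing)
        null = permutation_null(
            transformed[OOCYTE], transformed[CUMULUS], experiment.pairing,
            B=cx.permutations, seed=cx.seed, thresholds=grid, signed=cx.signed)
        curve = efdr_curve(observed, null, regularize=cx.regularize)
        curve.to_frame().to_csv(artifact("efdr_all.tsv"), sep="\t", index=False)
        t_all = choose_threshold(curve, cx.alpha)
        finite = observed.r[observed.finite_mask]
        stage_report = {
            "alpha": cx.alpha,
            "threshold": t_all,
            "median_r": float(np.median(finite)),
            "min_r": float(finite.min()),
            "n_comparisons": observed.n_finite,
        }
        if t_all is not None:
            edges = edges_at_threshold(observed, t_all, signed=cx.signed)
            edges.to_csv(artifact("edges_all.tsv"), sep="\t", index=False)
            conn = connectivity(edges, hub_min=config.network.hub_min)
            conn.to_csv(artifact("connectivity_all.tsv"), sep="\t", index=False)
            stage_report.update({
                "n_edges": int(len(edges)),
                "n_hubs": int(conn["hub"].sum()) if len(conn) else 0,
            })
        else:
            edges = None
            stage_report["n_edges"] = 0
        report["stages"]["coexpression"] = stage_report

    nw = config.network
    with stage("differential_network"):
        reports = {}
        for focal in (BCB_POS, BCB_NEG):
            rep = differential_coexpression(
                transformed[OOCYTE], transformed[CUMULUS], experiment.pairing,
                focal=focal, alpha=nw.alpha, B=nw.permutations, seed=nw.seed,
                thresholds=grid, signed=cx.signed)
            rep.edges.to_csv(
                artifact(f"edges_{focal}.tsv"), sep="\t", index=False)
            reports[focal] = rep
            report["stages"].setdefault("differential_network", {})[focal] = rep.summary()

    with stage("mirror_clustering"):
        focal_rep = reports[nw.mirror_scope]
        mirror_report: dict = {"scope": nw.mirror_scope, "r_min": nw.mirror_r_min,
                               "k": nw.mirror_k, "linkage": nw.mirror_linkage}
        try:
            result = mirror_clustering(
                transformed[OOCYTE], transformed[CUMULUS], experiment.pairing,
                focal_rep.edges, r_min=nw.mirror_r_min, k=nw.mirror_k,
                linkage_method=nw.mirror_linkage, scope=nw.mirror_scope)
            mirror_report.update({
                "n_oocyte_genes": len(result.oocyte_genes),
                "n_cumulus_genes": len(result.cumulus_genes),
                "concordant_count": result.concordant_count,
                "n_pairs": result.n_pairs,
            })
        except ValueError as err:
            mirror_report["skipped"] = str(err)
        report["stages"]["mirror_clustering"] = mirror_report

    with stage("differential_expression"):
        groups = pd.Series(index=pd.Index([], dtype=object), dtype=object)
        for comp, cm in ((OOCYTE, experiment.oocyte), (CUMULUS, experiment.cumulus)):
            sample_col = f"{comp}_sample"
            groups = pd.Series(
                experiment.pairing["group"].to_numpy(),
                index=experiment.pairing[sample_col].to_numpy())
            result = de_consensus(
                cm, groups, factors[comp],
                fdr=config.de.fdr, shrink_weight=config.de.shrink_weight)
            result.to_csv(artifact(f"de_{comp}.tsv"), sep="\t")
            sig = result[result["significant"]]
            report["stages"].setdefault("differential_expression", {})[comp] = {
                "fdr": config.de.fdr,
                "n_significant": int(len(sig)),
                "n_higher_pos": int((sig["direction"] == BCB_POS).sum()),
                "n_higher_neg": int((sig["direction"] == BCB_NEG).sum()),
            }

    with stage("report"):
        path = artifact("report.json")
        path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report
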