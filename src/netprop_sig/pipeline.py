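"""End-to-end pipeline: simulate -> network -> signature -> diffuse -> enrich -> compare.

A single :class:`PipelineConfig` drives the run.  Inputs are either loaded
from files (network TSV, signature TSV, GMT) or generated by the synthetic
module with planted ground truth.  Every intermediate is written as a
plain-text artifact, plus a JSON manifest (config echo, seeds, version,
per-stage row counts).  The manifest contains no timestamps, so identical
config + seeds reproduce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compare import pathway_concordance, venn
from .diffuse import diffuse, heat_kernel, laplacian, scale_scores, top_n
from .enrich import fisher_enrichment
from .errors import ConfigError
from .netio import read_gmt, read_network, write_gmt, write_network
from .sig import exclude_gene_patterns, filter_signature, relevance_vector
from .synth import make_pathway_collection, make_sbm_network, make_signature

logger = logging.getLogger(__name__)

SIGNATURE_TSV_COLUMNS = ["gene", "log2fc", "p", "p_adj", "provenance"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips losslessly through YAML."""

    outdir: str = "netprop_run"
    # optional file inputs; when absent the synthetic generators are used
    network_path: str | None = None
    signature_path: str | None = None
    gmt_path: str | None = None
    # synthetic-scenario parameters (the standard planted-module fixture)
    n_genes: int = 500
    n_modules: int = 5
    p_in: float = 0.2
    p_out: float = 0.01
    observe_frac: float = 0.6
    lfc_mean: float = 0.0
    lfc_sd: float = 0.5
    n_background: int = 20
    n_random_pathways: int = 20
    pathway_size_min: int = 5
    pathway_size_max: int = 50
    seed: int = 7
    # analysis thresholds (upstream-anchored defaults)
    string_min: float = 300.0
    rnainter_min: float = 0.25
    alpha: float = 0.1
    top_n: int = 200
    max_p_adj: float = 0.05
    min_count: int = 3
    # flags
    scaling: str = "zscore"
    gene_ratio_convention: str = "pathway"
    apply_exclude_patterns: bool = False

    def validate(self) -> None:
        if self.alpha < 0:
            raise ConfigError(f"alpha must be >= 0, got {self.alpha}")
        if not (0 < self.observe_frac <= 1):
            raise ConfigError(f"observe_frac must be in (0, 1], got {self.observe_frac}")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ConfigError(f"require 0 <= p_out < p_in <= 1, got {self.p_in}/{self.p_out}")
        if not (0 < self.max_p_adj <= 1):
            raise ConfigError(f"max_p_adj must be in (0, 1], got {self.max_p_adj}")
        if self.top_n < 1 or self.top_n > self.n_genes:
            raise ConfigError(f"top_n must be in [1, n_genes], got {self.top_n}")
        if self.min_count < 0:
            raise ConfigError(f"min_count must be >= 0, got {self.min_count}")
        if self.scaling not in ("zscore", "minmax"):
            raise ConfigError(f"unknown scaling {self.scaling!r}")
        if self.gene_ratio_convention not in ("pathway", "query"):
            raise ConfigError(f"unknown gene_ratio_convention {self.gene_ratio_convention!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _write_signature(table: pd.DataFrame, path: Path) -> None:
    cols = [c for c in SIGNATURE_TSV_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)


def read_signature(path: str | Path) -> pd.DataFrame:
    """Read a signature TSV (gene, log2fc, p, p_adj[, provenance])."""
    table = pd.read_csv(path, sep="\t")
    for col in ("gene", "log2fc", "p", "p_adj"):
        if col not in table.columns:
            raise ConfigError(f"{path}: signature table missing column {col!r}")
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to disk).

    Stages: simulate (or load), network, signature, diffusion, ranking,
    enrichment, comparison.  Any stage error halts with the stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seeds": {"network": config.seed, "signature": config.seed + 1,
                  "pathways": config.seed + 2},
        "stages": {},
    }
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        truth = None
        if config.network_path:
            network = read_network(config.network_path)
        else:
            network, truth = make_sbm_network(
                config.n_genes, config.n_modules, config.p_in, config.p_out,
                seed=config.seed,
            )
        if config.signature_path:
            signature = read_signature(config.signature_path)
        else:
            if truth is None:
                raise ConfigError(
                    "signature_path is required when a network file is supplied"
                )
            signature, truth = make_signature(
                truth, network,
                observe_frac=config.observe_frac, lfc_mean=config.lfc_mean,
                lfc_sd=config.lfc_sd, n_background=config.n_background,
                seed=config.seed + 1,
            )
        if config.gmt_path:
            collection = read_gmt(config.gmt_path)
        else:
            if truth is None:
                raise ConfigError("gmt_path is required when file inputs are supplied")
            collection = make_pathway_collection(
                truth, n_random=config.n_random_pathways,
                size_range=(config.pathway_size_min, config.pathway_size_max),
                seed=config.seed + 2,
            )
        if truth is not None:
            truth_path = outdir / "truth.json"
            truth_path.write_text(json.dumps(
                {
                    "module_assignment": truth.module_assignment,
                    "phenotype_module": truth.phenotype_module,
                    "hidden_genes": sorted(truth.hidden_genes),
                    "observed_genes": sorted(truth.observed_genes),
                    "background_genes": sorted(truth.background_genes),
                    "seed": truth.seed,
                },
                sort_keys=True, indent=1,
            ))
        manifest["stages"][stage] = {
            "simulated": truth is not None,
            "outputs": ["truth.json"] if truth is not None else [],
        }
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "network"
        write_network(network, outdir / "network.tsv")
        manifest["stages"][stage] = {
            "n_nodes": network.n_nodes,
            "n_edges": network.n_edges,
            "component_sizes": network.component_sizes()[:10],
            "outputs": ["network.tsv"],
        }

        stage = "signature"
        filtered = filter_signature(signature, max_p_adj=config.max_p_adj)
        if config.apply_exclude_patterns:
            kept = set(exclude_gene_patterns(filtered["gene"]))
            filtered = filtered[filtered["gene"].isin(kept)].reset_index(drop=True)
        _write_signature(filtered, outdir / "signature.tsv")
        write_gmt(collection, outdir / "pathways.gmt")
        manifest["stages"][stage] = {
            "n_input": len(signature),
            "n_filtered": len(filtered),
            "outputs": ["signature.tsv", "pathways.gmt"],
        }

        stage = "diffusion"
        t0 = time.perf_counter()
        relevance = relevance_vector(filtered, network)
        kernel = heat_kernel(laplacian(network), alpha=config.alpha)
        result = scale_scores(diffuse(kernel, relevance), method=config.scaling)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
        manifest["stages"][stage] = {
            "alpha": config.alpha,
            "n_mapped": relevance.n_mapped,
            "n_unmapped": len(relevance.unmapped),
            "outputs": [],
        }

        stage = "ranking"
        ranked = top_n(result, n=config.top_n)
        result.frame.sort_values("rank").to_csv(
            outdir / "diffusion_scores.tsv", sep="\t", index=False
        )
        ranked.to_csv(outdir / "ranked_top.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "top_n": config.top_n,
            "outputs": ["diffusion_scores.tsv", "ranked_top.tsv"],
        }

        stage = "enrichment"
        universe = list(network.nodes)
        before = fisher_enrichment(
            list(filtered["gene"]), collection, universe,
            gene_ratio_convention=config.gene_ratio_convention,
        )
        after = fisher_enrichment(
            list(ranked["gene"]), collection, universe,
            gene_ratio_convention=config.gene_ratio_convention,
        )
        before.to_csv(outdir / "enrichment_signature.tsv", sep="\t", index=False)
        after.to_csv(outdir / "enrichment_propagated.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_pathways": len(before),
            "outputs": ["enrichment_signature.tsv", "enrichment_propagated.tsv"],
        }

        stage = "comparison"
        report = pathway_concordance(before, after)
        sig_genes = set(filtered["gene"]) & set(network.nodes)
        vc = venn(sig_genes, set(ranked["gene"]))
        report_dict = report.to_dict()
        report_dict["venn_signature_vs_top"] = dataclasses.asdict(vc)
        (outdir / "comparison.json").write_text(
            json.dumps(report_dict, sort_keys=True, indent=1)
        )
        report.paired.to_csv(outdir / "paired_pathways.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "represented_before": report.represented_before,
            "represented_after": report.represented_after,
            "outputs": ["comparison.json", "paired_pathways.tsv"],
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
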