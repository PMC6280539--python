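"""End-to-end pipeline driver: build -> enumerate -> score -> permute ->
select -> networks -> enrichment, with a run manifest for reproducibility."""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from . import io as mio
from .datatypes import MGDT
from .disease import (drug_participation_ranking, score_profile_summary,
                      significant_network)
from .enrichment import (common_pathways, mirna_pathway_profiles)
from .network import (build_tripartite_network, degree_stats, enumerate_mgdts,
                      fit_power_law, topological_coefficients)
from .scoring import permutation_significance, select_significant

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs and knobs of one pipeline run (YAML-serializable)."""

    disease_genes: str = ""
    mirna_targets: str = ""
    drug_targets: str = ""
    mrna: str = ""
    mirna: str = ""
    labels: str = ""
    gmt: str = ""                      # optional; skips enrichment if empty
    out_dir: str = "mgdt_out"
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    welch: bool = False
    allow_degenerate_groups: bool = False
    pooled_null: bool = False
    bh_adjust: bool = False
    min_fraction: float = 1.0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        required = ["disease_genes", "mirna_targets", "drug_targets",
                    "mrna", "mirna", "labels"]
        for name in required:
            p = getattr(self, name)
            if not p:
                raise ValueError(f"config field {name!r} is required")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file: {p}")
        if self.gmt and not Path(self.gmt).exists():
            raise FileNotFoundError(f"gmt: no such file: {self.gmt}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order and write all result tables to
    ``config.out_dir``; returns the output directory.

    Outputs: network files (SIF + GraphML), degree/topology tables, the
    scored-triplet table, the significant subset with its network and drug
    ranking, score-profile summaries, and (when a GMT is configured)
    per-miRNA enrichment profiles with their common pathways. A
    ``manifest.json`` records version, seed, parameters, and input
    checksums.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = [f"mgdtnet {__version__}", f"seed = {config.seed}",
                  f"n_perm = {config.n_perm}", f"alpha = {config.alpha}"]

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("load")
        catalog = mio.read_interaction_catalog(
            config.disease_genes, config.mirna_targets, config.drug_targets)
        study = mio.read_expression_study(config.mrna, config.mirna,
                                          config.labels)
    except Exception as exc:
        raise StageError("load", str(exc)) from exc

    try:
        stage("build")
        net = build_tripartite_network(catalog)
        mio.write_network(net, out / "network.sif", "sif")
        mio.write_network(net, out / "network.graphml", "graphml")
        triplets = enumerate_mgdts(net)
        stats = degree_stats(net, k=min(10, max(1, net.n_nodes)))
        tc = topological_coefficients(net)
        with open(out / "topology.tsv", "w", encoding="utf-8") as fh:
            for line in provenance:
                fh.write(f"# {line}\n")
            fh.write("node\tclass\tdegree\ttopological_coefficient\n")
            for n in sorted(net.nodes):
                fh.write(f"{n}\t{net.node_class(n)}\t{net.graph.degree(n)}"
                         f"\t{tc[n]:.10g}\n")
        try:
            plaw = fit_power_law(stats.distribution)
            plaw_row = {"slope": plaw.slope, "intercept": plaw.intercept,
                        "r_squared": plaw.r_squared}
        except ValueError:
            plaw_row = None
        summary = {
            "nodes": net.n_nodes, "edges": net.n_edges,
            "class_counts": net.class_counts(),
            "class_mean_degree": stats.class_means,
            "n_triplets": len(triplets),
            "power_law": plaw_row,
        }
        (out / "network_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n",
            encoding="utf-8")
    except Exception as exc:
        raise StageError("build", str(exc)) from exc

    if not triplets:
        raise StageError("build", "network contains no triplet to score")

    try:
        stage("score+permute")
        records = permutation_significance(
            study, catalog, triplets, n_perm=config.n_perm, seed=config.seed,
            welch=config.welch,
            allow_degenerate_groups=config.allow_degenerate_groups,
            pooled=config.pooled_null)
        mio.write_records(records, out / "scores.tsv", alpha=config.alpha,
                          header_comments=provenance)
        stage("select")
        significant, fraction = select_significant(
            records, config.alpha, bh_adjust=config.bh_adjust)
        sig_triplets = {r.triplet for r in significant}
        prof = score_profile_summary(records)
        with open(out / "score_profile.tsv", "w", encoding="utf-8") as fh:
            for line in provenance:
                fh.write(f"# {line}\n")
            prof.stats.to_csv(fh, sep="\t", float_format="%.10g",
                              lineterminator="\n")
    except Exception as exc:
        raise StageError("score", str(exc)) from exc

    try:
        stage("networks")
        if sig_triplets:
            sig_net = significant_network(sig_triplets)
            mio.write_network(sig_net, out / "significant_network.sif", "sif")
            mio.write_network(sig_net, out / "significant_network.graphml",
                              "graphml")
        ranking = drug_participation_ranking(sig_triplets)
        with open(out / "drug_ranking.tsv", "w", encoding="utf-8") as fh:
            for line in provenance:
                fh.write(f"# {line}\n")
            fh.write("drug\ttriplet_count\n")
            for drug, count in ranking:
                fh.write(f"{drug}\t{count}\n")
    except Exception as exc:
        raise StageError("networks", str(exc)) from exc

    enrich_summary = None
    if config.gmt:
        try:
            stage("enrichment")
            sets = mio.read_gene_sets(config.gmt)
            sig_mirnas = sorted({t.mirna for t in sig_triplets})
            profiles = mirna_pathway_profiles(
                sig_mirnas, catalog, sets, alpha=config.alpha,
                bh_adjust=config.bh_adjust)
            with open(out / "mirna_pathways.tsv", "w",
                      encoding="utf-8") as fh:
                for line in provenance:
                    fh.write(f"# {line}\n")
                fh.write("mirna\tpathways\n")
                for m in sorted(profiles):
                    fh.write(f"{m}\t{','.join(sorted(profiles[m]))}\n")
            common = (common_pathways(profiles, config.min_fraction)
                      if profiles else set())
            (out / "common_pathways.txt").write_text(
                "".join(pw + "\n" for pw in sorted(common)),
                encoding="utf-8")
            enrich_summary = {"n_profiled_mirnas": len(profiles),
                              "n_common_pathways": len(common)}
        except Exception as exc:
            raise StageError("enrichment", str(exc)) from exc

    manifest = {
        "version": __version__,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k != "extra"},
        "inputs": {name: _sha256(getattr(config, name))
                   for name in ("disease_genes", "mirna_targets",
                                "drug_targets", "mrna", "mirna", "labels")},
        "results": {
            "n_triplets": len(triplets),
            "n_significant": len(sig_triplets),
            "significant_fraction": fraction,
            "enrichment": enrich_summary,
        },
    }
    if config.gmt:
        manifest["inputs"]["gmt"] = _sha256(config.gmt)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    logger.info("pipeline finished: %d/%d significant triplets",
                len(sig_triplets), len(triplets))
    return out
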