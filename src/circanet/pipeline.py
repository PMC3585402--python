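"""End-to-end pipeline orchestration with a config file and manifest.

Stages run in dependency order — normalize, rhythms, joint calls,
light-response, phase-window enrichment, co-expression, motif scanning,
network — each writing TSV/GraphML outputs into a run directory; a JSON
manifest records the package version, seed, configuration hash, and a SHA-256
of every result file so a rerun with the same config can be checked for
bit-identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .coexpression import annotate_clusters, cluster_graph, reciprocal_topk_graph
from .enrichment import sliding_window_phase_enrichment
from .io import TimeSeriesMatrix, load_timeseries, quantile_normalize, save_timeseries
from .light import light_response_calls
from .motifs import call_motif_targets, collapse_motif_groups, motif_gene_tests, parse_jaspar, parse_transfac, build_network, tissue_specific_tfs
from .phase import phase_shift_fraction
from .rhythms import call_zcogs, permutation_fdr, rhythm_calls
from .simulate import read_promoters_fasta

log = logging.getLogger("circanet.pipeline")

ALL_STAGES = ("normalize", "rhythms", "light_response", "enrichment", "coexpression", "motifs", "network")

DEFAULT_THRESHOLDS = {
    "p_zcog": 0.5,
    "n_perm": 1000,
    "p_ld": 0.15,
    "p_joint": 1e-4,
    "r_min": 0.6,
    "k": 20,
    "p_motif": 0.01,
    "top_gene": 20,
    "top_target": 5,
    "window": 6.0,
    "step": 1.0,
    "alpha_window": 0.001,
}


@dataclass
class PipelineConfig:
    """Inputs, stage toggles, thresholds, and the seed for one run."""

    expression_ld: str = ""
    expression_dd: str = ""
    sample_sheet: str = ""
    promoter_fastas: list = field(default_factory=list)
    ortholog_map: str = ""
    pwm_file: str = ""
    pwm_format: str = "jaspar"
    tf_motif_map: str = ""
    atlas: str = ""
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    seed: int = 0

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        th = self.thresholds
        if not (0 < th["p_zcog"] <= 1 and 0 < th["p_ld"] <= 1 and 0 < th["p_joint"] <= 1):
            raise ValueError("p thresholds must be in (0, 1]")
        if th["n_perm"] < 1 or th["k"] < 1 or th["top_gene"] < 1 or th["top_target"] < 1:
            raise ValueError("count thresholds must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the configured stages and return the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    matrix = load_timeseries(config.expression_ld, config.sample_sheet)
    if config.expression_dd and config.expression_dd != config.expression_ld:
        dd_matrix = load_timeseries(config.expression_dd, config.sample_sheet)
        both = TimeSeriesMatrix(matrix.values.join(dd_matrix.values), matrix.samples.combine_first(dd_matrix.samples))
    else:
        both = matrix

    if "normalize" in config.stages:
        log.info("[normalize] quantile normalization of %s", both)
        both = quantile_normalize(both)
        save_timeseries(both, out / "normalized.tsv", out / "samples.tsv")

    zcogs = None
    if "rhythms" in config.stages:
        log.info("[rhythms] g-test and joint calls")
        ld = both.condition("LD")
        dd = both.condition("DD")
        zcogs = call_zcogs(ld, dd, th["p_zcog"])
        fdr = permutation_fdr(ld, dd, int(th["n_perm"]), th["p_zcog"], config.seed)
        zcogs["fdr_at_threshold"] = fdr
        zcogs.to_csv(out / "rhythms.tsv", sep="\t")
        count, frac = phase_shift_fraction(zcogs)
        log.info("[rhythms] %d joint calls, FDR=%.3f, >4h shifts: %d (%.1f%%)",
                 int(zcogs["zcog"].sum()), fdr, count, 100 * frac if frac == frac else float("nan"))

    light = None
    if "light_response" in config.stages:
        log.info("[light_response] joint LD/DD template fits")
        ld = both.condition("LD")
        dd = both.condition("DD")
        rl = rhythm_calls(ld, "LD")
        light = light_response_calls(ld, dd, rl, th["p_ld"], th["p_joint"])
        light.to_csv(out / "light_response.tsv", sep="\t")

    if "enrichment" in config.stages and zcogs is not None:
        called = zcogs[zcogs["zcog"]]
        if len(called) >= 3:
            windows = sliding_window_phase_enrichment(
                called["mean_phase"].dropna().to_numpy(),
                called["mean_phase"].dropna().to_numpy(),
                th["window"], th["step"], th["alpha_window"],
            )
            pd.DataFrame([w.__dict__ for w in windows]).to_csv(out / "phase_windows.tsv", sep="\t", index=False)

    clusters = None
    if "coexpression" in config.stages:
        log.info("[coexpression] reciprocal top-%d graph", int(th["k"]))
        graph = reciprocal_topk_graph(both.values, th["r_min"], int(th["k"]))
        nx.write_graphml(graph, out / "coexpression.graphml")
        nx.to_pandas_edgelist(graph).to_csv(out / "coexpression_edges.tsv", sep="\t", index=False)
        if graph.number_of_nodes():
            clusters = cluster_graph(graph, seed=config.seed)
            pd.DataFrame(
                [(g, i) for i, c in enumerate(clusters) for g in sorted(c)],
                columns=["gene", "cluster"],
            ).to_csv(out / "clusters.tsv", sep="\t", index=False)
            if zcogs is not None:
                table = annotate_clusters(
                    clusters, zcogs.index[zcogs["zcog"]], zcogs["mean_phase"].dropna()
                )
                table.to_csv(out / "cluster_annotation.tsv", sep="\t")

    grouped = None
    if "motifs" in config.stages and config.pwm_file:
        log.info("[motifs] promoter scanning")
        text = Path(config.pwm_file).read_text()
        pwms = parse_jaspar(text) if config.pwm_format == "jaspar" else parse_transfac(text)
        promoters = read_promoters_fasta(config.promoter_fastas)
        orthologs = pd.read_csv(config.ortholog_map, sep="\t")
        tests = motif_gene_tests(promoters, orthologs, pwms)
        calls = call_motif_targets(tests, th["p_motif"], int(th["top_gene"]))
        calls.to_csv(out / "motif_targets.tsv", sep="\t", index=False)
        grouped = collapse_motif_groups(calls, {})
        grouped.to_csv(out / "motif_groups.tsv", sep="\t", index=False)

    if "network" in config.stages and grouped is not None and config.tf_motif_map:
        log.info("[network] regulatory network assembly")
        tf_map = pd.read_csv(config.tf_motif_map, sep="\t")
        phases = zcogs["mean_phase"] if zcogs is not None else None
        tissues = None
        if config.atlas:
            atlas_df = pd.read_csv(config.atlas, sep="\t", header=None, names=["gene", "tissue"])
            tissues = atlas_df.set_index("gene")["tissue"]
        net = build_network(grouped, tf_map, phases, th["p_motif"], int(th["top_target"]), tissues)
        nx.write_graphml(net, out / "network.graphml")
        nx.to_pandas_edgelist(net).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        if tissues is not None:
            tissue_specific_tfs(net, tissues, th["p_motif"]).to_csv(out / "tissue_tfs.tsv", sep="\t")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": list(config.stages),
        "files": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
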