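"""Reciprocal top-k co-expression graph and modularity clustering.

A gene pair is co-expressed when its Pearson correlation exceeds a floor
(0.6 by default) and each gene ranks within the other's top-k (20) most
correlated partners. The resulting undirected graph is partitioned with
seeded Louvain modularity communities — a documented stand-in for
significance-driven recursive spectral clustering, so cluster-level claims
are structural (planted-partition recovery) rather than algorithm-identical.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import fisher_enrichment, sliding_window_phase_enrichment
from .phase import circular_mean

__all__ = ["reciprocal_topk_graph", "cluster_graph", "annotate_clusters"]


def reciprocal_topk_graph(values: pd.DataFrame, r_min: float = 0.6, k: int = 20) -> nx.Graph:
    """Build the mutual top-k Pearson correlation graph.

    ``values`` is genes x samples. Constant rows cannot be correlated and are
    dropped with a warning (they still appear as isolated nodes). Ranking is
    by descending correlation with ties broken lexicographically on gene id;
    the rank threshold is inclusive (rank k still qualifies).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples per gene")
    genes = list(values.index)
    vals = values.to_numpy(dtype=float)
    constant = vals.std(axis=1) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene rows excluded from correlation")
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    active = [g for g, c in zip(genes, constant) if not c]
    if len(active) < 2:
        return graph
    sub = values.loc[active].to_numpy(dtype=float)
    corr = np.corrcoef(sub)
    np.fill_diagonal(corr, -np.inf)
    n = len(active)
    # rank partners per gene: descending r, ties by lexicographic gene id
    lex = np.argsort(np.array(active))
    lex_rank = np.empty(n, dtype=int)
    lex_rank[lex] = np.arange(n)
    order = np.lexsort((lex_rank[None, :].repeat(n, 0), -corr), axis=1)
    rank = np.empty_like(order)
    rows = np.arange(n)[:, None]
    rank[rows, order] = np.arange(n)[None, :] + 1
    in_topk = rank <= k
    mutual = in_topk & in_topk.T & (corr > r_min)
    for i in range(n):
        for j in range(i + 1, n):
            if mutual[i, j]:
                graph.add_edge(active[i], active[j], weight=float(corr[i, j]))
    return graph


def cluster_graph(graph: nx.Graph, seed: int = 0) -> list[set]:
    """Partition the co-expression graph into modularity communities.

    Louvain with a fixed seed: deterministic given the seed, singletons
    allowed (isolated nodes form their own communities).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(graph, weight="weight", seed=seed)
    return [set(c) for c in comms]


def annotate_clusters(
    clusters: list[set],
    zcog_genes,
    phases: pd.Series | dict,
    motif_targets: dict | None = None,
    window_width: float = 6.0,
    window_step: float = 1.0,
    window_alpha: float = 0.001,
) -> pd.DataFrame:
    """Per-cluster circadian and motif enrichment summary.

    For every cluster, reports the Fisher enrichment of joint circadian calls
    (background: all clustered genes), the circular mean phase with the best
    phase-window p, and — when a {motif: target set} map is supplied — the
    top-ranked motif by Fisher p.
    """
    background = set().union(*clusters)
    zcog_genes = set(zcog_genes) & background
    phases = pd.Series(phases)
    bg_phases = phases.reindex(list(background)).dropna()
    rows = []
    for i, cluster in enumerate(clusters):
        zres = fisher_enrichment(cluster, zcog_genes, background, term=f"cluster_{i}")
        cl_phases = phases.reindex(list(cluster)).dropna()
        mean_phase, best_window, best_window_p = float("nan"), float("nan"), float("nan")
        if len(cl_phases) >= 2 and len(bg_phases) > len(cl_phases):
            mean_phase = circular_mean(cl_phases.to_numpy())
            windows = sliding_window_phase_enrichment(
                cl_phases.to_numpy(), bg_phases.to_numpy(),
                width=window_width, step=window_step, alpha=window_alpha,
            )
            best = min(windows, key=lambda w: w.p)
            best_window, best_window_p = best.window_start, best.p
        top_motif, top_motif_p = None, float("nan")
        if motif_targets:
            motif_res = [
                (m, fisher_enrichment(cluster, set(t) & background, background, term=m).p)
                for m, t in motif_targets.items()
            ]
            top_motif, top_motif_p = min(motif_res, key=lambda mp: (mp[1], mp[0]))
        rows.append(
            {
                "cluster": i,
                "size": len(cluster),
                "zcog_in_cluster": zres.a,
                "zcog_odds_ratio": zres.odds_ratio,
                "zcog_p": zres.p,
                "mean_phase": mean_phase,
                "best_phase_window": best_window,
                "best_phase_window_p": best_window_p,
                "top_motif": top_motif,
                "top_motif_p": top_motif_p,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
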