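"""Gene-set enrichment: 2x2 Fisher tests and circular phase-window scans.

One generic machinery serves several questions: whether a gene set is
enriched for a pathway/tissue/motif annotation (hypergeometric 2x2), and in
which circadian time window a set of phases concentrates relative to a
background (a sliding 2x2 over windows wrapping modulo 24).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "enrichment_table",
    "PhaseEnrichmentWindow",
    "sliding_window_phase_enrichment",
    "merge_significant_windows",
    "read_gmt",
    "read_annotation_tsv",
]


@dataclass
class EnrichmentResult:
    term: str
    a: int  # set & term
    b: int  # set, not term
    c: int  # background (excluding set) & term
    d: int  # background (excluding set), not term
    odds_ratio: float
    p: float


def fisher_enrichment(gene_set, term_genes, background, term: str = "") -> EnrichmentResult:
    """One-sided (greater) Fisher exact test of a gene set against a term.

    ``gene_set`` must be contained in ``background``; the comparison group is
    the background with the set removed. The odds ratio is ad/bc with the
    convention inf when bc = 0 and a > 0.
    """
    gene_set = set(gene_set)
    term_genes = set(term_genes)
    background = set(background)
    if not background:
        raise ValueError("empty background")
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of background")
    rest = background - gene_set
    a = len(gene_set & term_genes)
    b = len(gene_set - term_genes)
    c = len(rest & term_genes)
    d = len(rest - term_genes)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if b * c == 0:
        odds = float("inf") if a > 0 else 0.0
    return EnrichmentResult(term=term, a=a, b=b, c=c, d=d, odds_ratio=float(odds), p=float(p))


def enrichment_table(gene_set, annotations: dict, background) -> pd.DataFrame:
    """Run :func:`fisher_enrichment` over a term -> gene-set mapping."""
    rows = [fisher_enrichment(gene_set, genes, background, term) for term, genes in annotations.items()]
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("term")
    return df.sort_values("p")


@dataclass
class PhaseEnrichmentWindow:
    window_start: float
    width: float
    targets_in: int
    targets_total: int
    background_in: int
    background_total: int
    p: float
    significant: bool


def _in_window(phases: np.ndarray, start: float, width: float, period: float) -> np.ndarray:
    return ((phases - start) % period) < width


def sliding_window_phase_enrichment(
    set_phases,
    background_phases,
    width: float = 6.0,
    step: float = 1.0,
    alpha: float = 0.001,
    period: float = 24.0,
) -> list[PhaseEnrichmentWindow]:
    """Scan circadian windows for over-representation of a phase set.

    For every window [s, s+width) mod 24, s = 0, step, ..., a one-sided Fisher
    test compares the set's in-window count against the rest of the
    background's (the set is assumed to be part of the background and is
    subtracted from it). All windows are returned; those with p < alpha are
    flagged. No multiple-testing correction is applied across windows — the
    alpha is a raw per-window threshold.
    """
    if not 0 < width < period:
        raise ValueError("width must be in (0, period)")
    set_phases = np.asarray(set_phases, dtype=float)
    bg_phases = np.asarray(background_phases, dtype=float)
    if len(set_phases) > len(bg_phases):
        raise ValueError("background must be a superset of the set")
    rest_total = len(bg_phases) - len(set_phases)
    out = []
    for start in np.arange(0.0, period, step):
        a = int(_in_window(set_phases, start, width, period).sum())
        bg_in = int(_in_window(bg_phases, start, width, period).sum())
        c = max(bg_in - a, 0)
        table = [[a, len(set_phases) - a], [c, rest_total - c]]
        _, p = stats.fisher_exact(table, alternative="greater")
        out.append(
            PhaseEnrichmentWindow(
                window_start=float(start),
                width=width,
                targets_in=a,
                targets_total=len(set_phases),
                background_in=bg_in,
                background_total=len(bg_phases),
                p=float(p),
                significant=p < alpha,
            )
        )
    return out


def merge_significant_windows(
    windows: list[PhaseEnrichmentWindow], period: float = 24.0
) -> list[tuple[float, float]]:
    """Merge overlapping significant windows into maximal circular runs.

    Returns (start, end) intervals on the circle; end may exceed the period
    when a run wraps past 24. An all-significant scan collapses to one full
    circle.
    """
    sig = sorted((w for w in windows if w.significant), key=lambda w: w.window_start)
    if not sig:
        return []
    starts = [w.window_start for w in sig]
    width = sig[0].width
    step_candidates = np.diff(starts)
    # group starts into runs where consecutive windows overlap
    runs = [[starts[0]]]
    for s_prev, s_next in zip(starts, starts[1:]):
        if s_next - s_prev < width:
            runs[-1].append(s_next)
        else:
            runs.append([s_next])
    # wraparound: last run may continue into the first
    if len(runs) > 1 and (starts[0] + period) - runs[-1][-1] < width:
        runs[0] = runs.pop(-1) + [s + period for s in runs[0]]
    intervals = [(run[0], run[-1] + width) for run in runs]
    return [(s % period, s % period + (e - s)) for s, e in intervals]


# -- annotation readers --------------------------------------------------------


def read_gmt(path) -> dict:
    """Read a GMT gene-set file into {term: set of genes}."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def read_annotation_tsv(path) -> dict:
    """Read a two-column gene->term TSV into {term: set of genes}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str, comment="#")
    if len(df) and tuple(df.iloc[0]) == ("gene", "term"):
        df = df.iloc[1:]
    out: dict = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(term, set()).add(gene)
    return out
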