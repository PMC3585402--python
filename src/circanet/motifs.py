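"""Promoter motif scanning and circadian regulatory-network assembly.

The TF-target prediction follows a comparative-genomics recipe: promoters
(1 kb upstream to 200 bp downstream of the TSS) of a gene and its orthologs
in related fish species are scanned with a position weight matrix (PWM); the
group's mean best log-odds hit is compared with the genome-wide background of
best hits by a z-test. Motifs enriched for a gene group (p < 0.01, within the
gene's top-20 motifs) become motif-target calls; similar motifs are collapsed
to motif groups by the minimum p rule; network edges keep, per motif group,
the top-5 targets at p < 0.01. TF->motif edges come from a supplied mapping
table, and TFs whose called targets concentrate in the TF's own tissue are
flagged as tissue-specific regulators.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PWM",
    "parse_jaspar",
    "parse_transfac",
    "reverse_complement",
    "estimate_background",
    "extract_promoter_coords",
    "scan_promoter",
    "ortholog_group_motif_test",
    "motif_gene_tests",
    "call_motif_targets",
    "collapse_motif_groups",
    "build_network",
    "tissue_specific_tfs",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass
class PWM:
    """Position weight matrix: 4 x L counts (rows A, C, G, T)."""

    id: str
    counts: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError(f"PWM {self.id}: need a 4 x L matrix with L >= 4")
        if (self.counts < 0).any():
            raise ValueError(f"PWM {self.id}: negative entries")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def probabilities(self) -> np.ndarray:
        """Column-normalized probabilities with the pseudocount added."""
        p = self.counts + self.pseudocount
        return p / p.sum(axis=0, keepdims=True)

    def log_odds(self, background: np.ndarray = UNIFORM_BACKGROUND) -> np.ndarray:
        bg = np.asarray(background, dtype=float)[:, None]
        return np.log(self.probabilities() / bg)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities().argmax(axis=0))

    def max_score(self, background: np.ndarray = UNIFORM_BACKGROUND) -> float:
        return float(self.log_odds(background).max(axis=0).sum())


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# -- PWM text formats ----------------------------------------------------------


def parse_jaspar(text: str, pseudocount: float = 0.01) -> list[PWM]:
    """Parse JASPAR-style PWM text: '>ID ...' then 4 rows A/C/G/T.

    Rows may be bare numbers or the bracketed dialect ``A [ 1 2 3 ]``.
    """
    pwms = []
    current_id, rows = None, []

    def flush():
        if current_id is not None:
            if len(rows) != 4:
                raise ValueError(f"PWM {current_id}: expected 4 rows, got {len(rows)}")
            pwms.append(PWM(current_id, np.array(rows), pseudocount))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            current_id = line[1:].split()[0]
            rows = []
        else:
            nums = re.findall(r"[-+]?\d+(?:\.\d+)?", re.sub(r"^[ACGTacgt]", "", line))
            rows.append([float(v) for v in nums])
    flush()
    if not pwms:
        raise ValueError("no PWMs found")
    return pwms


def parse_transfac(text: str, pseudocount: float = 0.01) -> list[PWM]:
    """Parse TRANSFAC-dialect matrices (AC/ID header, P0 count block)."""
    pwms = []
    pwm_id, in_block, rows = None, False, []
    for line in text.splitlines() + ["//"]:
        tag = line[:2]
        if tag in ("AC", "ID") and pwm_id is None:
            pwm_id = line.split(maxsplit=1)[1].strip()
        elif tag == "P0":
            order = line.split()[1:5]
            if [b.upper() for b in order] != list(BASES):
                raise ValueError(f"unsupported P0 column order: {order}")
            in_block = True
        elif in_block and re.match(r"^\d+", line):
            rows.append([float(v) for v in line.split()[1:5]])
        elif tag in ("//", "XX") and rows:
            pwms.append(PWM(pwm_id or f"M{len(pwms)}", np.array(rows).T, pseudocount))
            pwm_id, in_block, rows = None, False, []
    if not pwms:
        raise ValueError("no TRANSFAC matrices found")
    return pwms


# -- promoter handling ---------------------------------------------------------


def extract_promoter_coords(
    tss: int,
    strand: str,
    seq_length: int,
    upstream: int = 1000,
    downstream: int = 200,
) -> tuple[int, int]:
    """0-based half-open promoter interval around a TSS, boundary-truncated.

    On the plus strand this is [tss - upstream, tss + downstream); on the
    minus strand the mirror image [tss - downstream, tss + upstream).
    """
    if not 0 <= tss < seq_length:
        raise ValueError("TSS outside sequence")
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream, tss + upstream
    else:
        raise ValueError(f"bad strand {strand!r}")
    return max(start, 0), min(end, seq_length)


def estimate_background(sequences) -> np.ndarray:
    """A/C/G/T frequencies pooled over a promoter collection (N ignored)."""
    counts = np.zeros(4)
    for seq in sequences:
        for i, base in enumerate(BASES):
            counts[i] += seq.upper().count(base)
    if counts.sum() == 0:
        raise ValueError("no ACGT bases found")
    return counts / counts.sum()


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)  # 4 = N / other
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _strand_scores(lo: np.ndarray, encoded: np.ndarray, L: int) -> np.ndarray:
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    return lo[windows, np.arange(L)].sum(axis=1)


def scan_promoter(
    pwm: PWM,
    sequence: str,
    background: np.ndarray = UNIFORM_BACKGROUND,
    return_position: bool = False,
):
    """Best log-odds hit of a PWM over both strands of a sequence.

    N (or any non-ACGT) base contributes the background-expected log-odds of
    its column. The reverse strand is scanned on the reverse complement, so
    the score is invariant under reverse-complementing the input.
    """
    L = pwm.length
    if len(sequence) < L:
        raise ValueError("sequence shorter than motif")
    bg = np.asarray(background, dtype=float)
    lo = pwm.log_odds(bg)
    expected = (bg[:, None] * lo).sum(axis=0)  # per-column score for N
    lo5 = np.vstack([lo, expected])
    fwd = _strand_scores(lo5, _encode(sequence), L)
    rev = _strand_scores(lo5, _encode(reverse_complement(sequence)), L)
    best_fwd, best_rev = int(fwd.argmax()), int(rev.argmax())
    if fwd[best_fwd] >= rev[best_rev]:
        score, pos, strand = float(fwd[best_fwd]), best_fwd, "+"
    else:
        score = float(rev[best_rev])
        pos, strand = len(sequence) - L - best_rev, "-"
    return (score, pos, strand) if return_position else score


# -- ortholog-group enrichment -------------------------------------------------


def ortholog_group_motif_test(group_scores, background_scores) -> tuple[float, float]:
    """z-test of a gene group's mean best hit against the background pool.

    ``z = (mean(group) - mean(background)) / (sd(background)/sqrt(n))`` with
    an upper-tail normal p; the background pool is the best score of the same
    PWM over every promoter genome-wide.
    """
    group = np.asarray(group_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    sd = bg.std(ddof=1)
    if sd == 0:
        raise ValueError("background score variance is zero")
    z = (group.mean() - bg.mean()) / (sd / np.sqrt(group.size))
    return float(z), float(stats.norm.sf(z))


def motif_gene_tests(
    promoters: dict,
    ortholog_map: pd.DataFrame,
    pwms: list[PWM],
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per (motif, gene-group) enrichment z and p over all PWMs.

    ``promoters`` maps species -> {gene: sequence}; ``ortholog_map`` has
    columns gene, species, ortholog_gene linking each reference gene to its
    ortholog's promoter key in every species. Background base frequencies
    default to the pooled promoter composition.
    """
    if background is None:
        background = estimate_background(
            seq for per_gene in promoters.values() for seq in per_gene.values()
        )
    records = []
    for pwm in pwms:
        best: dict[tuple, float] = {}
        for species, per_gene in promoters.items():
            for gene, seq in per_gene.items():
                best[(species, gene)] = scan_promoter(pwm, seq, background)
        pool = np.fromiter(best.values(), dtype=float)
        for gene, grp in ortholog_map.groupby("gene"):
            scores = [
                best[(row.species, row.ortholog_gene)]
                for row in grp.itertuples()
                if (row.species, row.ortholog_gene) in best
            ]
            if not scores:
                continue
            z, p = ortholog_group_motif_test(scores, pool)
            records.append({"motif": pwm.id, "gene": gene, "z": z, "p": p})
    return pd.DataFrame.from_records(records)


def call_motif_targets(tests: pd.DataFrame, p_max: float = 0.01, top_gene: int = 20) -> pd.DataFrame:
    """Retain motif-gene calls with p < p_max within the gene's top-k motifs.

    Motifs are ranked per gene by ascending p (ties by motif id); the
    complementary per-motif rank of the gene is attached for downstream edge
    selection. Returns only the retained calls.
    """
    df = tests.copy()
    df = df.sort_values(["p", "motif"], kind="stable")
    df["rank_in_gene"] = df.groupby("gene").cumcount() + 1
    df = df.sort_values(["p", "gene"], kind="stable")
    df["rank_in_motif"] = df.groupby("motif").cumcount() + 1
    keep = (df["p"] < p_max) & (df["rank_in_gene"] <= top_gene)
    return df[keep].sort_values(["gene", "rank_in_gene"]).reset_index(drop=True)


def collapse_motif_groups(calls: pd.DataFrame, motif_grouping: dict) -> pd.DataFrame:
    """Collapse motif-level calls onto motif groups by the minimum-p rule.

    ``motif_grouping`` maps motif id -> group id; ungrouped motifs form
    singleton groups under their own id. Per (group, gene) the smallest p
    wins and its z is carried along.
    """
    df = calls.copy()
    df["motif_group"] = df["motif"].map(lambda m: motif_grouping.get(m, m))
    df = df.sort_values(["p", "motif"], kind="stable")
    grouped = df.groupby(["motif_group", "gene"], as_index=False).first()
    return grouped[["motif_group", "gene", "motif", "z", "p"]]


def build_network(
    grouped_calls: pd.DataFrame,
    tf_motif_map: pd.DataFrame,
    tf_phases: pd.Series | dict | None = None,
    p_max: float = 0.01,
    top_targets: int = 5,
    tissues: pd.Series | dict | None = None,
) -> nx.DiGraph:
    """Assemble the TF -> motif -> target regulatory network.

    Motif->target edges keep, per motif group, the ``top_targets`` smallest-p
    calls below ``p_max`` (ties by gene id); TF->motif "binds" edges come from
    the mapping table (columns tf, motif_group). Node attributes carry kind
    (tf / motif / gene), circadian phase, and tissue where supplied.
    """
    tf_phases = pd.Series(tf_phases, dtype=float) if tf_phases is not None else pd.Series(dtype=float)
    tissues = pd.Series(tissues, dtype=object) if tissues is not None else pd.Series(dtype=object)
    net = nx.DiGraph()
    for row in tf_motif_map.itertuples():
        net.add_node(row.tf, kind="tf")
        net.add_node(row.motif_group, kind="motif")
        net.add_edge(row.tf, row.motif_group, kind="binds")
    if len(grouped_calls):
        df = grouped_calls[grouped_calls["p"] < p_max].sort_values(
            ["p", "gene"], kind="stable"
        )
        df = df.groupby("motif_group", group_keys=False).head(top_targets)
        for row in df.itertuples():
            net.add_node(row.motif_group, kind="motif")
            if row.gene not in net or net.nodes[row.gene].get("kind") is None:
                net.add_node(row.gene, kind=net.nodes.get(row.gene, {}).get("kind", "gene"))
            net.add_edge(row.motif_group, row.gene, kind="targets", p=float(row.p), z=float(row.z))
    for node in net.nodes:
        if node in tf_phases.index and pd.notna(tf_phases.get(node)):
            net.nodes[node]["phase"] = float(tf_phases[node])
        if node in tissues.index and pd.notna(tissues.get(node)):
            net.nodes[node]["tissue"] = tissues[node]
    return net


def tf_called_targets(network: nx.DiGraph, tf) -> set:
    """Targets reachable from a TF through its motif nodes."""
    targets = set()
    for motif in network.successors(tf):
        if network.edges[tf, motif].get("kind") != "binds":
            continue
        for gene in network.successors(motif):
            if network.edges[motif, gene].get("kind") == "targets":
                targets.add(gene)
    return targets


def tissue_specific_tfs(
    network: nx.DiGraph,
    atlas: pd.Series | dict,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Flag TFs whose called targets are enriched in the TF's own tissue.

    ``atlas`` maps gene -> tissue. A TF is flagged when the Fisher test of
    its target set against the TF's tissue (background: all atlas genes)
    gives p < p_max. TFs absent from the atlas are skipped with a warning.
    """
    from .enrichment import fisher_enrichment

    atlas = pd.Series(atlas, dtype=object)
    background = set(atlas.index)
    rows = []
    tfs = [n for n, d in network.nodes(data=True) if d.get("kind") == "tf"]
    for tf in tfs:
        if tf not in atlas.index:
            warnings.warn(f"TF {tf} absent from atlas; skipped")
            continue
        tissue = atlas[tf]
        targets = tf_called_targets(network, tf) & background
        if not targets:
            rows.append({"tf": tf, "tissue": tissue, "n_targets": 0,
                         "targets_in_tissue": 0, "odds_ratio": float("nan"),
                         "p": 1.0, "tissue_specific": False})
            continue
        in_tissue = set(atlas.index[atlas == tissue])
        res = fisher_enrichment(targets, in_tissue, background, term=tissue)
        rows.append(
            {
                "tf": tf,
                "tissue": tissue,
                "n_targets": len(targets),
                "targets_in_tissue": res.a,
                "odds_ratio": res.odds_ratio,
                "p": res.p,
                "tissue_specific": res.p < p_max,
            }
        )
    return pd.DataFrame(rows).set_index("tf") if rows else pd.DataFrame(
        columns=["tissue", "n_targets", "targets_in_tissue", "odds_ratio", "p", "tissue_specific"]
    )
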