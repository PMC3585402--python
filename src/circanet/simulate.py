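"""Synthetic circadian studies with known ground truth.

The generator emulates the design of a two-condition (LD 14h:10h light/dark
and DD constant-dark) whole-larva time course: 12 timepoints at 4 h intervals
over 48 h starting at CT0, log2-scale intensities, and a gene mixture of

* ``null`` — flat baseline plus noise in both conditions;
* ``core`` — 24 h cosine of amplitude A in LD, amplitude rho*A in DD
  (the endogenous clock persists in darkness at reduced amplitude);
* ``fast_light`` — saturating-exponential rise after lights-on (time constant
  tau = 1.5 h) toward baseline + A, decaying after its peak; flat in DD;
* ``slow_light`` — same shape with tau = 6 h, peaking before lights-off;
  flat in DD;
* ``dark_induced`` — low during the light period, rising after lights-off
  (tau = 2 h) to a peak in the dark; constant *elevated* (baseline + A/2)
  in DD.

A subset of core genes act as transcription factors; each TF's targets get
phases von-Mises-concentrated around the TF phase plus a fixed lag, the TF's
binding motif is planted into the target's promoter in every simulated fish
species (with per-species point mutations), and TFs share a tissue label with
most of their targets. Everything is driven by one seed: identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import TimeSeriesMatrix
from .motifs import PWM, BASES

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "make_pwm_library",
    "simulate_expression",
    "simulate_promoters",
    "simulate_atlas",
    "write_promoters_fasta",
    "read_promoters_fasta",
    "write_ortholog_map",
    "write_atlas",
]

SPECIES = ("zebrafish", "fugu", "medaka", "stickleback", "tetraodon")
CLASSES = ("null", "core", "fast_light", "slow_light", "dark_induced")
LIGHTS_OFF = 14.0  # CT hours; lights-on at CT0 in a 14h:10h cycle

DEFAULT_FRACTIONS = {
    "null": 0.70,
    "core": 0.20,
    "fast_light": 0.04,
    "slow_light": 0.04,
    "dark_induced": 0.02,
}

# per-class pulse kinetics: saturating-exponential rise from the driving
# light transition (lights-on for light-induced, lights-off for dark-induced)
# up to the gene's peak time, exponential decay afterwards
RISE_TAU = {"fast_light": 1.5, "slow_light": 6.0, "dark_induced": 2.0}
DECAY_TAU = {"fast_light": 6.0, "slow_light": 6.0, "dark_induced": 3.0}
PULSE_ONSET = {"fast_light": 0.0, "slow_light": 0.0, "dark_induced": LIGHTS_OFF}

# ranges the per-gene peak times are drawn from; chosen so the resulting
# first-harmonic (cosinor) phases — what the truth records — sit inside the
# classifier's CT windows with margin: fast [2,8), slow [8,16), dark [16,2)
PEAK_TIME_RANGES = {
    "fast_light": (3.0, 6.0),
    "slow_light": (10.0, 13.5),
    "dark_induced": (17.5, 21.5),
}

# DD level of dark-induced genes, as a fraction of the LD peak deviation:
# the induced state persists in constant darkness near (but below) the LD
# peak — the "trough elevated" configuration
DARK_DD_PEAK_FRACTION = 0.75

_FINE_GRID = np.arange(0.0, 24.0, 0.05)


@dataclass
class SimulationConfig:
    n_genes: int = 1000
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    timepoints: tuple = tuple(np.arange(0, 48, 4.0))
    conditions: tuple = ("LD", "DD")
    noise_sd: float = 0.5
    amplitude_range: tuple = (1.0, 2.0)
    dd_amplitude_ratio: float = 0.7
    n_tfs: int = 5
    targets_per_tf: int = 20
    target_phase_kappa: float = 3.5
    target_phase_lag: float = 6.0
    motif_length: int = 12
    promoter_length: int = 1200
    n_species: int = 5
    gc_content: float = 0.40
    mutation_rate: float = 0.05
    n_tissues: int = 5
    tissue_share: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.timepoints) == 0:
            raise ValueError("timepoints must be non-empty")
        if not all(b > a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if set(self.class_fractions) - set(CLASSES):
            raise ValueError(f"unknown classes: {set(self.class_fractions) - set(CLASSES)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        rho = self.dd_amplitude_ratio
        bounds = (rho, rho) if np.ndim(rho) == 0 else tuple(rho)
        if not all(0 < r <= 1 for r in bounds) or bounds[0] > bounds[1]:
            raise ValueError("dd_amplitude_ratio must be in (0, 1] (scalar or (lo, hi))")
        if self.motif_length > self.promoter_length:
            raise ValueError("motif longer than promoter")
        if not 1 <= self.n_species <= len(SPECIES):
            raise ValueError(f"n_species must be in 1..{len(SPECIES)}")

    @property
    def species(self) -> tuple:
        return SPECIES[: self.n_species]


@dataclass
class SimulationTruth:
    """Ground truth for one synthetic study.

    ``genes``: per-gene frame (class, phase, amplitude, baseline, tissue,
    is_tf, regulator). ``tf_edges``: TF -> target pairs. ``planted_motifs``:
    one row per planted site (motif, gene, species, offset, strand), filled
    by :func:`simulate_promoters`.
    """

    genes: pd.DataFrame
    tf_edges: pd.DataFrame
    planted_motifs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["motif", "gene", "species", "offset", "strand"])
    )

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes.reset_index().to_dict(orient="list"),
            "tf_edges": self.tf_edges.to_dict(orient="list"),
            "planted_motifs": self.planted_motifs.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        genes = pd.DataFrame(payload["genes"]).set_index("gene")
        return cls(
            genes=genes,
            tf_edges=pd.DataFrame(payload["tf_edges"]),
            planted_motifs=pd.DataFrame(payload["planted_motifs"]),
        )


def _allocate_classes(n_genes: int, fractions: dict) -> list[str]:
    """Deterministic largest-remainder allocation of class counts."""
    items = [(c, fractions.get(c, 0.0)) for c in CLASSES]
    raw = [(c, f * n_genes) for c, f in items]
    counts = {c: int(np.floor(x)) for c, x in raw}
    short = n_genes - sum(counts.values())
    for c, _ in sorted(raw, key=lambda cf: (-(cf[1] - np.floor(cf[1])), CLASSES.index(cf[0])))[:short]:
        counts[c] += 1
    labels = []
    for c in CLASSES:
        labels.extend([c] * counts[c])
    return labels


def _light_waveform(ct: np.ndarray, cls: str, peak_time, amplitude=1.0) -> np.ndarray:
    """Unit-height light-driven pulse(s) evaluated at CT (periodic mod 24).

    Rises from the class's driving transition with its rise time constant
    until ``peak_time``, then decays exponentially (the pre-onset part of the
    cycle carries the previous cycle's decay tail). ``peak_time`` may be an
    array (one pulse per gene); the result is then genes x timepoints.
    """
    tau_r, tau_d = RISE_TAU[cls], DECAY_TAU[cls]
    onset = PULSE_ONSET[cls]
    peak = np.atleast_1d(np.asarray(peak_time, dtype=float))[:, None]
    rel = (np.asarray(ct, dtype=float)[None, :] - onset) % 24.0
    peak_rel = (peak - onset) % 24.0
    peak_val = 1.0 - np.exp(-peak_rel / tau_r)
    w = np.where(
        rel < peak_rel,
        1.0 - np.exp(-rel / tau_r),
        peak_val * np.exp(-(rel - peak_rel) / tau_d),
    )
    out = np.asarray(amplitude)[..., None] * w if np.ndim(amplitude) else amplitude * w
    return out[0] if np.ndim(peak_time) == 0 else out


def _harmonic_phase_amp(waveforms: np.ndarray, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First-harmonic (24 h) phase and amplitude of waveform rows."""
    omega = 2 * np.pi / 24.0
    design = np.column_stack([np.ones_like(grid), np.cos(omega * grid), np.sin(omega * grid)])
    coef = np.atleast_2d(waveforms) @ np.linalg.pinv(design).T
    phase = (np.arctan2(coef[:, 2], coef[:, 1]) / omega) % 24.0
    return np.where(phase >= 24.0, 0.0, phase), np.hypot(coef[:, 1], coef[:, 2])


def simulate_expression(config: SimulationConfig):
    """Generate (LD matrix, DD matrix, truth) for one synthetic study."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    labels = _allocate_classes(n, config.class_fractions)
    gene_ids = [f"g{i:05d}" for i in range(1, n + 1)]
    classes = pd.Series(labels, index=gene_ids, name="class")

    baseline = rng.uniform(6.0, 12.0, size=n)
    lo, hi = config.amplitude_range
    amplitude = rng.uniform(lo, hi, size=n)
    # DD/LD amplitude ratio: fixed, or drawn per gene from a (lo, hi) interval
    if np.ndim(config.dd_amplitude_ratio) == 0:
        dd_ratio = np.full(n, float(config.dd_amplitude_ratio))
    else:
        r_lo, r_hi = config.dd_amplitude_ratio
        dd_ratio = rng.uniform(r_lo, r_hi, size=n)
    phase = np.full(n, np.nan)

    core_idx = np.flatnonzero(classes.to_numpy() == "core")
    n_needed = config.n_tfs * (1 + config.targets_per_tf)
    if config.n_tfs and len(core_idx) < n_needed:
        raise ValueError(
            f"need >= {n_needed} core genes for {config.n_tfs} TFs with "
            f"{config.targets_per_tf} targets each"
        )
    phase[core_idx] = rng.uniform(0.0, 24.0, size=len(core_idx))
    peak_time = np.full(n, np.nan)
    for cls, (a, b) in PEAK_TIME_RANGES.items():
        idx = np.flatnonzero(classes.to_numpy() == cls)
        peak_time[idx] = rng.uniform(a, b, size=len(idx))

    is_tf = np.zeros(n, dtype=bool)
    regulator = np.full(n, None, dtype=object)
    edges = []
    if config.n_tfs:
        tf_idx = core_idx[: config.n_tfs]
        is_tf[tf_idx] = True
        # phase-specific regulators occupy distinct phases: spread the TFs
        # evenly around the clock at a random rotation
        phase[tf_idx] = (rng.uniform(0, 24) + 24 * np.arange(config.n_tfs) / config.n_tfs) % 24
        target_pool = core_idx[config.n_tfs : n_needed]
        for j, ti in enumerate(tf_idx):
            targets = target_pool[j * config.targets_per_tf : (j + 1) * config.targets_per_tf]
            center = (phase[ti] + config.target_phase_lag) * 2 * np.pi / 24.0
            drawn = rng.vonmises(center, config.target_phase_kappa, size=len(targets))
            phase[targets] = (drawn * 24.0 / (2 * np.pi)) % 24.0
            for gi in targets:
                regulator[gi] = gene_ids[ti]
                edges.append({"tf": gene_ids[ti], "target": gene_ids[gi]})

    # tissue labels: each TF owns a tissue, shared with `tissue_share` of its
    # targets; everything else drawn uniformly
    tissue_names = [f"tissue_{k + 1}" for k in range(config.n_tissues)]
    tissue = np.array(rng.choice(tissue_names, size=n), dtype=object)
    if config.n_tfs:
        for j, ti in enumerate(core_idx[: config.n_tfs]):
            t_name = tissue_names[j % config.n_tissues]
            tissue[ti] = t_name
            targets = core_idx[config.n_tfs : n_needed][
                j * config.targets_per_tf : (j + 1) * config.targets_per_tf
            ]
            share = rng.random(len(targets)) < config.tissue_share
            tissue[targets[share]] = t_name

    ct = np.asarray(config.timepoints, dtype=float)
    omega = 2 * np.pi / 24.0
    ld = np.tile(baseline[:, None], (1, ct.size)).astype(float)
    dd = ld.copy()
    cls_arr = classes.to_numpy()
    idx = np.flatnonzero(cls_arr == "core")
    if idx.size:
        wave = amplitude[idx, None] * np.cos(omega * (ct[None, :] - phase[idx, None]))
        ld[idx] += wave
        dd[idx] += dd_ratio[idx, None] * wave
    # light-driven classes: pulse scaled so its first-harmonic amplitude
    # equals the gene's amplitude — "amplitude" then means the same
    # (cosinor) quantity for every class; the truth phase is the pulse's
    # first-harmonic phase, which is what a cosinor fit recovers
    for cls in ("fast_light", "slow_light", "dark_induced"):
        idx = np.flatnonzero(cls_arr == cls)
        if not idx.size:
            continue
        fine = _light_waveform(_FINE_GRID, cls, peak_time[idx])
        phi1, a1 = _harmonic_phase_amp(fine, _FINE_GRID)
        phase[idx] = phi1
        scale = amplitude[idx] / a1
        ld[idx] += scale[:, None] * _light_waveform(ct, cls, peak_time[idx])
        if cls == "dark_induced":
            dd[idx] += (DARK_DD_PEAK_FRACTION * scale * fine.max(axis=1))[:, None]
    if config.noise_sd > 0:
        ld += rng.normal(0.0, config.noise_sd, size=ld.shape)
        dd += rng.normal(0.0, config.noise_sd, size=dd.shape)

    def _matrix(values: np.ndarray, cond: str) -> TimeSeriesMatrix:
        sample_ids = [f"{cond}_CT{int(t):02d}" for t in ct]
        vals = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"), columns=sample_ids)
        sheet = pd.DataFrame(
            {"condition": cond, "ct": ct}, index=pd.Index(sample_ids, name="sample_id")
        )
        return TimeSeriesMatrix(vals, sheet)

    genes = pd.DataFrame(
        {
            "class": cls_arr,
            "phase": phase,
            "peak_time": peak_time,
            "amplitude": amplitude,
            "dd_ratio": dd_ratio,
            "baseline": baseline,
            "tissue": tissue,
            "is_tf": is_tf,
            "regulator": regulator,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    truth = SimulationTruth(genes=genes, tf_edges=pd.DataFrame(edges, columns=["tf", "target"]))
    out = {}
    if "LD" in config.conditions:
        out["LD"] = _matrix(ld, "LD")
    if "DD" in config.conditions:
        out["DD"] = _matrix(dd, "DD")
    return out.get("LD"), out.get("DD"), truth


# -- promoters -----------------------------------------------------------------


def make_pwm_library(tf_ids, length: int = 12, seed: int = 0, consensus_weight: float = 0.85):
    """One informative random PWM per TF plus the TF<->motif mapping table."""
    rng = np.random.default_rng(seed)
    pwms = []
    rows = []
    for tf in tf_ids:
        consensus = rng.integers(0, 4, size=length)
        counts = np.full((4, length), (1 - consensus_weight) / 3 * 100)
        counts[consensus, np.arange(length)] = consensus_weight * 100
        motif_id = f"M_{tf}"
        pwms.append(PWM(motif_id, counts))
        rows.append({"tf": tf, "motif_group": motif_id})
    return pwms, pd.DataFrame(rows, columns=["tf", "motif_group"])


def simulate_promoters(
    truth: SimulationTruth,
    pwm_library: list[PWM],
    config: SimulationConfig,
    genes=None,
):
    """Background promoters with the TF consensus planted in target genes.

    Every gene gets an i.i.d. background promoter (stated GC content) in each
    species; for every TF->target edge the TF's motif consensus is planted
    once per species promoter at a random offset and strand, with per-species
    per-base mutation probability ``config.mutation_rate``. Planted positions
    are recorded in ``truth.planted_motifs``. Returns
    ``(promoters, ortholog_map)`` with promoters[species][gene] -> sequence.
    """
    if not pwm_library:
        raise ValueError("pwm_library must be non-empty")
    rng = np.random.default_rng((config.seed + 101) % 2**31)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list(BASES))
    pwm_by_tf = {pwm.id.removeprefix("M_"): pwm for pwm in pwm_library}
    genes = list(truth.genes.index) if genes is None else list(genes)
    promoters: dict = {}
    plants = []
    targets_of = truth.tf_edges.groupby("target")["tf"].first() if len(truth.tf_edges) else pd.Series(dtype=object)
    for species in config.species:
        per_gene = {}
        for gene in genes:
            seq = rng.choice(bases, size=config.promoter_length, p=probs)
            if gene in targets_of.index:
                tf = targets_of[gene]
                pwm = pwm_by_tf.get(tf)
                if pwm is None:
                    raise KeyError(f"no PWM in library for TF {tf}")
                if pwm.length > config.promoter_length:
                    raise ValueError("motif longer than promoter")
                site = np.array(list(pwm.consensus))
                if config.mutation_rate > 0:
                    mut = rng.random(pwm.length) < config.mutation_rate
                    for k in np.flatnonzero(mut):
                        choices = [b for b in BASES if b != site[k]]
                        site[k] = rng.choice(choices)
                offset = int(rng.integers(0, config.promoter_length - pwm.length + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                    site = np.array([comp[b] for b in site[::-1]])
                seq[offset : offset + pwm.length] = site
                plants.append(
                    {"motif": pwm.id, "gene": gene, "species": species,
                     "offset": offset, "strand": strand}
                )
            per_gene[gene] = "".join(seq)
        promoters[species] = per_gene
    truth.planted_motifs = pd.DataFrame(
        plants, columns=["motif", "gene", "species", "offset", "strand"]
    )
    ortholog_map = pd.DataFrame(
        [
            {"gene": gene, "species": species, "ortholog_gene": gene}
            for gene in genes
            for species in config.species
        ]
    )
    return promoters, ortholog_map


def simulate_atlas(truth: SimulationTruth) -> pd.Series:
    """Two-column gene -> tissue annotation straight from the truth labels."""
    if "tissue" not in truth.genes:
        raise ValueError("truth has no tissue labels")
    return truth.genes["tissue"].rename("tissue")


# -- writers -------------------------------------------------------------------


def write_promoters_fasta(promoters: dict, out_dir) -> list[Path]:
    """One FASTA per species with headers '<species>|<gene>'."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for species, per_gene in promoters.items():
        records = [
            SeqRecord(Seq(seq), id=f"{species}|{gene}", description="")
            for gene, seq in per_gene.items()
        ]
        path = out_dir / f"promoters_{species}.fasta"
        SeqIO.write(records, path, "fasta")
        paths.append(path)
    return paths


def read_promoters_fasta(paths) -> dict:
    """Inverse of :func:`write_promoters_fasta`."""
    from Bio import SeqIO

    promoters: dict = {}
    for path in paths:
        for record in SeqIO.parse(str(path), "fasta"):
            species, gene = record.id.split("|", 1)
            promoters.setdefault(species, {})[gene] = str(record.seq)
    return promoters


def write_ortholog_map(ortholog_map: pd.DataFrame, path) -> None:
    ortholog_map.to_csv(path, sep="\t", index=False)


def write_atlas(atlas: pd.Series, path) -> None:
    atlas.rename_axis("gene").reset_index().to_csv(path, sep="\t", index=False, header=False)
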