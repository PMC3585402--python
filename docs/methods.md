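# Methods

## Rhythm detection

A gene's time course (default: 12 equally spaced samples, Δt = 4 h, two full
24 h cycles) is mean-removed and Fourier-transformed; the periodogram keeps
the interior Fourier frequencies k/(nΔt), k = 1…⌊(n−1)/2⌋. With n = 12 that
is m = 5 ordinates and 24 h is index k = 2. The Nyquist ordinate is excluded:
under Gaussian white noise the interior ordinates are i.i.d. exponential
while the Nyquist term is not, and the exact tail formula for Fisher's
g = max/sum,

P(G > g) = Σ_{k=1}^{⌊1/g⌋} (−1)^{k−1} C(m,k) (1 − kg)^{m−1},

is valid only over exchangeable exponential ordinates. The dominant-period
requirement is "argmax ordinate sits at the 24 h frequency", with exact ties
resolved in favor of 24 h. Zero-variance series are degenerate: g undefined,
p = 1. The g statistic is invariant to affine transforms of the series, so no
prior normalization affects it.

Joint calls require p < 0.5 with 24 h dominance in both LD and DD. Both
thresholds are lenient on purpose: each condition contributes an independent
screen and the compound rule's error rate is controlled empirically by the
permutation FDR (below), not by the nominal p level.

### Permutation FDR

Each of n_perm (default 1000) replicates shuffles every gene's time labels —
independently in LD and DD — and re-applies the joint rule. The estimate is
mean permuted positives / observed positives, capped at 1 (a Benjamini-style
plug-in without π₀ correction; with no observed positives the estimate is
undefined and returned as NaN). The per-condition permutations are
independent because the joint null (a gene rhythmic in neither condition) has
independent noise across conditions. Applying one shared permutation to both
conditions was evaluated and rejected: it preserves the cross-condition rank
coupling of genuinely rhythmic genes, which then re-pass the joint rule at
single-condition rates and inflate the estimate roughly two-fold on mixtures
with strong signal.

The realized number of false joint calls in a 900-null study is small
(≈ Poisson with mean ~9 at the default thresholds), so any single study's
realized FDR has ~33% coefficient of variation; comparisons of the plug-in
against truth average several simulation replicates.

## Phase and amplitude

The cosinor fit maximizes Pearson correlation with cos(2π(t−φ)/24) over a
phase grid (default step 0.01 h, matching two-decimal phase tables);
amplitude is the least-squares scale of the winning unit template. The
closed-form harmonic regression (φ = atan2(b_sin, b_cos)/ω) agrees within
one grid step on any nonconstant input and is used where speed matters
(bootstrap loops, waveform calibration). At the study's sampling (n = 12) and
amplitude/noise ratio 2, the circular phase RMSE is ≈ 0.77 h, which is the
Cramér–Rao limit √(2σ²/(nA²)) for this model — the estimator is efficient,
and tighter accuracy at that SNR is not achievable by any method.

Circular machinery: means via the resultant vector (returning NaN when the
resultant is numerically zero, e.g. antipodal pairs), distances as
min(|Δ|, 24−|Δ|), and the Fisher–Lee circular correlation computed with the
O(n) product-sum identity of its pairwise definition; it is rotation
invariant, so a uniform phase shift between conditions does not reduce it.

Amplitude-change calls between conditions use the ratio A_DD/A_LD from
harmonic-regression fits plus a residual-resampling bootstrap (default 200
resamples) of that ratio: "reduced" requires ratio < 0.5 with the 95%
percentile CI excluding 1, "increased" is symmetric, anything else is
"unchanged". The rule (threshold + CI) is this package's own; the source
analyses report such counts without stating a rule.

Cross-species comparison: per homolog pair the difference (φ_mouse −
φ_zebrafish) mod 24, summarized by its circular mean; the associated
regression line on the torus is constrained to unit slope with the mean
shift as intercept. Pairs with "Not present"/"Not oscillating" markers are
excluded. The bundled 41-row table yields a mean shift of ~8.6 h over its 32
numeric pairs.

## Light-response classification

Candidates are LD oscillators (g-test p < 0.15, 24 h dominant; DD behavior
deliberately ignored so genes arrhythmic in DD are kept). The 24-point joint
vector (12 LD, then 12 DD values) is z-scored **as one vector** and
correlated with z-scored templates: cos(2π(t−φ)/24) in LD and a constant −1
or +1 in DD, over a φ grid (step 0.1 h) × both constants. Scaling the data
jointly is what gives the template's ±1 a scale: −1 is the LD cosine trough
and +1 its peak on the data's own standardized axis. The fit's p-value is the
one-sided t-transform of the correlation at 24−2 degrees of freedom, with
p < 10⁻⁴ required for a class call; a permutation option (shuffling the 24
labels and re-correlating against the winning template) agrees with the
t-transform within Monte-Carlo error. Both are significance levels of the
*reported* template, not selection-corrected over the grid — adequate here
because the threshold is extreme and the classifier's false-call rate is
validated empirically on pure-clock simulations (≤ 2% among core genes with
undamped DD oscillation).

Windows (half-open, CT0 = lights-on, CT14 = lights-off): peak-decreased with
φ ∈ [2, 8) → fast light-induced; [8, 16) → slow light-induced;
trough-elevated with φ ∈ [16, 24) ∪ [0, 2) → dark-induced; everything else →
none. The 2 h offset from the light transitions makes "light-induced" mean
rising after lights-on rather than merely peaking in daylight.

## Enrichment

One 2×2 machinery serves pathway/tissue/motif questions: one-sided (greater)
Fisher exact test of a gene set against the background with the set removed;
odds ratio ad/bc with the ∞ convention when bc = 0 and a > 0. Phase
enrichment slides a window (default width 6 h, step 1 h) around the circle,
testing set-in-window against the rest of the background; windows with
p < 0.001 are flagged with **no** multiple-testing correction across windows
(reported raw, as is conventional for these displays), and overlapping
significant windows are merged into maximal circular runs.

## Co-expression

Edges require Pearson r > 0.6 **and** mutual membership in each other's
top-20 most-correlated genes (ranked by descending signed r, ties broken
lexicographically, rank threshold inclusive). Constant rows are excluded
with a warning. Clustering is seeded Louvain modularity maximization — a
deliberate stand-in for significance-driven recursive spectral clustering,
so cluster-level guarantees here are structural (planted-partition recovery,
determinism given the seed) rather than identical cluster boundaries.

## Motif scanning and the regulatory network

PWMs (JASPAR text or TRANSFAC P0 blocks) are normalized per column with a
0.01 pseudocount; scanning scores are log-odds against background base
frequencies estimated from the supplied promoter set (uniform by default),
maximized over both strands and all offsets; non-ACGT bases contribute their
column's background-expected score. Promoters are 0-based half-open windows,
1 kb upstream to 200 bp downstream of the TSS, mirrored on the minus strand
and truncated at sequence ends.

Per (motif, gene) the enrichment statistic is a z-test of the mean best hit
over the gene's ortholog-group promoters against the genome-wide pool of
best hits of the same motif (mean, SD of the pool; standard error scaled by
group size), upper-tail normal p. This preserves the "enrichment across an
orthologous promoter group" semantics of Pscan-style analysis without that
program's unpublished internals. Target calls keep p < 0.01 within a gene's
top-20 motifs (within-gene ranking); motif groups collapse by minimum p with
the argmin motif's z; network edges keep each motif group's top-5 targets at
p < 0.01 (within-motif ranking). Both ranking directions are intentional:
the within-gene rule mirrors per-gene motif discovery, the within-motif rule
mirrors network edge pruning. TF→motif edges come from a supplied mapping
table. A TF is tissue-specific when the Fisher test of its called targets in
the TF's own atlas tissue (background: all atlas genes) gives p < 0.01.

## The synthetic-study generator

The generator emulates the assumed study design — two conditions sampled at
CT0, 4, …, 44; log2 values; Gaussian noise (default SD 0.5 log2 units) — with
five gene classes allocated deterministically by largest remainder (defaults:
70% null, 20% core, 4% fast light-induced, 4% slow light-induced, 2%
dark-induced; a scaled-up signal fraction relative to a genome-scale study so
that class-level statistics are measurable at n = 1000).

* **core**: μ + A·cos(2π(t−φ)/24) in LD; amplitude ρ·A in DD (default
  ρ = 0.7; a (lo, hi) interval draws ρ per gene). Phases uniform, amplitudes
  uniform in (1, 2) log2 units — A/σ between 2 and 4.
* **fast/slow light-induced**: saturating-exponential rise from lights-on
  (τ = 1.5 h fast, 6 h slow) to a per-gene peak time, then exponential decay
  (τ = 6 h); flat at baseline in DD.
* **dark-induced**: the same pulse driven from lights-off (rise τ = 2 h,
  decay τ = 3 h); in DD a constant at 0.75 of the LD peak deviation — the
  trough-elevated configuration, near but below the LD peak.

Each light-driven pulse is rescaled so its **first-harmonic (cosinor)
amplitude equals the gene's drawn A**, making amplitude mean the same
measurable quantity in every class (a raw τ = 1.5 h pulse at 4 h sampling
carries ~3× less 24 h power than a cosine of equal peak height, which would
silently give light classes a fraction of the nominal SNR). The recorded
truth phase is the pulse's first-harmonic phase — the quantity a cosinor fit
estimates — and the per-class peak-time ranges keep those phases inside the
classifier's CT windows with margin.

A configurable subset of core genes act as TFs. TF phases are evenly spaced
around the clock at a random rotation (distinct phase-specific regulators;
i.i.d. phases let two TFs collide and contaminate each other's target-phase
background). Targets draw phases von Mises-concentrated (default κ = 3.5,
circular SD ≈ 2 h, matching tightly phased regulons) around the TF phase
plus a 6 h lag. Promoters are i.i.d. background sequence at 40% GC; each
TF's motif consensus is planted once per species promoter at a random
offset/strand with 5%/bp per-species point mutations; TFs share a tissue
label with 80% of their targets, other genes are assigned uniformly.

What the generator does **not** emulate: probe-level microarray structure,
dye/batch effects, detection calls, non-Gaussian or heteroskedastic noise,
correlated noise across genes, phase drift between conditions, promoter
repeats or composition heterogeneity, and overlapping regulons. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to those real-data phenomena.

## Problem sizes and determinism

Validation suites run at 1000 genes per study, 200 permutation replicates,
10⁴ null series for calibration and 10⁵ for the Monte-Carlo tail, and a
promoter universe of ~255 genes × 5 species × 1.2 kb for motif recovery —
sizes at which every tested bound has comfortable sampling margin while a
full run stays in tens of seconds. All randomness flows from explicit seeds
(one per study; the acceptance script derives per-section seeds from its
`--seed` via `numpy` SeedSequence); equal seeds give bit-identical matrices,
sequences, and downstream outputs. Degenerate inputs (constant series,
zero-variance backgrounds, empty phase lists, antipodal means) return
flagged markers or raise, as documented per function.

## Known limitations

* Only a 24 h period is tested; no multi-harmonic or period-estimation
  support.
* The joint-template p is per-template (grid-selection uncorrected), as is
  the analytic form it mirrors; its operating characteristics are verified
  by simulation rather than theory.
* The motif z-test treats the background best-hit pool as normal; very short
  or very biased promoter sets would violate that.
* Louvain clustering is a stand-in for the original significance-driven
  clustering; cluster boundaries are not expected to be identical.
* The amplitude-change bootstrap resamples residuals around a first-harmonic
  fit; genes with strongly non-sinusoidal waveforms get conservative CIs.
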