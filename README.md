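# circanet

Circadian transcriptome analysis for short two-condition time courses, with
promoter-motif regulatory-network inference — built around the design of a
whole-larva zebrafish study: 12 samples at 4 h intervals over 48 h under a
14 h:10 h light/dark cycle (LD) and under constant darkness (DD).

## Who this is for

Chronobiologists and computational biologists who have a genes × samples
log2 expression matrix sampled around the clock in one or more lighting
conditions and want to:

* call 24 h rhythmic genes per condition and jointly, with a permutation FDR;
* estimate each gene's circadian phase φ and amplitude A;
* classify light-entrainment responses — fast light-induced, slow
  light-induced, and dark-induced genes;
* find the circadian time windows in which a gene set's phases concentrate;
* build co-expression groups and a TF → motif → target regulatory network
  from orthologous promoter sequences.

## The statistics at the core

**Fisher's g-test.** For an equally spaced series of length *n* the
periodogram ordinates *I(ω_k)* are taken at the Fourier frequencies
*k/(nΔt)*, *k = 1…⌊(n−1)/2⌋* (Nyquist excluded). The test statistic is

    g = max_k I(ω_k) / Σ_k I(ω_k)

with the exact null tail
*P(G > g) = Σ_{k=1}^{⌊1/g⌋} (−1)^{k−1} C(m,k)(1−kg)^{m−1}*. A gene is
rhythmic at 24 h when its g-test p is small *and* the argmax ordinate is the
24 h frequency. Genes with p < 0.5 and a 24 h dominant period in **both** LD
and DD are the joint circadian calls; the FDR of that rule is estimated by
re-running it on time-label-permuted data.

**Cosinor phase.** φ̂ maximizes the Pearson correlation of the series with
cos(2π(t−φ)/24) over a fine phase grid; a closed-form harmonic regression
(φ = atan2(b_sin, b_cos)/ω) is provided as a fast equivalent. Circular
statistics (circular mean, Fisher–Lee correlation, wraparound distances)
handle everything phase-valued.

**Joint LD/DD template.** Light-driven genes oscillate in LD but sit flat in
DD. The 24-point LD+DD vector is correlated against templates that are a 24 h
cosine in LD and a constant −1 (peak decreased) or +1 (trough elevated) in
DD. Peak-decreased genes with LD phase in CT2–8 are fast light-induced, in
CT8–16 slow light-induced; trough-elevated genes with phase in CT16–CT2 are
dark-induced (CT0 = lights-on, CT14 = lights-off).

**Motif networks.** Promoters (1 kb upstream to 200 bp downstream of the
TSS) of a gene and its orthologs in four other fish species are scanned with
PWMs (log-odds, both strands); the group's mean best hit is z-tested against
the genome-wide background of best hits. Calls with p < 0.01 in a gene's
top-20 motifs become motif→target predictions; similar motifs collapse to
groups by minimum p; network edges keep each motif group's top-5 targets at
p < 0.01.

Every stage is exercised end-to-end on a synthetic-study generator
(`circanet.simulate`) that emulates the design above with known ground truth:
gene classes, phases, amplitudes, TF→target edges, planted promoter motifs,
and a tissue atlas.

## Worked example

```python
from circanet import SimulationConfig, simulate_expression, call_zcogs, permutation_fdr
from circanet.light import light_response_calls
from circanet.rhythms import rhythm_calls
from circanet.phase import phase_shift_fraction, cross_species_shift
from circanet.datasets import mouse_zebrafish_phase_table

config = SimulationConfig(n_genes=1000, seed=7)
ld, dd, truth = simulate_expression(config)

zcogs = call_zcogs(ld, dd)                      # joint LD+DD rhythm calls
fdr = permutation_fdr(ld, dd, n_perm=200, seed=7)
print(f"joint circadian calls: {int(zcogs['zcog'].sum())} of {len(zcogs)} genes (FDR = {fdr:.3f})")

count, frac = phase_shift_fraction(zcogs)
print(f"phase shifts > 4 h between LD and DD: {count} ({100 * frac:.1f}%)")

calls = light_response_calls(ld, dd, rhythm_calls(ld.condition('LD'), 'LD'))
print("light-response classes:", calls['class'].value_counts().to_dict())

shift = cross_species_shift(mouse_zebrafish_phase_table())
print(f"mouse-zebrafish circadian phase shift: {shift.mean_shift:.2f} h over {len(shift.differences)} homolog pairs")
```

prints

```
joint circadian calls: 212 of 1000 genes (FDR = 0.049)
phase shifts > 4 h between LD and DD: 10 (4.7%)
light-response classes: {'none': 213, 'slow_light': 41, 'fast_light': 34, 'dark_induced': 18}
mouse-zebrafish circadian phase shift: 8.61 h over 32 homolog pairs
```

The 212 joint calls recover the simulated 20% oscillator fraction at an
estimated FDR of ~5%; phases barely move between LD and DD (the generator
keeps them fixed, damping only DD amplitude); the light-response counts
track the planted 40/40/20 fast/slow/dark genes plus their selection losses;
and the bundled homolog phase table shows the near-anti-phase (~9 h)
relationship between mouse and zebrafish circadian genes.

The same stages run from the shell:

```bash
circanet simulate --out study --n-genes 1000 --seed 7
circanet rhythms --expression study/expression.tsv --samples study/samples.tsv \
    --out study/rhythms.tsv --n-perm 200 --seed 7
circanet run-all --config pipeline.yaml --out study/run
```

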