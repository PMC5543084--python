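# comaprime

In-silico evaluation and design toolkit for PCR primers targeting the *amoA*
gene of complete ammonia-oxidizing (comammox) *Nitrospira*.

Comammox bacteria oxidize ammonia all the way to nitrate within a single
*Nitrospira* cell, and their distinct ammonia monooxygenase subunit A gene
(*amoA*) is the marker of choice for detecting and counting them in
environmental samples. Because comammox *amoA* forms two sister clades (A and
B) and sits near two abundant off-target gene families — betaproteobacterial
*amoA* and *pmoA* — primer design for this marker is a balancing act between
clade coverage and specificity. `comaprime` packages the computational side of
that workflow for microbial ecologists:

- **IUPAC primer algebra** — degenerate-pattern expansion, ambiguity-aware
  reverse complement, and a mismatch metric in which two codes disagree only
  when their base sets are disjoint, so `pattern_mismatches(a, b)` equals the
  minimum Hamming distance over all expanded variant pairs.
- **Built-in primer catalog** — the comaA-244F/659R and comaB-244F/659R
  degenerate pairs and the corresponding equimolar mixtures of 6 forward + 6
  reverse low-degeneracy oligonucleotides, with the canonical 244/659
  coordinates implying the 415 bp amplicon.
- **In-silico PCR, coverage and specificity** — binding-site scans over
  group-labeled reference databases with gap/truncation-aware eligibility;
  coverage is the fraction of eligible target sequences with a 0-mismatch hit
  for both primers, and specificity reports per-sequence minimum-mismatch
  histograms for off-target groups (max over the two primers of the
  per-primer minima).
- **Equimolar mixture design** — phantom-free weighted maximum-coverage
  selection of ≤ *k* oligonucleotides (≤ 1 ambiguity each) from observed
  binding-site k-mers, solved exactly on small instances.
- **OTU clustering** — greedy centroid clustering of amplicons at a fixed
  identity threshold (95% default) with a free-end-gap global-alignment
  identity metric.
- **qPCR quantification** — standard-curve OLS fits (slope, intercept, r²,
  efficiency `E = (10^(−1/slope) − 1)·100`), dilution-consistency
  quantification of unknowns, and relative-abundance profiles across
  ammonia-oxidizer assays.
- **Synthetic data** — seeded generators for labeled databases with planted
  binding-site mismatch truth, amplifiable templates, and dilution-series Cq
  tables with known efficiency.

## Worked example

```python
from comaprime import (builtin_catalog, insilico_pcr, pattern_mismatches,
                       fit_standard_curve, melt_temp, ThermoParams)
from comaprime.simulate import TemplateSpec, gen_template, gen_qpcr

cat = builtin_catalog()                      # 4 sets: A/B degenerate, A/B mix
template = gen_template(TemplateSpec(seed=1))
product = insilico_pcr(template.seq, cat[0])[0]
print(f"product: start={product.start} end={product.end} length={product.length}")

print("fwd/rev cross-clade mismatches:",
      pattern_mismatches(cat[0].forward[0], cat[1].forward[0]),
      pattern_mismatches(cat[0].reverse[0], cat[1].reverse[0]))

std, _, _ = gen_qpcr(efficiency=0.885, noise_sd=0.0, seed=1)
curve = fit_standard_curve(list(zip(std.log10_copies, std.Cq)))
print(f"slope={curve.slope:.4f} r2={curve.r2:.4f} "
      f"efficiency={curve.efficiency_percent:.1f}%")

tm = melt_temp("TACAACTGGGTGAACTA", ThermoParams("salt_adjusted", 0.05))
print(f"Tm salt-adjusted: {tm.mean:.2f} C")
```

prints

```
product: start=243 end=658 length=415
fwd/rev cross-clade mismatches: 6 5
slope=-3.6323 r2=1.0000 efficiency=88.5%
Tm salt-adjusted: 47.55 C
```

The 415 bp product spans both primer footprints: the forward site starts at
0-based position 243 (reference coordinate 244) and the amplicon ends before
position 658 (coordinate 659), so the length equals 659 − 244. The clade-A
and clade-B primers differ by at least 5 mismatches in every variant
combination — the basis of clade-specific amplification. A noise-free
dilution series generated at 88.5% efficiency is refit exactly, and the
salt-adjusted melting temperature of the first clade-A forward oligo lands
near the 48 °C the primers were designed around.

A CLI mirrors the library (`comaprime catalog | expand | pcr | coverage |
specificity | windows | design-mix | tm | otu | qpcr | simulate`); every run
with `--out` echoes a `run_config.json` for reproducibility.

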