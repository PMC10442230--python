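# m6adosage

Chromosome-stratified analysis of N6-methyladenosine (m6A) and mRNA
stability, built around a question in dosage compensation: X-chromosomal
genes are present in one active copy against two autosomal copies, and one
proposed balancing mechanism is post-transcriptional — X transcripts carry
fewer m6A marks, are therefore less exposed to m6A-directed decay, and live
longer. If that is right, acutely inhibiting the m6A methyltransferase
should stabilize *autosomal* transcripts selectively and push the
X-to-autosome (X:A) expression ratio down.

The package provides the full computational chain to test this on
SLAM-seq, RNA-seq and single-nucleotide m6A site data, plus a seeded
synthetic-data generator with known ground truth so every stage is
verifiable by parameter recovery:

- `m6adosage.synth` — synthetic "mini-mouse" transcriptome: GTF/FASTA/BED
  annotation and sequences with GGACH motifs planted at configured per-kb
  densities (3.1 autosome vs 1.7 X in 3'UTRs), expression-dependent m6A
  site detection, first-order-decay conversion time courses, and
  treatment count matrices with spike-ins.
- `m6adosage.slamfit` — half-life estimation from T-to-C conversion time
  courses: background subtraction, T0 normalization, log-linear decay fit
  (t_half = ln 2 / k), the standard acceptance filters (T coverage > 100,
  0.67–18 h, residual s.e. ≤ 0.3, valid in both conditions), and
  condition/chromosome contrasts.
- `m6adosage.m6amap` — m6A sites per transcript in 12 expression bins,
  per-chromosome fold changes with bootstrap CIs and a negative-binomial
  Wald test, stop-codon-window and subsampling controls, methylated-motif
  fractions, ChIP peak density ratios.
- `m6adosage.dosage` — reference-gene (median-of-ratios) normalization
  validated against spike-ins, per-gene log2 fold changes, chromosome
  medians and median-shift/IQR effect sizes, X:A ratios with a paired
  gene bootstrap, m6A-burden response, time-course separation.
- `m6adosage.motifs` — canonical-isoform selection (TSL/level/CCDS,
  longest isoform), IUPAC motif scanning, per-region densities,
  strong/weak DRACH and ortholog/gene-set comparisons.
- `m6adosage.io` / `m6adosage.pipeline` / CLI — GTF/FASTA/BED6/TSV
  readers and writers, and a driver chaining the stages.

See `docs/methods.md` for the model, estimators, defaults, and what the
synthetic data does and does not emulate.

## Worked example

Simulate the default study conditions (2,000 genes on 19 autosomes + chrX)
and run the whole pipeline:

```bash
m6adosage all --seed 1 --outdir run1
```

or, from Python, the core half-life contrast on the same data:

```python
from m6adosage.synth import SynthConfig, simulate
from m6adosage import slamfit

ds = simulate(SynthConfig(seed=1))
norm, _ = slamfit.correct_and_normalize(ds.conversions, ds.unlabeled)
kept, ledger = slamfit.filter_fits(slamfit.fit_all(norm))
print(ledger)
print(kept.groupby("condition")["t_half"].median())
```

prints

```
{'low_coverage': 0, 't_half_low': 4, 't_half_high': 12, 'poor_fit': 528,
 'pass': 3456, 'input': 4000, 'dropped_missing_condition': 374, 'kept': 3082}
condition
control    3.746346
treated    4.438927
Name: t_half, dtype: float64
```

i.e. of 2 × 2,000 fitted series, 3,456 pass the coverage, half-life-window
and goodness-of-fit filters, 3,082 have a valid fit in both conditions,
and the median half-life rises upon m6A depletion (the generator's
destabilization-per-site acting on methylated, mostly autosomal,
transcripts). The dosage stage on the same run reports an autosomal median
log2 fold change of +0.18 against −0.005 on chrX (effect size 84% of the
average IQR) and an X:A ratio drop from 1.34 to 1.15 with a paired
bootstrap p = 0.003 — the dosage-compensation perturbation the pipeline is
designed to detect.

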