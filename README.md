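# mirnet

Stage-wise miRNA expression analysis for small-sample multistage tumour
designs: moderated-F differential screening, stage-trend pattern
classification, miRNA-target anti-correlation integration, gene-set
over-representation, and TF-miRNA regulatory-network / feedback-loop
inference. The package is organised as an analysis project: the numbered
drivers under `analysis/` narrate the pipeline over a synthetic benchmark,
while all computation lives in the importable library under `src/mirnet/`.

It is aimed at computational biologists working with ordered clinical designs
(e.g. normal epithelium → tumour stages I-II, III, IV → lymph-node
metastasis) profiled with very few samples per arm, where gene-by-gene
variance estimates are too unstable for a classical ANOVA screen.

## The statistics at the core

**Random-variance-model moderated F.** For feature *g* in a one-way layout
with *k* groups and *n* samples, the residual variance s²_g is modelled as
exchangeable across features with a Gamma(a, b) prior on the inverse variance
1/σ²_g. Under the model, s²·a·b ~ F(n−k, 2a), which is the likelihood used to
fit (a, b) across all features. Testing replaces s² with the shrunken

    σ̃² = ((n−k)·s² + 2/b) / ((n−k) + 2a)

and refers F̃ = MS_between / σ̃² to F(k−1, n−k+2a): the prior is worth 2a
extra denominator degrees of freedom, which is what makes the screen usable at
4-6 samples per group. As a → 0 and 2/b → 0, F̃ reduces to the classical
one-way F. Multiplicity is controlled with Benjamini-Hochberg q-values.

**Downstream integration.** Significant features are classified into six
stage-trend patterns (gradual decrease/increase, early drop, transient shapes,
metastasis spike); predicted miRNA-target pairs are narrowed to
tissue-specific genes and to pairs whose mRNA differential direction is
inverse to the miRNA's, optionally requiring expression anti-correlation
(Pearson r ≤ r_max); retained genes are tested for term over-representation
with an upper-tail hypergeometric (or EASE) test; bipartite miRNA-gene and
TF-miRNA networks are built with degree-based hub calling (degree ≥ 10), and
TF-miRNA-target feedback loops — a TF binding a miRNA's promoter while that
miRNA targets the TF's own transcript — are mined from the two edge sets.

Published reference tables (the per-stage aberrant-miRNA lists, the
coordinate miRNA/target table, the per-stage promoter-binding TFs, and the
self-repression feedback loops) ship as packaged fixtures and are used in
golden tests; a synthetic-data generator reproduces the study design for
recovery testing.

## Worked example

```bash
python analysis/01_simulate_benchmark.py
python analysis/02_differential_screen.py
```

prints

```
benchmark (seed 20120119) written to results/benchmark/
  766 miRNAs x 22 samples, 48 planted DE
  regulome: 63 predicted pairs, 3 planted loops
fitted variance prior: a = 1.964, b = 1.521 (denominator df 20.9 vs classical 17)
50 features pass p<0.05 & q<0.05: 48/48 planted recovered (100.0%), 2 false positives
  stage I-II: 21 down, 10 up
  ...
```

The fitted prior (â ≈ 1.96, b̂ ≈ 1.52) recovers the generating values
(a = 2, b = 1.5); its 2â ≈ 3.9 extra denominator degrees of freedom raise the
screen's df2 from 17 to ≈ 21, and all 48 planted differential miRNAs pass the
p < 0.05, q < 0.05 gate with 2 false positives among 718 nulls. Continuing with
`analysis/03...07` clusters the 22 samples into five largely stage-pure
subgroups, classifies the stage-trend patterns, reproduces the published
coordinate-target table through the inverse-direction rule, recovers 23/23
planted anti-correlated pairs at r ≤ −0.3 and 3/3 planted feedback loops, and
recovers planted qPCR fold changes from noisy triplicate Ct tables.

The same steps are available as a CLI for file-based use:
`mirnet simulate|diff|patterns|integrate|enrich|network|qpcr --help`.

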