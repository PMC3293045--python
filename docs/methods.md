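# Methods

## Study design and data model

The pipeline targets ordered multistage designs profiled with very few
samples per arm. The reference configuration, used by the synthetic benchmark
and all defaults, is 22 samples: 6 normal, 4 per tumour stage I-II / III / IV,
and 4 lymph-node metastases, with ~766 detected miRNAs on a log2 intensity
scale. Expression values are assumed log2 and already normalised; the package
performs no further normalisation. Missing values are carried explicitly
(never imputed as zero); a feature with any missing value among tested
samples is dropped from that test with a logged count.

## Moderated F screen (random variance model)

Gene-by-gene variance estimates at n = 4-6 per group have so few degrees of
freedom that a classical one-way ANOVA screen is badly powered, while
assuming one shared variance for all genes is clearly false. The random
variance model is the standard middle ground: the inverse residual variance
1/σ²_g is Gamma(a, b) distributed across features (equivalently σ²_g is
inverse-gamma). Under this prior the scaled residual variance s²·a·b follows
an F(m, 2a) distribution with m = n − k, and (a, b) are fitted by maximising
that likelihood over all features.

Numerical choices:

- the likelihood is optimised in log-parameter space with Nelder-Mead from
  the fixed start (a, b) = (1, 1/mean(s²)); no randomness, so fits are
  bit-reproducible;
- shape estimates beyond 1e5 (or below 1e-5) are flagged as boundary fits and
  reported as non-converged — this is what degenerate inputs such as
  identical variances produce; optimiser failure raises, carrying the last
  iterate and the gradient norm;
- zero variances are excluded from the fit (counted), and fewer than 50
  usable features triggers a warning;
- testing uses σ̃² = ((n−k)s² + 2/b)/((n−k) + 2a), F̃ = MS_between/σ̃², with
  p from F(k−1, n−k+2a). σ̃² is a strictly convex combination of s² and the
  prior scale 1/(ab), hence always positive; a feature with zero between- and
  within-group variance gets p = 1 and a flag.

FDR control is Benjamini-Hochberg (the community default where the procedure
is unnamed), delegated to `statsmodels` and cross-checked in the tests
against an independent step-up implementation.

Per-stage direction calls complete the screen: a feature enters a stage's
up/down list when the global gate (p < 0.05 and q < 0.05) passes AND a
per-stage contrast rule fires. The default rule is a Welch two-sample t-test
of the stage against the reference at p < 0.05 (a fold-change rule,
|log2 FC| ≥ 1 by default, is available); direction is the sign of the
stage-minus-reference mean difference. The per-stage rule is a design choice:
the global multi-group gate alone cannot produce stage-resolved lists.

## Stage-trend patterns

Stage-mean trajectories over the five ordered stages are reduced to a sign
vector of successive differences under a flatness tolerance ε (default 0.25
log2 units, i.e. steps below ~19% change count as flat). Six patterns are
defined; three follow published verbal semantics and three complete the
taxonomy symmetrically:

1. monotone decrease (all steps ≤ 0, at least one negative);
2. early decrease then flat (first step negative, the rest flat) — split out
   of class 1;
3. decrease then recovery (first non-flat step down, a later step up);
4. increase then decline (mirror of 3);
5. monotone increase (mirror of 1);
6. flat through the primary stages with a metastasis jump of at least δ
   (default 1.0 log2 units); 6 takes precedence over 5.

Patterns 2-4 are an interpretation (the source taxonomy is defined only
graphically); a reduced mode classifying only 1/5/6 is available. Pattern
assignment is invariant to adding a constant to all stage means, and classes
1 and 5 are mutually exclusive for any non-flat trajectory.

Hierarchical clustering uses centred-Pearson distance (d = 1 − r) and average
linkage by default (complete linkage available). The agglomeration is written
in-package because the contract requires a specific deterministic tie-break —
equal minimum distances merge the lexicographically smaller cluster-index
pair — making results invariant to input order up to relabelling;
`scipy.cluster.hierarchy` is used as an independent oracle on tie-free
instances in the tests. At these problem sizes (22 samples, ≤ ~766 features)
the O(n³) cost is irrelevant.

## Target integration

Predicted miRNA-target pairs (a TargetScan-style export, taken as a file) are
narrowed by two restrictions whose order does not matter: intersection with a
tissue-specific gene list, and the inverse-direction overlay (miRNA up ⇒
target down, and vice versa; pairs touching an uncalled feature are dropped).
"Inverse" is read strictly — it matches every row of the published coordinate
table. Gene directions are per comparison, so the overlay is applied per
miRNA group; one gene may legitimately carry opposite directions under
different miRNA groups. An optional third filter keeps pairs whose expression
Pearson r across shared samples is ≤ r_max (default 0, i.e. any negative
correlation; at least 3 shared samples required).

## Over-representation

Upper-tail hypergeometric test per term: with background M, term size K
(after intersection with the background), list size N and x hits,
p = P(X ≥ x). The EASE variant (x − 1, the DAVID tool's conservative score)
is available, as are BH and Bonferroni corrections; terms with fewer than 2
hits are not reported by default. The default background is all genes in the
annotation. Published enrichment p-values are not reproduction targets: they
depend on an external, version-bound annotation database.

## Regulatory networks

The miRNA-gene network has one `mirna_targets_gene` edge per retained pair;
hubs are nodes with degree ≥ 10. The threshold is inclusive because the
published table of "core" TFs captions itself with degree ≥ 10 even though
the surrounding text says "greater than 10"; a strict-greater flag is
provided.

TF-miRNA edges come from scanning upstream windows of pre-miRNA loci for
IUPAC consensus motifs: every window within the mismatch budget is reported
on the + strand and (reverse-complement) − strand, positions 0-based on the
plus strand, output deterministically ordered. The motif model is consensus
plus mismatch budget; PWM scoring is out of scope. When paired expression is
supplied, each TF→miRNA edge is weighted by the Pearson correlation of the
two series ("regulatory ability"); no significance test is attached. A
feedback loop is any (TF, miRNA) with a binding edge TF→miRNA and a targeting
pair (miRNA, TF): predicted self-repression.

## qPCR quantification

Relative quantification follows the Livak convention: ΔCt = Ct(target) −
Ct(reference) within a group, ΔΔCt = ΔCt(sample) − ΔCt(calibrator), fold =
2^(−ΔΔCt) — the negated exponent is the only reading consistent with the
reported up/down directions; a literal 2^(+ΔΔCt) flag exists. Replicates are
averaged on the ΔΔCt scale (geometric mean of folds) with the SD of replicate
log2 folds as spread; a single replicate yields an undefined SD and a
warning. Standard-curve efficiency is E = 10^(−1/slope) − 1, so slope
−1/log10(2) ≈ −3.32 is 100% (one doubling per cycle).

## Synthetic benchmark

The generator emulates the reference design exactly: 6/4/4/4/4 arms, 766
features, 48 planted differential features spread equally over the six
patterns, per-feature variances drawn from the Gamma(a = 2, b = 1.5) inverse
variance prior (typical σ ≈ 0.7 log2 units, heavy-tailed), baselines
N(8, 1.5²) log2 intensity, Gaussian noise on the log2 scale. Planted
trajectories span 4 log2 units (16-fold across the full progression), the
scale of strongly aberrant tumour miRNAs; an a-priori power analysis at these
settings put per-feature detection near 98% with no seed below 90% planted
recovery in 100 trials, so planted features are recoverable by design rather
than by tuning. The regulome generator plants exact feedback loops (motif
inserted into the partner miRNA's 1000-bp upstream window AND the TF's
transcript added to that miRNA's target set), draws anti-correlated
miRNA-target expression with generative r ≈ −0.9, and uses i.i.d. uniform
ACGT background sequence with 10-base motifs; background predicted pairs
never point at TF transcripts, so chance motif hits cannot close a spurious
loop and the planted loop count is recovered exactly. Ct tables are generated
by inverting the 2^-ΔΔCt rule with Gaussian cycle noise on triplicates.

What the generator does **not** emulate: probe-level chemistry, batch and
array-position effects, correlated features, heavy-tailed intensity noise
(a flag exists for the expression generator's noise only in the Gaussian
sense), stage-dependent variance, or realistic promoter composition.
Passing recovery tests therefore show that the machinery is correct under
its own model assumptions at the study's scale — not that the original
biological lists would be reproduced from raw arrays.

## Problem sizes

Defaults are chosen so that the full suite and the acceptance run complete in
well under a minute: 766 × 22 expression matrices, 5000-feature null and
prior-recovery simulations, 30-miRNA / 60-gene / 8-TF regulomes with 1000-bp
promoters, and 100-sequence motif-scan oracles.

## Known limitations

- The exact published 48-miRNA list is not reproducible without the raw
  array intensities; golden tests work from the printed tables instead.
- Identifier matching between tables is exact-string (including the star/arm
  suffixes and one anomalous printed token kept verbatim); no miRBase
  version remapping is attempted.
- The per-stage call rule and patterns 2-4 are documented interpretations,
  configurable but not asserted as the source taxonomy.
- Promoter windows are caller-supplied; no genome coordinates are resolved.
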