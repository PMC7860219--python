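# Methods

`npomics` implements an integrated analysis of paired proteome and
transcriptome profiles of nucleus pulposus (NP) cells from normal (IVD) and
degenerated (IDD) intervertebral discs: per-layer differential expression,
protein–mRNA concordance, condition-specific co-expression networks ranked
by k-core and degree, gene-set over-representation, and 2^−ΔΔCt
quantification for qPCR validation panels. This note records the models,
the defaults and why, and what the bundled synthetic data does and does not
establish.

## Differential expression

Signals are analysed on the log2 scale. For each feature, the IDD and IVD
group means give `log2FC = mean(IDD) − mean(IVD)`; the signed linear fold
change is `2^log2FC` for up-regulation and `−2^(−log2FC)` for
down-regulation, so its range is (−∞, −1] ∪ [1, ∞) (the "±1.5-fold"
convention). Significance comes from a two-sided Student's t-test with
pooled variance (Welch's correction available via `equal_var=False`); BH
q-values are computed across all features of a layer. A feature is called
differential when its raw p-value is below `p_threshold` (default 0.05) and
|signed fold change| reaches `fc_threshold` — 1.5 for the mRNA layer and
2.0 for the protein layer by default, both configurable, with an optional
q-value gate instead of raw p. Features with zero variance in both groups
and equal means are reported as t = 0, p = 1; zero variance with unequal
means degenerates to p = 0.

With three samples per group the pooled t-test has 4 degrees of freedom.
Under Gaussian log2 noise it is exactly calibrated, which the null
simulation confirms (empirical p < 0.05 rate within the binomial 95% band
over 5,000 features), and at the default synthetic effect size (|log2FC| =
2, noise SD 0.5) it detects ≈ 95% of planted features while flagging < 4%
of nulls.

## Integration and concordance

Layers are joined by exact gene symbol; an optional protein-accession →
symbol map collapses many-to-one by keeping the protein feature with the
smallest p-value, and collapses whose significant directions contradict are
flagged ambiguous and excluded from all counts (reported separately). A
gene significant in both layers is `concordant_up`/`concordant_down` when
the two fold changes share a sign and `discordant` when they oppose; a zero
fold change has no direction and is reported under `zero_direction` rather
than inflating either class. Venn counts (protein-only, mRNA-only, both)
partition the genes significant in at least one layer.

## Co-expression networks

For each condition separately, Pearson correlation is computed between all
pairs of the integrated significant-feature profiles over that condition's
samples. Each r receives a p-value from the t transform
`t = r·√((n−2)/(1−r²))` with n−2 df (two-sided) and a BH q-value across all
pairs; edges require `q < q_threshold` and `|r| ≥ r_threshold`. Isolated
nodes are kept. Genes significant in both layers enter as a single node
tagged `both`, with a profile averaged from the two per-layer z-scored
profiles (correlation itself is affine-invariant per feature, so the
z-scoring matters only for this averaging). Node importance is the k-core
index — the largest k such that the node survives iterated pruning of
nodes with degree < k — with degree and then lexicographic id as
tie-breakers. The IDD-vs-IVD contrast reports density, component counts,
largest-component fraction, mean degree and maximum k-core per condition
and their differences.

**Sample-size caveat on edge gates.** The package defaults are
`q < 0.05` and `|r| ≥ 0.95`. At n = 3 samples per condition the correlation
p-value has a single degree of freedom, so even |r| = 0.99 gives p ≈ 0.09
and no pair can survive a BH gate at 0.05: at the study's own sample size
the q-gate must be relaxed (`network_q_threshold: 1.0`) and the |r| gate
does the filtering, at the cost of a substantial chance level
(P(|r| > 0.95) ≈ 0.2 for null pairs at n = 3). Network analyses at n = 3
are therefore exploratory; the recovery and contrast tests use 10 samples
per condition, where both gates are informative (null pairs pass at
≈ 3·10⁻⁴ with `|r| ≥ 0.8, q < 0.05`).

## Enrichment

Over-representation of a query list in GMT terms uses the hypergeometric
upper tail P(X ≥ k) for overlap k between a query of size n and a term of
size K in a universe of size N, with BH correction across the terms of one
annotation source and fold enrichment (k/n)/(K/N). The universe is the set
of measured features, not the genome. One-sided over-representation only;
no ontology-graph propagation.

## 2^−ΔΔCt quantification

Replicates are averaged on the Ct scale; per sample
`ΔCt = Ct(target) − Ct(reference)`; `ΔΔCt = mean ΔCt(treated) − mean
ΔCt(control)`; relative expression `fold = 2^−ΔΔCt`. Per-sample folds
`2^−(ΔCt − mean control ΔCt)` feed a two-sided Student's t-test between
groups. The sample-mean ΔΔCt convention (rather than per-replicate ΔΔCt) is
used throughout. No amplification-efficiency correction is applied.
Reference-gene normalization makes all results invariant to whole-sample Ct
shifts, and swapping the group labels inverts the fold exactly.

## Synthetic paired-omics generator

The generator emulates the processed-signal level of a small two-condition
study: per-feature baselines uniform on log2 [4, 12] (a microarray-like
range), Gaussian noise on the log2 scale (SD `noise_sd`, default 0.5), and
3 samples per condition by default. Planted structure, all recorded in a
`GroundTruth` object:

- a fraction `frac_de` (default 0.1) of features per layer with an exact
  group-mean difference of ±`log2_effect` (default 2) before noise;
- among shared-gene DE features, a fraction `frac_concordant` (default 2/3)
  with same-direction effects in both layers, the rest with opposite
  directions (alternating which layer is up);
- `n_modules` disjoint blocks of `module_size` mRNA features sharing a
  per-sample latent factor, `x = √ρ·f + √(1−ρ)·ε` scaled by `noise_sd`, so
  pairwise expected correlation is `module_rho` — only in the
  `module_condition` samples (default IDD), which is what produces the
  condensed-degenerated versus scattered-normal network contrast;
- one annotation term drawing 80% of its members from the planted mRNA DE
  set, the remaining terms uniform from the universe.

All randomness derives from the single config seed through fixed
`default_rng([seed, k])` sub-streams (baselines, assignments, per-layer
noise, module factors, annotation), so identical configs are bit-identical.
qPCR plates shift the treated-condition target Ct by −`planted_log2fc`
against a constant-Ct reference gene, with Gaussian replicate noise.

What the generator does **not** emulate: probe-level microarray artifacts,
mass-spectrometry missingness and intensity-dependent variance, batch
effects, unpaired designs, or heavy-tailed noise. Passing tests establish
that the pipeline's statistics behave correctly under the stated Gaussian
log2 model at the stated sizes — not that the biological conclusions of
any particular real dataset are correct.

## Numerical and procedural choices

- Hierarchical clustering: average linkage on d = 1 − Pearson r (the
  Cluster/TreeView idiom), after median centering; zero-variance profiles
  fall back to distance 1 with a warning; dendrograms export as Newick.
- Quantile normalization: reference distribution is the mean of sorted
  per-sample vectors; ties receive the mean of the reference values over
  their tied ranks; idempotent; a single-sample matrix is returned
  unchanged with a warning.
- BH adjustment validates p ∈ [0, 1] and maps q back to input order.
- Volcano tables cap −log10 p at 320 when p underflows to 0.
- Duplicated feature ids at load keep the row with the higher mean signal
  (warned); unmapped samples and non-numeric cells are hard errors naming
  the offending feature/sample/line.
- Hub ranking ties break by (k-core desc, degree desc, id asc) for
  determinism.

## Problem sizes used in validation

The test-suite and acceptance-script simulations use: 5,000 features for
null calibration; 2,000 features × 50 seeds for effect recovery; the
study-scale default (656 protein / 2,000 mRNA features, 400 shared, 3
samples per group) for integration recovery; 60 features × 10 samples per
condition × 100 seeds for the network contrast; and exhaustive enumeration
up to N = 12 (hypergeometric), 720 permutations (Pearson p), and 100 random
graphs ≤ 50 nodes (k-core) for the oracle equivalences.

## Known limitations

- The cross-layer network stage requires identical sample ids in both
  matrices (a paired design); unpaired designs can still be analysed per
  layer.
- The correlation p-value is the parametric t-transform; at n = 6 it tracks
  the exact permutation null to a few permutation quanta on well-behaved
  data but can deviate substantially on high-leverage profiles.
- No moderated-variance (empirical-Bayes) testing, paired designs,
  covariate adjustment, ortholog mapping, or GSEA-style permutation
  statistics.
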