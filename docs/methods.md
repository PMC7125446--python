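# Methods

This note documents the models, numerical conventions, and design
choices behind `mdgnet`, and what the synthetic-data experiments do and
do not establish about real data.

## The screening cascade

For each gene, the control-cohort values X and experimental-cohort
values Y run through a decision tree:

1. **Two-sample KS.** If the empirical distributions differ
   (FDR q ≤ 0.0005), the gene exits immediately as differential with
   route `KS2-different`. The p-value is scipy's two-sample KS
   (exact for small samples, asymptotic otherwise).
2. **Normality.** Otherwise each cohort is standardized by its sample
   mean and SD and tested against N(0, 1) with the one-sample KS
   (FDR q cutoff 0.001). With estimated parameters the classical KS
   p-value is conservative — it passes non-normal samples too easily
   (the Lilliefors issue); a Lilliefors-corrected mode is available
   (`lilliefors=True`), but the plain KS is the default because it is
   the test the procedure names. By default a gene counts as normal
   only when *both* cohorts pass (`normality_rule="both"`); a Fisher
   combined test over the two cohorts is available as an alternative.
3. **Variance homogeneity.** Both-normal genes take the two-sided
   variance-ratio F test, p = 2·min(lower tail, upper tail) capped at
   1, which is symmetric in the cohorts. Homogeneous genes (q > 0.001)
   use the pooled t test, the rest Welch's t with Satterthwaite
   degrees of freedom.
4. **Location.** Not-both-normal genes use Mann–Whitney: exact
   enumeration when both samples have ≤ 8 untied values, otherwise the
   normal approximation with continuity and tie corrections. The final
   location p-values form one BH family across every gene that reached
   a location test; flagged means q ≤ 0.001.

Multiple-testing scope: BH is applied **per stage, over the genes that
reach the stage**, with the two cohorts' normality tests adjusted as
separate families (`fdr_scope="staged"`, the default). The alternative
`"global"` scope corrects every stage as if all genes had been tested
there (family size = total gene count), which can only be more
conservative at the later stages. One cutoff per stage is kept in both
scopes.

Degenerate genes (zero variance in a cohort) skip the parametric
stages, whose preconditions fail, and fall through to Mann–Whitney;
fully tied data returns p = 1 by convention. A constant sample is
treated as decisively non-normal (p = 0).

## Correlation networks and degree analysis

The Spearman coefficient is computed as the product-moment correlation
of average-ranked values; a constant gene has undefined ranks and gets
sentinel correlation 0 (with a warning), so flat profiles never create
edges. Edges use the inclusive rule |SCC| ≥ α, and correlations are
rounded to 12 decimals before the comparison so that ties at the
threshold resolve identically across platforms. Self-loops are
excluded; the average degree of a network with n nodes and m edges is
2m/n.

Degrees are swept over α ∈ {0.1, …, 0.9} (one correlation matrix per
cohort, re-thresholded). **Separability** demands strict dominance of
one cohort's average-degree curve at *every* grid point — any tie or
crossing breaks it — and is allowed in either direction, because under
a symmetric null either cohort may dominate. The MD-G score is the
uniform mean over the grid of the per-gene absolute degree difference;
absolute rather than relative differences are used because relative
change divides by the reference cohort's degree and explodes for
sparsely connected genes. Ties in the ranking break by ascending gene
id so output is deterministic.

### The Monte Carlo null experiment

`null_separability_probability` estimates the chance that two cohorts
drawn from the *same* distribution nonetheless separate. Two models
are exposed:

* `iid-normal` (default): both cohorts i.i.d. standard normal at the
  given dimensions;
* `label-permutation`: the pooled real samples are randomly split into
  pseudo-cohorts of the original sizes, preserving the gene-gene
  correlation structure while destroying cohort labels.

The estimate is the fraction of B replicate pairs separable in either
direction, with binomial standard error √(p̂(1−p̂)/B); the confidence in
an observed separation is 1 − estimate. B = 200 replicates gives a
standard error below 0.036 at any p̂ and runs in seconds at the default
dimensions.

**Model dependence.** At cohort sizes of ~60–80 samples, the null
distribution of a single Spearman coefficient has standard deviation
≈ 1/√(n−1) ≈ 0.11–0.13, so under the i.i.d. model the probability of
any |SCC| ≥ 0.8 edge among a few hundred genes is negligible
(~10⁻¹² per pair). Both cohorts' networks are then empty at the high
thresholds, the average-degree curves tie at zero, and strict
separability at the full grid is essentially impossible: the
i.i.d.-normal estimate at the default dimensions is ~0%. A null model
that preserves realistic inter-gene correlation (the
label-permutation model on real data) keeps high-threshold edges alive
and can produce materially larger separability probabilities; which
model is appropriate depends on what "random network" is meant to
capture, and both are reported with their model name.

## Enrichment

Term significance is the upper-tail hypergeometric probability
P(X ≥ k) with universe N, term size K, query size n, overlap k. The
universe defaults to the union of all GMT genes — "the whole genome"
is not reproducible without pinning an annotation release, so the
annotation file itself defines the background (overridable). q-values
are BH over **all** tested terms, the standard FDR family, not only
the retained ones. Retention requires p < 0.01, k ≥ 3 and enrichment
factor k/(K·n/N) strictly > 1.5.

Term similarity is Cohen's kappa of the two membership indicator
vectors restricted to the **query** genes (the DAVID/Metascape
convention); when expected agreement is 1 kappa is defined as 1 if
observed agreement is 1, else 0. Retained terms are clustered by
average-linkage hierarchical clustering on distance 1 − kappa, cutting
the dendrogram so that clusters are maximal subtrees whose merges all
have similarity strictly above 0.3 (singletons allowed); the linkage
method is configurable since no canonical choice exists. Terms are
canonically ordered by (p, term id) before clustering, which makes the
output invariant to input order; each cluster's representative is its
smallest-p member with ties to the lexicographically smaller id.

## Function-level expression

The expression level of a function F in a cohort is the sum over F's
member genes of the gene's mean expression across the cohort's
samples; the reported difference is the absolute difference of the two
totals. The per-gene difference statistics (max/min/mean/variance of
|mean_C − mean_E|) default to the **population** variance (ddof = 0,
configurable) and, in the pipeline, to the MD-G list as the gene set
(a flag switches to all flagged genes) — the natural scope when the
question is whether the structurally different genes also differ in
level.

## Synthetic data: what it emulates and what it does not

The generators emulate the shape of a two-cohort peripheral-blood
microarray design — 64 control vs 82 experimental samples over
hundreds to thousands of genes — with marginally standard-normal
expression. Branch parameters were chosen once, from power
considerations at these cohort sizes and FDR cutoffs:

* **shape** branch: E is a "contaminated" two-normal mixture — a
  narrow spike (weight 0.97, sd 0.02) slightly left of zero plus a
  broad balancing component at +5 — with mean 0 and variance 1 exactly
  matched to C. A symmetric bimodal mixture with matched moments
  caps at KS distance ≈ 0.34, too small for the strict 0.0005 cutoff
  at n ≈ 60–80; the asymmetric mixture reaches ≈ 0.5 and exits at
  stage 1 with power near 1 while staying invisible to location and
  scale tests.
* **mean-shift** branch: E = N(δ, 1), default δ = 3.
* **variance-shift** branch: E = N(δ, 4) — a variance ratio of 4,
  decisively detected by the F test at these sample sizes.
* **nonnormal-shift** branch: both cohorts are a sharply bimodal
  mixture at ±1 (component sd 0.05, standardized), E shifted by δ.
  The same shape in both cohorts keeps the stage-1 two-sample KS
  silent at δ = 0, while the bimodality fails the normality KS with
  power ≈ 1. A heavy-tailed Student-like family was considered and
  rejected: its KS distance to a fitted normal (~0.06 at small df) is
  far below what an 0.001-FDR normality test can detect at n ≈ 60–80,
  so it cannot route genes to Mann–Whitney at all.
* **connectivity** modules: x_g = λ_g·f + √(1−λ_g²)·ε with a shared
  per-sample factor; planted genes load ρ_C in C and ρ_E in E. Since
  marginals stay N(0, 1), connectivity is the only planted signal.

Note an interaction that is a property of the cascade, not of the
generator: at δ = 3 a location shift *is* a large distribution
difference, so the stage-1 KS detects mean-shift branches before
their designed location tests are reached. Route fidelity (t / Welch /
Mann–Whitney) is therefore assessed at δ = 0, where only shape and
scale signals remain; at large δ the cascade's correct behaviour is to
flag those genes through whichever stage fires first.

The generators deliberately omit microarray noise features: no probe
effects, no MAS5/RMA preprocessing artefacts, no batch effects, no
heteroscedastic intensity-dependent noise, and no heavy inter-gene
correlation beyond the planted modules. Passing the recovery and
calibration experiments therefore shows the *methods* behave as
specified under their own assumptions; it does not show robustness to
the systematic artefacts of real microarray data.

## Problem sizes and numerical conventions

The packaged experiments use: B = 200 null replicates at 244 genes
(64/82 samples); 20-seed screening calibration at 2,000 all-null
genes; 20-seed MD-G recovery with a 30-gene module (ρ_C = 0.9,
ρ_E = 0.1, 5 planted) over 200 background genes at 60 samples per
cohort. These sizes keep each experiment's Monte Carlo error small
relative to the thresholds being checked while completing in minutes
on one CPU. All replicate seeds derive from a single user seed through
`numpy.random.default_rng`; identical configurations give
byte-identical outputs.

## Known limitations

* The screening cascade's staged FDR families are conditionally
  defined (membership in a stage depends on earlier outcomes), so the
  realized false-flag rate is only approximately the nominal per-stage
  level; the null calibration experiment bounds it empirically.
* The plain one-sample KS after standardization is conservative;
  genuinely mild non-normality (e.g. moderate heavy tails) will pass
  as normal at these sample sizes.
* The i.i.d.-normal null for separability ignores inter-gene
  correlation and, as documented above, yields ~0% separability at
  realistic sample sizes; conclusions about chance separability on
  real data should use the label-permutation model.
* Enrichment results depend entirely on the user's GMT annotation;
  no ontology is bundled and term p-values are not comparable across
  annotation releases.
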