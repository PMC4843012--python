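# Methods

## The problem being modelled

Routine staging of resected gastric tumours (and solid tumours
generally) labels a patient N0M0 — "non-metastatic" — when imaging and
single-section lymph-node pathology find no tumour deposits. Both tests
have substantial false-negative rates for micrometastases. Any analysis
that contrasts "metastatic" against "non-metastatic" tissue therefore
compares a fairly pure case group against a control group contaminated
with occult cases, which attenuates every differential signal and makes
DEG lists unstable across cohorts. Post-surgery recurrence is an
independent, delayed readout of the same latent state: a patient whose
resection was truly curative rarely relapses, while an occult
metastasis usually declares itself in follow-up. The pipeline encodes
this reasoning as a reclassification rule and quantifies its benefit by
cross-cohort concordance of signed DEG lists.

## Grouping rules

TNM-only: N0 and M0 → non-metastasis; N+ or M+ → metastasis; any
unknown stage → excluded.

TNM + recurrence, in order of precedence: M+ → metastasis; unknown
recurrence → excluded; M0 with recurrence → metastasis; N+M0 without
recurrence → excluded (possible staging false positive); N0M0 without
recurrence → non-metastasis, unless adjuvant-treatment annotations are
in use (`adjuvant_available=True`) and the patient was treated
(excluded — non-recurrence under therapy is uninformative; unknown
treatment status is likewise excluded). Samples whose stage is too
incomplete to place under these rules are excluded as `unknown_stage`.
Excluding (rather than keeping) unknown-recurrence and
unknown-adjuvant samples is deliberate: neither group membership can be
asserted for them, and follow-up completeness varies by cohort. No
minimum follow-up duration is imposed; `follow_up_months` is carried
through for user-side filtering only.

## Differential testing

* **Log-intensity expression and beta-value methylation**: two-sided
  Wilcoxon rank-sum per feature. With 12 or fewer tie-free observations
  in the two groups combined the exact null distribution is used;
  otherwise the normal approximation with continuity and tie
  correction. Features constant across all grouped samples get p = 1.
  Direction is the sign of the metastasis-minus-non-metastasis median
  difference, falling back to the mean difference when medians tie;
  `tied` means both contrasts are exactly zero.
* **RNA-seq counts**: a simplified negative-binomial conditional exact
  test, deliberately self-contained so it can be validated against an
  enumeration oracle. Columns are normalized by median-of-ratios size
  factors (library-size fallback when no gene is all-positive); a
  single common dispersion φ is estimated by pooled within-group method
  of moments (var = μ + φμ², floored at 0); each gene's normalized
  counts are summed per group at equalized library size and rounded,
  and the group-A total is tested against its conditional null given
  the grand total — the NB-convolution conditional, which is exactly
  Binomial(t, n_A/(n_A+n_B)) when φ = 0. The two-sided p sums the
  probabilities of all outcomes as or less likely than the observed one
  (with a 1+10⁻⁷ relative guard against float ties). The test is
  classic-style by construction: no tagwise or trended dispersion, no
  TMM, no covariates.
* **Binary alterations** (CNV peaks, mutation calls): two-sided
  Fisher's exact test per feature.
* **Multiplicity**: Benjamini–Hochberg step-up across the whole tested
  family (all genes, or all CpG loci as one family — not per-gene);
  a feature is significant when q is strictly below the FDR threshold.
  Defaults 0.10 and 0.20 are exposed as parameters.
* **DM genes**: a significant CpG locus is hypermethylated when its
  mean beta in the metastasis group exceeds the non-metastasis mean;
  a gene with at least one significant promoter locus is a DM gene, and
  genes with loci in both directions are excluded as bidirectional.

## Concordance score

For two signed lists sharing k genes with s direction agreements the
score is 100·s/k % and the significance is the one-sided upper tail
P(X ≥ s) of Binomial(k, Pe), Pe = 0.5 by default (a symmetric up/down
null). The one-sided reading was chosen because it reproduces the
published worked values exactly (e.g. 232/2²¹ = 1.11×10⁻⁴ for s = 19 of
k = 21). Ties (`direction = tied`) are dropped from a list before
intersecting, so they can neither count as concordant nor discordant.
k = 0 yields NA, not 0% or 100%: an undefined ratio must not masquerade
as signal. Tails are also computed in log10 by log-space summation;
for k in the thousands the upper tail can fall hundreds of orders of
magnitude below the smallest positive double, in which case the linear
value reported is 0.0 and the log10 value carries the information.
Scores are displayed rounded to one decimal; machine output keeps full
precision.

## Enrichment

Hypergeometric upper tail P(X ≥ x) for x hits of a k-gene interesting
list in an m-gene set, drawn from the n genes actually analysed in the
dataset (the background is the post-collapsing matrix, not the genome).
Up- and down-regulated lists are analysed separately — mixed lists
dilute direction-specific pathway signal — each with its own BH
correction. Set members are intersected with the background before
counting; pathway topology is not used. Gene sets are consumed as GMT.

## Synthetic cohorts

Per sample, a latent `true_met ~ Bernoulli(prevalence)` drives
everything observable:

* expression: per-gene baseline ~ N(7.5, 1.5²) on the log2 scale, plus
  `effect_size_log2 · sign_g` for the DE genes in truly metastatic
  samples, plus N(0, noise²) noise; DE signs are drawn 50/50 up/down so
  the concordance null is symmetric;
* staging: a truly metastatic sample is staged N0M0 with probability
  `fn_staging_rate` (the micrometastasis), otherwise N+ with an M+ call
  at `m_plus_rate` (0.2); a truly non-metastatic sample is falsely
  staged N+ with probability `fp_staging_rate`;
* recurrence: Bernoulli(`p_recur_given_met`) for true metastases,
  multiplied by `adjuvant_recur_reduction` when the patient drew
  adjuvant treatment (rate `adjuvant_rate`); Bernoulli
  (`p_recur_given_nonmet`) otherwise — recurrence is conditionally
  independent of expression given true status, which is precisely the
  hypothesis that recurrence proxies undetected metastasis;
* counts (optional): gene fractions 2^(log2 expression) scaled to
  Poisson-drawn library sizes, sampled NB with `nb_dispersion`;
* methylation (optional): each DE gene receives, with probability
  `meth_coupling_prob`, one promoter locus whose mean beta shifts by
  `meth_effect_beta` in truly metastatic samples *opposite* to the
  expression sign (hyper↔down), with N(0, 0.05) noise, clipped to
  [0.01, 0.99]; `meth_codirectional_prob` diverts a minority of coupled
  loci to co-directional shifts to mimic the weaker hypo/up coupling of
  real promoters; `n_null_loci` unshifted loci complete the panel.

Multi-cohort generation shares `round(shared_de_fraction · n_de_genes)`
DE genes (same signs) across cohorts and draws the remainder disjointly
per cohort; baselines and noise are independent per cohort. Truth
(true status, true DE/DM features) is written to separate `truth_*.tsv`
files so analysis stages, which read only the observed files, cannot
consume it. Generation is deterministic given the seed (per-cohort
streams are spawned from one seed sequence).

### Default study conditions and why

Defaults: 2000 genes, 200 DE, 150 samples, prevalence 0.8, effect
0.6 log2 units against unit-SD noise, fn 0.3, fp 0.1, recurrence
sensitivity 0.8 with 5% background, adjuvant rate 0.2 halving
recurrence, NB dispersion 0.1, mean library 10⁵ reads (a scaled-down
depth chosen so the O(total-count) conditional exact test stays cheap),
methylation coupling 0.9 with a 0.2 beta shift. Prevalence 0.8 mirrors
the metastasis-heavy composition of published resection cohorts and
yields recurrence-aware non-metastasis groups of roughly thirty
samples, the size such studies report; fp = 0.1 reflects the staging
false positives that motivate excluding non-recurrent N+M0 patients.
The effect size was set so that, at 150 samples, TNM-only grouping sits
in the low-power regime where BH at FDR 20% finds few or no
reproducible DEGs while recurrence-aware grouping has moderate power —
the contrast the pipeline exists to demonstrate.

### What the generator does not emulate

Observed group compositions differ between policies, but a detected
gene's direction almost always matches its true sign under either
policy, because contamination attenuates effects without inverting
them. Consequently the synthetic TNM-only failure mode is *absence of
reproducible overlap* (k ≈ 0), not the large-but-discordant DEG lists
seen in real cohorts; producing the latter would require cohort-
specific confounding correlated with staging (platform, subtype,
population structure), which the generator deliberately omits. Passing
tests therefore demonstrate the reclassification mechanics and the
statistics, not robustness to real-data confounding. Probe IDs,
barcodes, batch effects and survival-time structure are likewise out of
scope.

## Numerical choices

Exact rank-sum enumeration only for tie-free small samples (ties fall
back to the corrected normal approximation, which is tie-aware);
two-sided exact tests use the minimum-likelihood rule with a 1+10⁻⁷
relative guard; binomial and hypergeometric tails come from scipy's
survival functions, validated in the test suite against exact-rational
(fraction-arithmetic) oracles — to 12 significant digits for all
binomial tails with k ≤ 64; degenerate inputs (all-zero genes, constant
features, never-altered calls, empty intersections, empty direction
lists) return p = 1 / NA / empty tables rather than errors. TSV is the
single matrix dialect, UTF-8 with '.' decimals, so outputs are
byte-reproducible.

## Known limitations

The NB test is a deliberately simplified stand-in for mature count-DE
machinery: common dispersion only, conditional on rounded equalized
totals, cost linear in the total count per gene. The adjuvant exclusion
rule assumes the treatment annotation, when declared available, is
trustworthy. Concordance is pairwise only; no multi-list statistic is
provided. Enrichment in the orchestrated pipeline runs only when a GMT
file is supplied, since synthetic genes carry no pathway structure and
building sets from generator truth would leak ground truth into the
analysis path.
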