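# Methods

This note documents the statistical models, the numerical choices, and
the design decisions behind `salmeth`, together with what the synthetic
data generator does and does not emulate.

## Count model and differential methylation

Methylated read counts at a CpG are modelled as beta-binomial:
conditional on a sample-level methylation probability p ~ Beta with
mean μ_g and dispersion φ_g = 1/(α+β+1), the methylated count is
Binomial(N, p). φ captures among-individual biological variance on top
of binomial read sampling; the variance of a single sample's fraction
is μ(1−μ)(1 + (N−1)φ)/N.

**Smoothing.** "500 bp smoothing" is implemented as coverage-weighted
pooling per sample: for site s, the smoothed counts are the sums of
methylated and total reads over all retained CpGs within ±250 bp on
the same chromosome. A site alone in its window keeps its raw
fraction; a window with no data in a sample is missing for that
sample. Pooling is per sample (not per group), the simplest reading
consistent with group-specific dispersion estimation downstream.

**Dispersion.** Per site and group, φ is estimated from the *pooled*
fractions p_i with weights w_i equal to the pooled totals by the
weighted (Kleinman) moment estimator

    φ̂ = ( S/(p̄(1−p̄)) − (m−1) ) / ( W − Σw_i²/W − (m−1) ),

with W = Σw_i, p̄ = Σw_i p_i / W, S = Σw_i (p_i − p̄)². The estimate is
shrunk toward the genome-wide 10 %-trimmed mean of per-site estimates
with weight m/(m+m₀), m₀ = 20 by default, then clamped to
[10⁻⁴, 0.9]. Working on pooled counts is deliberate: φ then becomes an
*effective* dispersion of the smoothed estimator, so the Wald variance

    Var μ̂ = Σ_i w_i μ(1−μ)(1 + (w_i−1)φ) / W²

tracks the true sampling variance of the smoothed group mean whether
CpGs are isolated (pooled = raw, φ ≈ biological dispersion) or dense
(pooling shrinks φ and the variance together). Applying the raw-count
variance formula to smoothed means would instead overstate the variance
several-fold at dense sites and destroy power. The Monte-Carlo
calibration tests (null fraction of p < 0.001 within [2×10⁻⁴, 5×10⁻³]
at ~5×10⁴ sites; per-site power > 0.5 at |Δ| = 0.39 with n = 8/group
at ~8×) validate this choice empirically rather than by distributional
fiat.

**Test.** z = (μ̂₁−μ̂₂)/√(Var μ̂₁+Var μ̂₂), two-sided p from the standard
normal. μ is clamped to [10⁻⁵, 1−10⁻⁵] inside the variance so boundary
sites keep a nonzero variance; sites with data in only one group are
excluded. All p-values of a contrast enter one Benjamini–Hochberg
adjustment (delegated to `statsmodels.multipletests`, cross-checked in
tests against a brute-force step-up oracle).

## DMR construction

Clusters are maximal runs of significant CpGs (p < 0.001) with
consecutive significant sites ≤ 100 bp apart; the region spans the
first to last cluster CpG (+1, half-open) and its membership is every
tested CpG inside the span. Emission rules: length ≥ 50 bp, ≥ 4 CpGs,
and significant fraction strictly > 0.5. Direction is the sign of the
mean per-CpG difference (focal group minus reference; an exact zero
would be labelled hyper, unreachable with floating diffs). The 100 bp
merge gap is a configuration knob; it mirrors the smoothing scale.

The hypo:hyper imbalance uses the exact two-sided binomial test at
p₀ = 0.5, doubling the smaller tail and capping at 1.

**Overlap permutation null.** Cross-set DMR overlap is assessed by
re-placing each query region at a uniformly chosen start CpG on the
tested-CpG backbone and extending over the region's own CpG count —
preserving CpG-density structure, which bp-uniform placement would
ignore (inflating significance in CpG-dense regions). The empirical p
uses the add-one form (1+#{null ≥ obs})/(1+n_perm), so its smallest
attainable value is 1/(n_perm+1) and it can never be 0. Because
overlap counts are integers, ties make this p slightly *super-uniform*
(conservative) under the null; the effect shrinks as expected overlap
counts grow, and the null-uniformity test therefore uses region sets
dense enough that the discreteness is mild. With very sparse overlaps
a KS test against the uniform can flag the conservatism itself; that is
a property of add-one empirical p-values, not an error.

## Annotation and enrichment

A gene is associated with a region when the interval gap (half-open
coordinates, zero when overlapping or abutting) between region and
gene *body* is ≤ 5000 bp; strand is ignored and no TSS anchoring is
applied, as the 5 kb rule is body-based here. Term enrichment is the
classic one-sided hypergeometric over-representation test per term;
no term-hierarchy decorrelation (topGO-style `weight01`) is applied,
so p-values of nested terms are positively correlated — a documented
simplification. Raw p is the selection convention; a BH column is
emitted for convenience.

## Co-methylation network

Windows are non-overlapping 100 bp tiles; a window's value per sample
is Σmeth/Σtotal over member CpGs. Windows need ≥ 3 CpGs and
among-sample variance (ddof = 1) strictly above 0.05.

Biweight midcorrelation uses the tuning constant 9 MADs with a
Pearson-style mean-centering fallback for zero-MAD vectors (the WGCNA
convention). The network is unsigned: adjacency a_ij = |bicor|^18
(soft threshold approximating scale-free topology), and topological
overlap

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij),

with TOM_ii = 1 and diagonal-zero adjacency inside the formula.

**Module detection** replaces the Dynamic Hybrid tree cut with a
simplified procedure: average-linkage clustering of 1−TOM, a static
cut at height 0.99, a module size floor of 10, then iterative merging
of modules whose eigenvectors correlate ≥ 0.75 (the complement of
WGCNA's `mergeCutHeight = 0.25`). Above 30 000 windows the network is
built in chromosome-contiguous blocks that are merged afterwards by
eigenvector correlation — cruder than WGCNA's projective-k-means
pre-clustering, and a module split across blocks is only reunified if
each fragment clears the size floor. Validation is against planted
synthetic structure (ARI ≥ 0.8), not label parity with WGCNA.

**Eigenvectors and statistics.** The module eigenvector is the first
right-singular vector (per-sample scores, unit norm) of the module's
row-z-scored window matrix, signed to correlate non-negatively with
the module's average methylation; zero-variance windows are excluded
from the PCA with a warning. MM is |Pearson(window, eigenvector)|; GS
is |bicor(window, trait)|. Module–trait association is
bicor(eigenvector, trait) with a two-sided Student-t p on n−2 df
(guarded to the smallest positive float at |r| = 1); the r = 0.69,
n = 16 → p ≈ 0.003 convention check pins this down. Module/DMR
enrichment redraws |module| windows without replacement from all
network windows (add-one empirical p); MM/GS contrasts between DMR-
and non-DMR windows use Welch t-tests with Satterthwaite df.

Region-level module–trait r/p pairs (computed across windows rather
than samples) are deliberately not produced: sample-level statistics
are the defensible inference at n = 16.

## Phenotype statistics

Fulton's K = 100·W/(L/10)³ with W in g, L in mm. Note that the mean of
per-fish K differs from K evaluated at group-mean L and W
(mean-of-ratios vs ratio-of-means). The "random effect for family"
group comparison is implemented as a family-means one-way ANOVA
(df 1, n_families−2): with balanced families this equals the
mixed-model group test (checked against a REML fit in the tests) and
matches the printed degrees of freedom for a 10-family design; a full
REML mixed model is out of scope.

## Synthetic data generator

The generator emulates, at desk scale, the statistical features the
analysis relies on:

- **Backbone**: exponential inter-CpG gaps (mean 150 bp, default
  3 chromosomes × 2.5 Mb ≈ 5×10⁴ CpGs) plus CpG-island-like clusters
  (probability 0.01 per background gap; 8–16 CpGs at 20–60 bp spacing).
  Islands give the caller's gap rule something to find: with purely
  exponential 150 bp spacing nearly every dense region would fragment
  below the ≥4-CpG rule.
- **Baseline methylation**: a three-component Beta mixture — 5 %
  near-unmethylated Beta(0.4, 12), 4 % intermediate Beta(2, 2), 91 %
  high Beta(45, 2.5) — drawn block-constant over 500 bp. This
  reproduces the sperm-like bimodality (~91 % of sites above 0.8,
  genome average ≈ 0.89).
- **Reads**: coverage 1 + Poisson(7.3) truncated at 20 (mean ≈ 8.3×);
  counts beta-binomial with φ = 0.1, independently per site and
  sample.
- **DMRs**: 50 regions on dense runs (≥ 6 CpGs, gaps ≤ 100 bp),
  |effect| ~ Uniform(0.08, 0.70) (mean 0.39), hypo with probability
  2/3; the local baseline is redrawn so baseline±effect stays inside
  [0.01, 0.99] — with the ~0.95 genomic baseline a hyper shift would
  otherwise clip to nothing.
- **Modules**: sets of ≥3-CpG windows (disjoint from DMRs) whose
  per-sample means follow 0.5 + b·z with a shared standardized latent
  sample signal z per module and loadings |b| ∈ [0.25, 0.40]
  (70 % positive), clipped to [0.02, 0.98]. Loadings below ~0.21 would
  fail the 0.05 variance filter, so the range is chosen to survive it.
- **Phenotypes**: length is Gaussian per group (65.2/63.2 ± 6.6 mm,
  40 % of variance among families); condition K = mean_K·(1+δ) with δ
  mixing the first module's latent z and noise so that the population
  correlation of K with the module signal equals 0.69; weight is
  derived as W = K·L_cm³/100, keeping the three traits internally
  consistent. Families affect phenotypes only, not methylation.

Everything is driven by one integer seed through a single
`numpy.random.Generator`, and planted truth (DMR intervals, module
windows, latent signals, trait links) is returned for recovery
scoring.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: read-level artefacts (bisulfite
conversion error, mapping bias, PCR duplicates), sample-level regional
methylation haplotypes (biological deviations are independent across
sites within a sample, which makes smoothing more effective than it
may be in vivo), strand asymmetries, genuine GO structure, population
genetic signal, and family effects on methylation.

## Problem sizes and determinism

Validation runs use ~5×10⁴ CpGs for calibration and DMR recovery,
~90–140 network windows for module recovery, 50 replicates for the
module–trait recovery envelope, and 200 runs × 499 permutations for
the null-uniformity check — sizes at which every property is stable
across seeds while the whole battery completes in well under a minute.
All tests are seeded; `scripts/acceptance.py` derives every stream
from its `--seed` argument.

## Known limitations

- The static tree cut under-segments heavily nested module structure
  compared with Dynamic Hybrid; merge behaviour across blocks depends
  on fragments clearing the size floor.
- The Wald test relies on moment-based φ with shrinkage; at very low
  coverage (< 3×) or n < 4 per group its calibration is untested.
- The permutation overlap p is conservative for sparse overlap counts
  (see above).
- GO enrichment treats terms independently; no DAG propagation.
- The family ANOVA requires each family nested in one group and ≥ 2
  families per group.
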