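# Methods

`chickdiv` re-implements, as a tested library, the analysis stack used to
characterise genome diversity in re-sequenced crop variety panels — here
parameterised after a chickpea (*Cicer arietinum*) panel of desi and kabuli
market types grouped into three release periods (RP1/RP2/RP3).  Every
stage is exercisable on synthetic panels whose ground truth is returned as
an explicit ledger, so recovery can be measured rather than assumed.

## The synthetic panel generator

### Neutral background

Candidate variant sites arise along each chromosome as a Poisson process
with rate `theta * a1(n_pool)` per bp, where `a1(n) = sum_{i<n} 1/i` and
`n_pool = 1000` haplotypes is a large notional source population.  Each
site's ancestral allele frequency is drawn from the discrete neutral
frequency spectrum `P(k) ∝ 1/k`, `k = 1..n_pool-1`.  Because binomial
subsampling preserves the neutral spectrum, a sample of `n` haplotypes
then satisfies `E[S] = theta·L·a1(n)` and `E[pi] = theta·L` up to a
discretisation error of order `n/n_pool` (≈0.3 % here).  This gives a
desk-scale generator whose frequency spectrum is *calibrated* — the
Watterson and pairwise estimators recover the configured `theta`, and
Tajima's D is centred near zero — without any coalescent machinery.

### Structure, admixture, selfing

With `K > 1` subpopulations, per-subpopulation frequencies follow the
Balding–Nichols Beta model around the ancestral frequency with divergence
`F` (default 0.15), and each variety's ancestry vector is
Dirichlet(`alpha` = 0.2) — strongly admixed, as observed in breeding
panels.  Genotypes are Binomial(2, `q_i·F_j`) dosages.  Selfing is applied
as genotype collapse: a heterozygote becomes a random homozygote with
probability equal to the selfing rate (default 0.9; chickpea is a
predominantly selfing species), which makes realised heterozygosity
decline monotonically with that rate.

The collapse rule has a real population-genetic consequence: it removes
sample singletons at rate `s/2`, so the naive 2N-haplotype Tajima's D is
*positively* biased (≈ +0.4 at `s = 0.9`, by the argument above applied to
the singleton class).  This is a property of selfing, not a defect of the
estimators, and it is why the estimator-calibration runs use the
`neutral_config` preset — one panmictic subpopulation, selfing 0, no
missingness, no planted features: the conditions under which the D/θ_w
sampling theory actually applies.  The chickpea-like default panel keeps
selfing 0.9.

### Planted signals and depth

* **Sweeps**: inside a planted interval, site density is thinned by the
  stated factor and surviving minor-allele frequencies are multiplied by
  it — the diversity deficit plus rare-shifted spectrum of a completed
  sweep.
* **Balancing regions**: frequencies are pulled toward 0.5 with a weight
  (default demos use 0.9–0.95), planting the excess of
  intermediate-frequency variation positive Tajima's D detects.
* **Depth**: per sample, 1 kb bins carry `Poisson(mean_depth ×
  multiplier)` counts; the multiplier is 1 outside events, the planted
  copy number inside CNV events, and 0.05 inside presence/absence
  dropouts (residual cross-mapping).  Per-site sample depths follow the
  same local multiplier, and genotypes inside a sample's absent regions
  are uncallable (missing).
* **Missingness**: uniform random masking at the configured rate
  (default 5 %).

### What the generator does not emulate

Sites in the main generator are *independent*: there is no linkage,
recombination, GC or mappability bias, no genotype-calling error
correlated with depth, and no shared pedigree among varieties.  Passing
recovery tests on this substrate shows the callers implement their rules
correctly and are calibrated under Poisson/neutral assumptions; it does
not certify performance on real panels where those assumptions bend.  For
LD specifically a second entry point, `simulate_haplotype_mosaic`, builds
panels with genuine linkage: each sampled haplotype copies one of
`n_founders` founder haplotypes at a time, switching founders between
consecutive sites with probability `1 − exp(−r·gap)`, so r² decays with
distance on the `1/r` scale toward a `~1/n_founders` floor.  Real LD decay
additionally reflects demography and selection, which the mosaic does not
model.

## Variant filtering and annotation

The retention cascade keeps a site iff: pooled depth across samples lies
in the policy range; the mean relative copy number (per-sample site depth
over that sample's genome-wide mean, averaged over samples) is ≤ 1.5 — a
repeat-region guard; the missing-call ratio is ≤ 0.5 (a site missing in
exactly half the panel is retained); and the panel alt-allele frequency is
strictly between 0 and 1.  The literal pooled-depth bounds [78, 2500] were
calibrated for a 129-variety panel at ~7.6×; `FilterPolicy.for_panel`
rescales them to 0.6×–20× of `n_samples × mean depth` for any other panel
size and keeps the literal bounds when `n = 129`.  A per-site
reason ledger (`depth` / `copy_number` / `missing` / `fixed` / `pass`)
records the first failing rule, and filtering is idempotent.

Genic context is interval membership against the gene models (exonic =
inside a CDS chunk; intronic = inside the gene span but not CDS).  Coding
effects translate the reference and alternate codons with the standard
nuclear code (reverse-complemented for minus-strand genes): same amino
acid → silent; alternate codon a stop when the reference is not →
nonsense; otherwise missense (stop-loss counts as missense).  The effect
is a property of the site, independent of which samples carry it.  dN/dS
uses Nei–Gojobori (1986) site counting over all reference codons
(reference stops skipped); a cohort's substitution counts are sites where
any non-missing member carries the alt allele; zero synonymous
substitutions yield an undefined (NaN) ratio, never infinity.  Note the
source analyses of such panels describe the same quantity both as dN/dS
and as dS/dN "> 1 indicating positive selection"; these cannot both be
the intended statistic, so this package computes dN/dS and leaves the
interpretation to the user.

## Depth-based CNV calling

Per-bin depth is modelled as Poisson.  Two Poisson rates are compared with
the conditional binomial exact test: given totals `x` over `w_x` bins and
`y` over `w_y` bins, `x ~ Binomial(x+y, w_x/(w_x+w_y))` under equality.

1. **Initial windows** grow greedily left to right; a bin joins while it
   does not differ from the window's pooled rate at the *raw* alpha
   (default 0.01).  Splitting is deliberately liberal: one bin's exact
   test against a long window has bounded evidence (a 3× drop at 10×
   depth caps near p ≈ 3×10⁻⁴), so a multiplicity-corrected threshold
   here would make trailing event edges undetectable and smear or lose
   calls.  False splits merely fragment the genome.
2. **Two merge passes** re-join adjacent windows whose pooled rates do not
   differ at alpha Bonferroni-corrected by the window count — this is the
   step that controls the final false-segment rate (verified: ≤1 spurious
   call per null genome in ≥95 % of seeds).
3. **Copy number** is the segment's mean depth over the sample's *median*
   bin depth.  The median shares the mode's robustness to contamination
   by large amplifications (50 % breakdown) but avoids the mode's
   instability on integer counts at ~10× coverage, which misrounds CN.
   Calls with rounded CN ≤ 1 are dropped — depletion is the
   presence/absence caller's province — and adjacent calls with equal
   rounded CN merge.

Copy numbers are reported on the relative scale where 1 is the reference
state, making all calls invariant under uniform depth rescaling.

## Presence/absence variation and gene loss

A deletion-type region is **absent** in a sample when its length-weighted
mean depth is `< 0.10 ×` that sample's genome-wide mean; an insertion-type
region is **present** when mean depth is `> 0.50 ×` the genome mean.  Both
thresholds are strict (a region at exactly 10 % is present).  A group
carries a region-level PAV when **more than three** of its members share
the variant state (absent at deletion-type, present at insertion-type
regions); groups of ≤3 samples can never be flagged and are warned about.
Gene loss is bin-approximated coverage: a bin counts as covered at mean
depth ≥ 1, and a gene is lost in a sample when under 10 % of its span lies
in covered bins.  With the default dropout multiplier 0.05 a 1 kb bin in
an absent region still shows reads ~5 % of the time at 10×, so clean
gene-loss experiments plant multiplier-0 dropouts.

## Windowed diversity and selection scans

Per non-overlapping window (default 10 kb; 50 kb is the appropriate scale
when hunting ≥150 kb selection regions):

* haploidisation: dosage `g` contributes `g` alt haplotypes of 2;
  missing genotypes are pairwise-deleted per site;
* `pi` = mean pairwise difference per site, `2c(m−c)/(m(m−1))` summed and
  divided by window length;
* `theta_w = S / (a1(n)·L)` with `n` the window-average non-missing
  haplotype count, rounded (the per-window effective sample size used in
  all constants);
* Tajima's `D = (piL − S/a1) / sqrt(e1·S + e2·S(S−1))` with the standard
  constants; Fu & Li's `D*` is the no-outgroup singleton form with the
  Simonsen-corrected `u*`, `v*`; both undefined (NaN) at `S = 0`;
* Hudson's FST as ratio of sums over sites,
  `N = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)`,
  `D = p1(1−p2) + p2(1−p1)` — slightly negative in expectation for
  identical finite samples, as for any unbiased estimator.

The **differentiation scan** intersects the top-fraction windows by FST
with the top-fraction by |Δπ| (default 2 %, matching the published scan's
~2 %-of-genome span) and merges adjacent survivors.  The **Tajima's-D
region scan** compares each window's D against a null built by permuting
site-to-window labels within the genome and recomputing the statistic
(50 permutations by default): permutation destroys the spatial clustering
selection creates while preserving the genome-wide frequency spectrum.
Empirical two-sided p-values are Benjamini–Hochberg adjusted at α = 0.05,
and runs of significant windows of the requested sign are reported when
their merged span reaches `min_span` (default 150 kb).  An
`empirical-quantile` mode (rank against the observed window-D
distribution) is available as a pure outlier criterion; note that
combining it with BH is conservative to the point of never firing, which
is why permutation is the default.

## Population structure

* **Distance**: `1 − IBS`, with per-site IBS `1 − |g_i − g_j|/2` averaged
  over jointly called sites.
* **Neighbor joining**: Saitou–Nei with the standard Q criterion;
  negative branch lengths are clamped to zero with the deficit moved to
  the sibling branch (preserving the pair's summed path length); ties in
  Q break to the first pair.  Output is an unrooted scikit-bio `TreeNode`
  (trifurcating root).  NJ is exact on additive matrices — verified
  against independently generated random trees and against scikit-bio's
  implementation.
* **PCA**: sites mean-centred and scaled by `sqrt(p(1−p))` (Patterson
  normalisation), missing dosages imputed at the site mean,
  eigendecomposition of the sample covariance.  Each leading eigenvalue
  gets a Tracy–Widom statistic via the moment-matched effective marker
  count `n_eff = (m+1)S1²/((m−1)S2 − S1²)`; p-values use the Chiani
  shifted-gamma approximation of TW1, which reproduces the tabulated 95 %
  and 99 % points (0.9793, 2.0234) to ~0.01.
* **Admixture**: maximum-likelihood EM on
  `g_ij ~ Binomial(2, Σ_k q_ik f_kj)` — the Frappe/STRUCTURE likelihood.
  The E-step distributes each observed allele over source populations in
  proportion to `q_ik f_kj / p_ij`; the M-step re-estimates Q (rows
  automatically on the simplex) and F from expected counts.  The
  log-likelihood is non-decreasing every iteration; missing genotypes are
  excluded from all sums; `K = 1` is closed-form.  Defaults: 10,000
  iteration cap, 5 random restarts keeping the best likelihood, tolerance
  1e-4 on the log-likelihood gain.  Estimated and true ancestry are
  compared after Hungarian alignment of the K labels.

## Linkage disequilibrium

Haplotype frequencies for a SNP pair come from the genotype-pair table:
all categories except the double heterozygote are phase-certain; the
double heterozygote is split between coupling and repulsion phase by a
two-locus EM.  In a selfing panel double heterozygotes are rare, so the
EM touches few pairs.  Then `D = f11 − pA·pB`,
`r² = D²/(pA(1−pA)pB(1−pB))`, `D' = D/Dmax`.  The LD-decay profile is
mean r² per distance bin with a pool-adjacent-violators non-increasing
fit; the decay distance is the start of the first bin where the smoothed
curve falls below half its maximum (stated explicitly because published
decay figures rarely define their criterion; for the same reason the
published 290/230/250/260 kb figures are not comparison targets).

Haplotype blocks follow the Gabriel confidence-interval method at
Haploview-like defaults: the 90 % CI of |D'| by likelihood profiling on a
101-point grid (allele frequencies fixed at their estimates, D's sign at
its point estimate, grid likelihoods normalised to weights, 5th/95th
percentiles); "strong LD" when the CI lies within [0.70, 0.98], "strong
recombination" when its upper bound is < 0.90.  A candidate span is a
block when its outermost pair is strong LD and ≥95 % of its informative
pairs are; blocks are taken greedily, longest span first, non-overlapping.
The HWE-style pair likelihood is approximate under selfing, which is why
the CI is used only to classify pairs, not reported as an interval
estimate.

## Reporting

The summary table counts, per cohort (all varieties, each market type,
each release period), SNPs and indels split by genic context with
enforced additivity (each total must equal the sum of its categories),
plus CNV calls in cohort members and PAV states departing from the
reference.  A variant belongs to a cohort when any non-missing member
carries its alt allele, so sub-cohort counts can never exceed the full
panel's.  The package also ships the published per-category counts of the
129-variety chickpea panel as a worked-example dataset; the additivity
identity on those rows (e.g. 46,387 + 115,360 + 1,217,043 = 1,378,790
SNPs) is recomputed, never stored.

`run_pipeline` chains simulate → filter → annotate → cnv → pav → stats →
scan → structure → ld → report.  All randomness derives from the single
panel seed, so reruns are byte-identical; a stage's files are rewritten
only when missing or when an upstream stage reran, so deleting one
stage's outputs regenerates that stage and everything downstream while
upstream files are left untouched.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale panels chosen to make the
statistical checks sharp: estimator calibration uses 100 seeds of 1 Mb ×
20 samples at θ = 0.002/bp (≈8,500 segregating sites per panel); CNV
recovery plants 30-bin CN=3 events on 300 kb genomes; sweep recovery
plants 200 kb factor-0.1 sweeps on 1 Mb scanned in 50 kb windows;
admixture recovery uses 36 varieties × ~5,000 SNPs.  Tolerances: exact
statistics are compared to oracles at 1e-9; EM monotonicity allows 1e-6
numerical slack; frequencies are clipped to [1e-9, 1−1e-9] inside
likelihoods; degenerate inputs (monomorphic windows, empty pair sets,
groups too small to test) return NaN sentinels or raise with explicit
messages rather than propagating infinities.

## Known limitations

* No linkage in the main generator (see above); the mosaic variant covers
  LD mechanics only.
* The CNV caller reports amplifications only, by design; CN estimates
  assume a diploid baseline and Poisson counts (no overdispersion).
* Gene-loss coverage is bin-approximated (1 kb), not base-wise.
* Tajima's D and D* on highly selfing panels are biased when computed on
  2N haplotypes; the package reports them as defined and leaves
  effective-size corrections to the analyst.
* The admixture EM can snap Q rows to simplex vertices on small panels
  (few samples × many sites), a known behaviour of the unpenalised
  maximum-likelihood estimator.
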