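# Methods

This note documents the statistical models behind `microgwas`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make runs reproducible.

## The analysis model

The pipeline treats microbiome features as quantitative traits of the host
and asks, SNP by SNP, whether the additive allele count predicts the trait
after adjusting for everything that could confound the pair. The adjusted
model for trait $y$ and genotype $g \in \{0, 1, 2\}$ is ordinary least
squares:

$$ y^{(\lambda)} = \mu + \beta g + \gamma^\top c + \varepsilon $$

where $c$ stacks sex (binary), age, collection site and sequencing center
(dummy-coded against the first observed level), total sequence count, and
the first five MDS coordinates of the host IBS matrix; significance of
$\beta$ is a two-sided t-test. Missing data are handled by listwise
deletion per test; the per-test sample size is reported. A covariate
column that is constant in the analysis sample is dropped (it is collinear
with the intercept); genuinely collinear designs raise an error naming the
offending columns, and a constant genotype yields a flagged NA result
rather than an error.

Traits enter the model Box-Cox-normalized: $y^{(\lambda)} = (y^\lambda -
1)/\lambda$, with $\log y$ as the $\lambda = 0$ limit. $\lambda$ is chosen
per trait by maximizing the normal profile log-likelihood over $[-5, 5]$
(bounded scalar minimization, tolerance $10^{-8}$); non-positive trait
values are shifted by a constant making the minimum $10^{-6}$, and the
shift is recorded. Multiple testing is controlled with Benjamini-Hochberg
step-up Q values across all (SNP, trait) tests in a run.

Although the covariate-adjusted fixed-effects OLS here is sometimes loosely
described as a "mixed model" in the microbiome-GWAS literature, no random
effect is fitted: ancestry enters through the MDS covariates, which is the
fixed-covariate stratification control this package implements.

### Population structure

Identity-by-state between individuals $i, j$ is the mean over SNPs typed
in both of $(2 - |g_i - g_j|)/2$, a similarity in $[0, 1]$ computed over
pairwise-complete SNPs without imputation. Its complement $1 -
\mathrm{IBS}$ feeds classical (Torgerson) metric MDS: double-center the
squared distances, eigendecompose, scale eigenvectors by the square roots
of their eigenvalues. Requesting more dimensions than there are positive
eigenvalues is an error that reports the attainable number. Axis signs are
fixed deterministically (largest-magnitude loading positive) so
coordinates are bit-reproducible.

### QC boundaries

All three filter boundaries are strict, matching the convention "above
10 %", "P > 10⁻³", "less than 50 % missing": a SNP at exactly the MAF
threshold is removed. Hardy-Weinberg uses the conditional exact test
(enumerate heterozygote counts given allele counts via a ratio recurrence
anchored at the mode; two-sided P sums configurations no more probable
than the observed). "Autosomal" means chromosome labels 1-22 after
stripping an optional `chr` prefix. Per-filter failure counts are
reported with a SNP failing several filters counted under each.

### Microbiome traits

Lineage strings (`k__;p__;...;g__`) collapse to the genus level or, for
taxa unclassified at genus, to the deepest classified ancestor — so a
family-only OTU still contributes one family-level trait. After closure
to relative abundance, taxa are filtered by prevalence (fraction of
samples with non-zero abundance, default floor 0.1) and mean abundance
(default 10⁻⁴), then inter-correlated pairs (Spearman > 0.95) are pruned
greedily, keeping the higher-prevalence member. Alpha diversity is
Shannon entropy in nats; beta diversity is Bray-Curtis; microbiome "PCs"
are principal coordinates of the Bray-Curtis matrix computed by the same
classical-MDS routine used for host structure (a user-supplied distance
matrix, e.g. UniFrac, can be substituted). Alpha and beta metrics are
config switches because the upstream literature is ambiguous about the
exact metrics used in this design.

### Enrichment

A SNP maps to every gene whose interval it overlaps or lies within
`max_dist` bp of (default 50 kb, boundary inclusive; distance measured
SNP-point to gene-interval in 0-based half-open coordinates — BED ingest
and the VCF's 1-based positions are reconciled in one place). The fold
enrichment of a query set $M$ against a scored universe at cutoff $P_i$
uses the background-rate reading: with $G_i = \{x : p_x \le P_i\}$,
$\mathrm{fold} = |M \cap G_i| \,/\, (r\,|G_i|)$ where $r = |M \cap (U
\setminus G_i)|/|U \setminus G_i|$. The raw background-overlap count is
emitted alongside, since the verbal definition admits both readings.
Degenerate cutoffs (empty significant set, empty background, zero
background overlap) are flagged, never silently dropped. Fisher's exact
test on the 2×2 membership table quantifies overlap between two discrete
sets; being discrete, its null P values are conservative rather than
exactly uniform.

### F_ST comparison

For each body site, SNPs associated with any of the site's traits at
P < 10⁻⁴ (strict) form the linked group; the background is all other
scored SNPs. The test statistic is the difference of group medians under
random re-splits of the pooled values at the original group sizes
(default 10,000 permutations), with ties counted as non-exceeding. P
values use the add-one rule $(k+1)/(B+1)$: the unmodified "proportion of
permutations" definition can return exactly 0, which breaks downstream
FDR; the price is a floor of $1/(B+1)$. Both directions (higher/lower)
are computed, BH-adjusted across all (site, pair) comparisons per
direction, and flagged both at Q < 0.05 and at P < 10⁻³ so either
highlighting convention can be reproduced. The group median's 95 % CI is
the 2.5-97.5 percentile range of medians over bootstrap resamples at the
original size (default 10,000). Empty linked groups yield flagged NaN
rows. Medians are equivariant under strictly increasing transforms, so
the permutation P is invariant to any common monotone rescaling of the
scores (asserted by test).

## The synthetic-data generator

The generator emulates the statistical structure of a ~93-individual
multi-body-site cohort so every stage can be tested against known ground
truth:

- **Genotypes** follow the Balding-Nichols model: ancestral frequency
  $p \sim U(\text{maf\_range})$ per SNP, population frequency $\sim
  \mathrm{Beta}(p(1-F)/F,\ (1-p)(1-F)/F)$ at differentiation $F$
  (populations share $p$ exactly at $F = 0$), genotypes
  $\mathrm{Binomial}(2, p_{\mathrm{pop}})$, entries masked missing
  completely at random at `missing_rate`. The realised genome-wide Hudson
  F_ST (ratio-of-averages combination, which avoids the downward Jensen
  bias of averaging per-SNP ratios) recovers the target within ±0.02 at
  5,000 SNPs, n = 200.
- **Abundances**: log-abundance = per-taxon baseline $\sim N(0, 2)$ +
  $\sum$ effect·genotype over planted causal pairs + covariate terms
  (fixed per-center offsets, 0.2·sex, 0.01·(age − 29)) + $N(0, 1)$ noise,
  exponentiated and closed to relative abundance per sample (or drawn
  multinomially at a configurable depth). Effect sizes are therefore in
  units of residual SD on the log scale. Causal SNPs are planted
  preferentially at SNPs that survive the default QC (observed MAF >
  0.1, exact-HWE P > 10⁻³) so ground truth stays in the analysis set; a
  zero-variance candidate triggers a warning and resampling. Missing
  causal genotypes contribute the SNP's observed mean so complete-case
  regression stays unbiased.
- **Covariates**: sex, age (U(18, 40)), collection site (2 sites),
  sequencing center (4 centers), total sequence count (log-normal). With
  `confound_strength` $c$, each individual's center is its population's
  designated center with probability $c$ — at $c = 1$ center
  deterministically tracks population, the worst-case stratification
  scenario the adjustment must absorb.
- **F_ST scores**: background Beta(0.6, 8) (right-skewed, most mass near
  zero, long upper tail), linked SNPs shifted by a constant before
  clipping to [0, 1].
- **Gene annotations**: non-overlapping intervals packed per chromosome
  with random lengths and gaps; infeasible packings are an error.

Defaults (93 individuals, 2 populations, F_ST 0.1, MAF 0.05-0.5, 5 %
missingness, 15 body sites, 50 taxa, 3 causal pairs of 1.5 SD) mirror the
design the package targets. One master seed spawns named child streams in
a fixed order; identical configuration and seed give bit-identical output.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium between SNPs (sites are
independent), phylogenetic correlation among taxa, sequencing-error or
read-level artifacts, coverage-driven (informative) missingness, and
zero-inflation of rare taxa. One property of the compositional closure is
worth flagging: a planted effect raises the causal taxon's share of the
community, so the slope of log *relative* abundance on genotype is
attenuated by roughly effect × E[causal-taxon share] relative to the
planted log-abundance effect (≈ 0.14 at effect 1.5 with 50 taxa). The
estimator itself is unbiased — the attenuation is a fact about closed
data, and is why estimator-bias checks use traits generated under the
regression model directly.

## Numerical conventions

- Reported P values are floored at 10⁻³⁰⁰, never 0.
- The genome scan assembles each SNP's normal equations directly from the
  missingness mask and batch-solves all SNPs at once — algebraically
  identical (to 10⁻¹⁰, asserted by test) to the per-SNP QR path, which
  remains the reference implementation and the fallback for traits with
  missing values.
- MDS eigenvalue positivity uses a relative tolerance of
  $n \cdot \max|\lambda| \cdot 10^{-12}$; ties in eigenvalues are ordered
  by the (deterministic) LAPACK ordering.
- Greedy taxon de-correlation breaks prevalence ties by mean abundance,
  then name.
- Bootstrap and permutation loops are chunked (500-1,000 draws per block)
  to bound memory; chunking does not change the stream of random numbers
  consumed.
- Every output file carries `#`-comment provenance (tool, seed, config
  hash); stages are skipped when their stamp matches the configuration
  digest and all outputs exist, and a matching stamp with a missing file
  is an error naming the stage rather than a silent regeneration.

## Problem sizes used in the checks

The statistical acceptance checks run at: 500 replicates for null
calibration of the association P (n = 100 per replicate) and the
permutation type-I rate (199 permutations per replicate, pool of 400);
200 replicates for the fold-enrichment null (universe 10,000, query 500);
100 replicates at n = 500 and 1,000 SNPs × 50 taxa for planted-effect
recovery; 500 Normal samples of size 200 with 2,000 bootstrap resamples
for CI coverage; and an end-to-end run at 100 individuals, 1,000 SNPs,
3 body sites. These sizes make the full suite complete in minutes on one
CPU while leaving each check's Monte-Carlo error well inside its
acceptance band.

## Known limitations

- The pipeline models one trait at a time; no multivariate or kernel
  association tests.
- No LD pruning before IBS and no kinship/GRM mixed model — structure
  control is purely via MDS covariates, as in the design this package
  reimplements.
- The exact prevalence/abundance floors and inter-correlation rule used
  upstream of the "615 traits" figure in the motivating design are not
  public; the defaults here (0.1 / 10⁻⁴ / Spearman 0.95, keep the more
  prevalent) are reasonable stand-ins and are fully configurable.
- Pairwise IBS-beta regression treats non-independent pairs as
  independent; the nominal P is flagged and a Mantel permutation
  alternative is provided.
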