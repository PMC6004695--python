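# Methods

## Statistical model and procedure

### Per-gene divergence statistics

The unit of analysis is the gene: all statistics are computed per site from
population allele counts and aggregated as unweighted means (π,
D<sub>XY</sub>) or a ratio of summed variance components (F<sub>ST</sub>)
over the sites retained inside each gene interval. The mean (rather than the
sum) keeps genes of different lengths on one scale, which matters because
outlier status is assigned by genome-wide rank cut-offs.

Per site, with alternate-allele frequency *pᵢ* and non-missing allele count
*nᵢ* in population *i*:

- **π** (within-population diversity): 2p(1−p)·n/(n−1), the unbiased
  probability that two distinct alleles sampled from the population differ.
  Sites with n < 2 are skipped for that population.
- **D<sub>XY</sub>** (absolute divergence): p₁(1−p₂) + p₂(1−p₁), the
  probability that one allele from each population differ. Exactly symmetric
  in the populations.
- **F<sub>ST</sub>**: the Weir–Cockerham analysis-of-variance estimator with
  alleles as sampling units. Per site, MSP = Σnᵢ(pᵢ−p̄)²/(r−1),
  MSG = Σnᵢpᵢ(1−pᵢ)/(n_tot−r), n_c = (n_tot − Σnᵢ²/n_tot)/(r−1) with r = 2
  populations; the per-site numerator is MSP − MSG and the denominator
  MSP + (n_c−1)·MSG. The per-gene estimate is Σnum/Σden over retained sites
  ("weighted" form, the default); the mean of per-site ratios over
  polymorphic sites is exposed as `method="mean"` because the two
  conventions coexist in common tooling and differ on real data. The
  weighted form is the default because the mean-of-ratios is unstable at
  low-diversity sites. Estimates are not clamped: slightly negative values
  are informative for ranking and the estimator is unbiased around zero
  under no differentiation.

Sites monomorphic in both populations contribute 0 to π and D<sub>XY</sub>
means and nothing to the F<sub>ST</sub> denominator; a gene whose
denominator sums to zero (no polymorphic sites) carries a missing
F<sub>ST</sub>, and a gene with no retained sites is reported with missing
statistics, never zeros.

**Site filters.** Three removal rules run in a fixed order, each logged:
repeat-masked intervals (overlaps merged silently); indel-affected spans
plus 10 bp on each side; and a minimum of 6 genotyped individuals (12
alleles) per population. Coordinates follow the standard conventions — VCF
positions 1-based, BED intervals 0-based half-open — and a site at 1-based
position P belongs to interval [s, e) iff s ≤ P−1 < e. Multiallelic records
and non-SNPs are excluded at VCF parse time, mirroring hard-filtered SNP
input.

### Selection calls

Per-SNP selection statistics are taken as external input (the
haplotype-based model that produces them is deliberately not reimplemented).
P-values come from a genome-wide normal fit: standardise by the genome-wide
mean and sample standard deviation (ddof = 1) and take the standard normal
upper tail, since larger statistics indicate stronger evidence of selection;
a two-sided variant sits behind a flag. A gene is significant when its
minimum SNP p-value is below α = 0.05; genes containing no SNPs are dropped
("no data") rather than reported as non-significant. Under k independent
null SNPs per gene the per-gene significance rate is 1 − 0.95ᵏ, which is the
calibration the tests check at k ∈ {1, 5, 10}.

### Outlier classification

Dense ranks (ties share a rank; ranks consecutive from 1, ascending in the
metric) are computed per metric over genes with data. A gene is a
divergence outlier when it meets **any** of: dense rank > (1−0.05)·R_max for
F<sub>ST</sub>, rank > (1−0.20)·R_max for D<sub>XY</sub> (0.05 supported as
a stricter alternative), or selection p < 0.05 — and is not among the 500
genes with the smallest surface-population π (ties broken by gene id for
determinism). Three consequences of this design are intentional:

- boundary ties share fate (dense ranking cannot split a tie), so the
  flagged fraction can exceed the nominal cut-off but never falls below it;
- the π exclusion removes genes from outlier *calling*, not from the rank
  computation of other genes; a flag re-ranks after exclusion for users who
  prefer that order, since the original procedure's order is ambiguous;
- a gene missing one metric can still be an outlier through another.

### Enrichment

- **2×2 contingency:** the continuity-corrected (Yates) chi-square,
  statistic Σ(max(|O−E|−0.5, 0))²/E with 1 df, is the primary test because
  it is the statistic printed in the study design this pipeline follows; a
  two-sided Fisher exact p is available. The genome rows of the table
  include the focal set by default (set ⊂ genome), which reproduces the
  published statistic; a disjoint construction sits behind a flag.
- **Odds ratio:** sample ad/bc with a Woolf log-scale 95% CI; any zero cell
  triggers Haldane–Anscombe +0.5 on all cells. On the published counts
  (86/635 vs 1648/22,710) this gives OR ≈ 2.00, whereas the originally
  printed 1.94 is not reproducible from the printed counts under any
  standard construction we tried; the documented Woolf construction is
  reported as-is.
- **Kruskal–Wallis:** tie-corrected H with a chi-square reference
  distribution, written out directly (midranks computed internally) so
  scipy can serve as an independent oracle in the tests.
- **Bootstrap null:** the observed percent-significant of the focal set is
  compared with 9999 replicates, each sampling 500 genes without replacement
  from the expression universe (with-replacement behind a flag); the
  percentile counts replicates strictly below the observed value (ties count
  as not-below — conservative) and is labelled ">99.9" when the observed
  value exceeds every replicate. Replicate draws come from one seeded
  generator, so results are bit-for-bit reproducible.
- Bonferroni correction for test families multiplies p by the family size
  and caps at 1.

### Expression concordance

Directions are called at BH-adjusted p < 0.05 with the sign of the log2
fold-change (case/cave vs control/surface); significant genes with exactly
zero fold-change have no direction and are dropped with a warning. The BH
step-up adjustment is implemented directly (adjusted p never below raw,
monotone, capped at 1) and checked against statsmodels.

Orthogroup summaries use the **any-paralog rule** — an orthogroup is
significant when at least one member paralog is — recorded in the output
metadata because the alternative (majority rule) is defensible; the
any-paralog rule is the one consistent with orthogroup rates exceeding
paralog rates in the tabulations this design follows. An orthogroup-level
direction is assigned only when all significant paralogs agree, else marked
inconsistent.

Concordance is scored at the **paralog level**: each fish paralog with a
direction whose mapped human gene also has a direction counts as jointly DE,
and agreement is a sign match. Human genes whose multiple reports conflict
in direction are excluded and counted; reports silent on a gene do not veto
an agreeing call. Swapping up/down in both species leaves the concordance
percentage unchanged (checked as a property).

## Synthetic data: what it emulates and what it does not

The generator supplies every input format with known ground truth.

- **Genotypes** follow the Balding–Nichols model: per gene, an ancestral
  frequency p ~ U(0.05, 0.95) (bounded away from 0/1 so doubly monomorphic
  sites do not dominate); each population's frequency is
  Beta(p(1−F)/F, (1−p)(1−F)/F) — mean p, and F is exactly the
  F<sub>ST</sub> estimand — with F the background value or the planted value
  for outlier genes; diploid genotypes are Binomial(2, freq) and genotypes
  go missing independently. Degenerate F (0 or 1) is rejected; the limits
  are approached with F = 0.001 / 0.99 fixtures instead.
- **Selection statistics**: standard normal per SNP, with a configurable
  number of SNPs per planted gene shifted upward (default +5).
- **DE tables**: each human gene founds an orthogroup of 1–2 fish paralogs.
  Human genes are DE with probability `de_fraction` (multiplied by
  `geneset_enrichment`, capped at 1, inside the gene set); DE genes get
  ±`de_effect` log2FC with N(0, 0.1) noise and adjusted p below 0.05;
  adjusted p-values are simulated directly (uniform below threshold for DE,
  Beta(2,1)-shaped above it for null) rather than refitting a DE model,
  which is out of scope. Paralogs of DE human genes are DE with the human
  magnitude, matching the human direction with probability
  `concordance_rate` independently per paralog.

Defaults (1000 genes × 50 sites, 25 + 25 diploids, background F = 0.05,
2% planted at F = 0.6, 5% missing genotypes, 30% DE at |log2FC| = 1.5, 60%
concordance, a 200-gene set with doubled significance) describe a mid-scale
two-morph study; larger problem sizes used in specific checks (e.g. 7500
genes for concordance recovery, so that ≥3000 paralog pairs are jointly DE)
are chosen so that sampling error is small against the tolerance being
checked.

**What passing tests do not show about real data:** sites are unlinked (no
LD, no haplotype structure), allele frequencies are exchangeable across
sites within a gene, missingness is independent of genotype, DE adjusted
p-values are not derived from counts, and fish-only DE (human gene null,
paralog DE) does not occur. Estimator recovery and calibration results
therefore validate the implementation, not the robustness of the procedure
to demographic history, linked selection or expression-model misfit.

## Numerical choices

- Negative F<sub>ST</sub> reported as-is (ranking stays monotone in the
  estimator).
- Dense ranks exclude missing values; an all-missing metric is an error.
- Normal-fit p-values are clipped into the open interval (0, 1); a
  zero-variance statistic table raises a dedicated error.
- Bootstrap percentile uses strict inequality; seeded `numpy.random`
  Generators everywhere; the pipeline seed is recorded in every output
  header and the run MANIFEST.
- The π-exclusion tie-break (smallest π, then gene id) makes outlier calls
  deterministic under ties.
- The 2×2 tests require positive row and column margins; empty gene sets,
  empty groups, and set/universe mismatches raise errors rather than
  returning silent NaNs.

## Known limitations

- F<sub>ST</sub> uses the allele-count (random-union-of-gametes) form of
  Weir–Cockerham; within-individual heterozygosity information is not used,
  so inbred samples would bias the estimate.
- Only two populations are supported for F<sub>ST</sub>/D<sub>XY</sub>,
  matching the cave-vs-surface design; no windowed (non-gene) scans.
- The selection-scan model itself (haplotype clustering, kinship) is
  consumed, never recomputed.
- The bootstrap null resamples genes uniformly; it does not preserve gene
  length, GC content or expression level, so confounding by those covariates
  is not addressed.
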