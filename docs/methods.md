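# Methods

`pgrscan` implements a population-level genome-wide association analysis
of plant growth response (PGR) to a plant-growth-promoting bacterium
(PGPB), of the kind used for *Arabidopsis thaliana* accessions sampled
as populations across a region: ordinal growth phenotypes from a
split-plot in-vitro assay, fixed-effects genotypic values and
heritability, a Spearman genome scan on structure-standardized
population allele frequencies, local-score (Lindley) QTL segmentation,
gene annotation, and a test for enrichment of association signals in
signatures of local adaptation. Every stage is exercisable on synthetic
data whose statistical structure matches what the analysis assumes.

## Phenotype side

**Design.** Two treatments (mock, inoculated) nested within two blocks;
each block x treatment cell holds 24 plates of 48 wells (8 columns x 6
rows). The last column of every plate carries the Col-0 reference
accession as an uninoculated micro-environmental control; the remaining
7 columns receive the test accessions (54 populations x 3 accessions =
162), each with 12 replicate wells per treatment (one column of six per
block). Column randomization is shared between the two treatments of a
block and redrawn between blocks. With these defaults the design holds
4,608 wells: 3,888 accession wells, 576 control wells and 144 unsown
wells (162 accessions fill 162 of the 168 assignable columns per cell).

**Scores.** Growth is scored visually on an ordinal 1-7 scale at 14, 21
and 28 days after inoculation (dai). The models treat scores as numeric
responses in ordinary least squares with all factors fixed — the
pragmatic convention for this kind of staged visual score. Two
covariates enter every model: germination day (recorded between 3 and 7
days after sowing) and the mean Col-0 score of the well's plate, which
absorbs plate effects within blocks.

**Genotypic values** are least-squares means from per-treatment OLS fits
of score on block + accession + covariates, evaluated at equal weight
over blocks and at the covariate means. Because accession is nested in
population, the accession factor carries the population term; the
population LS-mean is the equal-weight average of its member
accessions' LS-means — the same convention the LSMEANS machinery of
mixed-model packages uses for nested classifications.

**Split-plot ANOVA.** The full model contains block, treatment,
block x treatment, population, treatment x population,
accession(population), treatment x accession(population) and the two
covariates. Factors use sum-to-zero (deviation) coding so that each
term's drop-one-term (marginal) sum of squares tests the main effect
averaged over the other factors, and accession contrasts are explicitly
coded within population so that population and accession(population)
occupy disjoint column spaces. Following split-plot logic, block and
treatment are tested against the block x treatment mean square; all
other terms against the residual. With two blocks the whole-plot
stratum has a single degree of freedom, so whole-plot p-values are
honest but weak: no effect, however large, can reach p < 0.001 there.
Benjamini-Hochberg flags are attached across the table's terms.

**Variance components and H2.** Within one treatment, germination day
and the control-score covariate are regressed out first; block and
accession components are then estimated on the residuals by the
fitting-constants (Henderson III) method of moments, with both block
and accession treated as random and negative solutions truncated at
zero. An EM-REML refinement is available behind `reml=True` but is not
the default — on the near-balanced designs generated here the two
agree closely, and the MoM estimator is deterministic and fast enough
to permute. Broad-sense heritability is

    H2 = VF / (VF + VB/B + VR/N)

with VF the accession variance, VB the block variance, VR the residual
variance, B the blocks per treatment and N the number of blocks (both 2
under the default design). The printed source formula for the
denominator is ambiguous; this reading is the package default and the
alternative (VR divided by B*N) is available via
`heritability(..., reading="vr-over-bn")`. A permutation p-value
(accession labels shuffled within block; equivalently, covariate-free
residuals permuted within block) is provided with the add-one rule;
199 permutations by default.

**PGR and trade-off.** The growth-response index per unit and time
point is `(value_inoculated - value_mock) / value_mock * 100`. The
trade-off between response and growth under mock conditions is the
Spearman correlation between PGR and the mock genotypic value across
populations (or accessions).

## Genotype side

**Standardization.** Population allele frequencies are assumed to share
an across-population covariance Omega induced by common demographic
history. The package estimates (pi, Omega) by a deterministic method of
moments: pi_s is the across-population mean, and Omega averages outer
products of the scaled deviations (p_s - pi_s)/sqrt(pi_s(1-pi_s)). This
is a surrogate for the Bayesian hierarchical treatment of the same
quantities; precomputed standardized frequencies and XtX can be
ingested instead (`io.read_std_panel`) when fidelity to the original
machinery matters. Two numerical choices:

- *Neutral-set refinement.* Omega is re-estimated after dropping the
  top 1% of preliminary XtX, the usual "estimate the covariance on
  putatively neutral SNPs" practice. Without it, strongly
  differentiated trait-coupled SNPs leak into Omega along the trait
  direction and visibly deflate null scan p-values.
- *Ridge.* 1e-6 x trace/P is added to the diagonal before Cholesky
  factorization. Centering on the per-SNP mean makes the raw estimate
  exactly singular along the all-ones direction; since deviations are
  orthogonal to that direction, the ridge stabilizes the factorization
  without touching the standardized values.

Whitening uses the lower Cholesky factor L of Omega:
z_s = L^-1 (p_s - pi_s 1)/sqrt(pi_s(1-pi_s)); frequencies at the
boundary are clipped to [0.001, 0.999] first. XtX is the squared norm
of z_s, an Fst-analogue corrected for shared history; the upper-tail
mask takes the floor(q*S) largest values (q = 1% by default; at the
1,638,649 SNPs of a full A. thaliana panel that is 16,386 SNPs), with
cutoff ties resolved in genome order.

**Genome scan.** For each SNP, Spearman's rho between the standardized
frequencies and a population-level trait (PGR at each dai by default;
per-treatment genotypic values can be scanned instead). Mid-ranks
handle ties; p-values use the t approximation
t = rho sqrt((n-2)/(1-rho^2)) on n-2 df, which is adequate at n = 54;
for n <= 8 without ties the p-value is exact by enumeration of all n!
permutations (used mainly by the test suite's oracle comparisons).
Constant SNPs are flagged with rho = 0, p = 1 rather than dropped. QQ
diagnostics report the genomic-inflation factor (median chi-square
ratio) and the KS distance of the p-values from Uniform(0,1).

**Local score.** p-values become scores X_i = -log10(p_i) - xi with
xi = 2 (configurable; p floored at 1e-300), so unremarkable SNPs
contribute negatively, and the Lindley recursion
L_i = max(0, L_{i-1} + X_i) accumulates weak adjacent signals.
Per-chromosome significance thresholds come from the null distribution
of max L over a chromosome of independent Uniform(0,1) p-values —
defensible where linkage disequilibrium decays within ~50 bp, i.e.
faster than the SNP spacing — via B Monte-Carlo replicates (empirical
1-alpha quantile, the default) or a Gumbel fit to the same maxima; a
circular-shift resampling of the observed p-values
(`threshold_from_pvalues`) is provided for autocorrelated cases.
alpha = 0.05 per chromosome by default and recorded in the outputs.
Each positive excursion of L whose maximum exceeds the threshold is a
QTL segment; its "top SNPs" are the excursion's SNPs with L above the
threshold (an "up to the peak" membership rule is available), the
interval spans the top-SNP positions, and the peak sits at the first
argmax. No genome-wide multiplicity correction is applied beyond the
per-chromosome thresholds.

**Annotation.** Gene features are read from GFF3 (a minimal gene-level
reader; 1-based closed coordinates, strand ignored). A gene is a
candidate for a trait when its interval, extended by `flank_bp`
(default 0, given the short LD), intersects any of the trait's
segments. Interval statistics report mean and 5%/95% quantiles of
segment lengths. Candidate lists per time point are partitioned into
exact Venn classes (specific, pairwise-common, three-way-common).

**Enrichment.** Fold enrichment of top SNPs in the XtX upper tail is
FE = (n_a/n)/(N_a/N), with n the tail size, n_a the top SNPs inside
it, N_a all top SNPs and N all SNPs. Significance comes from circular
permutations: SNPs are laid on one circle in genome order (chromosomes
concatenated; per-chromosome rotation is available), the outlier mask
is rotated by a uniform random offset (rotating the top mask instead is
an equivalent option), and the one-sided p is
(1 + #{FE_null >= FE_obs})/(1 + n_perm) over 10,000 rotations by
default. Rotation preserves the spatial clustering of both masks, which
a label permutation would destroy.

## Synthetic data generator

The generator reproduces the statistical structure the analysis
assumes, at the study's design scale:

- **Structure:** compound-symmetry Omega = scale((1-rho)I + rho J) with
  defaults rho = 0.3, scale = 0.05 — an Fst-like drift magnitude with a
  shared component, the simplest covariance exhibiting the confounding
  the standardization corrects.
- **Frequencies:** per SNP, pi ~ Uniform(0.1, 0.9) and
  p ~ Normal(pi 1, pi(1-pi) Omega), truncated (not resampled) to
  [0.001, 0.999]; SNPs evenly spaced at 50 bp on 5 chromosomes.
  Panels record the true pi and a clipping flag so estimator-recovery
  tests can condition on them.
- **QTLs:** each injected locus spans 5 adjacent SNPs (a short-LD
  association peak) whose frequency deviations are proportional to a
  latent standard-normal population growth-response value g with slope
  `beta` (default 0.2, i.e. frequencies spanning roughly 0.1-0.9 across
  +/-2 sd of g). A fraction `xtx_overlap_frac` (default 0.5) of loci
  keep an inflated deviation amplitude (2.5x the panel's null-typical
  magnitude) and land in the XtX upper tail; the rest are rescaled to
  null-typical amplitude, which leaves rank correlations — hence scan
  detectability — intact while keeping their XtX unremarkable. This
  separates the two properties the enrichment test relates.
- **Phenotypes:** a latent Gaussian well value sums a per-dai baseline
  (3.2/4.0/4.4), block (sd 0.3), plate (sd 0.2), population (sd 0.5)
  and accession-within-population (sd 0.4) effects, a germination-day
  slope (-0.35 per day), and residual noise (sd 0.6); inoculated wells
  add a per-dai treatment effect (0/0.05/0.35 — growth promotion
  emerging at the last time point) plus a genotype-dependent response
  `-0.5 x genotypic effect + 0.4 x g`, which generates the negative
  response/growth trade-off and couples the response to the injected
  QTL frequencies. The latent value is cut at fixed thresholds
  1.5, 2.5, ..., 6.5 into scores 1-7. Control wells are never
  inoculated and only feed the plate control-mean covariate.

What the generator does **not** emulate: real LD and recombination
(SNP signals are injected as independent clusters, not coalescent
haplotypes), binomial sampling noise on allele frequencies (input
frequencies are taken as given, as when retrieved from a prior panel),
ordinal rater behavior beyond deterministic thresholding, germination
failure (the full design's 576 control wells are all phenotyped), and
the posterior-vs-point distinction of the hierarchical standardization
machinery. Passing tests therefore certify the pipeline's statistical
behavior under its own assumptions, not robustness to those real-data
features.

## Verification strategy and problem sizes

The test suite checks every algorithmic core against an independent
oracle (Lindley maxima vs O(n^2) contiguous-segment sums up to length
200; exact Spearman p vs full 6! enumeration; gene overlap vs an
all-pairs scan; circular-permutation p vs exhaustive offsets at
N <= 20), calibrates every stochastic procedure under its null
(chromosome-wide exceedance over 1,000 null chromosomes of 5,000 SNPs;
split-plot treatment type-I error over 800 simulated designs; scan
p-value uniformity on a 10,000-SNP neutral panel; enrichment p over
400 independent-mask datasets; H2 permutation p over 120 null
datasets), and verifies recovery at the generator's default effect
sizes (variance components within 15% relative over 200 replicates;
>= 80% of injected QTL loci covered by called segments and a negative
trade-off at p < 0.01 in a full 54-population run). The acceptance
script runs the full pipeline at the study's design conditions with a
20,000-SNP x 54-population panel — the package's scaled stand-in for
the undeposited 1.64M-SNP panel — and recomputes all headline
quantities from scratch.

## Known limitations

- The whole-plot stratum of the default two-block design has one
  degree of freedom; block and treatment tests are valid but
  low-powered, and published-scale p-values for those terms are not
  reachable under the literal stratum rule.
- The method-of-moments standardization identifies Omega only up to
  the mean-centering projection (rank P-1); this is self-consistent
  for whitening but differs from the hierarchical model's posterior
  standardization.
- Ordinal scores are modeled linearly; heritability and LS-means are
  on the observed score scale, and discretization mildly attenuates
  large effects.
- The t approximation for Spearman p-values is biased under heavy
  ties; the scan flags constant SNPs but does not switch to exact
  enumeration at scan scale.
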