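# Methods

## The screening model

The assay underlying the pipeline serially digests genomic DNA with the
isoschizomers SmaI (methylation-sensitive, blunt cut CCC^GGG) and XmaI
(methylation-insensitive), amplifies the methylated fraction, and
cohybridizes two individuals' products on a two-color array.  The unit of
analysis is the *restriction interval*: the span between the blunt-cut
positions of two consecutive CCCGGG sites on a contig.  We use 0-based
half-open coordinates; an interval runs cut-to-cut, so its length is the
difference of cut positions and its two flanking motifs protrude 3 bp on
either side of each boundary.  The motif is palindromic, so a single-strand
scan is complete; motifs containing N never match, while intervals spanning
N runs are allowed (treating assembly gaps as interval-splitting would
silently fragment contigs).  The informative length range is 60–1500 bp,
both bounds inclusive.

Candidate calling uses two tissues from different germ layers (PBL,
mesoderm; HF, ectoderm) across four individual-pair comparisons.  A locus
set before gastrulation shows the *same* interindividual contrast in both
tissues; one set after lineage separation does not.  The primary-hit rule
(probe-average ratio > 1.8 or < 0.556, median probe P < 0.0002, both
tissues) is applied with strict inequalities exactly as the thresholds are
printed, and we additionally require the two tissues to deviate on the same
side of 1 — "concordant" differences; without that requirement a locus up
2× in PBL and down 2× in HF would pass.  The concordance filter then
requires the ratio of tissue ratios R_PBL/R_HF to stay strictly inside
(0.445, 2.25) in *all four* comparisons.  The bound 2.25 is defined by its
extreme admissible configuration — 1.5 in one tissue, 0.667 in the other —
whose raw quotient is 2.2489; we therefore round the ratio of ratios to
3 significant figures before the strict comparison, so that configuration
itself is excluded (2.25 is not < 2.25) and the bound arithmetic is exact
at the printed precision.  "Probe-average ratio" is the arithmetic mean of
linear per-probe ratios (a geometric-mean mode is available); the median of
an even number of P values is the mean of the central two.  Intervals
missing a tissue or a comparison are disqualified, never imputed.

## Variant exclusion

A restriction screen confounds methylation with genotype.  Three hazards
are annotated per interval: a catalogued SNP inside either flanking CCCGGG
motif (*disrupts*), a SNP whose alternate allele creates a CCCGGG match
within the interval body that the reference lacks (*creates*; only the
11-bp window around the variant can gain a motif), and ≥1 bp overlap with a
CNV or segmental-duplication region.  "Disrupts" is positional — any SNP in
the motif flags the interval whether or not the specific allele destroys
the site — which is the conservative, track-style reading; "within a CNV"
defaults to any-overlap with full containment switchable.  The cascade
removes SNP-flagged candidates first, then structurally flagged ones, and
finally re-adds an explicit allow-list (candidates whose methylation
variation was validated independently of the flags).  It is idempotent and
order-deterministic.  Enrichment of a flag among screen hits uses Pearson's
chi-square on the 2×2 hits-vs-background × flagged-vs-not table, 1 df, no
continuity correction by default.

## Genomic context

Signed distances run from interval midpoint to annotation midpoint
(floor((start+end)/2); a nearest-edge mode is available), within a ±3000 bp
window, both ends inclusive.  Intervals are unstranded, so
upstream/downstream is defined by genome coordinate (negative = lower
coordinate); positional asymmetry between candidate and control sets is
tested by one-way ANOVA on the signed distances — the literal reading of an
ANOVA-based comparison — with a binomial upstream/downstream split as a
secondary statistic.

## Validation statistics

All correlation analyses average replicate measurements per individual
first.  Twin concordance correlates co-twin values with pair-member order
randomized under a seed (member order is arbitrary; a double-entry mode is
available), and compares this against the correlation between technical
replicate measurements.  The *nonshared variance fraction* is defined as
1 − r clipped to [0, 1]; this is a declared operationalization, not an
inferred variance decomposition.  Genotype association reports per-genotype
means, one-way ANOVA F and P, and R² = SS_between/SS_total.

## Cohort model

Percent methylation is arcsine transformed, y = arcsin√(p/100) — the
standard variance stabilizer for proportions (the alternative reading
arcsin(p) is not variance-stabilizing and was not adopted).  The model

    y ~ locus_type + season:locus_type + (1 | individual) + (1 | locus)

is fitted by REML (statsmodels MixedLM, variance-components formulation;
locus is nested in locus type by construction since each locus has one
type).  Parameterizing season within locus type makes the two season
coefficients directly the within-type rainy−dry contrasts; the overall
season test is the joint Wald test of both coefficients and the a-priori
season×locus-type test is the Wald test of their difference.  Effects are
reported on the arcsine scale and back-transformed to percentage points as
the difference of back-transformed season means evaluated at the type's
dry-season mean; per-locus descriptive contrasts (with Welch t P values)
accompany the pooled fit.  Non-convergence raises with diagnostics; the
degenerate zero-variance input returns an exact null fit.  "Sequential
Bonferroni" in the normality screen is Holm's step-down procedure applied
to the per-(locus × season) Shapiro–Wilk P values at family α = 0.05.

The season×year interaction screen adds year and season×year fixed terms to
the same mixed model and jointly Wald-tests the interaction; years lacking
one season are flagged and excluded from the fit rather than silently
dropped.  Leave-one-year-out refits identify the year whose removal
maximizes the remaining interaction P — automating the identification of a
year with aberrant seasonality.

Kinship for twin-panel verification is estimated per pair from observed
identity-by-state counts (N0, N1, N2) over the SNP panel.  Expected IBS
given 0/1/2 alleles shared IBD follows from Hardy–Weinberg allele
frequencies; (p0, p1, p2) is recovered by least squares constrained to the
probability simplex (SLSQP), and φ = p₁/4 + p₂/2.  Monomorphic markers are
excluded; at least 10 co-typed polymorphic markers are required.  For
duplicate genotypes the estimate is exactly (0, 0, 1), φ = 0.5.  The
simplex constraint makes φ slightly conservative for truly unrelated pairs
(truth on a vertex; measured mean φ ≈ 0.035 at 48 markers, MAF 0.3), a
known property of constrained moment estimators at boundary truth.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (config, seed) and emit ground truth
sufficient to score every downstream call.

* **Genome**: random background with CCCGGG suppressed and motifs planted
  to realize requested interval lengths, including sub-60 bp and >1500 bp
  decoys.  Spurious motifs are destroyed by substituting an A (CCCGGG
  contains no A, so scrubbing cannot create new motifs and terminates).
* **Arrays**: default 2.3 probes/interval (1 + Poisson(1.3), minimum 1,
  matching the 43,222-probe / 19,187-interval array density), lognormal
  per-probe ratio noise (sd 0.15 on the log scale), a dye swap on the HF
  hybridizations, and per-probe P from a two-sample noise model — the
  two-sided normal tail of the observed log ratio against the known probe
  noise — so null probes have uniform P.  Variable loci carry a single
  contrasted comparison with linear contrast 3.0 by default (2.5 in the
  recall benchmark); systemic and artifact loci express it in both tissues,
  tissue-specific loci in one.  Class proportions default to
  tissue-specific ≈ 6× systemic, the imbalance characteristic of real
  two-tissue screens.  Not emulated: spatial/array artifacts, intensity-
  dependent (loess-type) bias, probe-sequence effects — so passing tests
  show threshold logic and operating characteristics, not robustness to
  normalization failures.
* **Cohorts**: locus baselines N(50, 8²), individual effects N(0, 5²),
  residual N(0, 3²) (percentage points), rainy-season increments
  {PAX8: 12, ZFYVE28: 12, BOLA3/FLJ20433/SLITRK1: 6, controls: 0},
  n = 25/season over four years, values clipped to [0, 100] with a logged
  count (warning above 1%).  A beta-distributed baseline option mimics the
  wide, U-shaped interindividual ranges real MEs show.  Ages are
  N(8.9, 1.0) years.  Not emulated: year-specific recruitment imbalance,
  batch effects, locus-locus correlation of stochastic state.
* **Twins**: bivariate-normal co-twin latents (biological sd 10) at a
  configurable per-locus intra-pair correlation (defaults 0 at BOLA3 and
  FLJ20433, 0.5 at PAX8), technical replicate sd 2 — biological variation
  well above measurement error, as in real twin panels.
* **Genotypes**: 48 Hardy–Weinberg SNPs at MAF 0.3; MZ pairs duplicate,
  with an error model that flips a genotype to one of the other two, so
  expected discordance per pair = markers × error rate.

## Numerical choices

* Ratio-of-ratios rounded to 3 significant figures before strict bound
  comparison (see above); all other threshold comparisons strict on raw
  floats.
* REML fits use lbfgs with a Powell fallback; the convergence flag is
  checked and failure raises.  Wald tests use the fitted fixed-effect
  covariance.
* The IBD simplex projection solves the constrained least-squares problem
  directly rather than clipping a sequential moment estimate — smaller
  boundary bias.
* Degenerate inputs: zero-variance responses give exact null fits
  (season model) or flagged NaN (correlations); empty annotation sets give
  all-false flags; groups below minimum size are skipped with warnings.

## Problem sizes used in the test suite

The operating-characteristic checks run at the design scale of the study
they emulate: null false-positive-rate and recall benchmarks on
19,000-interval arrays over 20 seeds; season-model type-I error over 500
null cohort replicates and power over 50; estimator bias over 200
replicates; kinship calibration over 500 pairs per relationship.  The
digest oracle comparison uses a 1 Mb random sequence.

## Known limitations

* Exact reproduction of the original screen's genome-wide interval count
  and 107-candidate list would require the original genome build, SNP/CNV
  tracks, and array data, plus the (unspecified) per-probe P-value method
  of the original feature extraction; these are supported mechanically via
  the file adapters but not asserted.
* Enrichment P values depend on the choice of background set (all
  informative intervals vs on-array intervals); both are supported, and
  agreement with historical values is order-of-magnitude only.
* The per-probe P is consumed as input; the package takes no position on
  how a scanner derives it.
* The upstream/downstream asymmetry statistic is coordinate-based;
  intervals are unstranded, so biological orientation is not resolved.
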