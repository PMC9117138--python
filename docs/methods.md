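# Methods

## The generative model behind the synthetic cohort

The synthetic cohort emulates a large whole-genome-sequenced
parent–offspring trio cohort at desk scale.  For trio *i*:

- **Ages.** Maternal age at birth ~ Normal(30, 4) clipped to [16, 55];
  paternal age = maternal age + 3 + Normal(0, 2.5).  This centres the
  cohort at paternal/maternal medians of 33/30 years and induces the
  strong father–mother age correlation real cohorts show (which is what
  makes the maternal slope the harder parameter to estimate).
- **Counts.** De novo SNV count Y ~ NB(μ, θ) with
  μ = β₀ + β_pat·fa + β_mat·ma, defaults β = (20, 1.28, 0.35), and
  Var = μ + μ²/θ.  Indel counts follow the same form with defaults
  (2.6, 0.071, 0.019), giving a median of ~5 per child.
- **Dispersion calibration.** θ defaults to 240.  This single choice
  fixes two cohort-level facts simultaneously: Var(Y)/mean(Y) ≈ 2, and
  ~70 % of the super-Poisson (explainable) count variance is driven by
  parental age — with the age spread above, Var(μ) ≈ 52 while the NB
  component E[μ²]/θ ≈ 22.  Both facts are properties a large real trio
  cohort exhibits; the calibration was fixed when the generator was
  designed and all recovery tests are run against it.
- **Parent of origin.** Each SNV is paternal with probability
  0.77 + 0.0017·(fa − 33), clipped to [0, 1]; the base fraction and the
  additive per-year trend match the phased fractions large cohorts
  report.
- **Spectra.** Each mutation draws a signature from its trio's
  etiology-specific mixture and then a 96-channel class from that
  signature.  The default germline mixture is 25 % a CpG-deamination-
  like spiky C>T profile and 75 % a flat clock-like profile.
- **Genome.** 22 autosomes + X with lengths ~1/100 of the human genome;
  positions uniform per chromosome (optionally outside masks).
  Trinucleotide context is carried as a per-mutation label, not derived
  from a FASTA, so no reference needs to be bundled.
- **Read support.** Child depth ~ Poisson(35) conditioned > 20; alt
  reads ~ Binomial(depth, VAF).  For true heterozygous calls
  (VAF = 0.5) the allele balance is resampled into (0.3, 0.7).  The
  generator emulates *post-calling* DNM tables — variant callers do not
  emit marginal-depth or extreme-allele-balance de novo genotypes — so
  a clean cohort passes the depth/allele-balance filters at ≥ 99 %,
  which is also what makes the filter-loss bound meaningful.  Mosaic
  calls are not conditioned.

### Injections

- *Repair defect*: the trio's paternal count is multiplied by a fold;
  extra mutations carry a chosen signature and paternal truth labels.
- *Chemotherapy-like*: a fixed number of extra paternal mutations drawn
  from an exposure signature.
- *Post-zygotic*: extra mutations with ~50/50 parental truth and
  underlying VAF ~ Uniform(0.30, 0.45) — below the heterozygous 0.5 but
  mostly inside the caller's allele-balance window, so they survive
  filtering and show up as a low-VAF shift, as real mosaic calls do.
- *Loss of transmitted allele (LOTA)*: n pseudo-calls confined to one
  region of one chromosome, with the implicated parent's binned het/hom
  ratio depressed to 15 % of its expectation inside the region.  This
  reproduces the known false-positive mode in which a parental somatic
  blood deletion unmasks inherited alleles as apparent DNMs.

What the generator does **not** emulate: sequencing reads themselves
(read evidence is an abstract observation table), mapping or calling
error beyond the per-site error-rate column, relatedness structure,
locus-specific mutation-rate variation, and real trinucleotide genome
composition.  Passing tests therefore demonstrate the statistical
machinery, not robustness to raw-data pathologies.

## Filters

Both filter sets apply every printed inequality strictly as written
(">" excludes equality; the child allele-balance window (0.3, 0.7)
excludes its endpoints).  The 20-bp SNV cluster rule is inclusive
(|Δpos| ≤ 20), per child, per chromosome, and transitive — all members
of a chained cluster are removed; indels are exempt.  Mask overlap is
point-in-interval against 0-based half-open BED intervals.  A record
missing a required field fails `incomplete-record` and is never
silently passed; in the eleven-rule follow-up set, a rule whose input
column is absent is recorded `not-evaluable` and the call removed
(conservative).  The strand-bias rule accepts a precomputed Fisher p or
builds the 2×2 as forward/reverse alt reads, child vs both parents
combined.  The per-site error rule keeps a call when a one-sided
binomial test shows the child's alt fraction exceeds the supplied site
error rate (level configurable, default 0.05).

## Phasing

A site within 500 bp (inclusive) is informative when the child is
heterozygous and each child allele is attributable to exactly one
parent; sites heterozygous in child and both parents are excluded.
Reads carrying the DNM alt allele vote through the site allele they
co-carry; a DNM is phased only when all votes point to one parent
(a single supporting read suffices, configurable), mixed votes are a
conflict, and no co-covering read is no-data.  A read pair counts once
per site even when both mates span both loci.  The paternal fraction is
regressed on paternal age with an identity-link binomial ML fit
(constrained to (0,1)); the identity link mirrors the additive
per-year interpretation, and a logit link is available.

## The identity-link negative-binomial fit

The identity link is not canonical, so the mean must be kept positive
explicitly.  The fit is constrained maximum likelihood: least-squares
initialization pulled into the feasible cone, inner SLSQP over the
coefficients with the linear predictor constrained ≥ 1e−8, and the
dispersion θ profiled on an outer bounded one-dimensional
minimization of the profile likelihood (Var = μ + μ²/θ everywhere).
Standard errors come from finite differences of the analytic score
(observed information); Wald p-values are two-sided normal.  The null
model for McFadden's pseudo-R² is the intercept-only NB with its own
profiled dispersion (its ML mean is exactly ȳ because the identity-link
weights are constant under a constant mean).  Leverages are the
diagonal of the weighted hat matrix W^½X(XᵀWX)⁻¹XᵀW^½ with W = 1/Var
(the identity link has unit mean derivative).  The implementation is
checked in the tests against a brute-force likelihood grid on tiny
instances and against an independent IRLS implementation at fixed
dispersion.

Degenerate inputs: a constant response (e.g. all-zero phased maternal
counts) is returned as a flagged boundary fit rather than an error;
constant covariate columns (no carriers, no hypermutators) are dropped
and reported as inestimable, since they make the information matrix
singular.

## Hypermutator detection

Every report carries the studentized residual — the Pearson residual
(y − μ̂)/√(μ̂ + μ̂²/θ̂) scaled by √(1 − leverage) — and its two-sided
t p-value with df = N − 3, the conventional studentized-outlier
construction for regression scans.  The *flagging* rule, however,
defaults to the exact two-sided NB tail probability of the observed
count under the fitted model (doubled smaller tail), Bonferroni
corrected at 0.05/N where N counts the analysed children after
artifact exclusions.  The reason is distributional: count
distributions at these means are right-skewed, and at Bonferroni-scale
thresholds (~1e−5) normal-approximation residual tests over-reject
several-fold — measured family-wise false-positive rates on null
5,000-trio cohorts are ~16 % for the Pearson-residual t rule and ~9 %
for its deviance-residual variant, versus ~1 % for the exact tail.
The exact rule restores the family-wise guarantee with no measurable
power loss at two-fold hypermutation and above (fold-4 power 100 %,
fold-2 ≈ 70 % at 5,000 trios).  `pvalue_method="t"` reproduces the
residual-based rule exactly.  Detection is iterative: flagged children
are screened for artifacts, identified artifacts are excluded, and the
model refit, one round per exclusion update, until stable.

**Artifact screen.**  Sub-flag *clustered*: > 50 % of a child's DNMs on
one chromosome and concentrated within one 100-kb window (10 Mb at the
1/100 genome scale), found by a sliding-window maximum; the implicated
region is the 2.5–97.5 % trimmed extent of the in-window calls, which
keeps a stray background call from stretching the region into
normal-heterozygosity territory.  Sub-flag *parental LOH*: a parent's
het/hom ratio in the implicated region below 50 % of that parent's
genome-wide ratio.  Both sub-flags are reported separately; the
artifact verdict requires both.  All thresholds are arguments.

**Characterization.**  Per mutation type (six SNV classes + indel): an
exact two-sided Poisson test (minimum-likelihood method: the p-value
sums all outcomes no more likely than the observed one) of the child's
count against the cohort per-child mean, with Bonferroni over
(flagged children × 7) tests.  Phase bias: two-sided binomial test of
the maternal count among phased DNMs against the cohort phased
fraction (≈ 0.77 under the default configuration) — the cohort
expectation, not 0.5, is the relevant null for "more paternal than
expected".  VAF shift: two-sided binomial test of the number of
low-VAF (< 0.4) SNVs against the cohort proportion.  Strand bias:
two-sided Poisson test of transcribed-strand counts against half the
stranded total.

The excess of a confirmed hypermutator is its observed count minus the
cohort median; the fold is observed/median to one decimal.  The
absolute disease-risk arithmetic scales a 1/300 baseline risk of a
DNM-caused severe developmental disorder by the fold (a fourfold child
reaches ~1.3 %).

## Signatures

Channels follow the conventional alphabetical catalogue layout (six
pyrimidine-strand classes × 16 flanks, `A[C>A]A … T[T>G]T`);
purine-reference substitutions are folded by reverse complement, and
spectrum totals conserve input counts (ambiguous contexts are excluded
with a tally).  The bundled catalogue is **synthetic** — deterministic
unit-sum profiles shaped like well-known processes (CpG deamination,
flat clock-like, platinum-adduct-like, alkylating-like, two
repair-defect shapes) — because the published somatic catalogues are
external data; any user catalogue in the same TSV layout is accepted.

Refitting solves nonnegative least squares against the catalogue and
reports exposures as counts and proportions plus the residual norm.
With a deliberately overlapping catalogue, weak collinear signatures
absorb mixture mass; the sparsity pruning the refitter provides
(drop exposures below a threshold, refit, iterate) is therefore part of
the intended operating procedure, and the recovery tests use it at
threshold 0.05.

De-novo extraction is Frobenius NMF by multiplicative updates with
seeded restarts; the objective is asserted non-increasing on every
update.  Per rank the best-objective restart is kept, and stability is
the mean Hungarian-matched cosine of all restarts against the best run;
rank choice is left to the caller via the stability/error report, since
rank selection is a judgement call in practice.  The paternal/maternal
spectra comparison tests each of the six classes in one parent's set
against the proportion observed in the other; because the choice of
null side is arbitrary the test is run in both directions and the
symmetric average reported (both one-sided constructions are also
returned).  Note this construction treats the null proportion as fixed,
ignoring its own sampling noise — with two independent samples of
similar size it is anti-conservative by up to √2 on the z-scale, which
is acceptable for the large effects it is used on here.

## Variance decomposition

Counts are Poisson-noisy reads of an underlying rate, so only
Var(Y) − Ȳ is explainable.  The Poisson-corrected fraction is
F = R² · Var(Y)/(Var(Y) − Ȳ).  The R² entering this formula defaults
to the explained-variance ratio Var(fitted)/Var(Y) — the quantity an
OLS R² estimates — because a likelihood-ratio pseudo-R² (McFadden) is
not commensurable with variance fractions: on cohorts with
Var ≈ 2·mean it sits near 0.06 regardless of how much rate variance
the covariates explain, and plugging it into the correction cannot
recover a configured explainable share.  McFadden's value is still
computed and reported per model, and `r2_method="mcfadden"` switches
the formula input.  A published variant of the correction formula,
written with (1 − Ȳ) in the numerator, is dimensionally inconsistent
(negative whenever Ȳ > 1) and is exposed only behind
`formula="printed"` for comparison.

The three nested models are: parental ages; + per-member data-quality
covariates (mean depth, proportion aligned, SNV counts, median DNM VAF,
median caller quality; standardized, collinear columns dropped with a
warning); + the hypermutation-excess covariate (observed minus cohort
median for flagged children, zero otherwise).  Component increments are
successive F differences and telescope to the full-model F exactly;
the residual fraction is 1 − F_full.  Uncertainty is a case bootstrap
over trios (percentile interval; failing replicates dropped and
counted).  The hypermutation component scales as Σ excess²/n, so on a
desk-scale cohort a handful of injected outliers claim a far larger
share than the same outlier *rate* does at ten times the cohort size —
the acceptance report therefore also prints the clean-cohort age
share (~70 %, the generative truth).

The small-cohort instability experiment subsamples 78 trios without
replacement, fits OLS of count on paternal age, applies the OLS form of
the Poisson correction, and summarizes the estimate distribution
(median, sd, percentile interval, share ≥ 0.95); its point is that
78-family estimates of the age-explained share are too wide to
distinguish ~70 % from ~95 %.

## Exposure analysis

A parent is *eligible* when any well-formed record predates the child's
birth year by ≥ 2 years (a year-resolution proxy for conception);
cancer-before-conception requires a 'C'-prefix or 'Z85'-prefix code at
that lag, and 'Z511' flags antineoplastic chemotherapy.  Malformed
codes are tallied and ignored; classification is order-independent.
Group comparisons use the two-sided Wilcoxon rank-sum on residuals from
the full NB model (ages + quality + hypermutation status).  The matched
design draws 20 controls per case with replacement, matched on both
parental ages — exact year first, widening to ±1 then ±2 years; cases
with no control in the widest caliper are dropped and counted.  The
hypermutation enrichment test is the exact two-sided Fisher test, and
agrees with direct hypergeometric enumeration on all small tables by
test.  A code-based classifier cannot see exposures that never
generated a qualifying record (the known sensitivity limit of
record-based exposure ascertainment).

## Problem sizes

The test suite exercises recovery at 5,000 trios (50 replicates for
coefficient recovery and the variance share; 200 null and 100 injected
replicates for detector error rates), record-level cohorts of 120–800
trios for phasing, screening and characterization, 10,000-replicate
resampling, and 20-restart NMF on 24-sample panels — sizes at which
every Monte-Carlo bound in the tests has comfortable margin while the
whole suite runs in about a minute.  The analysis drivers use a
1,500-trio record-level cohort.

## Known limitations

- The exact NB tail used for flagging conditions on the estimated
  (β, θ); at a few thousand trios the estimation noise is negligible,
  but on very small cohorts the t-based reporting fields are the safer
  summary.
- NNLS exposures have no uncertainty quantification; refits of spectra
  with a few hundred mutations should be read qualitatively.
- The phased-spectra binomial comparison is anti-conservative under the
  null (above).
- The synthetic catalogue's profiles are caricatures; cosine matches
  against it say nothing about real catalogue deconvolution ambiguity.
- X-chromosome filtering is implemented but the generator places
  relatively few mutations on X, so those rules are exercised mainly by
  targeted unit tests.
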