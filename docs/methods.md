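# Methods

## The score

`adgrs` builds a probability-scale Alzheimer's genetic risk score (GRS)
from a table of risk loci with published per-allele log odds ratios.  For
person *i* with effect-allele dosages *d<sub>ij</sub>* and weights
*β<sub>j</sub>*:

1. weighted allele sum  *s<sub>i</sub> = Σ<sub>j</sub> d<sub>ij</sub> β<sub>j</sub>*;
2. odds  *q<sub>i</sub> = π · exp(s<sub>i</sub>)*, where *π* is an assumed
   disease prevalence (default 0.10 for dementia in an age-65+ cohort);
3. probability  *p<sub>i</sub> = q<sub>i</sub> / (1 + q<sub>i</sub>)*.

The probability scale makes the score interpretable as "the probability of
dementia predicted by the score loci alone", at the cost of a nonlinear
dependence on the weighted sum.  The default weight table carries APOE
(coded as the ε4 allele count via rs429358) plus nine further loci (BIN1,
CLU, ABCA7, CR1, PICALM, MS4A6A, CD33, MS4A4E, CD2AP).  The shipped odds
ratios are approximate stand-ins at the published ranking; any delimited
weight file with locus/allele/OR columns can replace them.  An
APOE-excluded score variant drops the flagged APOE loci from the sum; by
construction the full weighted sum is exactly the APOE-only plus
APOE-excluded sums.

Genotype harmonisation follows standard polygenic-score practice: the
effect allele is matched to VCF REF/ALT directly or via reverse
complement (strand flip); strand-ambiguous palindromic (A/T, C/G) sites
are excluded by default with a force-accept flag; unresolvable sites are
reported, never silently scored.  Missing dosages are mean-imputed per
locus by default (keeps panels balanced); a strict mode drops the person.

APOE ε4 carriage is called from rs429358 alone by default, since carrier
analyses need only "at least one ε4 allele".  A strict mode flags the
unphased rs429358/rs7412 double heterozygote as indeterminate, because the
two phase-consistent haplotype assignments (ε2/ε4 vs the rare ε1/ε3)
cannot be distinguished without phase.

## The synthetic cohort

The simulator generates the structure the downstream models assume, so the
whole pipeline is testable without restricted data:

* **Panel shape.** Up to three biennial waves (2006/2008/2010); everyone
  is observed at wave 1 (the emulated cohort conditions on contributing at
  least one assessment); later waves apply absorbing death (default 0.034
  per transition) and transient nonresponse (0.022), chosen to match the
  observation-level exclusion fractions of the emulated sample accounting.
* **Demographics.** Two race groups (13.2% NHB), truncated-normal wave-1
  ages on [50, 95] (NHW mean 74.0, SD 7.08; NHB 71.63, SD 6.62), male
  proportions 0.433/0.377.
* **Genotypes.** Independent Hardy–Weinberg dosages, binomial(2, f), with
  race-specific frequencies.  Frequencies are *calibrated*: a single
  logit-scale shift, signed by each locus's direction of risk, is applied
  to all score loci from base frequencies (APOE starts at the printed ε4
  frequencies 0.285/0.415) and solved by Brent's method so that the exact
  population mean probability-scale score — computed by enumerating the
  3^10 joint dosage distribution, no Monte Carlo — equals the target
  (0.092 NHW, 0.122 NHB).  The sign-aware shift makes the objective
  strictly monotone, so the root is unique.  APOE is included in the
  shift: with the stand-in weights, pinning APOE at its printed frequency
  makes the NHW target arithmetically unreachable within frequency bounds
  [0.01, 0.99], so the calibrated APOE frequency lands below the printed
  value.  A related consequence of the stand-in weights is that the
  simulated score's dispersion exceeds the dispersion printed for the real
  cohort; recovery tests therefore always compare against the simulator's
  own generating values, never against published standard errors.
* **Dementia outcome.** Log odds linear in the probability-scale GRS with
  race-specific slope ln(OR)/0.1 (defaults OR 2.22 NHW, 1.33 NHB per 0.1
  units), anchored so a 70-year-old man at GRS 0.1 has the race-specific
  baseline probability (1.1% NHW, 3.3% NHB), plus age (0.11/yr on the
  log-odds scale, roughly doubling every six years), sex (−0.05 male) and
  year (0.02/yr) terms.  `binary` mode draws a Bernoulli outcome (cleanly
  identified, used for parameter recovery); `fractional` mode stores a
  logit-normal perturbation of the model probability (σ = 0.5), a
  simulator convention for a continuous probability score, not a claim
  about any real instrument.
* **Memory outcome.** Linear in GRS per 0.1 (defaults −0.07 SD NHW, −0.01
  NHB), race main effect −0.49 SD, age slope −0.027/yr (the cross-
  sectional gradient in the emulated cohort's descriptives), Gaussian
  noise SD 0.95, then divided by the realized wave-1 SD — mirroring the
  convention of standardizing by a fixed baseline-year SD.  The noise SD
  is set so the wave-1 SD is ≈1 and generating slopes survive
  standardization approximately unchanged.

What passing tests show: the estimators recover the effects this
generator encodes under correct specification, independence between loci,
and genotype-independent mortality.  They do not show robustness to
linkage disequilibrium, population stratification, differential survival
by genotype, or outcome-measurement structure in real cohorts.

## Estimation

Pooled logistic regression on stacked person-waves for dementia
(quasi-binomial score equations, so binary and fractional outcomes fit
identically at the point-estimate level), OLS for memory.  Inference uses
the cluster-robust sandwich with persons as clusters — bread the inverse
expected information, meat the sum over persons of summed score outer
products — CR0 by default (no small-sample correction; cluster counts in
the intended applications are in the thousands), CR1 optional.  Wald
z-inference throughout.  Every model adjusts for age (years, centered at
70 purely for numerics; centering leaves exposure effects unchanged),
gender, and assessment year; race main effects enter whenever both races
are in the fit.  Effects are reported per 0.1 score units: exp(0.1·b) as
an odds ratio for dementia, 0.1·b in SD units for memory.  Degenerate
adjustment columns (e.g. year in a single-wave fit) are dropped rather
than left to alias the intercept; genuinely collinear designs raise with
the offending columns named.  Interaction tests are cluster-robust Wald
z-tests of the exposure×factor coefficient.

Numerical choices: IRLS to tolerance 1e-10, max 100 iterations;
separation or non-convergence surfaces as a `NotEstimableError` /
`converged=False`, never silent; strata with no outcome variation refuse
to fit; quintile ties share the lower bin and an all-equal input is an
error.

## Absolute risk

`shift_probability` converts a baseline probability to odds, multiplies
by OR^(Δ/0.1), and converts back; `risk_difference` is the resulting
percentage-point change.  This printed-number route exists so the
relative-vs-additive reconciliation is reproducible from published
quantities alone; `predict_from_fit` provides the model-based route, and
the two agree by construction (tested to 1e-6).  The conversion makes the
core epidemiological point explicit: with a 1.10% baseline an OR of 2.22
per 0.1 units moves a +0.037 shift to ≈1.47%, while with a 3.30% baseline
an OR of 1.33 moves it to ≈3.65% — both ≈0.4 percentage points.

## Sample-flow accounting

Exclusion cascades apply ordered rules (pandas query expressions or
predicates, observation- or person-scoped); an observation is charged to
the first rule it fails, removals plus survivors always sum exactly to
the start count, and percentages are recomputed from integers at one
decimal rather than stored.

## Problem sizes used in the checks

Parameter recovery runs 200 replicates at the emulated cohort's own size
(7,690 persons × 3 waves), asserting mean log-OR recovery within
Monte-Carlo error, CI coverage in [92%, 98%], and a sub-unity race
interaction OR in >90% of replicates.  Null interaction calibration runs
500 replicates at 5,000 persons: replicate size is set where the Wald
test's asymptotics hold — at materially smaller cohorts the NHB stratum
carries only a few dozen events and the cluster-robust Wald interaction
test genuinely over-rejects, a finite-sample property of the test rather
than a defect, while the calibration claim is about its asymptotic level.
Simulator calibration is checked on 20,000 sampled genotypes per race
against the exact enumerated mean (tolerance 0.005).

## Known limitations

Stand-in default weights (replaceable); linkage equilibrium; no
principal-component adjustment for population structure; mortality
independent of genotype by default, so survival-bias scenarios are a
configuration exercise, not a calibrated replication; no GEE working
correlations, mixed models, or survival models; the fractional-outcome
likelihood is a quasi-likelihood reading of "logistic regression on a
probability score", one of several defensible choices.
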