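# Methods

`trialemu` emulates, end to end and on fully synthetic data, an in-silico
superiority trial of coronary artery bypass grafting (CABG) versus complex
percutaneous coronary intervention (PCI) in hospitalized heart-failure
patients, as such trials are emulated from English Hospital Episode
Statistics (HES)-style administrative data linked to a death registry. This
note documents the generative model, the analysis procedures, the numerical
choices, and what the synthetic validation does and does not establish.

## The synthetic population

Each simulated patient carries baseline covariates (age, sex, ethnicity, a
deprivation score, and seven binary comorbidities), a latent standard-normal
frailty `U`, and a region. Defaults approximate an elderly revascularized
heart-failure population: age ~ N(70, 10) years, 76% male, deprivation
lognormal with median ≈ 18, comorbidity prevalences between 2% (prior
stroke) and 79% (hypertension). The deprivation score is missing completely
at random in 1.4% of patients; such patients stay in the cohort but are
dropped from model fits that use the score.

**Treatment.** Each of `n_regions` regions (default 30) draws a CABG
preference on the logit scale from N(`region_pref_mean_logit`,
`region_pref_spread`²). Treatment (CABG = 1) is Bernoulli with

    logit P(CABG) = instrument_strength · pref_logit(region)
                    + γ'x_centred − confounding_strength · U .

The negative sign on `U` encodes confounding by indication: frailer patients
are steered towards PCI. Measured covariates confound in the same direction
(older, CKD, prior-stroke patients towards PCI). A fraction of PCI patients
(default 5%) is demoted to *simple* (non-complex) PCI; these are excluded by
phenotyping, mirroring the protocol's restriction to complex PCI.

**Outcomes.** Death and cardiovascular (CV) hospitalization are competing
exponential processes with per-year baseline intensities `death_rate` and
`cv_hosp_rate`, both multiplied by `exp(θ'x_centred + u_loghr·U + β_T·T)`.
Exponential hazards were chosen so the oracle has closed forms (the
composite is exponential with the summed intensity when covariate and
frailty effects are off). Potential outcome times under both arms are drawn
with common exponential variates, so individual treatment effects and the
oracle ATE are exact by construction. Times are converted to integer days;
a readmission cannot begin before the index discharge, so CV-hospitalization
days are clamped past the index length of stay (this never moves an event
across the 5-year horizon of 1826 days). Optional `treatment_loghr_modifiers`
add covariate-dependent shifts to `β_T` for effect-modification studies.

**The study-condition preset** (`paper_like_config`) fixes: regional
preference centred at logit 1.35 with SD 0.9, giving a mean regional CABG
rate near 78% and empirical regional rates spanning at least 0.5 at
n = 20 000; `confounding_strength = 0.6`; CABG log hazard ratio ln(0.65);
and baseline intensities (0.06939, 0.12445)/year calibrated once — by a
deterministic Monte-Carlo root-solve (`calibrate_control_rate`) — so the
complex-PCI arm's factual 5-year composite rate is 70%. Under this preset
the naive rate difference is roughly −24 percentage points while the oracle
ATE is roughly −13, a deliberate demonstration of bias by indication.

**Episode emission.** The fast vectorised path (`generate_core`) returns the
patient-level table; `generate_hes_like` layers HES-like records on it: a
qualifying heart-failure admission 31–700 days before index (primary I50x,
comorbidity codes in secondary positions), occasional unrelated lookback
admissions, the index revascularization episode with OPCS-4 codes (CABG
K40–K46; complex PCI as multivessel K492, three-plus stents K752/K754, or a
staged pair of K49 episodes within 90 days), the first CV follow-up
admission when the hospitalization process fires first, Poisson noise
admissions — 30% of which carry a CV code in a *secondary* position, so the
wider coding dialect finds strictly more events — and a death-registry row
(70% CV-coded causes). Violators are injected post hoc into disjoint random
subsets of CABG/complex-PCI patients by editing histories (acute MI within
30 days, valve-surgery procedure within 2 years, cardiogenic shock within 7
days, maternal admission within ±1 year, a bleeding-diathesis code within 2
years, or a heart-failure history displaced beyond the 2-year lookback), so
the eligibility engine's per-rule exclusion counts are known exactly.

**Trial IPD.** `generate_trial_ipd` draws a STICH-like baseline table from
shifted marginals (defaults: 10 years younger, −19 points hypertension,
−13 points CKD, +46 points prior MI, +12 points male), reflecting that trial
participants are younger and differently selected than the administrative
population.

## Phenotyping

Codes are matched by prefix after normalization (dots stripped, uppercased):
a 3-character stem such as `I50` matches 4-character HES codes. All windows
are integer-day arithmetic: 5 years = 1826 days, 2-year lookback = 730 days;
"within N days" is inclusive of day N and exclusive of the index day. The
first episode with a revascularization procedure determines candidacy; CABG
codes take precedence over PCI codes on the same episode (audit-flagged).
The staged-PCI window is inclusive of day 90, and the staged index date is
the first PCI's date. Eligibility evaluates every rule without
short-circuiting and records all failures. Comorbidity covariates use the
2-year lookback *including* the index episode's diagnoses. CV
hospitalization follow-up starts the day after the index date; MI follow-up
starts from the first admission after the index episode's discharge, because
an MI code on or around the index episode is usually the indication for the
procedure rather than an outcome. The component episodes of a staged index
are never counted as outcomes — otherwise every staged patient would
mechanically register a CV hospitalization at the second stage. Deaths come
from the registry table alone; a death dated before the index raises a
data-integrity error, and a death on the index day counts from day 1.

The bundled exclusion code lists are deliberately conservative placeholders
(the real protocol's supplementary lists are not public) and fully
configurable as YAML. In particular the default bleeding-risk list uses
severe, specific codes (bleeding diathesis D65–D68, oesophageal varices I85,
liver disease with portal hypertension K76.6, malignancy C, brain AVM
Q28.2) rather than bare CKD/stroke stems — a fifth of a realistic cohort
carries CKD as a comorbidity, so a stem-level exclusion would contradict the
observed prevalence of CKD among eligible patients.

## Matching to trial IPD

A logistic model of IPD membership on age, sex and six comorbidities gives
propensity scores per treatment stratum (CABG and complex PCI are matched to
the IPD separately). Greedy nearest-neighbour matching runs in a seeded
random claimant order with a caliper of 0.01 on the probability scale, 1:1
and without replacement; distance ties break to the lower candidate id. The
IPD rows act as claimants (each anchors at most one cohort patient per
stratum), because the purpose of this step is to reshape the cohort towards
the trial population. Balance is summarized as standardized mean
differences; the conventional adequacy threshold is 10%. Greedy caliper
matching needs absolute tail mass to bridge a one-SD age shift: in synthetic
experiments the post-match SMDs fall reliably below 10% when the cohort pool
is large relative to the anchors (≈50 pool patients per anchor at these
shifts), and the bundled tests use that regime.

## Instrument diagnostics

The instrument is each patient's regional CABG share among CABG + complex
PCI. Diagnostics: (i) per-region rates with unweighted mean/SD; (ii) a
funnel plot of standardized surgical ratios (observed/expected CABG counts
from a patient-level logistic case-mix model with no region terms) with 95%
and 99.8% control limits from the normal approximation to the binomial
variance of the expected count; (iii) the first-stage F — the squared
t-statistic of the excluded instrument in a linear regression of treatment
on instrument plus covariates — compared with the single-instrument
Stock–Yogo critical value 16.38 (10% maximal-bias level); (iv) covariate
balance across instrument quartiles (sample quartiles, ties broken
rank-then-order, so quartile sizes differ by at most one). A leave-one-out
instrument (removing the patient's own procedure from their region's rate)
is available and off by default.

## Treatment-effect estimation

All estimators target the ATE of CABG on the binary 5-year composite, on the
risk-difference scale, adjusting for the prespecified covariates (age, sex,
ethnicity as indicator contrasts against the largest level with a retained
missing category, deprivation, diabetes, hypertension, lipidaemia, CKD,
prior stroke, prior MI).

1. **Recursive bivariate probit IV** (primary). Two probit equations with
   jointly normal latent errors: treatment on instrument + covariates,
   outcome on treatment + covariates; the error correlation ρ absorbs
   unmeasured confounding. The likelihood uses an Owen's-T-based bivariate
   normal CDF (`bvn_cdf`, vectorised, absolute accuracy far below 1e−8;
   `scipy`'s per-point integrator is the independent oracle in tests, not
   the implementation). Joint MLE by BFGS with analytic gradients on the
   mean log-likelihood, parameterized in atanh ρ for an unconstrained
   search, three starts (ρ ∈ {0, ±0.4}) from single-equation probit
   estimates, gradient tolerance 1e−7. ATE by G-computation on the outcome
   equation: mean of Φ(c + β + θ'x) − Φ(c + θ'x).
2. **Probit regression adjustment** with the same G-computation.
3. **Within-cohort propensity matching**: probit propensity of treatment,
   greedy 1:1 caliper-0.01 matching without replacement (the smaller arm
   claims, maximizing pairs), ATE as the matched rate difference; the
   bootstrap re-runs the entire match per resample.
4. **S/T/X meta-learners** over a gradient-boosted tree base learner
   (XGBoost regressor; depth 3, 120 rounds, learning rate 0.1, single
   thread, seeded; hyperparameters recorded in the estimate's notes). The
   X-learner blends the two imputed-effect models by a logistic propensity.
5. **Subgroup ATEs**: regression adjustment within each stratum
   (single-arm strata flagged, not estimated) plus a likelihood-ratio
   interaction test from a pooled probit with treatment-by-stratum terms.

Confidence intervals are percentile bootstrap (default B = 500, seeded, the
interval widened if needed to bracket the point estimate); a
normal-approximation bootstrap variant exists for simulation studies that
need many cheap intervals. The bivariate probit refits bootstrap resamples
from a single start at the full-sample solution.

Because the generator's treatment model is logistic and its outcomes arise
from exponential hazards, the bivariate probit is deliberately *not* the
data-generating process. Validation therefore separates two questions:
(i) correctness of the MLE, checked on data drawn exactly from the probit
process (nested-model equivalence at ρ = 0, recovery of ρ and β when errors
are correlated); and (ii) robustness of the IV route under realistic link
misspecification, checked against the Monte-Carlo oracle on the
study-condition preset, where a small residual bias (well under one
percentage point at n = 50 000, against a 12-point confounding bias in the
naive contrast) remains and is the expected price of the parametric link.

## Trial design

Required events follow the Schoenfeld formula
`d = (z_{1−α/2} + z_{1−β})² / (p(1−p)(ln hr_eff)²)` with allocation fraction
`p` and crossover dilution `hr_eff = exp(ln(hr)(1 − 2·crossover))` on the
log-hazard scale (simple, documented, replaceable). Participants come from
the per-patient event probability under exponential survival calibrated to
the control 5-year rate, uniform accrual over the accrual period, and
administrative censoring at study end; events and per-arm n always round
up. At HR 0.7, two-sided α 0.05, 90% power, equal allocation and no
crossover this gives 331 events. A published feasibility figure of
"370 events or 592 participants" for this design came from a flexible
non-proportional-hazards routine whose power setting is not stated; it sits
between the 80%- and 90%-power answers of the transparent route above, so it
is documented here but not treated as a check target. Kaplan–Meier curves
and the log-rank test are thin surfaces over `lifelines`, with Greenwood
variances recomputed from the event table.

## Problem sizes used in the bundled checks

Simulation-based checks run at sizes chosen to keep the default suite quick
while leaving clear margins: IV parameter recovery, 40 replicates at
n = 20 000 against an oracle of 400 000 Monte-Carlo draws; null-effect CI
coverage, 40 replicates at n = 5 000 with B = 40 bootstrap resamples;
estimator concordance on a randomized cohort at n = 10 000; null-instrument
F calibration over 200 replicates; funnel-limit calibration over 300
replicates; interaction-test calibration over 150 replicates. The seeds are
fixed in the tests; the acceptance script derives all its seeds from the
single `--seed` argument.

## What passing tests do and do not show

The generator reproduces the *structure* of the real analysis problem —
regional preference variation, confounding by indication in a known
direction, a ~70% control-arm composite rate, eligibility violators in known
numbers, a coding dialect that widens outcome capture — with known
counterfactual truth. It does not reproduce real HES coding noise
(mis-coding, transfers, duplicate spells), realistic ICD/OPCS frequency
distributions beyond the codes the phenotyper consumes, non-exponential
hazard shapes, or the actual (access-controlled) HES and STICH data; the
published cohort effect sizes are therefore not reproduction targets, and
agreement of the estimators with the synthetic oracle demonstrates
correctness of the machinery, not of any clinical conclusion.

## Known limitations

* Greedy caliper matching on the probability scale degrades near propensity
  0 or 1; a logit-scale caliper is a known alternative and is not
  implemented because the emulated procedure specifies the probability
  scale.
* The bivariate-probit ATE's standard errors are bootstrap-based throughout;
  no analytic (delta-method) intervals are provided.
* The funnel's control limits use the binomial normal approximation without
  overdispersion inflation by default; very small regions are omitted only
  when their expected count is zero.
* `subgroup_ates` refits the adjustment model per stratum; strata smaller
  than a few dozen patients will produce unstable intervals.
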