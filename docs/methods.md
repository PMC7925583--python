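# Methods

## The data model

A cohort is a set of CSV tables sharing two keys — `PatientID` and
`SampleID` — on a deidentified day axis: every `Timepoint` is an integer
offset from a secret per-patient reference date, so only day differences
carry information and no calendar date exists anywhere in the data.
`DayRelativeToNearestHCT` columns re-express days relative to the nearest
hematopoietic cell transplant; when a patient has several transplants the
nearest one is used, and an exact tie between two equidistant transplants is
broken toward the earlier one (deterministic, and flagged in the validation
report). Drug administrations are closed intervals `[StartTimepoint,
StopTimepoint]` — the stop day is a dosed day. Empty CSV cells are nulls,
never zeros. Loading is strict by default (any invariant violation raises);
lenient loading collects violations — negative counts, duplicate keys,
orphaned sample references, inverted drug intervals, implausible
temperatures, day-axis inconsistencies — into a machine-readable report.
Writing and re-loading a cohort reproduces it field-for-field (floats are
parsed with exact decimal round-tripping; the fast CSV float path of pandas
is deliberately bypassed).

## Growth-rate model and inference

Each taxon's absolute abundance N_k (relative abundance × qPCR 16S copies
per gram) is assumed to grow exponentially at rate g_k, shifted additively by
ε_{k,j} whenever antibiotic group j is present. Between two consecutive
stool samples at days t_i < t_f this integrates exactly to

    log N_k(t_f) − log N_k(t_i) = g_k Δt + Σ_j ε_{k,j} C_j ,

with Δt = t_f − t_i and C_j the number of exposed days. Natural logarithms
are used throughout (the integral form forces them).

Conventions and filters:

* **Exposure day-counting.** C_j counts exposed days in the half-open window
  (t_i, t_f]: a course active only on the initial sample's day does not
  contribute, because that sample reflects the abundance before the day's
  subsequent dosing. The forward simulator uses the identical convention
  (the increment arriving at day d carries u_j(d)), so simulated data are
  exactly linear in the regression covariates.
* **Pairs.** "Consecutive" means adjacent in the per-patient day-sorted
  sample sequence — a pair never skips over an intermediate sample, even one
  later discarded for missing qPCR. Pairs with gap > 3 days or a missing
  qPCR endpoint are dropped; duplicate same-day samples keep the first by
  SampleID order.
* **Zero discard.** A pair contributes to taxon k only if k's count is
  nonzero at both endpoints (log of zero is undefined; absence is not
  evidence of rate).
* **Drug grouping.** Only antibacterial drug categories enter; atovaquone is
  excluded by name; within the miscellaneous class, metronidazole and
  aztreonam become their own groups and the remaining miscellaneous drugs
  are removed. Oral and intravenous administrations of a group are distinct
  covariates. All covariates enter one joint regression per taxon (a single
  intercept g_k), and results are reported split by route; fitting the routes
  jointly avoids omitted-variable bias from the other route's exposures.
* **Taxon choice.** The top-k (default 20) taxa by mean relative abundance
  over the unique pair-endpoint samples. The ranking statistic is
  configurable since alternatives (total counts, prevalence) are defensible.

The per-taxon system Y = D X is solved in closed form,
X = (DᵀD + λP)⁻¹DᵀY. The penalty includes the intercept by default —
the objective penalizes the full coefficient vector — with
`penalize_intercept=False` available for the conventional exemption. At λ=0
a rank-deficient system returns the minimum-norm least-squares solution with
a warning. λ is chosen from a 25-point log-spaced grid over [1e−4, 1e4] by
minimizing held-out squared error over 3 folds × 10 Monte-Carlo random row
partitions (rows, not patients, are partitioned, matching the row-wise
objective; patient-level grouping would be the leakage-averse alternative).
The CV is seeded and fully reproducible; a single-value grid skips CV.

## Synthetic cohorts

The generator emulates the regime of real allo-HCT hospitalome deposits,
with all knobs in `SimConfig`:

* stool sampled every 1–4 days over days −15…+35 around a transplant placed
  at a random absolute `Timepoint` (so day-axis arithmetic is exercised);
* ~3 antibacterial courses per patient, duration 3–7 days, drawn from a
  fixed taxonomy of drug classes each with its canonical route, plus
  non-antibacterial nuisance drugs (antifungals, antivirals, atovaquone)
  that the grouping rules must discard;
* latent dynamics follow the growth model exactly (daily Euler step, which
  is exact at day resolution), with multiplicative log-normal process noise
  of 0.2 per day^1/2 by default; growth rates are drawn in ±0.2/day and
  susceptibilities are mostly inhibitory (80% negative signs, magnitudes
  0.25–1/day, 30% exact zeros). The BSI target taxon gets a non-negative
  profile — the resistant, Enterococcus-like phenotype that blooms under
  antibiotic pressure — so domination arises mechanistically in roughly a
  fifth to a third of patients depending on the draw;
* observation: multinomial read counts at gamma-mixed depth (mean 5×10⁴),
  qPCR load = true total × 10^N(0, 0.1²), initial total load ~10^9.5
  copies/g; an absolute extinction floor (1 copy/g) records extinct taxa as
  absent. In the noiseless mode (`SimConfig.noiseless()`) counts carry the
  latent composition essentially exactly: taxa below a relative detection
  limit (10⁻⁹) read as zero — every real assay has such a limit — and the
  rest are scaled to the largest integers int64 allows, keeping log-abundance
  rounding below ~1e−9 so the forward model is invertible to numerical
  precision;
* bloodstream infections are drawn per patient-day with hazard
  h₀·exp(β·x_t), where x_t is the *observed* absorbing domination state
  (1 strictly after the first stool sample whose target-genus fraction
  exceeds the threshold). Driving the hazard with the sample-detected state
  rather than the latent daily state makes the generative model coincide
  with the covariate the survival analysis reconstructs, so β-recovery is a
  well-specified end-to-end check; β = log 4 and h₀ = 0.0015/day by default,
  giving ~8% of patients an event over the window, in line with the cohorts
  being emulated.

What the generator does **not** emulate: real taxon identities and their
co-occurrence structure, ecological interactions or carrying capacities,
pharmacokinetics (exposure is binary), informative sampling (sicker patients
sampled more), or death/discharge before day +35. Passing tests therefore
demonstrate correctness of the estimators under the model's own assumptions,
not robustness to their violation on real data.

## Survival analysis

Counting-process rows (start, stop] are built per patient over days −15…+35:
entry at −15, exit at the first positive blood culture of any tracked genus
or at +35 (no death/discharge record exists in the tables, so follow-up is
censored at the window end and documented as such). The event flag is set
only for the genus under analysis; another tracked genus' BSI censors.
The domination covariate is absorbing — once a stool sample strictly exceeds
the threshold the covariate is 1 from the following day onward and never
reverts — and a patient already dominated before entry starts at 1. Patients
with a matching BSI before entry are excluded; patients without samples
contribute baseline follow-up and are flagged. A patient with several
transplants contributes one observation per transplant window, truncated so
no patient-day is counted twice.

The Cox partial likelihood over these rows is maximized by Newton–Raphson to
|Δβ| < 10⁻⁸ with the Efron correction for tied event days (integer day axes
produce many ties); Breslow is available. Degenerate inputs fail loudly: no
events or a contrast-free covariate raise immediately, and a monotone
likelihood (all events in one stratum) raises a convergence error carrying
the per-stratum event counts. The Wald CI is exp(β ± 1.96·se). The fit is
cross-checked in the test suite against lifelines'
`CoxTimeVaryingFitter` to 10⁻⁶. Threshold sweeps (30/10/1/0.1%) refit per
threshold, report the dominated-patient count (monotone in threshold), carry
per-threshold failures as recorded errors without aborting the sweep, and are
deliberately not multiplicity-adjusted (a note is attached to the output).

## Figures

The patient timeline marks fevers above 100.4 °F (= 38.0 °C, the febrile-
neutropenia convention; the alternative 37 °C threshold is selectable since
the two are sometimes conflated) and neutropenia strictly below 500
cells/μL, draws anti-infective courses as horizontal bars, and stacks
relative abundances colored by the taxonomy's hex colors in `ColorOrder`.
The dataset map is an off-the-shelf t-SNE (scikit-learn) on relative
abundances, seeded and deterministic, with points colored by the dominant
taxon and one patient's day-ordered trajectory overlaid as arrows. Renders
never mutate the cohort.

## Problem sizes used by the automated checks

The packaged checks invert a noiseless 50-patient cohort (10 taxa, 4 drug
groups), measure noisy recovery on one 300-patient cohort, and assess Cox
CI calibration on 100 replicate cohorts of 150 patients — sizes at which the
whole battery completes in a couple of minutes on one CPU while leaving the
Monte-Carlo margins comfortable.

## Known limitations

* Susceptibilities are associational: confounding by indication (drugs given
  because of the microbiota state) is not modeled.
* The growth model has no saturation, so sustained dominations under
  continued exposure dilute the estimated effect of the exposure.
* CV partitions rows, not patients; consecutive pairs share a sample, so a
  small optimistic bias in the CV curve is possible (patient-level grouping
  is the conservative option).
* The Wald CI is first-order; with very few events per stratum its coverage
  degrades, which the calibration check quantifies empirically.
* Confidence columns of deposited taxonomies vary in scale (0–1 vs 0–100);
  the loader auto-detects and records the scale in provenance rather than
  rescaling.
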