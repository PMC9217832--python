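# Methods

## Problem and model

Cardiovascular autonomic failure (AF) in Parkinson's disease produces a
characteristic 24-h blood-pressure signature — loss of the nocturnal dip or
outright reverse dipping, elevated nocturnal pressure and loads, morning
hypotensive episodes after standing, postprandial pressure falls and
increased BP variability. The package screens for AF from a standard 24-h
ambulatory BP monitoring (ABPM) recording by (1) deriving that parameter
set and (2) combining it in a two-class linear discriminant against the
reference diagnosis from cardiovascular autonomic reflex testing (a
modified Composite Autonomic Symptom Score without the sudomotor component;
AF when cardiovagal + adrenergic subscores sum to ≥ 2).

### ABPM parameters

With day/night delimited by the patient diary (night = [sleep onset, next
awakening), half-open; all "within t" windows inclusive at the upper end):

* period means and sample SDs (n−1) of systolic, mean-arterial and
  diastolic pressure over 24 h, day, and night; MAP is taken from the file
  when present, otherwise derived as `dbp + (sbp − dbp)/3`;
* BP load: % of readings at/above the period reference (day 135/85 mmHg,
  night 120/70 mmHg; "exceeding" read as ≥);
* reverse dipping: mean day SBP − mean night SBP ≤ 0 mmHg (equality
  included);
* weighted BP variability `w-BPV = (SDday·hday + SDnight·hnight) /
  (hday + hnight)`, "increased" when > 11 mmHg; period hours come from the
  diary intervals clipped to the recorded span, so they sum exactly to it;
* postprandial hypotension: for each diary meal with ≥ 3 prior readings,
  reference = mean of the last three pre-meal SBPs; PPH if the minimum SBP
  in (meal, meal + 120 min] falls ≥ 20 mmHg below the reference for any
  meal;
* morning hypotensive episodes: readings in [awakening, lunch) with SBP ≤
  24-h mean − 15 mmHg, where lunch is the first diary meal at/after 11:00
  (fallback: awakening + 5 h, flagged); awakening hypotension = at least
  one episode within 90 min of awakening.

The discriminant's feature vector has 21 entries: the nine period means,
three systolic SDs (the reported variability measures are all systolic, so
only systolic SDs enter), four loads, w-BPV, and the PPH /
reverse-dipping / awakening-hypotension flags plus the episode count.
Binary flags enter as 0/1 without standardisation — LDA predictions are
affine-invariant, so scaling is immaterial.

### Linear discriminant

For classes with shared covariance, `w = S⁻¹(μ₊ − μ₋)` and a patient is
called AF-positive when `w·x > w·(μ₊ + μ₋)/2 − log(π₊/π₋)` — the Bayes rule
for two homoscedastic Gaussians. `S` is the within-class scatter divided by
n (not n−2): the direction is identical up to scale and this normalisation
makes the fit exactly invariant to duplicating every sample. Priors are
empirical class frequencies by default (clinical-prevalence reading), equal
by option. Derived MAP makes three mean columns exactly collinear, so when
cond(S) > 1e10 an escalating ridge `λ·trace(S)/p` (λ from 1e-6, ×10 steps,
capped at 1e-2) is added; because the class-mean difference lies in the
data subspace the coefficients remain bounded. With regularisation off a
singular matrix is an error naming the collinear columns.

Evaluation reports both resubstitution (the apparent accuracy a single fit
gives on its own training data) and leave-one-out / k-fold cross-validation
with refitting per fold, clearly labelled; resubstitution is optimistic and
the two are always shown together.

### Diagnostic statistics

Proportion CIs are exact Clopper–Pearson from beta quantiles (Wilson by
flag). Integer-percent display rounds half away from zero (with a 1e-9
relative epsilon so exact halves such as 17/40 land away from zero despite
binary floats); odds ratios display at two significant figures. The
empirical ROC is built over unique observed thresholds and integrated in
threshold order, which makes the trapezoidal AUC exactly the tie-corrected
Mann–Whitney concordance; the AUC CI is Hanley–McNeil; the Youden cut-point
maximises sens + spec − 1 with ties broken toward the lower threshold (the
more sensitive test). Odds ratios are cross-products with Woolf log-scale
CIs and the Haldane–Anscombe 0.5 correction for zero cells. Logistic
regression delegates to an IRLS GLM fit (statsmodels) with Wald CIs;
quasi-complete separation (|log-odds| > 15 or non-finite SE) is flagged
rather than raised. Two-group comparisons use t / Mann–Whitney for
continuous data (Shapiro–Wilk at 0.05 unless normality is asserted) and
chi-square for categorical data, switching to Fisher's exact test when any
expected cell is ≤ 5. No multiple-testing correction is applied to the
two-group tables.

## Synthetic cohort generator

The generator emulates the cohort structure of the clinical study the
parameter definitions come from: n = 80, AF prevalence 0.3625, and the
published group day/night SBP statistics (day 122 ± 10 / night 109 ± 11
mmHg in AF-negative; 118 ± 8 / 122 ± 17 in AF-positive patients).

Per patient: (day, night) true SBP means are bivariate normal with
correlation 0.5 — chosen so the implied day−night difference distribution
reproduces the published reverse-dipping prevalences (~10% / ~58%) under
the published means and SDs. Readings at 15-min cadence are period mean +
Gaussian noise whose SD is itself a patient-level draw (day N(12, 3) /
N(14, 4) mmHg, night N(9, 2.5) / N(11, 3), truncated at 0): the
between-patient spread of within-day SD is what gives realistic prevalences
of "SD day-SBP > 16" (~8% / ~34%) and "w-BPV > 11" flags. Morning dips are
Poisson-many (rates 0.4 / 3.4) rectangular one-to-two-slot depressions,
placed uniformly in [awakening, lunch), with depth U(20, 30) mmHg below the
nominal 24-h mean and the total capped at 12 slots — the cap bounds how far
the depressions can drag the empirical 24-h mean, so every injected dip is
guaranteed to satisfy the ≥ 15 mmHg episode criterion (verified exactly on
the noise-free configuration). With group probability 0.45 / 0.58 a
postprandial trough (U(25, 35) mmHg below the day level, 1–2 slots) is
inserted after lunch or dinner — never after breakfast, so it cannot
contaminate the morning episode window. Because the published group day
means are *observed* values, the deficit the injected depressions remove
from the daytime average is redistributed over the unmodified day readings;
without this the extracted day mean would sit systematically below the
configured one. DBP is SBP minus a patient-level pulse pressure
N(45, 5) truncated ≥ 25; covariates (age, sex, disease duration, levodopa
equivalent dose) are drawn from the published group distributions, and the
AF label is derived from sampled CASS subscores through the same ≥ 2 rule
the evaluation uses. Every patient consumes an independent spawned RNG
substream, so enlarging a cohort never perturbs earlier patients.

What the generator does **not** model: within-day autocorrelation (activity
runs, drug cycles), device artefacts and missing readings, HR–BP coupling,
non-Gaussian BP distributions, or diary misreporting. Consequently the
Gaussian tails create more spurious morning episodes than the clinical
counts (the per-group episode means come out ≈ 2 / 8 rather than 0.4 /
3.4, and awakening hypotension is correspondingly more prevalent), while
the *injected*-dip floor and all threshold conventions are exact. Passing
tests therefore demonstrate the correctness and calibration of the
pipeline's definitions and the internal consistency of the statistics, not
field performance on real recordings.

## Problem sizes and numerical choices

The default demonstration cohort is n = 80 (the clinical cohort size);
parameter-recovery checks use n = 2000, where Monte-Carlo error on group
night-SBP means is ≈ 0.3–0.6 mmHg; construction-guarantee checks use the
noise-free configuration at n = 200. Recording values are rounded to
integer mmHg (device realism); the noise-free configuration disables
rounding so exact-recovery checks are bit-clean. Readers skip unparseable
rows with a logged count, but any row violating a physiological invariant
(sbp > dbp, plausibility ranges) fails the whole recording with the row
named — silent editing of artefacts is deliberately out of scope. A
recording needs ≥ 70% of expected 15-min slots, a 20–30 h span and at least
one diary awakening. Timestamps are local clock time at minute resolution;
no time-zone or DST arithmetic is attempted.

## Known limitations

* Resubstitution accuracy on n = 80 with 21 features is optimistic by
  construction; LOOCV is reported alongside and is typically 4–8 points
  lower.
* The clinical study's own headline figures cannot be reproduced exactly
  without its (undeposited) patient-level data; what is reproduced exactly
  is every self-consistent cell derivable from the published 2×2 counts.
  A handful of published cells round inconsistently with their own counts
  and are excluded from exact checks.
* CASS subscores are inputs; their derivation from autonomic-test waveforms
  is outside the package.
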