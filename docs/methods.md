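# Methods

This note documents the models and procedures grazekit implements, the
defaults it ships, and the design choices made where the design was
genuinely open.

## Stocking rate and study layout

A camp's stocking rate is land area per animal unit, area / (cows·1.0 +
heifers·0.7), in ha/AU; lower is denser. The bundled study has three
cattle camps at 1.7, 1.5 and 0.95 ha/AU ("low", "intermediate", "high")
plus a small cattle-free camp used only by oribi in the wet season. Cattle
and oribi co-occur in the camps only during the wet season, so wet-season
contrasts measure direct interaction and dry-season contrasts measure the
carry-over of wet-season grazing.

## Sward structure

Transect quadrats record sward height (cm) and Walker's eight-point
percent-green class, collapsed to four bins: very brown (0–10%), mainly
brown (11–50%), mainly green (51–90%), very green (91–100%). Structural
heterogeneity is the coefficient of variation of height per camp × season,
CV = 100·sd/mean with the sample (n−1) standard deviation — the underlying
quantity is a field sample, so the unbiased-variance convention is used.
Ranges are the observed min/max. Greenness availability is the proportion
of quadrats per bin; absent bins are reported as 0 so the four proportions
always sum to 1.

## Regrowth and grazing-pressure inversion

Net relative regrowth of a marked sward over the trial window is
r = ln(h_final) − ln(h_initial), back-transformed for reporting to
percentage growth 100·(e^r − 1). The clipping experiment yields pairs
(x = clip count, y = r) for schedules of 3, 5 and 10 clips; the unclipped
control is excluded from the fit, which is ordinary least squares
(scipy `linregress`). Grazing frequency in a cattle camp is then the line
solved for x at the camp's mean regrowth, x̂ = (r − α)/β, reported both as
the continuous solution and rounded to the nearest integer (banker's
rounding); a negative x̂ is returned but flagged, since it means regrowth
exceeded the zero-defoliation prediction. The fit accepts either per-sward
points or treatment means — the noiseless round-trip (fit then invert)
is the identity in x either way.

Because grazing makes some regrowth values negative, Gamma-GLM comparison
of regrowth uses a shift transform: add |min| to every value when the
minimum is negative. The constant is returned and logged so the transform
is invertible. The shifted minimum is exactly 0, which a log-link Gamma
cannot take; such zeros are offset by half the smallest positive value in
the data. An offset at the edge of floating-point representation would put
log(y) near −37 and dominate the deviance, so the data-scaled offset is
the numerically sane reading of "smallest positive step"; the offset used
is recorded in the result object.

## Diet composition and overlap

Contributions are bites of a species over total bites ("pooled", the
default) or computed within each feeding station and averaged with equal
station weight ("station"). Both are exposed because field protocols
describe contributions per feeding station while the defining formula is
pooled, and the two genuinely differ when station bite counts are uneven;
outputs are labelled with the scale used. Top species are the smallest
highest-contribution set whose cumulative contribution exceeds a threshold
(default 0.9), ties broken by species label.

Overlap is Schoener's O_jk = 1 − ½·Σ|P_ij − P_ik| over the union of
species, with absent species at 0 and no renormalization of truncated
tables by default (a `renormalize` flag rescales both diets over the union
first). Seasonal diet expansion reports the wet-vs-dry overlap plus the
species newly included and dropped.

Known data note: published overlap values for studies of this design are
computed at the feeding-station scale from unpublished bite records, and
generally cannot be reproduced by applying the formula to a published
pooled contribution table; grazekit therefore treats published
contribution tables as generator inputs, not as overlap ground truth.
Similarly, one published cattle diet column sums to only ~81%, so the
"six species > 85% of cattle diets" claim is not checkable from the table
alone, while all six oribi columns do exceed 90% on their six largest
entries.

## Nutrition

Nutrient profiles are % crude protein (CP) and % organic-matter
digestibility (OMD) per species × greenness bin. A bite matches its exact
(species, bin) profile when present; otherwise it receives the unweighted
mean of all profiled species in its bin, flagged and counted as a
fallback. Per observation (five feeding stations):

* bite rate = total bites / elapsed minutes;
* DMI (g/min) = mean bite mass × bite rate;
* CP intake (g/min) = mean over bites of (CP fraction × bite mass) × bite
  rate. Composing per-bite before averaging is deliberate: it equals
  (mean concentration × mean mass) only when CP and mass are uncorrelated,
  and the per-bite composition is the faithful reading of
  concentration-of-what-was-eaten. With a uniform concentration c it
  factorizes exactly to c × DMI.
* OMD is reported as the bite-mass-weighted mean % (digestibility of the
  consumed vegetation); an unweighted mean and a literal OMD "intake"
  (g digestible organic matter/min) are also emitted since the weighting
  convention is ambiguous in the field literature.

## Group comparisons

One-factor Gamma GLMs with log link (statsmodels IRLS). With a saturated
factor design the fitted group means equal the arithmetic group means, and
the likelihood-ratio statistic is invariant to rescaling the response. The
omnibus statistic is the deviance difference scaled by the Pearson-based
dispersion estimate of the full model, referred to χ²(levels−1); the
equivalent F-statistic with its p-value is reported alongside and is the
more conservative choice at small n (simulation places both within 5% ± 2%
nominal size at n = 50–100 per group). Pairwise Wald contrasts on the log
scale are available for ≥ 3 groups, with unadjusted p-values by default
(no correction is assumed) and a Holm-adjusted column always attached.
`pool_groups` relabels several groups into one (e.g. all stocking-rate
camps vs the cattle-free camp) without touching the values.

## Synthetic-data generator

The generator is the package's test bed: it emulates the study's sampling
design with the simplest distributions consistent with positivity and the
Gamma-GLM analysis family, and its defaults are the study conditions.

* **Sward heights**: Gamma per camp × season, parameterized by mean and CV
  (wet: 23/58%, 24/55%, 18/47%; dry: 34/53%, 34/53%, 21/46% for
  low/intermediate/high). 1,200 quadrats (2 transects × 20 points ×
  2 quadrats per month; 2 wet and 3 dry months).
* **Greenness**: camp- and season-specific multinomials over the four
  bins, refined to Walker classes by a fixed within-bin split. Dry-season
  green availability is 35/32/23% for low/intermediate/high, with very
  green absent and very brown present only in the high camp.
* **Diets**: species multinomials per herbivore × camp × season, stored as
  percentage contributions (normalized at load). Bite masses are lognormal
  per species (oribi ~0.08 g, cattle ~0.45 g), bite rates Gamma (15 and
  30 bites/min), elapsed times lognormal, and bites are spread over five
  stations multinomially, giving ~25 bites per observation. Wet-season
  diets draw only very green grass; dry-season oribi greenness follows the
  configured proportions (0.65/0.35, 0.64/0.36, 0.99/0.01 mainly/very
  green).
* **Regrowth trial**: 38 days sampled every 3 days, initial heights
  lognormal (20 cm, 20% CV), per-sward Gaussian noise (sd 0.05) on total
  log growth. Two growth models are available. The default,
  `proportional`, grows log-height at rate ρ per day and applies a
  constant log drop δ per defoliation event, so a sward's regrowth is
  exactly r = 38ρ + δ·x regardless of event timing. With the default
  ρ = 0.6502/38 and δ = −0.0606 the expected calibration line equals the
  canonical published one, and grazed-camp regrowth at the configured
  Poisson event rates (expectations 4, 3, 14 per trial) lands at
  ≈ +50%, +60%, −18%. The alternative `linear_reset` model (constant
  cm/day growth, reset to 8 cm at each event) is physically intuitive but
  makes expected regrowth depend only on the time since the last event,
  i.e. hyperbolically rather than linearly on event count — under it a
  linear calibration fit on 3–10 clips cannot recover a 14-event grazing
  rate by extrapolation. The multiplicative model is the one consistent
  with the observed linearity of regrowth in defoliation count (r² ≈ 0.9),
  which is why it is the default.
* **Clipping schedules**: 3 clips (days 3, 17, 31), 5 (weekly from day 3)
  and 10 (twice weekly), 30 swards each, plus an unclipped control; the
  first clip is on day 3 so every schedule fits the measurement grid.
* **Nutrients**: baseline CP/OMD per greenness bin (CP 3.5–15%, OMD
  42–68% from very brown to very green) plus per-species offsets (e.g.
  *H. contortus* −3 CP / −7 OMD, reflecting its lower palatability). Only
  the union of each diet column's six largest contributors is profiled, so
  the fallback path is exercised on the minor species.
* **Seeding**: one integer seed; per-stage generators are spawned from a
  `SeedSequence`, making every record deterministic across platforms.

What the generator does *not* emulate: spatial autocorrelation along
transects, animal movement and patch choice, compensatory growth dynamics,
within-individual correlation of repeated observations (the field study
could not identify individuals either), and seasonal nutrient drift within
a greenness bin. Passing tests therefore demonstrate the estimators'
correctness and internal consistency under the assumed sampling structure,
not robustness to these field realities.

## Sizes, tolerances, numerical choices

Default problem sizes (1,200 quadrats, 30 swards per camp and schedule,
~150 observations, 1,000 GLM null replicates in the calibration test) keep
a full pipeline run around a second and the entire test suite well under a
minute while leaving Monte-Carlo error comfortably inside the asserted
tolerances (2% on a Gamma mean at n = 10,000, 5% on its CV, ±1 event on
inverted grazing frequency at 30 swards). Proportion vectors are validated
to sum to 1 within 1e-9; diet overlap clips floating-point dust at [0, 1];
r² of an exact two-point fit is defined as 1. CSVs are written with
shortest-round-trip float formatting, so read → write → read is lossless
and repeated runs are byte-identical.

## Known limitations

* The calibration inversion extrapolates beyond the fitted 3–10-clip range
  for heavily grazed camps; the continuous estimate is reported alongside
  the rounded one so users can judge the extrapolation.
* Station-scale contributions weight all stations equally, including
  stations with a single bite.
* The Gamma GLM treats observations as independent; there is no random
  effect for individual animals or transects.
* Nutrient fallback uses an unweighted bin mean; with few profiled species
  in a bin the fallback can be coarse (the per-observation fallback count
  is reported for exactly this reason).
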