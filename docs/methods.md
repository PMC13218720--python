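# Methods

## The normative model

`bracenorms` implements regression-based demographic norming for a brief
tablet cognitive battery with four tests — Trail Making Test A and B
(TMT-A/B), Stroop-Color, and a Visual Spatial Learning Test (VSLT) — and
six outcomes: TMT-A and TMT-B time to completion, their difference B−A,
Stroop mean per-trial response time, Stroop accurate-trial count, and the
VSLT placement score (correct − incorrect).

Each raw outcome is first mapped to an *analysis scale* on which higher
values uniformly mean better performance:

* timed completion / per-trial times (ms): convert to seconds and take
  −log10 (the log reduces the right skew of response times);
* the TMT B−A switching cost (ms): convert to seconds and negate
  (the difference can be negative, so no log);
* counts (Stroop accuracy, VSLT): identity.

The base-10 log on the seconds scale is a deliberate dialect choice: the
bundled coefficient set is numerically consistent with −log10(seconds) —
evaluating each timed outcome's linear predictor at the reference
sample's mean demographics lands within 0.06 of −log10 of that outcome's
mean raw time (the gap is Jensen's inequality: the mean of a log is not
the log of a mean). A test (`test_transform_dialect_oracle`) ships this
check.

In a reference sample of adults without HIV, each analysis-scale outcome
y is fitted by ordinary least squares on demographics:

    y = β0 + β_age·age + Σ_k β_k·1[education = k] + ε

with age in years (continuous) and education in five ordered levels —
less than high school, completed high school (referent, no coefficient),
some college, 4-year college degree, graduate school — as four indicator
offsets. Optional predictor sets add biological sex and/or race/ethnicity
indicators; the default age+education model deliberately avoids
race-based corrections. The standard error of the estimate uses residual
degrees of freedom,

    SEE = sqrt(RSS / (n − p)),

with p the number of estimated parameters (6 in the default model).

A scored individual's T-score is the SEE-standardized residual:

    T = 50 + 10·(observed − predicted) / SEE.

Two construction identities follow and are enforced to 1e-9 in tests:
the reference sample's own mean T is exactly 50 (OLS residuals with an
intercept sum to zero), and its sample SD is 10·sqrt((n − p)/(n − 1)) —
at n = 1063 and p = 6, 9.976, printing as 9.98. The residual-df SEE is
what makes the reference SD come out just under 10; a maximum-likelihood
(1/n) scaling would put it just above.

Impairment is flagged at T < 40 (≥1 SD below the normative mean) and
T < 35 (≥1.5 SD), strict inequalities, so T = 40.0 exactly is
unimpaired. The global composite is the unweighted mean of the four test
T-scores (TMT-A, TMT-B, Stroop duration, VSLT); the B−A difference and
Stroop accuracy are excluded, and the composite is absent unless all
four components are present. T-scores are never truncated or rounded;
reports round to 2 decimals at display time only.

The coefficients released with the battery's norming study (reference
n = 1063) are bundled as `load_published_model()` so cohorts can be
scored without refitting. Fitted model sets serialize to a versioned
JSON schema at full float precision; a round trip reproduces T-scores
bit-for-bit.

## Quality control

QC decisions use trial counts only, never response times: Stroop passes
with strictly more than 15 accurate trials; TMT-A with strictly fewer
than 5 touch errors; TMT-B with strictly fewer than 10; VSLT has no rule.
"Not administered" (no trials) is distinct from "failed QC", and the
normative reference is restricted to participants passing QC on the full
battery. Implausibly long trial times (> 5 minutes) are logged as
warnings but never auto-excluded — exclusion on time would be a
different, undocumented rule.

## The synthetic cohort generator

Real cohort data for this battery are access-controlled, so the
generator produces cohorts with the statistical structure the pipeline
assumes. Its defaults are the study conditions:

* sizes 1063 without HIV (reference) + 1874 with HIV;
* age ~ Normal(56.95, 12.34²) truncated to [18, 95] (the truncation
  bounds are an artifact choice);
* education multinomial (0.143, 0.189, 0.289, 0.134, 0.243) over the five
  levels; 47% women; published race and site margins sampled
  independently (no site clustering or race×site joint structure);
* the five directly measured outcomes (TMT-A, TMT-B, Stroop duration,
  Stroop accuracy, VSLT) drawn on the analysis scale from the bundled
  published models, with residual SD equal to each model's SEE and a
  common pairwise residual correlation ρ;
* raw scores recovered by inverting each transform
  (time_ms = 1000·10^(−y)).

ρ is not published. The default 0.30 is a calibration, back-solved from
the printed composite SD: the mean of four equicorrelated T-scores (each
variance 100) has variance 25(1 + 3ρ), so SD 6.88 ⇒ ρ ≈ 0.30, and
10·sqrt((1+3·0.3)/4) = 6.89. Positive definiteness of the k×k
equicorrelation requires ρ > −1/(k−1) (k = 5 by default).

Two deliberate departures from a literal "every outcome from its own
linear model":

* the **B−A difference** is derived as raw(TMT-B) − raw(TMT-A), exactly
  as the QC stage derives it from real trial data, rather than simulated
  from its own published model. Simulating it independently would make
  the difference inconsistent with its parts; the cost is that the
  *derived* difference follows the published B−A model only
  approximately. The published B−A model is still bundled and used for
  scoring.
* the **Stroop accuracy count is floored at 16**, the lowest QC-passing
  count. The published models describe the QC-passing population, and an
  unbounded Gaussian tail would otherwise imply task disengagement for a
  fraction (~10⁻³) of elderly draws. The noiseless limit is unaffected
  (the linear predictor stays above 20 over ages 18–95).

Covariates (diabetes, hypertension, smoking, …) are Bernoulli draws at
the reference group's prevalences, independent of cognition by default;
`covariate_effects` injects additive analysis-scale shifts for power and
recovery experiments. Trial-level records are emitted so the QC stage
has real input: TMT completion times split over 24 Dirichlet-weighted
segments (sum preserved to < 1 ms), Stroop trial times rescaled to match
the recorded per-trial mean exactly, counts reproduced at their nearest
representable integer. Stroop uses 45 trials — the count must comfortably
exceed the largest accuracy count the published model generates (its
intercept alone is 36.2), which a 30-trial task cannot. A configurable
injection rate flips tests into QC-failing configurations; at rate 0
every emitted participant passes QC.

Randomness: one master seed; participant *i* draws from the counter
substream `[seed, i]` (trials from `[seed, i, 1]`), so any subset of
participants is reproducible and identical specs give byte-identical
tables.

What the generator does **not** emulate: site clustering, the race×site
joint distribution, practice or device effects, non-Gaussian residuals,
and any true HIV serostatus effect (both groups are drawn from the same
models by default, matching the near-null serostatus differences the
machinery is meant to detect). Passing tests therefore show the
*procedure* is correct and calibrated, not that real cohort effects are
reproduced.

## Group statistics

Two-group continuous contrasts use the pooled-variance t test — chosen
so the test statistic pairs exactly with |Cohen's d|, whose pooled SD is
sqrt(((n1−1)s1² + (n2−1)s2²)/(n1+n2−2)); `cohens_d` is callable straight
from printed summary statistics and agrees with the raw-array path to
1e-12. Rank-sum tests use the normal approximation with tie correction;
k-group contrasts use one-way ANOVA with η² = SS_between/SS_total.
Categorical contrasts use Pearson χ² without continuity correction,
switching to Fisher's exact test for 2×2 tables whenever an expected
cell falls below 5 (the χ² statistic still feeds Cramér's V =
sqrt(χ²/(n·(min(r,c)−1)))). Correlation panels use Pearson for
continuous covariates and point-biserial — identically Pearson on the
0/1 coding — for binary ones, pairwise-complete, with two-sided
significance tiers at .001/.01/.05 and no multiplicity adjustment by
default (α = .05 two-tailed convention); a flag switches the tiers to
Benjamini–Hochberg-adjusted p-values. Effect sizes are reported as
absolute values. A degenerate impairment contrast (nobody impaired in
any group) reports χ² = 0, V = 0, p = 1 rather than erroring.

## Numerical and design notes

* OLS goes through statsmodels on hand-built design matrices, so the
  education coding and referent are explicit and singular designs
  (absent levels, collinearity) are rejected with the offending terms
  named rather than silently pseudo-inverted.
* Whether the difference outcome is regressed in seconds or ms is a
  dialect question; seconds is adopted, consistent with the magnitude of
  its published SEE (13.7).
* Stroop's normative outcome is the per-trial mean response time, and
  its accuracy outcome is modeled as an untransformed count.
* Missingness: each outcome is scored independently; only the composite
  requires completeness.
* The acceptance summary (`scripts/acceptance.py`) uses a reference
  cohort of n = 1063 and 200 simulate-and-refit replicates for the
  recovery estimates; the replicate count keeps the Monte-Carlo error of
  the mean recovered age slope near 4·10⁻⁵, well inside its 3-decimal
  reporting precision.

## Known limitations

* The generator's equicorrelated residual structure is a stand-in; real
  inter-test correlations are surely not exchangeable.
* Fitting the B−A model to generator output recovers the published B−A
  coefficients only approximately (see above).
* Norms fitted on one demographic mix should not be extrapolated to
  education levels or ages unseen in the reference sample — the scorer
  raises on unseen categorical levels but cannot guard against age
  extrapolation.
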