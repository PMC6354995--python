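# Methods

## Criterion energy expenditure

Total energy expenditure is computed from gas exchange with the abbreviated
Weir equation, EE = 3.941·V̇O₂ + 1.106·V̇CO₂ (kcal·min⁻¹, gas in L·min⁻¹).
The urinary-nitrogen term is neglected: participants in treadmill
calibration protocols are fasted and protein oxidation contributes at most a
percent-level correction over 5-minute stages. The coefficient pair is kept
as a named constant (`WEIR_KCAL_PER_L_O2`, `WEIR_KCAL_PER_L_CO2`) so
alternative conventions can be configured. Dietary-induced thermogenesis is
ignored (fasted protocol).

PAEE is EE minus the per-minute resting metabolic rate, RMR/1440. Negative
PAEE values (expenditure below rest, possible in noisy low-intensity data)
are reported with a warning rather than clipped: clipping would truncate the
lower tail of the difference distribution and bias the Bland–Altman and
error statistics.

METs are defined relative to each participant's measured RMR
(MET = EE ÷ RMR/1440), which makes the resting stage exactly 1.0 and uses
the individual information the protocol actually collects. The population
convention (3.5 mL O₂·kg⁻¹·min⁻¹) is deliberately not the default; it would
decouple the rest row from 1.0 whenever a participant's measured RMR departs
from the population value.

Steady-state values are arithmetic means over the final 2 minutes of each
5-minute stage (samples with t ≥ 180 s at 30-s epochs, i.e. 4 epochs). A
stream that does not reach the averaging window raises an incomplete-task
error rather than silently averaging a transient.

## Calibration model and cross-validation

The prediction model is OLS of criterion PAEE on PAC and HR with an
intercept, fitted separately per group on the walking stages. The rest stage
is excluded from calibration and agreement: its criterion is zero by
definition (EE = RMR), which is a constraint of the protocol rather than an
observation of the sensor-to-energy relationship, and agreement statistics
are reported for treadmill walking. Rank deficiency (a constant or collinear
predictor) raises an error naming the offending column instead of returning
a minimum-norm solution.

The cross-validation unit is the participant: for each fold one
participant's stages are held out and the model is refitted on everyone
else. Observation-level leave-one-out would leak within-subject information
(the same participant's other stages would remain in the training set) and
overstate accuracy in samples of 9–10 subjects. A participant-level
bootstrap (resample subjects with replacement, refit) is provided as an
optional uncertainty summary; it is distinct from, and not a substitute
for, the leave-one-participant-out analysis.

Fit diagnostics follow the usual conventions: SEE = √(RSS/(n−p)) with p
counting the intercept (3 for PAC+HR, 2 for HR-only; externally supplied
prediction series use p = 1 since no parameters of ours were estimated),
and classical coefficient standard errors from σ̂²(XᵀX)⁻¹.

## Agreement statistics

Differences are taken as predicted − criterion, so a method that
underestimates shows a negative bias. Limits of agreement are
bias ± 1.96·SD(d) with the sample SD (ddof = 1); the multiplier is a named
constant. MAPE is averaged over pairs with positive criterion only — at
rest the criterion is exactly zero and a percentage error is undefined —
so "across all activities" in this package means across walking stages.
The power computation uses the two-sided normal-approximation paired form,
n = ⌈((z₁₋α/₂ + z₁₋β)/d)²⌉, which gives n = 8 at d = 1.0, α = 0.05,
power = 0.8.

## Synthetic cohort: what it emulates

The generator reproduces the structure of a three-group treadmill
calibration study. Defaults (all overridable):

| parameter | default | rationale |
| --- | --- | --- |
| group sizes | 9 / 10 / 9 (unilateral / bilateral / control) | study design |
| RMR (kcal·day⁻¹) | N(1776, 269) / N(1596, 178) / N(1846, 191) | published group demographics |
| resting HR (bpm) | N(66, 11) / N(67, 10) / N(54, 4) | published group demographics |
| task battery | rest + 0.48, 0.67, 0.89, 1.12, 1.34 m·s⁻¹ + 3%, 5% @ 0.89 | study protocol, 5-min stages |
| epoch length | 30 s | device recording epoch |
| onset time constant τ | 45 s | V̇O₂ steady state reached within 3 min; only the final-2-min plateau is consumed downstream, so the transient shape is non-critical |
| economy factor | lognormal, mean 1, σ = 0.15 | between-subject variance device; preserves positivity and yields coefficients of variation comparable to the published task-level SDs |
| steady-state scatter | PAC cv 10%, HR sd 5 bpm | between-subject task-level spread beyond the economy factor |
| epoch noise | PAC cv 5%, HR sd 1.5 bpm, gas cv 2% | epoch-to-epoch measurement noise; largely averaged out by the 4-epoch window |
| residual SD (kcal·min⁻¹) | 0.78 / 0.96 / 0.48 | the published SEE per group — the only printed estimate of unexplained scatter |
| completion probabilities | empirical completer fraction per group-task | e.g. 2/10 bilateral completers at 1.34 m·s⁻¹ |

Per participant-task, steady-state PAC and HR are drawn first, centred on
the published group-task means (the HR rise above rest and the PAC output
both scaled by the participant's economy factor), and the criterion PAEE is
then generated as TrueModel(PAC, HR) plus independent Gaussian residual.
This sensors-first direction is a deliberate design choice: it matches the
causal direction the regression model assumes, making OLS coefficient
recovery exactly unbiased. (The alternative — drawing PAEE first and
solving PAC back through the model — would make the regression residual
correlated with PAC and bias every downstream fit.) Because the published
equations are near-consistent with the published group-task means, the
simulated group PAEE means still converge to the published targets to
within ~2%.

Gas channels are obtained by inverting the Weir equation at the group-task
RER (V̇CO₂ = RER·V̇O₂), so calorimetry recomputes the intended energy
expenditure exactly; in noiseless mode the round trip is exact to machine
precision and the whole pipeline recovers the generating coefficients to
≤1e−9 relative error — the identifiability check the test suite exercises.

Dropout is independent Bernoulli per participant-task by default (the study
reports counts, not a mechanism), with an optional monotone mode in which
failing one stage fails all later walking stages in protocol order. A
non-completed stage is an empty stream, never a crash.

Determinism: every stream is a pure function of (configuration, master
seed); per-participant and per-task substreams are derived from
SeedSequence(seed, CRC32(participant id), CRC32(task name)) with distinct
salts for cohort draws, activity simulation and dropout. Identical runs
produce byte-identical datasets and report bundles.

### What the generator does not emulate

Real epoch data exhibit autocorrelated HR drift, breath-by-breath gas
noise, task-dependent RER drift within a stage, device-specific count
saturation, and within-subject correlation of economy across tasks beyond
the single scalar factor used here. Passing tests therefore demonstrate
that the statistical machinery is correct under the stated generative
model — not that any particular accuracy level would be attained on real
amputee gait data. Individual-level results (correlations, limits of
agreement) depend on raw participant data that public reports do not
include; the test suite substitutes distribution-level properties
(oracle-checked OLS, unbiased coefficient recovery, nominal
limits-of-agreement coverage, noiseless identifiability, seed
determinism).

## Numerical and degenerate-input choices

- Zero-SD group specs produce exactly degenerate (all-equal) profiles.
- TEE is floored at 0 when a large negative residual would push it below
  zero (gas volumes cannot be negative); untruncated criterion values are
  otherwise passed through.
- The correlation of a zero-variance series is an explicit error, not NaN.
- A leave-one-out fold whose training design is singular is skipped with a
  warning and NaN predictions; the remaining folds are unaffected.
- Report CSVs are written with full float precision and fixed ordering so
  fixed-seed runs are byte-identical.

## Known limitations

- The monotone dropout mode orders stages by protocol order; other
  orderings (e.g. by energetic cost) are not modelled.
- Group-level PCI computed from group-mean heart rates (ratio of means)
  differs from the mean of per-subject PCIs by ~2–3% in fully completing
  groups and by up to ~12% where dropout changes the completer subset
  between the rest row and a task row; both variants are reported.
- The proprietary multi-sensor device algorithm is represented only as an
  externally supplied prediction column; its internal model is not public
  and is not re-implemented.
- HR-only and PAC+HR models share the OLS machinery; published
  covariate-augmented variants (amputation level, waist circumference,
  body mass) are out of scope.
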