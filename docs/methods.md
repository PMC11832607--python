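# Methods

`crimpsim` is a Monte Carlo laboratory for one question: when the
analysis model is a cause-specific Cox model with competing risks and
covariates are missing at random, how should the outcome enter the
imputation models?  It compares chained-equations imputation (MICE with
predictive mean matching) under two outcome-predictor strategies against
substantive-model-compatible FCS (SMCFCS), with complete-case and
no-missing reference arms.

## Data-generating process

Each subject carries 10 covariates (age, systolic blood pressure, heart
rate, hemoglobin, cholesterol; and binary female, angina, diabetes,
previous AMI, current smoker).  Covariates are drawn from a 10-variate
normal; the last five coordinates are latent scores dichotomized at the
analytic `(1 - prevalence)` quantile of their own marginal, so the
expected prevalence is exact at every sample size and the threshold
never depends on the realized sample.

The real AMI cohort's mean vector, covariance matrix and prevalences are
not public.  The package ships one canonical synthetic covariate model
(`default_covariate_model`): age 65 ± 12 y, SBP 145 ± 25 mmHg, heart
rate 80 ± 18 bpm, hemoglobin 13.5 ± 1.8 g/dL, cholesterol 5.0 ± 1.1
mmol/L; prevalences 0.35 / 0.30 / 0.25 / 0.20 / 0.30; and a sparse
correlation structure with |r| ≤ 0.3 whose strict diagonal dominance
guarantees positive definiteness.  It is a stand-in with clinically
plausible scales, not a reconstruction of the cohort; every
acceptance-level experiment in the package references this one model.

Outcomes come from three constant cause-specific hazards
λ_k·exp(x'β_k), k ∈ {cardiovascular, cancer, other}, with the published
log-hazard-ratio vectors as defaults (`default_coefficient_set`).  The
event time is inverted from a single uniform,

    T = −log(u1) / Σ_k λ_k exp(x'β_k),

and the event type is multinomial with probabilities proportional to the
cause-specific hazards — so the cause-k hazard is exactly λ_k·exp(x'β_k)
and the cause-specific Cox models are correctly specified by
construction.  No latent failure times are ever drawn.  Censoring is
exponential; its rate is calibrated by bisection on log λ_c so the
realized censored fraction hits the target (default 25%) within 0.001.
One uniform per subject is drawn once and reused across bisection
iterations, which makes the calibration objective deterministic and
monotone.  The "true" coefficients of a scenario are the three Cox fits
on the complete super-population, not the generating vectors — sampling
error in the super-population is part of the estimand, as is standard
for super-population simulation designs.

## Missingness

Eight covariates can be missing (age and sex are registry-derived and
always complete, as are time and event type).  Missingness follows a
multi-pattern MAR design in the style of multivariate amputation: 67
binary patterns over the 8 variables with fixed relative frequencies;
every record is assigned a candidate pattern (multinomial) and becomes
incomplete with probability `expit(a + s)`, where `s` is the record's
standardized equal-weight sum score over the covariates its pattern
leaves observed and the intercept `a` is bisected so the realized
incomplete fraction equals p_missing within 0.002.  Standardizing the
sum score per pattern makes acceptance pattern-independent, so realized
pattern frequencies follow the library.  The mechanism never sees the
outcome, and never a record's own amputed values, so it is MAR by
construction; a logistic regression of the incompleteness indicator on
the outcome given the covariates recovers a null outcome coefficient.

The cohort's 67-pattern frequency table is unpublished.  The packaged
library is a deterministic synthetic stand-in: conditional-on-incomplete
marginals are taken as the published per-variable missingness shares
divided by the overall incomplete share (48.1%), pattern probabilities
are the independence products over the 8 flags, and the 67 most probable
nonzero masks are kept and renormalized.  This reproduces the qualitative
structure — a dominant single-variable cholesterol pattern, smoker a
distant second, everything else rare — but not the cohort's actual table.
Amputation is applied once to the super-population; replicates sample
from the amputed population.

## Imputation engines

**MICE/PMM.**  Every incomplete variable (continuous or binary) is
imputed by type-1 predictive mean matching: Bayesian linear regression
(residual variance from a scaled inverse-χ², coefficients from their
normal posterior), predicted means with point estimates for observed
rows and drawn parameters for missing rows, and the observed value of
one of k = 5 nearest-predicted-mean donors copied at random.  Predictor
sets per target variable:

- `all_causes`: the 9 other covariates, the three cause-specific
  Nelson–Aalen cumulative hazards at the record's observed time, the
  three event-type indicators, and the 27 hazard × covariate
  interactions (42 columns);
- `primary_only`: the 9 other covariates, the cardiovascular hazard and
  indicator, and its 9 interactions (20 columns).

Hazard features depend only on time/event (always complete) and are
computed once per sample; interaction columns are recomputed from
current imputed values every cycle (passive updating — the only coherent
choice inside chained equations).  Chains are initialized by resampling
observed values; the visit order is fixed ascending missingness count;
10 cycles and M chains run independently.  Donor count, cycles and order
are not dictated by the study design; the defaults follow common FCS
practice and are overridable from the CLI.

**SMCFCS.**  Imputations are made compatible with all three
cause-specific hazard models by rejection sampling.  Per cycle: the
three Cox models are refit on the current completed data, coefficient
vectors are drawn from their asymptotic normal posteriors, and Breslow
baseline cumulative hazards are rebuilt at the drawn coefficients; then
each incomplete variable is imputed by proposing from its covariate
model given the other nine covariates only (Bayesian linear regression
for continuous, logistic with a normal posterior draw for binary) and
accepting with probability proportional to the outcome-likelihood factor

    Π_k exp(x'b_k)^{1(event=k)} · exp(−H0_k(T) · exp(x'b_k)),

the exact term by which the joint density differs from the covariate
model (baseline jump factors free of x cancel).  No closed-form envelope
exists for continuous proposals, so the per-record bound is 1.5 × the
largest weight among the record's first 20 proposals, refreshed each
cycle; the acceptance ratio is clipped at 1, a documented approximation.
A cell exhausting `max_rejections = 1000` proposals keeps its
best-weight proposal (exhaustion counts are logged).  A Cox divergence
triggers one chain re-initialization before failing.  Cycles default to
10, matching the MICE engine so strategies are compared on equal terms.

## Analysis and pooling

Cause-specific Cox models treat competing events as censoring at their
time.  Fitting uses the package's own Newton–Raphson partial-likelihood
maximizer with Efron tie handling (simulated times are continuous, so
ties are measure-zero and Efron equals Breslow; the choice is inert but
explicit).  The score and observed information are assembled from suffix
cumulative sums plus a summation-reordering identity, so a fit costs
O(n p²) per Newton step with BLAS-level overhead only — the property
that makes 10⁴-fit simulation runs tractable on one core.  The fitter is
verified against an independent partial-likelihood implementation
(lifelines) to 1e-6 on a tied-time fixture, and Breslow baselines reduce
to Nelson–Aalen at β = 0.

Rubin's rules pool M estimates: Q̄ = mean, Ū = mean within-variance, B =
between-variance, T = Ū + (1 + 1/M)B.  Intervals use t quantiles with
Barnard–Rubin degrees of freedom, combining ν_old = (M−1)/λ² and
ν_obs = ((ν_com+1)/(ν_com+3))·ν_com·(1−λ) harmonically, with
ν_com = n − 10 (records minus covariates; the design does not dictate
this and n − 10 is the conventional complete-data choice).  B = 0 is
handled as the no-missing-information limit.  The reference arms
(complete-case, no-missing) use Wald intervals with t quantiles at
n − 10 degrees of freedom.

## Performance metrics

Per (scenario, method, cause, coefficient): relative bias
100·(mean(Q̄) − β_true)/β_true (undefined at β_true = 0, where only
absolute bias is reported), absolute bias, empirical 95% CI coverage,
and mean estimated SE, each with Monte Carlo standard errors.  At 1,000
replicates the normal-theory significance band around 95% coverage is
[93.65%, 96.35%].  Replicates in which a method fails are dropped for
that method with a logged count (`n_reps_used`).

## Problem sizes and determinism

The full design is 30 scenarios (5 rate triplets × 6 missingness
levels) at n_super = 10⁶, n_sample = 1,000, 1,000 replicates, M = 10.
The packaged test and acceptance experiments run a scaled-down profile —
n_super = 10⁵ (2×10⁵ for the coefficient-recovery check), 100
replicates, M = 5 — flagged `scaled_down` in outputs; the grid runner
accepts either profile and is resumable per scenario.  All randomness
flows through numpy `SeedSequence` spawning (scenario seed → replicate →
chain), so every stage is bit-reproducible given its seed.  Relative
bias of small true coefficients (e.g., hemoglobin, |β| < 0.01) is
intrinsically noisy at 100 replicates; coverage and absolute bias are
the stable summaries at desk scale.

## Known limitations

- The covariate model and pattern library are synthetic stand-ins; tests
  establish internal validity of the pipeline under those defaults, not
  agreement with the unpublished cohort moments.
- Constant baseline hazards only; no administrative truncation.
- No Fine–Gray/subdistribution modeling, no MNAR/MCAR mechanisms, no
  auxiliary variables in the shipped simulation design.
- The SMCFCS rejection envelope is adaptive rather than exact, so
  acceptance is approximate in the extreme tails of the proposal
  distribution.
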