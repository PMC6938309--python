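# Methods

## The model

AUD status at an assessment is a binary state: 0 = No-AUD, 1 = AUD. Between
assessments the state is modelled as a two-state continuous-time Markov
chain whose transition intensities depend log-linearly on the covariates
observed at the earlier assessment:

    log q_01 = α_01 + β_01·z      (onset:     No-AUD → AUD)
    log q_10 = α_10 + β_10·z      (remission: AUD → No-AUD)

`exp(β)` is the hazard ratio (HR) per one unit of the covariate on its
instrument scale; covariates are deliberately *not* standardized, so an HR
reads "per ASSIST point", "per year of age", and so on. Inhomogeneity enters
only through the covariates: intensities are constant within an
inter-assessment interval and updated at each observed assessment
(piecewise-constant generator). There is no absorbing state, no frailty, and
no time dependence within an interval.

Because the chain has two states, `P(dt) = expm(Q·dt)` has a closed form:
with `s = q_01 + q_10` and `E = exp(-s·dt)`,

    P_00 = (q_10 + q_01·E)/s ,  P_11 = (q_01 + q_10·E)/s ,

off-diagonals by complement. The implementation uses this closed form
everywhere; the test suite pins it against `scipy.linalg.expm` to 1e-10
over a wide rate/gap grid, and checks Chapman–Kolmogorov consistency.

## Panel likelihood

The data are panel observations: the state is seen only at assessment
times. The likelihood unit is the pair of consecutive *observed*
assessments; a missed wave simply lengthens the gap `dt` of the spanning
pair (e.g. a skipped 6-month wave yields one pair with `dt ≈ 12.7` months)
and requires no assumption about the unobserved interim state. The
log-likelihood is

    ℓ(θ) = Σ_pairs log P_{s_pre, s_post}(dt; z_pre) ,

summed with compensated (fsum) summation so the value is independent of
pair order. Pairs with a missing pre-transition covariate are dropped from
fitting with a logged count; no imputation is attempted.

## Constraints and parameterization

A covariate whose effect on *future* AUD does not depend on the current
state satisfies β_01 = −β_10. Constrained covariates contribute a single
free parameter γ (β_01 = γ, β_10 = −γ), which makes the onset and remission
HRs exact reciprocals — an algebraic identity of the parameterization, not
a numerical coincidence. The free parameter vector is
(α_01, α_10, {γ_c}, {β_01,k, β_10,k}) and is optimized unbounded;
positivity of intensities follows by exponentiation.

## Fitting

Maximum likelihood by BFGS with the analytic score (the closed-form `P` is
differentiated in the two rates, then chain-ruled through the log-linear
predictors). Starting values are method-of-moments: log crude rates
(events ÷ time at risk, with a half-count continuity guard) for the
intercepts and zero for all slopes; by default two further seeded random
perturbations of that start are tried and the best optimum kept. A fit is
accepted when BFGS reports success or the score's sup-norm is below
1e-6·(1+|ℓ|) — BFGS line searches routinely stall within rounding error of
the optimum on likelihoods of magnitude ~10³.

The covariance is the inverse observed information, computed by central
differences of the analytic score with relative step 1e-5 and symmetrized;
a singular information matrix falls back to the pseudo-inverse with a
warning flag. Wald CIs for HRs are formed on the log scale and
exponentiated. Linear predictors beyond ±50 raise an explicit overflow
error (and act as a barrier during optimization).

## Model-building workflow

Per age stratum (< 21 vs ≥ 21 at the *earlier* assessment of each pair —
consistent with using pre-transition covariates):

1. **Entry screening.** Pair-type contrasts (No→No vs No→AUD; AUD→No vs
   AUD→AUD): Welch t for numeric covariates, Yates-corrected chi-square for
   binary ones, on person-transition pairs without clustering adjustment. A
   covariate enters if either contrast has p < 0.05; age, sex, race and
   public assistance always enter.
2. **Symptom combination.** Anxiety and depression scores are averaged into
   one internalizing score whenever either screens in; the sources remain in
   descriptive output but not in models.
3. **State-dependence test.** For each entering covariate, the unadjusted
   single-covariate model is fit unconstrained and constrained, and
   compared by LRT on 1 df (the constrained model is nested, so the
   statistic is clipped at 0). The LRT was chosen over a Wald contrast for
   invariance to parameterization. Demographics are tested the same way, as
   strictly single-covariate models.
4. **Constraint selection.** p > 0.20 → constrain. The permissive threshold
   avoids imposing state-independence unless the data offer very little
   against it, which matters at stratum-level transition counts (tens of
   events). Selection is monotone in the threshold by construction.
5. **Adjusted fit.** One joint fit per stratum with the selected constraint
   set; constrained rows are daggered in rendered tables.

## Goodness of fit

Pearson-type lack of fit: pairs are grouped by pre-state × gap tertile ×
tertile of the fitted onset linear predictor; per group and post-state,
`T = Σ (o−e)²/e` with `e` the summed fitted probabilities. Blocks whose
minimum expected count falls below 5 are collapsed into the neighbouring
group. Because the cells mix heterogeneous gaps and covariates, `T` has no
clean asymptotic null; the p-value is a parametric bootstrap: post-states
re-simulated from the fitted model conditional on the observed pre-states,
gaps and covariates, the model refit (toggleable), and `T` recomputed with
the replicate's own grouping. `p = (1 + #{T_b ≥ T}) / (B + 1)` is never 0.
Replicate refit failures above 5% abort with diagnostics.

## Synthetic cohort generator

The generator emulates the study design the analysis assumes: n = 599
subjects, baseline plus four follow-ups at gaps N(6, 0.4²) months (clipped
positive), per-follow-up MCAR missingness 0.163 (baseline never missing,
matching ≥83.7% per-wave retention), baseline age uniform on 14–25 years,
static demographics (male 0.588, Black 0.583, public assistance 0.730).
Time-varying scores evolve as stationary AR(1) processes clamped to their
instrument ranges, with marginal means/SDs near the published descriptives
and lag-one persistence ρ of 0.6–0.7 (a design choice; the study reports no
autocorrelations). Binary victimization indicators persist with probability
0.6, else redraw.

States evolve wave-to-wave by direct draws from the closed-form `P(dt)` at
the earlier wave's covariates — the exact marginal law the panel likelihood
sees, so no event-time simulation is needed — with the baseline state drawn
from the stationary probability q_01/(q_01+q_10) at baseline covariates.
The "study" preset uses the published adjusted hazard ratios as true
coefficients (separate truths for the underage and legal strata, switching
at age 21) and baseline rates of 0.012/0.090 (underage onset/remission) and
0.010/0.080 (legal) events/month at stratum-typical covariates, chosen to
match the published crude transition tallies; intercepts are derived from
those anchors at preset construction.

What the generator does **not** emulate: informative dropout (missingness
is MCAR), cross-sectional covariate correlation beyond what the shared
state path induces, measurement error in the diagnostic interview, and the
recruitment mix over age/sex strata. Passing recovery and calibration tests
therefore demonstrates correctness of the estimator and procedure under the
assumed design, not robustness to violations of it.

## Numerical and design choices

- Time unit: months; intensities are per-month rates.
- Stratum boundary: age_pre < 21 → underage; exactly 21 → legal.
- Intercept recovery is assessed in a centred parameterization: covariates
  are shifted by fixed stratum-typical values before fitting, so the
  intercepts are log baseline rates for a typical subject rather than an
  extrapolation to covariate zero (where collinearity with age inflates
  their SE to ≈1.8). This is a shift of origin only; slopes and their CIs
  are unchanged.
- Degenerate inputs: a covariate constant across pairs is flagged
  unidentifiable; a direction with zero observed transitions triggers a
  weak-identification warning; empty pair tables are rejected.
- Replication sizes in the shipped tests: 100 cohorts for recovery, 500 for
  LRT calibration, 50 outer × B = 200 for bootstrap calibration — sizes at
  which the acceptance bands (±0.1 bias, [90, 99]% coverage, [3, 8]%
  type-I, KS at 1%) are informative without being dominated by Monte Carlo
  noise.

## Known limitations

- Only the two-state chain is implemented; the closed form does not extend
  to larger state spaces.
- Descriptive contrasts ignore within-subject clustering, so their p-values
  gate model entry but are not themselves inferential claims.
- The bootstrap GOF can correctly flag lack of fit when stratum-level
  screening (which is noisy at tens of events) omits a truly active
  covariate; that is a feature of the test, not an artefact.
- No multiple-testing correction is applied anywhere in the workflow, by
  design.
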