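"""Model-building procedure for the transition analysis.

The pipeline per age stratum:

1. descriptive pair-type contrasts gate model entry — a covariate enters if
   either its onset contrast or its remission contrast is significant at
   0.05; demographic controls (age, sex, race, public assistance) enter
   regardless;
2. anxiety and depressive symptom scores are combined by averaging (they are
   collinear and act alike), the combined score replacing both in models;
3. each entering covariate's *state-dependence* is tested on an unadjusted
   single-covariate model: the unconstrained fit (separate onset and
   remission coefficients) against the constrained fit (beta_onset =
   -beta_remission), by likelihood-ratio test on 1 df;
4. covariates with little evidence of state-dependence (p > 0.20) are
   constrained in the adjusted model — borrowing information across states —
   and the final joint model is fit with the selected constraint set.

The permissive 0.20 threshold deliberately avoids imposing the constraint
unless the data offer very little against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import descriptives
from .ctmc import FitResult, IntensityModel, fit_mle, hazard_ratios
from .panel import CovariateSchema, PanelCohort

logger = logging.getLogger(__name__)

DEMOGRAPHICS = ("age", "male", "black", "public_assistance")


@dataclass(frozen=True)
class WorkflowConfig:
    """Thresholds and rules of the model-building procedure."""

    screening_alpha: float = 0.05
    state_dependence_threshold: float = 0.20
    always_include: tuple[str, ...] = DEMOGRAPHICS
    combine_rules: dict = field(default_factory=lambda: {"dep_anx": ("anxiety", "depression")})
    age_cutoff: float = 21.0
    starts: int = 3

    def __post_init__(self) -> None:
        for t in (self.screening_alpha, self.state_dependence_threshold):
            if not (0.0 < t < 1.0):
                raise ValueError(f"thresholds must lie in (0, 1), got {t}")


@dataclass
class StateDependenceResult:
    """Likelihood-ratio test of beta_onset = -beta_remission for one covariate."""

    covariate: str
    loglik_unconstrained: float
    loglik_constrained: float
    statistic: float
    df: int
    p: float

    def constrain(self, threshold: float = 0.20) -> bool:
        return self.p > threshold


def combine_covariates(cohort: PanelCohort, name: str, sources: tuple[str, ...]) -> PanelCohort:
    """Add a covariate that is the element-wise mean of the named sources.

    Sources are retained (for descriptives) but callers exclude them from
    models once the combination exists.
    """
    missing = [s for s in sources if s not in cohort.data.columns]
    if missing:
        raise ValueError(f"combination sources missing from cohort: {missing}")
    data = cohort.data.copy()
    data[name] = data[list(sources)].mean(axis=1)
    ranges = dict(cohort.schema.ranges)
    lo = float(np.mean([ranges[s][0] for s in sources]))
    hi = float(np.mean([ranges[s][1] for s in sources]))
    ranges[name] = (lo, hi)
    return PanelCohort(data=data, schema=CovariateSchema(ranges=ranges), metadata=dict(cohort.metadata))


def screen_unadjusted(pairs: pd.DataFrame, covariates: list[str], seed: int | None = None,
                      starts: int = 3) -> pd.DataFrame:
    """Single-covariate unconstrained fits: onset and remission HRs with CIs.

    Fit failures are recorded per covariate without aborting the batch.
    """
    rows = []
    for i, cov in enumerate(covariates):
        model = IntensityModel(covariates=(cov,))
        try:
            fit = fit_mle(model, pairs, starts=starts, seed=None if seed is None else seed + i)
            hr = hazard_ratios(fit).iloc[0].to_dict()
            hr["covariate"] = cov
            hr["error"] = ""
            rows.append(hr)
        except Exception as exc:  # propagate per-covariate, keep the batch alive
            logger.warning("unadjusted fit failed for %s: %s", cov, exc)
            rows.append({"covariate": cov, "error": str(exc)})
    return pd.DataFrame(rows)


def test_state_dependence(pairs: pd.DataFrame, covariate: str, seed: int | None = None,
                          starts: int = 3) -> StateDependenceResult:
    """LRT of the state-independence constraint on a single-covariate model."""
    free = IntensityModel(covariates=(covariate,))
    tied = IntensityModel(covariates=(covariate,), constrained=frozenset({covariate}))
    fit_free = fit_mle(free, pairs, starts=starts, seed=seed, compute_cov=False)
    fit_tied = fit_mle(tied, pairs, starts=starts, seed=seed, compute_cov=False)
    if not fit_free.converged:
        raise RuntimeError(f"unconstrained fit for {covariate!r} did not converge")
    if not fit_tied.converged:
        raise RuntimeError(f"constrained fit for {covariate!r} did not converge")
    stat = max(0.0, 2.0 * (fit_free.loglik - fit_tied.loglik))
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return StateDependenceResult(
        covariate=covariate,
        loglik_unconstrained=fit_free.loglik,
        loglik_constrained=fit_tied.loglik,
        statistic=stat,
        df=1,
        p=p,
    )


def select_constraints(results: list[StateDependenceResult], threshold: float = 0.20) -> frozenset[str]:
    """Covariates with p above the threshold get the state-independence constraint."""
    return frozenset(r.covariate for r in results if r.p > threshold)


def fit_final_model(pairs: pd.DataFrame, covariates: list[str], constraints: frozenset[str],
                    seed: int | None = None, starts: int = 3) -> tuple[FitResult, pd.DataFrame]:
    """Joint adjusted fit with the selected constraint set; returns (fit, HR table)."""
    model = IntensityModel(covariates=tuple(covariates),
                           constrained=frozenset(constraints) & set(covariates))
    fit = fit_mle(model, pairs, starts=starts, seed=seed)
    table = hazard_ratios(fit)
    return fit, table


def render_hr_table(table: pd.DataFrame) -> pd.DataFrame:
    """Adjusted-model report layout: HR (CI) strings, daggered constrained rows."""
    def cell(hr, lo, hi):
        return f"{hr:.2f} ({lo:.2f}, {hi:.2f})"

    out = pd.DataFrame({
        "covariate": table["covariate"] + np.where(table["constrained"], " †", ""),
        "hr_onset": [cell(*t) for t in zip(table["hr_onset"], table["hr_onset_lo"], table["hr_onset_hi"])],
        "hr_remission": [cell(*t) for t in zip(table["hr_remission"], table["hr_remission_lo"],
                                               table["hr_remission_hi"])],
    })
    return out


@dataclass
class StratumReport:
    """Everything the procedure decided and estimated within one age stratum."""

    stratum: str
    n_pairs: int
    transitions: pd.DataFrame
    contrasts: list
    screened_in: list[str]
    model_covariates: list[str]
    state_dependence: list[StateDependenceResult]
    constraints: frozenset[str]
    fit: FitResult | None
    hr_table: pd.DataFrame | None
    unadjusted: pd.DataFrame | None
    error: str = ""


def run_stratum_analysis(pairs: pd.DataFrame, candidate_covariates: list[str],
                         config: WorkflowConfig, seed: int | None = None) -> StratumReport:
    """Apply the full model-building procedure to one stratum's pairs."""
    stratum = "stratum"
    transitions = descriptives.tabulate_transitions(pairs)
    contrast_covs = [c for c in candidate_covariates if c not in config.always_include]
    contrasts = descriptives.contrast_table(pairs, list(config.always_include) + contrast_covs)
    by_name = {r.covariate: r for r in contrasts}
    screened = [c for c in contrast_covs
                if by_name[c].significant_onset or by_name[c].significant_remission]
    logger.info("screened in by descriptive contrasts: %s", screened)

    # apply combination rules: any selected source is replaced by the mean score
    model_covs = list(config.always_include)
    consumed: set[str] = set()
    for combined, sources in config.combine_rules.items():
        if any(s in screened for s in sources):
            model_covs.append(combined)
            consumed.update(sources)
            logger.info("combining %s -> %s", sources, combined)
    model_covs += [c for c in screened if c not in consumed]

    n_onset = int(((pairs["pre_state"] == 0) & (pairs["post_state"] == 1)).sum())
    n_remission = int(((pairs["pre_state"] == 1) & (pairs["post_state"] == 0)).sum())
    if n_onset == 0 or n_remission == 0:
        return StratumReport(
            stratum=stratum, n_pairs=len(pairs), transitions=transitions, contrasts=contrasts,
            screened_in=screened, model_covariates=model_covs, state_dependence=[],
            constraints=frozenset(), fit=None, hr_table=None, unadjusted=None,
            error=f"insufficient transitions (onset={n_onset}, remission={n_remission})",
        )

    unadjusted = screen_unadjusted(pairs, model_covs, seed=seed, starts=config.starts)
    sd_results = []
    for i, cov in enumerate(model_covs):
        res = test_state_dependence(pairs, cov, seed=None if seed is None else seed + 100 + i,
                                    starts=config.starts)
        logger.info("state-dependence %s: LRT=%.3f p=%.3f -> %s", cov, res.statistic, res.p,
                    "constrain" if res.constrain(config.state_dependence_threshold) else "free")
        sd_results.append(res)
    constraints = select_constraints(sd_results, config.state_dependence_threshold)
    fit, hr_table = fit_final_model(pairs, model_covs, constraints,
                                    seed=None if seed is None else seed + 500,
                                    starts=config.starts)
    return StratumReport(
        stratum=stratum, n_pairs=len(pairs), transitions=transitions, contrasts=contrasts,
        screened_in=screened, model_covariates=model_covs, state_dependence=sd_results,
        constraints=constraints, fit=fit, hr_table=hr_table, unadjusted=unadjusted,
    )


def analyze_cohort(cohort: PanelCohort, config: WorkflowConfig | None = None,
                   seed: int | None = None) -> dict[str, StratumReport]:
    """Combine symptom scores, build pairs, stratify by age, and run each stratum."""
    from .panel import build_transition_pairs, stratify_by_age

    config = config or WorkflowConfig()
    for combined, sources in config.combine_rules.items():
        if all(s in cohort.data.columns for s in sources):
            cohort = combine_covariates(cohort, combined, sources)
    pairs = build_transition_pairs(cohort)
    strata = stratify_by_age(pairs, cutoff=config.age_cutoff)
    combined_names = set(config.combine_rules)
    candidates = [c for c in cohort.schema.names if c not in combined_names]
    reports = {}
    for i, (name, spairs) in enumerate(strata.items()):
        logger.info("=== stratum %s: %d pairs ===", name, len(spairs))
        rep = run_stratum_analysis(spairs, candidates, config,
                                   seed=None if seed is None else seed + 1000 * i)
        rep.stratum = name
        reports[name] = rep
    return reports
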