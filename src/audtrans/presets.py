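"""Bundled cohort specifications.

``study_spec`` emulates the source study design — an urban emergency-department cohort:
599 drug-using youth aged 14-24, five biannual assessments, 16.3% per-wave
attrition, and age-stratified true transition models whose hazard ratios are
taken from the published adjusted estimates (underage cannabis onset HR 1.18,
male onset HR 2.28, and so on). Those coefficients serve as simulation truth
for recovery and calibration exercises, not as claims about new data.

``null_spec`` has no covariate effects and symmetric intensities;
``state_dependent_spec`` carries a covariate whose onset and remission
effects are equal in sign (maximally state-dependent), for power checks.
"""

from __future__ import annotations

import math

import numpy as np

from .ctmc import IntensityModel
from .simulate import Ar1Process, BinaryProcess, CohortSpec, StaticBinary, TruthModel

#: printed composition of the recruited cohort, used as generator presets
STUDY_COMPOSITION = {
    "n_subjects": 599,
    "n_male": 352,
    "n_black": 349,
    "n_public_assistance": 437,
    "n_baseline_cannabis": 583,
    "n_ever_aud": 194,
    "n_interviews": 2631,
    "n_diagnoses": 352,
    "min_wave_retention": 0.837,
}

def composition_percentages(comp: dict | None = None) -> dict:
    """Cohort-composition percentages recomputed from their counts."""
    comp = comp or STUDY_COMPOSITION
    n = comp["n_subjects"]
    return {
        "pct_male": 100.0 * comp["n_male"] / n,
        "pct_black": 100.0 * comp["n_black"] / n,
        "pct_public_assistance": 100.0 * comp["n_public_assistance"] / n,
        "pct_baseline_cannabis": 100.0 * comp["n_baseline_cannabis"] / n,
        "pct_ever_aud": 100.0 * comp["n_ever_aud"] / n,
        "pct_diagnoses_of_interviews": 100.0 * comp["n_diagnoses"] / comp["n_interviews"],
    }


#: covariate processes on their instrument scales (means/SDs near the
#: published descriptives; persistence is a design choice, see docs)
PROCESSES = {
    "male": StaticBinary(p=0.588),
    "black": StaticBinary(p=0.583),
    "public_assistance": StaticBinary(p=0.730),
    "anxiety": Ar1Process(mean=0.55, sd=0.80, rho=0.6, clamp=(0.0, 4.0)),
    "depression": Ar1Process(mean=0.70, sd=0.85, rho=0.6, clamp=(0.0, 4.0)),
    "partner_victimization": BinaryProcess(p=0.45, stay=0.6),
    "nonpartner_victimization": BinaryProcess(p=0.40, stay=0.6),
    "parental_drinking": Ar1Process(mean=1.5, sd=0.70, rho=0.7, clamp=(1.0, 5.0)),
    "parental_support": Ar1Process(mean=3.1, sd=1.30, rho=0.7, clamp=(1.0, 5.0)),
    "friend_drinking": Ar1Process(mean=2.4, sd=1.10, rho=0.6, clamp=(1.0, 5.0)),
    "friend_positive_influence": Ar1Process(mean=2.2, sd=0.70, rho=0.6, clamp=(1.0, 5.0)),
    "community_violence": Ar1Process(mean=1.5, sd=0.90, rho=0.6, clamp=(1.0, 4.0)),
    "cannabis_use": Ar1Process(mean=1.7, sd=1.40, rho=0.7, clamp=(0.0, 6.0)),
}

DERIVED = {"dep_anx": ("anxiety", "depression")}

# adjusted hazard ratios used as simulation truth: (onset HR, remission HR)
# or a single HR for state-independent (constrained) effects
_UNDERAGE_EFFECTS = {
    "age": (0.83, 0.71),
    "male": (2.28, 1.57),
    "black": 0.73,
    "public_assistance": 0.87,
    "dep_anx": (0.95, 0.76),
    "parental_drinking": (0.62, 0.53),
    "friend_drinking": (1.70, 1.26),
    "community_violence": 1.04,
    "cannabis_use": 1.18,
}
_LEGAL_EFFECTS = {
    "age": 1.06,
    "male": (3.00, 1.13),
    "black": (0.57, 1.05),
    "public_assistance": 0.86,
    "dep_anx": 1.35,
    "friend_drinking": 1.18,
    "community_violence": (0.77, 0.69),
}

#: baseline transition rates (events/month) at stratum-typical covariates,
#: chosen to match the published crude transition tallies
_TARGET_RATES = {"underage": (0.012, 0.090), "legal": (0.010, 0.080)}
_TYPICAL_AGE = {"underage": 18.3, "legal": 22.7}


def _typical_z(covariates: tuple[str, ...], stratum: str) -> np.ndarray:
    z = []
    for c in covariates:
        if c == "age":
            z.append(_TYPICAL_AGE[stratum])
        elif c in DERIVED:
            z.append(float(np.mean([PROCESSES[s].mean for s in DERIVED[c]])))
        else:
            p = PROCESSES[c]
            z.append(p.mean if isinstance(p, Ar1Process) else p.p)
    return np.array(z)


def _truth_from_effects(effects: dict, stratum: str) -> TruthModel:
    covariates = tuple(effects)
    constrained = frozenset(c for c, hr in effects.items() if not isinstance(hr, tuple))
    model = IntensityModel(covariates=covariates, constrained=constrained)
    b01 = np.array([math.log(hr[0] if isinstance(hr, tuple) else hr) for hr in effects.values()])
    b10 = np.array([math.log(hr[1]) if isinstance(hr, tuple) else -math.log(hr)
                    for hr in effects.values()])
    zbar = _typical_z(covariates, stratum)
    r01, r10 = _TARGET_RATES[stratum]
    a01 = math.log(r01) - float(b01 @ zbar)
    a10 = math.log(r10) - float(b10 @ zbar)
    params = [a01, a10]
    for c, hr in effects.items():
        if isinstance(hr, tuple):
            params.extend([math.log(hr[0]), math.log(hr[1])])
        else:
            params.append(math.log(hr))
    return TruthModel(model=model, params=np.array(params))


def study_spec(n_subjects: int = 599, n_waves: int = 5, p_miss: float = 0.163,
               seed: int = 0) -> CohortSpec:
    """Cohort generated under the published study design and adjusted effects."""
    return CohortSpec(
        truth={
            "underage": _truth_from_effects(_UNDERAGE_EFFECTS, "underage"),
            "legal": _truth_from_effects(_LEGAL_EFFECTS, "legal"),
        },
        processes=dict(PROCESSES),
        derived=dict(DERIVED),
        n_subjects=n_subjects,
        n_waves=n_waves,
        p_miss=p_miss,
        seed=seed,
    )


def simple_spec(
    beta_onset: float = 0.0,
    beta_remission: float = 0.0,
    alpha_onset: float = math.log(0.05),
    alpha_remission: float = math.log(0.15),
    constrained: bool = False,
    n_subjects: int = 599,
    n_waves: int = 5,
    p_miss: float = 0.0,
    seed: int = 0,
) -> CohortSpec:
    """Single standardized covariate ``x``; the workhorse for calibration studies."""
    model = IntensityModel(covariates=("x",), constrained=frozenset({"x"}) if constrained else frozenset())
    if constrained:
        if beta_remission != -beta_onset:
            raise ValueError("constrained truth requires beta_remission == -beta_onset")
        params = np.array([alpha_onset, alpha_remission, beta_onset])
    else:
        params = np.array([alpha_onset, alpha_remission, beta_onset, beta_remission])
    return CohortSpec(
        truth={"all": TruthModel(model=model, params=params)},
        processes={"x": Ar1Process(mean=0.0, sd=1.0, rho=0.5, clamp=(-4.0, 4.0))},
        n_subjects=n_subjects,
        n_waves=n_waves,
        p_miss=p_miss,
        seed=seed,
    )


def null_spec(n_subjects: int = 599, n_waves: int = 5, rate: float = 0.02,
              p_miss: float = 0.0, seed: int = 0) -> CohortSpec:
    """No covariate effects, symmetric intensities: stationary prevalence 1/2."""
    return simple_spec(alpha_onset=math.log(rate), alpha_remission=math.log(rate),
                       n_subjects=n_subjects, n_waves=n_waves, p_miss=p_miss, seed=seed)


def state_dependent_spec(beta: float = 0.5, n_subjects: int = 599, n_waves: int = 5,
                         seed: int = 0) -> CohortSpec:
    """Covariate raising both onset and remission rates: strong state-dependence."""
    return simple_spec(beta_onset=beta, beta_remission=beta,
                       n_subjects=n_subjects, n_waves=n_waves, seed=seed)


PRESETS = {
    "study": study_spec,
    "null": null_spec,
    "state-dependent": state_dependent_spec,
}
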