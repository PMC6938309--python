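"""Synthetic panel cohorts with the structure the transition analysis assumes.

The generator emulates a prospective emergency-department cohort: ~599
drug-using youth aged 14-24 assessed at baseline and four biannual follow-ups
(jittered 6-month gaps), with per-wave attrition, static demographics, and
time-varying psychosocial covariates evolving as clamped AR(1) processes on
their instrument scales. Binary AUD state paths are drawn wave-to-wave from
the two-state model's closed-form transition probabilities, conditional on
the covariates at the earlier wave — the exact marginal law the panel
likelihood sees, so no event-time simulation is needed.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctmc import IntensityModel
from .panel import CovariateSchema, PanelCohort


@dataclass(frozen=True)
class Ar1Process:
    """Stationary AR(1) covariate on an instrument scale.

    ``mean``/``sd`` are the marginal (stationary) moments, ``rho`` the
    lag-one persistence; values are clamped to the instrument range.
    """

    mean: float
    sd: float
    rho: float
    clamp: tuple[float, float]

    def init(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.clip(rng.normal(self.mean, self.sd, n), *self.clamp)

    def step(self, rng: np.random.Generator, x: np.ndarray) -> np.ndarray:
        innov_sd = self.sd * np.sqrt(1.0 - self.rho**2)
        x_new = self.mean + self.rho * (x - self.mean) + rng.normal(0.0, innov_sd, x.size)
        return np.clip(x_new, *self.clamp)


@dataclass(frozen=True)
class BinaryProcess:
    """Persistent binary covariate: keep the previous value w.p. ``stay``,
    otherwise redraw Bernoulli(``p``)."""

    p: float
    stay: float = 0.6

    clamp: tuple[float, float] = (0.0, 1.0)

    def init(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return (rng.random(n) < self.p).astype(float)

    def step(self, rng: np.random.Generator, x: np.ndarray) -> np.ndarray:
        redraw = rng.random(x.size) >= self.stay
        fresh = (rng.random(x.size) < self.p).astype(float)
        return np.where(redraw, fresh, x)


@dataclass(frozen=True)
class StaticBinary:
    """Baseline demographic indicator, constant across waves."""

    p: float

    clamp: tuple[float, float] = (0.0, 1.0)

    def init(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return (rng.random(n) < self.p).astype(float)

    def step(self, rng: np.random.Generator, x: np.ndarray) -> np.ndarray:
        return x


@dataclass(frozen=True)
class TruthModel:
    """An intensity model together with its true parameter vector."""

    model: IntensityModel
    params: np.ndarray

    def intensities(self, z: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        a01, a10, b01, b10 = self.model.coefficients(self.params)
        Z = np.column_stack([np.asarray(z[c], dtype=float) for c in self.model.covariates]) \
            if self.model.covariates else np.empty((len(next(iter(z.values()))), 0))
        return np.exp(a01 + Z @ b01), np.exp(a10 + Z @ b10)


@dataclass(frozen=True)
class CohortSpec:
    """Full generative description of a synthetic cohort."""

    truth: dict[str, TruthModel]  # keys: "all", or "underage"/"legal" (cut at 21)
    processes: dict[str, Ar1Process | BinaryProcess | StaticBinary]
    derived: dict[str, tuple[str, ...]] = field(default_factory=dict)  # name -> averaged sources
    n_subjects: int = 599
    n_waves: int = 5
    wave_gap_mean: float = 6.0  # months
    wave_gap_jitter_sd: float = 0.4  # months, truncated positive
    p_miss: float = 0.163  # per follow-up wave
    age_range: tuple[float, float] = (14.0, 25.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_miss < 1.0):
            raise ValueError(f"p_miss must be in [0, 1), got {self.p_miss}")
        if self.n_subjects < 1 or self.n_waves < 1:
            raise ValueError("n_subjects and n_waves must be positive")
        if set(self.truth) not in ({"all"}, {"underage", "legal"}):
            raise ValueError("truth must have key 'all' or keys 'underage' and 'legal'")
        for name, tm in self.truth.items():
            for c in tm.model.covariates:
                if c != "age" and c not in self.processes and c not in self.derived:
                    raise ValueError(f"truth model covariate {name}:{c!r} has no generating process")
        for d, sources in self.derived.items():
            for s in sources:
                if s not in self.processes:
                    raise ValueError(f"derived covariate {d!r} references unknown source {s!r}")

    def schema(self) -> CovariateSchema:
        return CovariateSchema(ranges={name: proc.clamp for name, proc in self.processes.items()})


def _covariate_vectors(spec: CohortSpec, cov: dict[str, np.ndarray], age: np.ndarray) -> dict[str, np.ndarray]:
    z = dict(cov)
    z["age"] = age
    for name, sources in spec.derived.items():
        z[name] = np.mean([cov[s] for s in sources], axis=0)
    return z


def _rates(spec: CohortSpec, z: dict[str, np.ndarray], age: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = age.size
    q01 = np.empty(n)
    q10 = np.empty(n)
    if "all" in spec.truth:
        return spec.truth["all"].intensities(z)
    under = age < 21.0
    for key, mask in (("underage", under), ("legal", ~under)):
        if mask.any():
            zm = {k: v[mask] for k, v in z.items()}
            q01[mask], q10[mask] = spec.truth[key].intensities(zm)
    return q01, q10


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> PanelCohort:
    """Draw a complete cohort from the spec, then apply wave missingness.

    Per subject: baseline age uniform on the recruitment range; demographics
    and covariate processes initialised at their stationary laws; wave times
    accumulate jittered 6-month gaps; the baseline state is Bernoulli from
    the stationary AUD probability q01/(q01+q10) at baseline covariates;
    subsequent states are drawn from the closed-form P(dt) with the
    covariates of the earlier wave.
    """
    root_seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    rng, rng_miss = [np.random.default_rng(s) for s in ss.spawn(2)]

    n, W = spec.n_subjects, spec.n_waves
    age0 = rng.uniform(*spec.age_range, n)
    gaps = np.clip(rng.normal(spec.wave_gap_mean, spec.wave_gap_jitter_sd, (n, W - 1)), 0.5, None) \
        if W > 1 else np.empty((n, 0))
    times = np.concatenate([np.zeros((n, 1)), np.cumsum(gaps, axis=1)], axis=1)

    cov = {name: proc.init(rng, n) for name, proc in spec.processes.items()}
    cov_waves = {name: [arr] for name, arr in cov.items()}

    z0 = _covariate_vectors(spec, cov, age0)
    q01, q10 = _rates(spec, z0, age0)
    p_stat = q01 / (q01 + q10)
    states = np.empty((n, W), dtype=int)
    states[:, 0] = (rng.random(n) < p_stat).astype(int)

    for w in range(W - 1):
        age_w = age0 + times[:, w] / 12.0
        z = _covariate_vectors(spec, cov, age_w)
        q01, q10 = _rates(spec, z, age_w)
        dt = times[:, w + 1] - times[:, w]
        s = q01 + q10
        E = np.exp(-s * dt)
        p01 = q01 * (1.0 - E) / s
        p11 = (q01 + q10 * E) / s
        p_next = np.where(states[:, w] == 0, p01, p11)
        states[:, w + 1] = (rng.random(n) < p_next).astype(int)
        cov = {name: proc.step(rng, cov[name]) for name, proc in spec.processes.items()}
        for name, arr in cov.items():
            cov_waves[name].append(arr)

    rows = {
        "subject_id": np.repeat(np.arange(1, n + 1), W),
        "time": times.ravel(),
        "state": states.ravel(),
        "age": (age0[:, None] + times / 12.0).ravel(),
    }
    for name, waves in cov_waves.items():
        rows[name] = np.column_stack(waves).ravel()
    df = pd.DataFrame(rows)
    df["time"] = df["time"].round(2)
    df["age"] = df["age"].round(3)
    numeric = [name for name, p in spec.processes.items() if isinstance(p, Ar1Process)]
    df[numeric] = df[numeric].round(4)

    cohort = PanelCohort(
        data=df, schema=spec.schema(),
        metadata={"synthetic": True, "seed": int(root_seed), "n_subjects": n, "n_waves": W},
    )
    if spec.p_miss > 0:
        cohort = inject_missingness(cohort, spec.p_miss, rng=rng_miss)
    return cohort


def inject_missingness(
    cohort: PanelCohort,
    p_miss: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PanelCohort:
    """Remove each follow-up observation independently with probability p_miss.

    Baseline observations (a subject's first assessment) are never removed;
    a missed wave's covariates vanish with it, so the spanning transition
    pair simply carries a longer gap.
    """
    if not (0.0 <= p_miss < 1.0):
        raise ValueError(f"p_miss must be in [0, 1), got {p_miss}")
    if rng is None:
        rng = np.random.default_rng(seed)
    df = cohort.data
    is_baseline = df.groupby("subject_id")["time"].transform("min") == df["time"]
    drop = (~is_baseline) & (rng.random(len(df)) < p_miss)
    out = df[~drop].reset_index(drop=True)
    meta = dict(cohort.metadata)
    meta["p_miss"] = p_miss
    return PanelCohort(data=out, schema=cohort.schema, metadata=meta)
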