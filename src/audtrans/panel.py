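"""Long-format panel cohorts: reading, validation, transition pairs, strata.

A cohort is one row per subject-assessment with columns ``subject_id``,
``time`` (months since that subject's baseline), ``state`` (0 = No-AUD,
1 = AUD), ``age`` (years at assessment) and one column per covariate. The
likelihood unit is the *transition pair*: two consecutive observed
assessments of one subject, carrying the elapsed gap ``dt`` and the covariate
vector of the earlier assessment. Missed waves are handled implicitly — a
skipped assessment simply lengthens ``dt`` for the pair spanning it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "time", "state", "age")

#: columns of a transition-pair table, ahead of the covariate columns
PAIR_COLUMNS = ("subject_id", "pre_state", "post_state", "dt", "age_pre")

LEGAL_DRINKING_AGE = 21.0


class PanelValidationError(ValueError):
    """Input cohort violates the panel-data contract."""


@dataclass
class CovariateSchema:
    """Declared covariate names and permissible value ranges."""

    ranges: dict[str, tuple[float, float]]

    @property
    def names(self) -> list[str]:
        return list(self.ranges)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CovariateSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cov = raw["covariates"] if isinstance(raw, dict) and "covariates" in raw else raw
        return cls(ranges={name: (float(lo), float(hi)) for name, (lo, hi) in cov.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"covariates": {k: [float(a), float(b)] for k, (a, b) in self.ranges.items()}}, fh)


@dataclass
class PanelCohort:
    """Validated long-format cohort plus its covariate schema."""

    data: pd.DataFrame
    schema: CovariateSchema
    metadata: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_observations(self) -> int:
        return len(self.data)

    def subject_paths(self):
        return self.data.groupby("subject_id", sort=True)


def validate_panel(df: pd.DataFrame, schema: CovariateSchema) -> pd.DataFrame:
    """Validate and canonically sort a raw long-format table.

    Raises :class:`PanelValidationError` naming the first offending rows for
    duplicate (subject, time) keys, non-binary states, negative times,
    non-increasing times within a subject, or out-of-range covariate values.
    Row numbers refer to the input order (0-based, excluding the header).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"missing required columns: {missing}")
    missing_cov = [c for c in schema.names if c not in df.columns]
    if missing_cov:
        raise PanelValidationError(f"missing covariate columns: {missing_cov}")
    df = df.copy()
    # 1-based data-row numbers (header excluded), as a user counts CSV rows
    df["_row"] = range(1, len(df) + 1)

    bad_state = df.loc[~df["state"].isin([0, 1]), "_row"]
    if len(bad_state):
        raise PanelValidationError(f"state outside {{0,1}} at rows {bad_state.tolist()}")
    bad_time = df.loc[df["time"] < 0, "_row"]
    if len(bad_time):
        raise PanelValidationError(f"negative time at rows {bad_time.tolist()}")
    dup = df.duplicated(subset=["subject_id", "time"], keep=False)
    if dup.any():
        raise PanelValidationError(f"duplicate (subject, time) at rows {df.loc[dup, '_row'].tolist()}")
    for name, (lo, hi) in schema.ranges.items():
        col = df[name]
        bad = col.notna() & ((col < lo) | (col > hi))
        if bad.any():
            r = int(df.loc[bad, "_row"].iloc[0])
            raise PanelValidationError(
                f"covariate {name!r} outside declared range [{lo}, {hi}]: "
                f"value {col[bad].iloc[0]!r} at row {r}"
            )
    df = df.sort_values(["subject_id", "time"], kind="mergesort").drop(columns="_row")
    if len(df) == 0:
        logger.warning("empty cohort: header only, no observations")
    return df.reset_index(drop=True)


def read_panel(path: str | Path, schema: CovariateSchema) -> PanelCohort:
    """Read a cohort CSV, validate it, and sort by subject then time."""
    df = pd.read_csv(path)
    data = validate_panel(df, schema)
    return PanelCohort(data=data, schema=schema, metadata={"source": str(path)})


def write_panel(cohort: PanelCohort, path: str | Path) -> None:
    cols = list(REQUIRED_COLUMNS) + cohort.schema.names
    cohort.data[cols].to_csv(path, index=False)


def build_transition_pairs(cohort: PanelCohort) -> pd.DataFrame:
    """One row per consecutive pair of observed assessments within a subject.

    ``dt`` is the actual elapsed gap in months, so a missed wave produces a
    single pair with a roughly doubled gap. Covariates are taken verbatim
    from the earlier observation. Subjects with a single observation
    contribute no pairs; pair count always equals observations - subjects.
    """
    df = cohort.data
    covs = cohort.schema.names
    if len(df) == 0:
        return pd.DataFrame(columns=list(PAIR_COLUMNS) + ["age"] + covs)
    g = df.groupby("subject_id", sort=True)
    nxt_time = g["time"].shift(-1)
    nxt_state = g["state"].shift(-1)
    keep = nxt_time.notna()
    pre = df[keep]
    pairs = pd.DataFrame({
        "subject_id": pre["subject_id"].to_numpy(),
        "pre_state": pre["state"].to_numpy(dtype=int),
        "post_state": nxt_state[keep].to_numpy(dtype=int),
        "dt": (nxt_time[keep] - pre["time"]).to_numpy(dtype=float),
        "age_pre": pre["age"].to_numpy(dtype=float),
    })
    # age at the earlier observation doubles as a model covariate named "age"
    pairs["age"] = pairs["age_pre"]
    for c in covs:
        pairs[c] = pre[c].to_numpy()
    if (pairs["dt"] <= 0).any():
        raise PanelValidationError("non-increasing times within a subject")
    return pairs.reset_index(drop=True)


def stratify_by_age(pairs: pd.DataFrame, cutoff: float = LEGAL_DRINKING_AGE) -> dict[str, pd.DataFrame]:
    """Partition pairs into underage (age_pre < cutoff) and legal strata."""
    if pairs["age_pre"].isna().any():
        raise PanelValidationError("pairs with missing age_pre cannot be stratified")
    under = pairs["age_pre"] < cutoff
    return {
        "underage": pairs[under].reset_index(drop=True),
        "legal": pairs[~under].reset_index(drop=True),
    }
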