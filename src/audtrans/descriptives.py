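"""Descriptive summaries: transition tallies, prevalence, and pair-type contrasts.

Contrasts compare the four consecutive-pair types (No-AUD→No-AUD,
No-AUD→AUD, AUD→No-AUD, AUD→AUD): the *onset contrast* asks whether a
covariate differs between pairs that stayed No-AUD and pairs that
transitioned to AUD; the *remission contrast* does the same among pairs
starting in AUD. The unit of analysis is the person-transition pair — a
subject contributes one row per consecutive assessment pair, and no
clustering adjustment is applied in these screening tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: the four pair types in display order
PAIR_TYPES = [(0, 0), (0, 1), (1, 0), (1, 1)]
PAIR_LABELS = {(0, 0): "noaud_to_noaud", (0, 1): "onset", (1, 0): "remission", (1, 1): "persistence"}

#: recruitment age bands
AGE_BANDS = [(14, 18, "14-17"), (18, 21, "18-20"), (21, 25, "21-24")]


def tabulate_transitions(pairs: pd.DataFrame) -> pd.DataFrame:
    """2x2 table of pair counts, pre-state by post-state."""
    table = pd.DataFrame(0, index=[0, 1], columns=[0, 1])
    counts = pairs.groupby(["pre_state", "post_state"]).size()
    for (i, j), n in counts.items():
        table.loc[i, j] = int(n)
    table.index.name = "pre_state"
    table.columns.name = "post_state"
    return table


def prevalence_any_aud(cohort, groups: bool = True) -> pd.DataFrame:
    """Share of subjects with an AUD diagnosis at >=1 assessment.

    With ``groups=True``, cells are sex x baseline-age band (14-17, 18-20,
    21-24); cells with no subjects are absent from the output.
    """
    df = cohort.data
    per_subject = df.groupby("subject_id").agg(
        any_aud=("state", "max"),
        male=("male", "first") if "male" in df.columns else ("state", lambda s: math.nan),
        baseline_age=("age", "first"),
    )
    rows = []
    if groups and "male" in df.columns:
        for sex, label in [(1, "male"), (0, "female")]:
            sub = per_subject[per_subject["male"] == sex]
            for lo, hi, band in AGE_BANDS:
                cell = sub[(sub["baseline_age"] >= lo) & (sub["baseline_age"] < hi)]
                if len(cell):
                    rows.append({"sex": label, "age_band": band, "n": len(cell),
                                 "n_any_aud": int(cell["any_aud"].sum()),
                                 "proportion": cell["any_aud"].mean()})
    rows.append({"sex": "all", "age_band": "all", "n": len(per_subject),
                 "n_any_aud": int(per_subject["any_aud"].sum()),
                 "proportion": per_subject["any_aud"].mean()})
    return pd.DataFrame(rows)


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return u.size <= 2 and np.all(np.isin(u, [0.0, 1.0]))


def _contrast_p(a: np.ndarray, b: np.ndarray, binary: bool) -> float:
    """Welch t-test for numeric covariates, Yates-corrected chi-square for binary."""
    if len(a) == 0 or len(b) == 0:
        return math.nan
    if binary:
        table = np.array([[np.sum(a == 1), np.sum(a == 0)],
                          [np.sum(b == 1), np.sum(b == 0)]], dtype=float)
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            return 1.0
        return float(stats.chi2_contingency(table, correction=True)[1])
    if np.std(a) == 0 and np.std(b) == 0:
        return 1.0 if (len(a) and len(b) and a[0] == b[0]) else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


@dataclass
class ContrastRow:
    """One covariate's summaries across pair types plus contrast p-values."""

    covariate: str
    binary: bool
    summaries: dict  # pair label -> {"n", "count","pct"} or {"n","mean","sd"}
    p_onset: float
    p_remission: float

    @property
    def significant_onset(self) -> bool:
        return not math.isnan(self.p_onset) and self.p_onset < 0.05

    @property
    def significant_remission(self) -> bool:
        return not math.isnan(self.p_remission) and self.p_remission < 0.05


def contrast_table(pairs: pd.DataFrame, covariates: list[str]) -> list[ContrastRow]:
    """Pair-type contrasts for each covariate, in the style of a Table-1 panel."""
    groups = {pt: pairs[(pairs["pre_state"] == pt[0]) & (pairs["post_state"] == pt[1])]
              for pt in PAIR_TYPES}
    rows = []
    for cov in covariates:
        vals = {pt: g[cov].dropna().to_numpy(dtype=float) for pt, g in groups.items()}
        binary = _is_binary(pairs[cov].dropna().to_numpy(dtype=float))
        summaries = {}
        for pt, v in vals.items():
            lab = PAIR_LABELS[pt]
            if binary:
                summaries[lab] = {"n": len(v), "count": int(v.sum()),
                                  "pct": 100.0 * v.mean() if len(v) else math.nan}
            else:
                summaries[lab] = {"n": len(v), "mean": float(np.mean(v)) if len(v) else math.nan,
                                  "sd": float(np.std(v, ddof=1)) if len(v) > 1 else math.nan}
        rows.append(ContrastRow(
            covariate=cov, binary=binary, summaries=summaries,
            p_onset=_contrast_p(vals[(0, 0)], vals[(0, 1)], binary),
            p_remission=_contrast_p(vals[(1, 0)], vals[(1, 1)], binary),
        ))
    return rows


def contrast_frame(rows: list[ContrastRow]) -> pd.DataFrame:
    """Flatten contrast rows to a tidy frame for CSV export."""
    recs = []
    for r in rows:
        rec = {"covariate": r.covariate, "binary": r.binary,
               "p_onset": r.p_onset, "p_remission": r.p_remission,
               "sig_onset": r.significant_onset, "sig_remission": r.significant_remission}
        for lab, s in r.summaries.items():
            for k, v in s.items():
                rec[f"{lab}_{k}"] = v
        recs.append(rec)
    return pd.DataFrame(recs)


def plot_prevalence(prev: pd.DataFrame, path) -> None:
    """Grouped bar chart of any-AUD prevalence by sex and age band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = prev[prev["sex"] != "all"]
    bands = [b for _, _, b in AGE_BANDS]
    x = np.arange(len(bands))
    width = 0.35
    fig, ax = plt.subplots(figsize=(6, 4))
    for off, sex in ((-width / 2, "male"), (width / 2, "female")):
        vals = [float(sub[(sub["sex"] == sex) & (sub["age_band"] == b)]["proportion"].iloc[0])
                if len(sub[(sub["sex"] == sex) & (sub["age_band"] == b)]) else 0.0
                for b in bands]
        ax.bar(x + off, vals, width, label=sex)
    ax.set_xticks(x, bands)
    ax.set_xlabel("age group at baseline")
    ax.set_ylabel("proportion with any AUD")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
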