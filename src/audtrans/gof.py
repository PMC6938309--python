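"""Pearson-type lack-of-fit test for the fitted panel Markov model.

Observed transition counts are contrasted with model-predicted counts inside
groups of pairs. Groups are formed by pre-state crossed with tertiles of the
time gap and tertiles of the fitted onset linear predictor; groups whose
expected cell counts are too small are collapsed into a neighbour. The
statistic is

    T = sum over cells (o - e)^2 / e,   e = sum of fitted P_ij over the
                                            group's pairs with pre-state i.

Because pairs share no common gap or covariate value, T has no clean
asymptotic null law; the p-value comes from a parametric bootstrap that
re-simulates every pair's post-state from the fitted model (conditional on
the observed pre-state, gap and covariates), refits, and recomputes T. The
add-one rule p = (1 + #{T_b >= T}) / (B + 1) keeps p strictly positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctmc import FitResult, fit_mle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GofConfig:
    n_dt_bins: int = 3
    n_lp_bins: int = 3
    min_expected: float = 5.0
    refit: bool = True  # refit the model inside each bootstrap replicate


@dataclass
class GofResult:
    statistic: float
    cells: pd.DataFrame
    boot_statistics: np.ndarray = field(default_factory=lambda: np.empty(0))
    p: float = float("nan")
    config: GofConfig = field(default_factory=GofConfig)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p": self.p,
            "n_boot": int(self.boot_statistics.size),
            "refit": self.config.refit,
            "n_cells": int(len(self.cells)),
        }


def _probabilities(fit: FitResult, pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair fitted (P_.0, P_.1) given pre-state, plus the onset linear predictor."""
    model = fit.model
    Z = pairs[list(model.covariates)].to_numpy(dtype=float) if model.covariates \
        else np.empty((len(pairs), 0))
    D01, D10 = model.design_matrices(Z)
    eta01 = D01 @ fit.params
    eta10 = D10 @ fit.params
    q01, q10 = np.exp(eta01), np.exp(eta10)
    s = q01 + q10
    dt = pairs["dt"].to_numpy(dtype=float)
    E = np.exp(-s * dt)
    p00 = (q10 + q01 * E) / s
    p11 = (q01 + q10 * E) / s
    pre = pairs["pre_state"].to_numpy(dtype=int)
    # probability the post-state is 1, given observed pre-state
    p_post1 = np.where(pre == 0, 1.0 - p00, p11)
    return p_post1, eta01, pre


def _grouping(pairs: pd.DataFrame, eta01: np.ndarray, config: GofConfig) -> np.ndarray:
    """Group labels: tertiles of dt crossed with tertiles of the linear predictor."""
    def bins(x, k):
        if k <= 1 or np.ptp(x) == 0:
            return np.zeros(len(x), dtype=int)
        return pd.qcut(pd.Series(x).rank(method="first"), k, labels=False).to_numpy()

    dt_bin = bins(pairs["dt"].to_numpy(dtype=float), config.n_dt_bins)
    lp_bin = bins(eta01, config.n_lp_bins)
    return dt_bin * max(1, config.n_lp_bins) + lp_bin


def pearson_statistic(fit: FitResult, pairs: pd.DataFrame,
                      config: GofConfig | None = None) -> tuple[float, pd.DataFrame]:
    """Lack-of-fit statistic and the observed/expected cell table."""
    config = config or GofConfig()
    p_post1, eta01, pre = _probabilities(fit, pairs)
    group = _grouping(pairs, eta01, config)
    post = pairs["post_state"].to_numpy(dtype=int)

    records = []
    for g in np.unique(group):
        for i in (0, 1):
            m = (group == g) & (pre == i)
            if not m.any():
                continue
            e1 = float(p_post1[m].sum())
            e0 = float(m.sum() - e1)
            o1 = int(post[m].sum())
            o0 = int(m.sum() - o1)
            records.append({"group": int(g), "pre_state": i, "post_state": 0,
                            "observed": o0, "expected": e0})
            records.append({"group": int(g), "pre_state": i, "post_state": 1,
                            "observed": o1, "expected": e1})
    cells = pd.DataFrame(records)

    # collapse sparse (group, pre-state) blocks into the next group over
    def block_ok(df):
        return (df.groupby(["group", "pre_state", "post_state"])["expected"].sum()
                  .groupby(["group", "pre_state"]).min())

    merged = cells.copy()
    for _ in range(len(np.unique(group))):
        mins = block_ok(merged)
        bad = mins[mins < config.min_expected]
        if bad.empty:
            break
        g_bad, pre_bad = bad.index[0]
        groups_here = sorted(merged.loc[merged["pre_state"] == pre_bad, "group"].unique())
        if len(groups_here) <= 1:
            break  # nothing left to merge into
        idx = groups_here.index(g_bad)
        target = groups_here[idx - 1] if idx > 0 else groups_here[idx + 1]
        merged.loc[(merged["group"] == g_bad) & (merged["pre_state"] == pre_bad), "group"] = target
        merged = (merged.groupby(["group", "pre_state", "post_state"], as_index=False)
                        [["observed", "expected"]].sum())
    usable = merged[merged["expected"] >= config.min_expected]
    if usable.empty:
        raise ValueError("all cells below the expected-count threshold; use coarser grouping")
    T = float(((usable["observed"] - usable["expected"]) ** 2 / usable["expected"]).sum())
    return T, merged.sort_values(["group", "pre_state", "post_state"]).reset_index(drop=True)


def bootstrap_pvalue(fit: FitResult, pairs: pd.DataFrame, B: int = 1000,
                     seed: int | None = None, config: GofConfig | None = None) -> GofResult:
    """Parametric-bootstrap p-value for the lack-of-fit statistic.

    Each replicate redraws every pair's post-state from the fitted model
    (states only — covariates and gaps stay as observed), refits when
    configured, and recomputes T on the replicate's own grouping.
    """
    config = config or GofConfig()
    T_obs, cells = pearson_statistic(fit, pairs, config)
    p_post1, _, _ = _probabilities(fit, pairs)
    rng = np.random.default_rng(seed)
    stats_b = np.empty(B)
    failures = 0
    for b in range(B):
        sim = pairs.copy()
        sim["post_state"] = (rng.random(len(pairs)) < p_post1).astype(int)
        try:
            if config.refit:
                refit = fit_mle(fit.model, sim, starts=1, compute_cov=False)
            else:
                refit = fit
            stats_b[b], _ = pearson_statistic(refit, sim, config)
        except Exception as exc:
            failures += 1
            stats_b[b] = np.nan
            logger.debug("bootstrap replicate %d failed: %s", b, exc)
    if failures > 0.05 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap refits failed; model too unstable for GOF")
    ok = stats_b[~np.isnan(stats_b)]
    p = (1.0 + float(np.sum(ok >= T_obs))) / (ok.size + 1.0)
    return GofResult(statistic=T_obs, cells=cells, boot_statistics=stats_b, p=p, config=config)
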