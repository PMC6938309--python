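"""Two-state continuous-time Markov chain with log-linear covariate effects.

The process has states 0 (No-AUD) and 1 (AUD). Transition intensities follow

    log q_01 = alpha_01 + beta_01 . z      (onset)
    log q_10 = alpha_10 + beta_10 . z      (remission)

where ``z`` is the covariate vector observed at the earlier of two panel
assessments. A covariate may be *constrained*, meaning its effect on the rate
of future AUD does not depend on the current state: beta_01 = -beta_10 = gamma,
a single free parameter, which makes the onset and remission hazard ratios
exact reciprocals.

Because only two states exist, the transition probability matrix over a gap
``dt`` has a closed form; with s = q_01 + q_10 and E = exp(-s dt),

    P_00 = (q_10 + q_01 E) / s        P_01 = q_01 (1 - E) / s
    P_10 = q_10 (1 - E) / s           P_11 = (q_01 + q_10 E) / s

The panel likelihood is the product over consecutive observation pairs of the
matrix entry matching the observed (pre, post) states.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: linear predictors beyond this magnitude are treated as an overflow error
MAX_LINEAR_PREDICTOR = 50.0

ONSET = "onset"  # 0 -> 1
REMISSION = "remission"  # 1 -> 0


class OverflowConfigurationError(ValueError):
    """A covariate configuration drove a linear predictor out of range."""


@dataclass(frozen=True)
class IntensityModel:
    """Specification of which covariates act on the two intensities.

    Parameters
    ----------
    covariates
        Ordered covariate names entering both intensities.
    constrained
        Subset of `covariates` whose onset and remission coefficients share a
        single parameter with opposite signs (state-independent effect).
    """

    covariates: tuple[str, ...] = ()
    constrained: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "constrained", frozenset(self.constrained))
        unknown = self.constrained - set(self.covariates)
        if unknown:
            raise ValueError(f"constrained covariates not in model: {sorted(unknown)}")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariate names")

    def to_dict(self) -> dict:
        return {"covariates": list(self.covariates), "constrained": sorted(self.constrained)}

    @classmethod
    def from_dict(cls, d: dict) -> "IntensityModel":
        return cls(covariates=tuple(d.get("covariates", ())),
                   constrained=frozenset(d.get("constrained", ())))

    @property
    def param_names(self) -> list[str]:
        names = ["alpha_onset", "alpha_remission"]
        for c in self.covariates:
            if c in self.constrained:
                names.append(c)
            else:
                names.extend([f"{c}:onset", f"{c}:remission"])
        return names

    @property
    def n_params(self) -> int:
        return 2 + sum(1 if c in self.constrained else 2 for c in self.covariates)

    def coefficients(self, params: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
        """Unpack a parameter vector into (alpha_01, alpha_10, beta_01, beta_10)."""
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters, got {params.shape}")
        a01, a10 = params[0], params[1]
        b01 = np.empty(len(self.covariates))
        b10 = np.empty(len(self.covariates))
        j = 2
        for k, c in enumerate(self.covariates):
            if c in self.constrained:
                b01[k] = params[j]
                b10[k] = -params[j]
                j += 1
            else:
                b01[k] = params[j]
                b10[k] = params[j + 1]
                j += 2
        return a01, a10, b01, b10

    def design_matrices(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Design matrices D01, D10 with linear predictors eta = D @ params."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        n = Z.shape[0]
        if Z.shape[1] != len(self.covariates):
            raise ValueError("covariate matrix width does not match model")
        D01 = np.zeros((n, self.n_params))
        D10 = np.zeros((n, self.n_params))
        D01[:, 0] = 1.0
        D10[:, 1] = 1.0
        j = 2
        for k, c in enumerate(self.covariates):
            if c in self.constrained:
                D01[:, j] = Z[:, k]
                D10[:, j] = -Z[:, k]
                j += 1
            else:
                D01[:, j] = Z[:, k]
                D10[:, j + 1] = Z[:, k]
                j += 2
        return D01, D10


def build_generator(model: IntensityModel, params: np.ndarray, z) -> np.ndarray:
    """2x2 generator matrix Q at covariate vector ``z``.

    ``z`` may be a mapping name -> value or an array in model covariate order.
    Rows of Q sum to zero; off-diagonals are the two intensities.
    """
    if isinstance(z, dict):
        missing = set(model.covariates) - set(z)
        if missing:
            raise ValueError(f"covariates missing from z: {sorted(missing)}")
        z = np.array([z[c] for c in model.covariates], dtype=float)
    else:
        z = np.asarray(z, dtype=float)
    a01, a10, b01, b10 = model.coefficients(params)
    eta01 = a01 + b01 @ z
    eta10 = a10 + b10 @ z
    if abs(eta01) > MAX_LINEAR_PREDICTOR or abs(eta10) > MAX_LINEAR_PREDICTOR:
        raise OverflowConfigurationError(
            f"linear predictor out of range (onset {eta01:.2f}, remission {eta10:.2f}) "
            f"at z={z.tolist()}"
        )
    q01, q10 = math.exp(eta01), math.exp(eta10)
    return np.array([[-q01, q01], [q10, -q10]])


def transition_matrix(Q: np.ndarray, dt: float) -> np.ndarray:
    """Transition probability matrix P(dt) = expm(Q dt), via the 2-state closed form."""
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    q01, q10 = Q[0, 1], Q[1, 0]
    s = q01 + q10
    if s <= 0 or dt == 0:
        return np.eye(2)
    E = math.exp(-s * dt)
    p00 = (q10 + q01 * E) / s
    p11 = (q01 + q10 * E) / s
    return np.array([[p00, 1.0 - p00], [1.0 - p11, p11]])


def _pair_arrays(model: IntensityModel, pairs: pd.DataFrame):
    """Extract (D01, D10, dt, pre, post) from a transition-pair table.

    Pairs with missing covariate values are dropped with a logged count: the
    likelihood is defined only for fully observed pre-transition covariates.
    """
    cols = list(model.covariates)
    needed = pairs[cols] if cols else pd.DataFrame(index=pairs.index)
    mask = ~needed.isna().any(axis=1) if cols else pd.Series(True, index=pairs.index)
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("dropping %d pairs with missing covariate values", n_drop)
        pairs = pairs[mask]
    Z = pairs[cols].to_numpy(dtype=float) if cols else np.empty((len(pairs), 0))
    D01, D10 = model.design_matrices(Z)
    dt = pairs["dt"].to_numpy(dtype=float)
    pre = pairs["pre_state"].to_numpy(dtype=int)
    post = pairs["post_state"].to_numpy(dtype=int)
    return D01, D10, dt, pre, post


def _log_probs_and_grad(theta, D01, D10, dt, pre, post, want_grad=True):
    """Per-pair log transition probabilities and the score w.r.t. theta.

    Returns (logp, grad) where logp is the per-pair vector (NaN-free only for
    in-range predictors; callers decide how to penalise overflow) and grad is
    the summed gradient, or None when not requested.
    """
    eta01 = D01 @ theta
    eta10 = D10 @ theta
    if np.any(np.abs(eta01) > MAX_LINEAR_PREDICTOR) or np.any(np.abs(eta10) > MAX_LINEAR_PREDICTOR):
        return None, None
    q01 = np.exp(eta01)
    q10 = np.exp(eta10)
    s = q01 + q10
    E = np.exp(-s * dt)
    p00 = (q10 + q01 * E) / s
    p11 = (q01 + q10 * E) / s
    P = np.where(pre == 0, np.where(post == 0, p00, 1.0 - p00),
                 np.where(post == 1, p11, 1.0 - p11))
    if np.any(P <= 0.0):
        return None, None
    logp = np.log(P)
    if not want_grad:
        return logp, None
    # dP/dq for the diagonal entries; off-diagonals are complements
    d00_d01 = (E * (1.0 - q01 * dt) - p00) / s
    d00_d10 = (1.0 - q01 * dt * E - p00) / s
    d11_d01 = (1.0 - q10 * dt * E - p11) / s
    d11_d10 = (E * (1.0 - q10 * dt) - p11) / s
    sign = np.where(pre == post, 1.0, -1.0)
    dP_d01 = np.where(pre == 0, d00_d01, d11_d01) * sign
    dP_d10 = np.where(pre == 0, d00_d10, d11_d10) * sign
    g01 = q01 * dP_d01 / P
    g10 = q10 * dP_d10 / P
    grad = D01.T @ g01 + D10.T @ g10
    return logp, grad


def cohort_loglik(model: IntensityModel, params: np.ndarray, pairs: pd.DataFrame) -> float:
    """Panel log-likelihood: sum over pairs of log P_{pre,post}(dt; z_pre).

    Uses compensated (fsum) summation so the value is independent of pair
    order. Raises if any pair's probability is numerically non-positive.
    """
    if len(pairs) == 0:
        raise ValueError("pairs table is empty")
    theta = np.asarray(params, dtype=float)
    D01, D10, dt, pre, post = _pair_arrays(model, pairs)
    logp, _ = _log_probs_and_grad(theta, D01, D10, dt, pre, post, want_grad=False)
    if logp is None:
        # locate the offender for the error message
        eta01 = D01 @ theta
        eta10 = D10 @ theta
        bad = np.where((np.abs(eta01) > MAX_LINEAR_PREDICTOR) | (np.abs(eta10) > MAX_LINEAR_PREDICTOR))[0]
        if bad.size:
            raise OverflowConfigurationError(f"linear predictor out of range at pair index {bad[0]}")
        raise ValueError("non-positive transition probability encountered")
    return math.fsum(logp.tolist())


@dataclass
class FitResult:
    """Maximum-likelihood fit of an :class:`IntensityModel` to panel pairs."""

    model: IntensityModel
    params: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_pairs: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def estimates(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names, name="estimate")

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "param_names": self.param_names,
            "estimates": self.params.tolist(),
            "covariance": self.cov.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_pairs": self.n_pairs,
            "diagnostics": {k: v for k, v in self.diagnostics.items() if not isinstance(v, np.ndarray)},
        }


def _crude_start(model: IntensityModel, dt, pre, post) -> np.ndarray:
    """Method-of-moments start: log crude rates, all covariate effects zero.

    Crude rate = (# observed i->j pairs) / (total gap time spent with
    pre-state i); a half-count continuity guard keeps the log finite when a
    direction was never observed.
    """
    theta = np.zeros(model.n_params)
    t0 = dt[pre == 0].sum()
    t1 = dt[pre == 1].sum()
    n01 = int(((pre == 0) & (post == 1)).sum())
    n10 = int(((pre == 1) & (post == 0)).sum())
    theta[0] = math.log(max(n01, 0.5) / max(t0, 1e-8))
    theta[1] = math.log(max(n10, 0.5) / max(t1, 1e-8))
    return theta


def fit_mle(
    model: IntensityModel,
    pairs: pd.DataFrame,
    starts: int = 3,
    seed: int | None = None,
    compute_cov: bool = True,
) -> FitResult:
    """Fit by direct maximisation of the panel likelihood.

    Quasi-Newton (BFGS) with the analytic score, started from the crude-rate
    intercepts, plus ``starts - 1`` seeded random perturbations; the best
    converged solution is kept. The covariance is the inverse of a
    central-difference observed information at the optimum.
    """
    D01, D10, dt, pre, post = _pair_arrays(model, pairs)
    n = len(dt)
    if n == 0:
        raise ValueError("no usable pairs (all dropped or empty)")
    n01 = int(((pre == 0) & (post == 1)).sum())
    n10 = int(((pre == 1) & (post == 0)).sum())
    if n01 == 0 or n10 == 0:
        warnings.warn(
            f"observed transitions: onset={n01}, remission={n10}; "
            "intensities for an unobserved direction are weakly identified",
            stacklevel=2,
        )
    # flag covariates constant over pairs: their effects are unidentifiable
    degenerate = [
        name
        for k, name in enumerate(model.covariates)
        if np.ptp(pairs[name].dropna().to_numpy(dtype=float)) == 0.0
    ]
    if degenerate:
        warnings.warn(f"covariates constant across pairs (unidentifiable): {degenerate}", stacklevel=2)

    def nll(theta):
        logp, grad = _log_probs_and_grad(theta, D01, D10, dt, pre, post)
        if logp is None:
            return 1e12, np.zeros_like(theta)
        return -float(np.sum(logp)), -grad

    start0 = _crude_start(model, dt, pre, post)
    rng = np.random.default_rng(seed)
    best = None
    attempts = []
    for i in range(max(1, starts)):
        x0 = start0 if i == 0 else start0 + rng.normal(0.0, 0.1, size=start0.size)
        res = optimize.minimize(nll, x0, jac=True, method="BFGS",
                                options={"gtol": 1e-5, "maxiter": 500})
        attempts.append({"start": i, "success": bool(res.success), "nll": float(res.fun)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise RuntimeError(f"optimization failed in all restarts: {attempts}")
    # BFGS can report precision loss with the gradient already tiny relative
    # to the likelihood's scale; accept by a scaled first-order criterion
    grad_best = nll(best.x)[1]
    scaled_ok = float(np.max(np.abs(grad_best))) < 1e-6 * (1.0 + abs(best.fun))
    converged = bool(best.success) or scaled_ok
    if not converged:
        warnings.warn("optimizer did not formally converge; best point retained", stacklevel=2)
    theta = best.x
    singular = False
    if compute_cov:
        H = _numerical_hessian(lambda t: nll(t)[1], theta)
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(H)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < -1e-8):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            singular = True
            warnings.warn("observed information singular; reporting pseudo-inverse", stacklevel=2)
            cov = np.linalg.pinv(H)
    else:
        cov = np.full((theta.size, theta.size), np.nan)
    loglik = cohort_loglik(model, theta, pairs)
    return FitResult(
        model=model,
        params=theta,
        cov=cov,
        loglik=loglik,
        converged=converged,
        n_pairs=n,
        diagnostics={
            "attempts": attempts,
            "n_onset": n01,
            "n_remission": n10,
            "singular_hessian": singular,
            "degenerate_covariates": degenerate,
        },
    )


def _numerical_hessian(grad_fn, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of the (negative) score: observed information."""
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        h = rel_step * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    return H


def hazard_ratios(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Hazard-ratio table: exp(beta) with Wald CIs per covariate and transition.

    For constrained covariates the remission row is the exact reciprocal of
    the onset row (the CI endpoints swap and invert).
    """
    if not fit.converged:
        warnings.warn("hazard ratios from a non-converged fit", stacklevel=2)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    model = fit.model
    se = fit.se
    names = model.param_names
    rows = []
    for c in model.covariates:
        if c in model.constrained:
            j = names.index(c)
            g, s = fit.params[j], se[j]
            lo, hi = g - zcrit * s, g + zcrit * s
            rows.append({
                "covariate": c, "constrained": True,
                "hr_onset": math.exp(g), "hr_onset_lo": math.exp(lo), "hr_onset_hi": math.exp(hi),
                "hr_remission": math.exp(-g), "hr_remission_lo": math.exp(-hi), "hr_remission_hi": math.exp(-lo),
                "p_onset": 2 * stats.norm.sf(abs(g) / s) if s > 0 else math.nan,
                "p_remission": 2 * stats.norm.sf(abs(g) / s) if s > 0 else math.nan,
            })
        else:
            j01 = names.index(f"{c}:onset")
            j10 = names.index(f"{c}:remission")
            b01, s01 = fit.params[j01], se[j01]
            b10, s10 = fit.params[j10], se[j10]
            rows.append({
                "covariate": c, "constrained": False,
                "hr_onset": math.exp(b01),
                "hr_onset_lo": math.exp(b01 - zcrit * s01), "hr_onset_hi": math.exp(b01 + zcrit * s01),
                "hr_remission": math.exp(b10),
                "hr_remission_lo": math.exp(b10 - zcrit * s10), "hr_remission_hi": math.exp(b10 + zcrit * s10),
                "p_onset": 2 * stats.norm.sf(abs(b01) / s01) if s01 > 0 else math.nan,
                "p_remission": 2 * stats.norm.sf(abs(b10) / s10) if s10 > 0 else math.nan,
            })
    return pd.DataFrame(rows)
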