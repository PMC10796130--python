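"""Maximum-likelihood estimation for right-censored exact event times.

Each subject contributes one row: a follow-up time ``t_i`` in years and an
event flag (1 = recurrent stroke observed at exactly ``t_i``, 0 = censored
at ``t_i``).  The log-likelihood of a hazard model ``h`` with cumulative
hazard ``H`` is

.. math::

    \\log L = \\sum_i \\bigl[ d_i \\log h(t_i \\mid x_i) - H(t_i \\mid x_i)
              \\bigr]

and the objective function value (OFV) is ``-2 log L``, so nested-model
OFV differences are asymptotically chi-squared.  Parameter uncertainty is
obtained by sampling importance resampling (SIR): draw parameter vectors
from a multivariate-normal proposal around the MLE, weight by the ratio
of the likelihood to the proposal density, and resample; the spread of
the resampled vectors gives relative standard errors (RSE%) and
percentile confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .hazard_models import (
    CovariateProfile,
    Family,
    HazardSpec,
    _base_cumhaz,
    _base_hazard,
)

__all__ = [
    "SubjectRecord",
    "FitResult",
    "SirResult",
    "ofv",
    "fit",
    "lrt",
    "sir_uncertainty",
    "hazard_ratio_ci",
    "half_life",
]

#: chi-squared(1) critical values used throughout the stepwise search
LRT_FORWARD_DROP = 3.84   # p < 0.05
LRT_BACKWARD_RISE = 6.64  # p < 0.01


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's follow-up: first recurrence or censoring, whichever first."""

    id: str | int
    time: float
    event: int
    covariates: CovariateProfile = field(default_factory=CovariateProfile)

    def __post_init__(self) -> None:
        if not (self.time > 0) or not math.isfinite(self.time):
            raise ValueError(f"subject {self.id!r}: time must be finite and > 0, "
                             f"got {self.time!r}")
        if self.event not in (0, 1):
            raise ValueError(f"subject {self.id!r}: event must be 0 or 1, "
                             f"got {self.event!r}")


def as_arrays(data: Sequence[SubjectRecord],
              covariate_names: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(times, events, design matrix) restricted to ``covariate_names``."""
    times = np.asarray([s.time for s in data], dtype=float)
    events = np.asarray([s.event for s in data], dtype=int)
    x = np.empty((len(data), len(covariate_names)))
    for j, name in enumerate(covariate_names):
        try:
            x[:, j] = [s.covariates.values[name] for s in data]
        except KeyError:
            raise KeyError(f"covariate {name!r} missing from at least one subject")
    return times, events, x


def _ofv_arrays(spec: HazardSpec, times: np.ndarray, events: np.ndarray,
                lp: np.ndarray) -> float:
    """-2 log L given precomputed per-subject linear predictors."""
    cumhaz = _base_cumhaz(spec, times) * np.exp(lp)
    loglik = -np.sum(cumhaz)
    ev = events.astype(bool)
    if np.any(ev):
        h = _base_hazard(spec, times[ev]) * np.exp(lp[ev])
        if np.any(~np.isfinite(h)) or np.any(h <= 0):
            raise FloatingPointError("non-finite or non-positive hazard at an "
                                     "event time")
        loglik += np.sum(np.log(h))
    return float(-2.0 * loglik)


def ofv(data: Sequence[SubjectRecord], spec: HazardSpec) -> float:
    """Objective function value, ``-2 log L``, of ``spec`` on ``data``."""
    names = list(spec.covariate_coefficients)
    times, events, x = as_arrays(data, names)
    if spec.family is Family.WEIBULL and np.any(times <= 0):
        raise ValueError("weibull likelihood requires all times > 0")
    coefs = np.asarray([spec.covariate_coefficients[n] for n in names])
    lp = x @ coefs if names else np.zeros(len(data))
    return _ofv_arrays(spec, times, events, lp)


# -- parameter packing --------------------------------------------------------

def _param_names(template: HazardSpec) -> list[str]:
    names = [f"h0[{a:g}]" for a, _ in template.h0_segments]
    names += [f"shape[{a:g}]" for a, _ in template.shape_segments]
    names += [f"beta[{c}]" for c in template.covariate_coefficients]
    return names


def _pack_natural(spec: HazardSpec) -> np.ndarray:
    vals = [v for _, v in spec.h0_segments]
    vals += [v for _, v in spec.shape_segments]
    vals += list(spec.covariate_coefficients.values())
    return np.asarray(vals, dtype=float)


def _unpack_natural(template: HazardSpec, theta: np.ndarray) -> HazardSpec:
    k = len(template.h0_segments)
    m = len(template.shape_segments)
    h0 = tuple((a, float(v)) for (a, _), v in zip(template.h0_segments, theta[:k]))
    sh = tuple((a, float(v)) for (a, _), v in zip(template.shape_segments,
                                                  theta[k:k + m]))
    cov = {c: float(v) for c, v in zip(template.covariate_coefficients,
                                       theta[k + m:])}
    return HazardSpec(template.family, h0, sh, cov)


def _natural_to_internal(template: HazardSpec, theta: np.ndarray) -> np.ndarray:
    x = theta.copy()
    k = len(template.h0_segments)
    x[:k] = np.log(theta[:k])  # baseline rates live on the log scale
    return x


def _internal_to_natural(template: HazardSpec, x: np.ndarray) -> np.ndarray:
    theta = x.copy()
    k = len(template.h0_segments)
    theta[:k] = np.exp(x[:k])
    return theta


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    spec: HazardSpec
    ofv: float
    estimates: dict[str, float]
    converged: bool
    n_subjects: int
    n_events: int
    message: str = ""
    n_evaluations: int = 0
    rse_percent: dict[str, float] | None = None
    ci: dict[str, tuple[float, float]] | None = None

    @property
    def hr_table(self) -> dict[str, tuple[float, float, float]] | None:
        """Per-covariate (HR, ci_low, ci_high); needs RSE% (run SIR first)."""
        if self.rse_percent is None:
            return None
        out = {}
        for cov, coef in self.spec.covariate_coefficients.items():
            out[cov] = hazard_ratio_ci(coef, self.rse_percent[f"beta[{cov}]"])
        return out

    def with_uncertainty(self, sir: "SirResult") -> "FitResult":
        return replace(self, rse_percent=dict(sir.rse_percent), ci=dict(sir.ci))


def fit(data: Sequence[SubjectRecord], template: HazardSpec, *,
        start: str = "auto", max_restarts: int = 20, ofv_tol: float = 1e-8,
        restart_seed: int = 0) -> FitResult:
    """Fit ``template``'s free parameters by minimizing the OFV.

    Baseline rates are optimized on the log scale (positivity by
    construction); shape and covariate coefficients are unconstrained.
    ``start="auto"`` initializes baselines at the crude event rate and
    shapes/coefficients at zero; ``start="template"`` starts from the
    values stored in ``template`` (with any new coefficient at its stored
    value), which is what the stepwise search uses to warm-start nested
    refits.  Deterministic given data, template, and settings; on
    non-convergence the start point is jittered up to ``max_restarts``
    times with a seeded generator.
    """
    if len(data) == 0:
        raise ValueError("no subjects")
    names = list(template.covariate_coefficients)
    times, events, x = as_arrays(data, names)
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("all subjects censored: the event-time parameters "
                         "are not identifiable")
    if template.family is Family.WEIBULL and np.any(times <= 0):
        raise ValueError("weibull likelihood requires all times > 0")

    k = len(template.h0_segments)
    m = len(template.shape_segments)

    if start == "template":
        theta0 = _pack_natural(template)
    elif start == "auto":
        crude = n_events / float(times.sum())  # events per person-year
        theta0 = np.concatenate([np.full(k, crude), np.zeros(m + len(names))])
    else:
        raise ValueError(f"unknown start policy {start!r}")
    x0 = _natural_to_internal(template, theta0)

    n_eval = 0

    def objective(xv: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        theta = _internal_to_natural(template, xv)
        spec = _unpack_natural(template, theta)
        lp = x @ theta[k + m:] if names else np.zeros(len(data))
        try:
            val = _ofv_arrays(spec, times, events, lp)
        except FloatingPointError:
            return 1e12
        if not math.isfinite(val):
            return 1e12
        return val

    rng = np.random.default_rng(restart_seed)
    best = None
    start_point = x0
    message = ""
    for attempt in range(max_restarts + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(objective, start_point, method="L-BFGS-B",
                                    options={"ftol": ofv_tol * 1e-4,
                                             "gtol": 1e-9, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
        if res.success and math.isfinite(res.fun) and res.fun < 1e11:
            message = res.message if isinstance(res.message, str) else ""
            break
        start_point = x0 + rng.normal(0.0, 0.5, size=x0.shape)
        message = f"restarted {attempt + 1} time(s): {res.message}"
    converged = bool(best.success and math.isfinite(best.fun) and best.fun < 1e11)
    if not converged:
        message = f"non-convergence after {max_restarts} restarts: {best.message}"

    theta_hat = _internal_to_natural(template, best.x)
    fitted = _unpack_natural(template, theta_hat)
    return FitResult(
        spec=fitted, ofv=float(best.fun),
        estimates=dict(zip(_param_names(template), theta_hat)),
        converged=converged, n_subjects=len(data), n_events=n_events,
        message=message, n_evaluations=n_eval,
    )


def lrt(ofv_reduced: float, ofv_full: float, df: int, *,
        tol: float = 1e-4) -> float:
    """Likelihood-ratio p-value for a nested comparison.

    ``delta = ofv_reduced - ofv_full`` is referred to the upper tail of
    chi-squared(``df``); the 3.84 / 6.64 gates of the stepwise search are
    the df=1 critical values at p=0.05 / p=0.01.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = ofv_reduced - ofv_full
    if delta < -tol:
        raise ValueError(f"full model OFV exceeds reduced by {-delta:g} "
                         "(not a nested comparison?)")
    return float(stats.chi2.sf(max(delta, 0.0), df))


# -- SIR uncertainty ----------------------------------------------------------

@dataclass(frozen=True)
class SirResult:
    """RSE% and percentile CIs from sampling importance resampling."""

    rse_percent: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n_proposal: int
    n_resample: int
    effective_sample_size: float
    asymptotic_fallback: bool = False
    resampled_with_replacement: bool = False


def _hessian(f, x0: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of scalar ``f`` at ``x0``."""
    n = len(x0)
    hess = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        ei = np.zeros(n); ei[i] = steps[i]
        fpp = f(x0 + 2 * ei); fmm = f(x0 - 2 * ei)
        hess[i, i] = (fpp - 2 * f0 + fmm) / (4 * steps[i] ** 2)
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = steps[j]
            fpj = f(x0 + ei + ej); fpm = f(x0 + ei - ej)
            fmj = f(x0 - ei + ej); fmn = f(x0 - ei - ej)
            hess[i, j] = hess[j, i] = (fpj - fpm - fmj + fmn) / (4 * steps[i] * steps[j])
    return hess


def sir_uncertainty(data: Sequence[SubjectRecord], fit_result: FitResult, *,
                    n_proposal: int = 2000, n_resample: int = 1000,
                    inflation: float = 1.5, seed: int = 0) -> SirResult:
    """Sampling-importance-resampling uncertainty for a converged fit.

    A multivariate-normal proposal is centred at the MLE with covariance
    ``inflation`` times the inverse Hessian of OFV/2 (the Hessian is
    taken on the internal scale — log baseline rates — and mapped to the
    natural scale by the delta method).  Each draw is weighted by
    ``exp(-(OFV - OFV_min)/2)`` over the proposal density and
    ``n_resample`` draws are kept without replacement.  If the Hessian is
    singular the asymptotic-normal summaries are returned with
    ``asymptotic_fallback=True``.
    """
    if not fit_result.converged:
        raise ValueError("SIR requires a converged fit")
    if n_resample > n_proposal:
        raise ValueError(f"n_resample ({n_resample}) must not exceed "
                         f"n_proposal ({n_proposal})")
    template = fit_result.spec
    names = list(template.covariate_coefficients)
    pnames = _param_names(template)
    times, events, x = as_arrays(data, names)
    k = len(template.h0_segments)
    m = len(template.shape_segments)

    def ofv_at(theta: np.ndarray) -> float:
        if np.any(theta[:k] <= 0):
            return math.inf
        if template.family is Family.WEIBULL and np.any(theta[k:k + m] <= -1):
            return math.inf
        spec = _unpack_natural(template, theta)
        lp = x @ theta[k + m:] if names else np.zeros(len(data))
        try:
            return _ofv_arrays(spec, times, events, lp)
        except FloatingPointError:
            return math.inf

    theta_hat = _pack_natural(template)
    x_hat = _natural_to_internal(template, theta_hat)
    ofv_hat = ofv_at(theta_hat)

    def half_ofv_internal(xv: np.ndarray) -> float:
        return 0.5 * ofv_at(_internal_to_natural(template, xv))

    steps = 1e-3 * np.maximum(np.abs(x_hat), 0.1)
    hess = _hessian(half_ofv_internal, x_hat, steps)
    # delta method: d(theta)/d(x) is diagonal (theta for log-rates, 1 else)
    jac = np.ones_like(theta_hat)
    jac[:k] = theta_hat[:k]
    try:
        cov_internal = np.linalg.inv(hess)
        if not np.all(np.isfinite(cov_internal)):
            raise np.linalg.LinAlgError("non-finite inverse")
        cov_natural = (jac[:, None] * cov_internal) * jac[None, :]
        np.linalg.cholesky(cov_natural + 1e-12 * np.eye(len(theta_hat)))
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian: falling back to asymptotic standard "
                      "errors from a pseudo-inverse", RuntimeWarning)
        cov_internal = np.linalg.pinv(hess)
        cov_natural = (jac[:, None] * cov_internal) * jac[None, :]
        se = np.sqrt(np.clip(np.diag(cov_natural), 0.0, None))
        rse = {n: float(100.0 * s / abs(t)) if t != 0 else math.inf
               for n, s, t in zip(pnames, se, theta_hat)}
        ci = {n: (float(t - 1.96 * s), float(t + 1.96 * s))
              for n, s, t in zip(pnames, se, theta_hat)}
        return SirResult(rse, ci, n_proposal, n_resample, float("nan"),
                         asymptotic_fallback=True)

    rng = np.random.default_rng(seed)
    proposal = stats.multivariate_normal(mean=theta_hat,
                                         cov=inflation * cov_natural,
                                         allow_singular=True)
    draws = proposal.rvs(size=n_proposal, random_state=rng)
    draws = np.asarray(draws).reshape(n_proposal, len(theta_hat))
    log_q = proposal.logpdf(draws)
    log_w = np.array([-0.5 * (ofv_at(th) - ofv_hat) for th in draws]) - log_q
    log_w[~np.isfinite(log_w)] = -math.inf
    finite = np.isfinite(log_w)
    if not np.any(finite):
        raise RuntimeError("all SIR proposal weights vanished")
    w = np.zeros(n_proposal)
    w[finite] = np.exp(log_w[finite] - log_w[finite].max())
    w /= w.sum()
    ess = float(1.0 / np.sum(w ** 2))

    with_replacement = int(np.count_nonzero(w)) < n_resample
    idx = rng.choice(n_proposal, size=n_resample, replace=with_replacement, p=w)
    kept = draws[idx]

    sd = kept.std(axis=0, ddof=1)
    lo, hi = np.percentile(kept, [2.5, 97.5], axis=0)
    rse = {n: float(100.0 * s / abs(t)) if t != 0 else math.inf
           for n, s, t in zip(pnames, sd, theta_hat)}
    ci = {n: (float(a), float(b)) for n, a, b in zip(pnames, lo, hi)}
    return SirResult(rse, ci, n_proposal, n_resample, ess,
                     resampled_with_replacement=with_replacement)


# -- reporting helpers --------------------------------------------------------

def hazard_ratio_ci(coefficient: float,
                    rse_percent: float) -> tuple[float, float, float]:
    """(HR, 95% CI low, high) from a log-hazard-ratio and its RSE%.

    HR = exp(coefficient); the CI exponentiates coefficient -/+ 1.96
    standard errors, with SE = (RSE%/100)*|coefficient|.
    """
    if rse_percent < 0:
        raise ValueError("rse_percent must be >= 0")
    se = rse_percent / 100.0 * abs(coefficient)
    hr = math.exp(coefficient)
    return (hr, math.exp(coefficient - 1.96 * se),
            math.exp(coefficient + 1.96 * se))


def half_life(shape_coefficient: float) -> float:
    """ln 2 over the Gompertz shape: the doubling/halving time (years)."""
    if shape_coefficient == 0:
        raise ValueError("half-life undefined for zero shape")
    return math.log(2) / shape_coefficient
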