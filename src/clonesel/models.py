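"""The four analysis models and their comparison statistics.

``STMwF``/``STMpF`` are single-trial fits without / with the family term;
``METMwF``/``METMpF`` are the multi-environment extensions with trial-
specific block and residual variances and unstructured across-trial
genetic covariances.  Model comparison uses AIC = -2l + 2p (p counts the
free covariance parameters) and the likelihood-ratio test computed as
2(l_full - l_reduced); at 5% and one degree of freedom a fit improvement
of 1.92 log-likelihood units is the critical increment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import (
    NAMED_SPECS,
    DesignSet,
    FitResult,
    VarianceEstimate,
    _Parameterization,
    _Workspace,
    build_design_matrices,
    fit_reml,
)

log = logging.getLogger(__name__)

__all__ = [
    "fit_named_model",
    "aic",
    "lrt",
    "ModelComparison",
    "IntervalEstimate",
    "varcomp_ci_chisq",
    "satterthwaite_df",
    "corr_ci_normal",
    "param_standard_errors",
]


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, ``-2 l + 2 p``."""
    if n_params < 0:
        raise ValueError("n_params must be nonnegative")
    return -2.0 * loglik + 2.0 * n_params


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of a nested model pair."""

    model_a: str  # reduced
    model_b: str  # full
    loglik_a: float
    loglik_b: float
    df: int
    lrt_stat: float
    p_value: float
    aic_a: float
    aic_b: float

    @property
    def significance(self) -> str:
        """The usual report codes: '**' (<1%), '*' (<5%), 'ns'."""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "ns"


def lrt(
    loglik_reduced: float,
    loglik_full: float,
    df: int,
    boundary_mixture: bool = False,
    model_a: str = "reduced",
    model_b: str = "full",
    n_params_reduced: int | None = None,
) -> ModelComparison:
    """Likelihood-ratio test of nested REML fits, statistic ``2(l2 - l1)``.

    With df=1 the 5% critical point is an increment of 1.92 units of l
    (half of chi2(1) at 3.84).  ``boundary_mixture=True`` uses the
    0.5*chi2(0) + 0.5*chi2(1) reference appropriate for a variance tested
    at its boundary; the default is the plain chi-square test.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    stat = 2.0 * (loglik_full - loglik_reduced)
    if stat < 0:
        warnings.warn("negative LRT statistic clipped to 0 (convergence issue?)")
        stat = 0.0
    p = float(stats.chi2.sf(stat, df))
    if boundary_mixture:
        if df != 1:
            raise ValueError("boundary mixture reference implemented for df=1")
        p = 0.5 * float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
    pa = n_params_reduced
    return ModelComparison(
        model_a=model_a,
        model_b=model_b,
        loglik_a=loglik_reduced,
        loglik_b=loglik_full,
        df=df,
        lrt_stat=stat,
        p_value=p,
        aic_a=np.nan if pa is None else aic(loglik_reduced, pa),
        aic_b=np.nan if pa is None else aic(loglik_full, pa + df),
    )


# ---------------------------------------------------------------------------
# Named model fitting
# ---------------------------------------------------------------------------


def _met_warm_start(table: pd.DataFrame, name: str, trait: str | None) -> VarianceEstimate:
    """Start MET fits from per-trial single-trial estimates (diagonals)
    with moderate positive starting correlations."""
    st_name = "STMpF" if name == "METMpF" else "STMwF"
    trials = sorted(table["trial"].unique())
    t = len(trials)
    diag_s, diag_c, s2b, s2e = [], [], {}, {}
    for tr in trials:
        f = fit_named_model(table[table["trial"] == tr], st_name, trait=trait,
                            compute_pev=False)
        e = f.estimate
        vfloor = 1e-8 * max(np.var(f.design.y), 1e-12)
        diag_s.append(max(e.sigma2_family or 0.0, vfloor))
        diag_c.append(max(e.sigma2_clone, vfloor))
        s2b[tr] = max(e.sigma2_block[tr], vfloor)
        s2e[tr] = max(e.sigma2_resid[tr], vfloor)
    r0 = 0.4

    def _mat(diag):
        d = np.sqrt(np.asarray(diag))
        m = r0 * np.outer(d, d)
        np.fill_diagonal(m, np.asarray(diag))
        return m

    G_ts = _mat(diag_s) if name == "METMpF" else None
    return VarianceEstimate(s2b, s2e, G_ts, _mat(diag_c))


def fit_named_model(
    table: pd.DataFrame,
    name: str,
    trait: str | None = None,
    compute_pev: bool = True,
    warm_start: bool = True,
    **fit_kwargs,
) -> FitResult:
    """Fit one of STMwF, STMpF, METMwF, METMpF on long-format data.

    MET fits are warm-started from per-trial single-trial fits, which
    substantially reduces the number of REML iterations.
    """
    if name not in NAMED_SPECS:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(NAMED_SPECS)}")
    spec = NAMED_SPECS[name]
    design = build_design_matrices(table, spec, trait=trait)
    init = fit_kwargs.pop("init", None)
    if init is None and spec.scope == "MET" and warm_start:
        df = table if trait is None else table[table["trait"] == trait]
        init = _met_warm_start(df, name, trait=None if trait is None else trait)
    return fit_reml(design, init=init, compute_pev=compute_pev, **fit_kwargs)


# ---------------------------------------------------------------------------
# Standard errors and confidence intervals
# ---------------------------------------------------------------------------


def param_standard_errors(fit: FitResult, step: float = 1e-4):
    """Asymptotic covariance of the REML parameters by numerical Hessian.

    Returns ``(cov_theta, par)`` where ``cov_theta`` is the covariance of
    the packed (log-scale / log-Cholesky) parameter vector and ``par`` the
    parameterization object (for delta-method work on derived quantities).
    """
    design: DesignSet = fit.design
    ws = _Workspace(design)
    par = _Parameterization(design)
    theta = par.pack(_safe_estimate(fit.estimate, design))

    def nll(th):
        try:
            m2, _ = ws.minus2_reml(par.unpack(th))
        except Exception:
            return np.inf
        return 0.5 * m2

    p = theta.size
    H = np.empty((p, p))
    f0 = nll(theta)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = step
        fp[i] = nll(theta + e)
        fm[i] = nll(theta - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / step**2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = step
            ej[j] = step
            fpp = nll(theta + ei + ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / step**2
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return cov, par, theta


def _safe_estimate(est: VarianceEstimate, design: DesignSet) -> VarianceEstimate:
    """Replace exact zeros (boundary reports) by a tiny positive value so
    the log-scale parameterization stays finite."""
    vfloor = 1e-8 * max(float(np.var(design.y)), 1e-12)
    return VarianceEstimate(
        {k: max(v, vfloor) for k, v in est.sigma2_block.items()},
        {k: max(v, vfloor) for k, v in est.sigma2_resid.items()},
        None if est.G_ts is None else est.G_ts + 0.0,
        est.G_tc + 0.0,
    )


def delta_method_se(fit: FitResult, func, step: float = 1e-4, precomputed=None) -> float:
    """SE of ``func(VarianceEstimate)`` by the delta method on the fitted
    covariance parameters.

    ``precomputed`` may carry the ``(cov, par, theta)`` triple from
    :func:`param_standard_errors` to avoid re-evaluating the Hessian.
    """
    cov, par, theta = (
        precomputed if precomputed is not None else param_standard_errors(fit, step=step)
    )
    p = theta.size
    grad = np.empty(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = step
        grad[i] = (func(par.unpack(theta + e)) - func(par.unpack(theta - e))) / (2 * step)
    var = float(grad @ cov @ grad)
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class IntervalEstimate:
    """A (1-level) confidence interval for one covariance-scale quantity."""

    parameter: str
    estimate: float
    lower: float
    upper: float
    level: float
    method: str  # "chisq_varcomp" | "normal_corr"
    intercepts_zero: bool = False

    def __post_init__(self) -> None:
        if not (self.lower <= self.estimate <= self.upper or self.intercepts_zero):
            raise ValueError("interval must bracket the estimate")


def satterthwaite_df(estimate: float, se: float) -> float:
    """Satterthwaite effective degrees of freedom, ``2 (sigma2/SE)^2``."""
    if se <= 0:
        raise ValueError("a positive SE is required (information matrix)")
    return 2.0 * (estimate / se) ** 2


def varcomp_ci_chisq(
    estimate: float,
    df_effective: float,
    level: float = 0.95,
    parameter: str = "variance",
) -> IntervalEstimate:
    """Chi-square confidence interval for a variance component.

    ``[nu * s2 / chi2_{1-a/2, nu},  nu * s2 / chi2_{a/2, nu}]`` with nu
    the Satterthwaite effective df.  A boundary estimate (0) or nu < 1 is
    reported as intercepting zero.
    """
    if estimate < 0:
        raise ValueError("variance estimate must be nonnegative")
    alpha = 1.0 - level
    if estimate == 0.0 or df_effective < 1.0:
        return IntervalEstimate(
            parameter, estimate, 0.0, np.inf if estimate == 0 else estimate,
            level, "chisq_varcomp", intercepts_zero=True,
        )
    nu = df_effective
    lo = nu * estimate / stats.chi2.ppf(1 - alpha / 2, nu)
    hi = nu * estimate / stats.chi2.ppf(alpha / 2, nu)
    return IntervalEstimate(parameter, estimate, float(lo), float(hi), level,
                            "chisq_varcomp")


def corr_ci_normal(
    correlation: float,
    se: float,
    level: float = 0.95,
    parameter: str = "correlation",
) -> IntervalEstimate:
    """Normal-theory interval for a genetic correlation, truncated to
    [-1, 1]; the SE comes from the delta method on the fitted covariance
    parameters."""
    if abs(correlation) > 1:
        raise ValueError("|correlation| must be <= 1")
    if se <= 0:
        raise ValueError("se must be positive")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    lo = max(correlation - z * se, -1.0)
    hi = min(correlation + z * se, 1.0)
    return IntervalEstimate(parameter, correlation, float(lo), float(hi), level,
                            "normal_corr")
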