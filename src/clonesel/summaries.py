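"""Post-fit genetic analytics.

Total genotypic values combine the family BLUP with the clone-within-
family BLUP; the family share of the genetic variance is

    rho_S = sigma2_s / (sigma2_s + sigma2_c),

accuracies derive from average prediction error variances (PEV) as
``sqrt(1 - pev/sigma2)``, and relative efficiency is the ratio of the
total-genotypic accuracy to the clone-within-family accuracy.  For MET
fits every quantity is computed per trial from that trial's diagonal of
the across-trial genetic covariance matrices; "average" rows are
arithmetic means of the per-trial values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import FitResult

__all__ = [
    "total_genotypic_st",
    "total_genotypic_met",
    "total_genotypic",
    "rho_s",
    "percent_contributions",
    "env_genetic_correlations",
    "accuracy",
    "relative_efficiency",
    "GeneticSummary",
    "summarize_fit",
]


def total_genotypic_st(
    u_s: pd.Series, u_c: pd.Series, family_of_clone: dict
) -> pd.Series:
    """u_g[clone] = u_s[family(clone)] + u_c[clone] (single-trial)."""
    missing = {family_of_clone.get(c) for c in u_c.index} - set(u_s.index)
    if None in {family_of_clone.get(c) for c in u_c.index} or missing:
        raise ValueError(f"clone(s) with family absent from u_s: {missing}")
    fam_vals = np.array([u_s[family_of_clone[c]] for c in u_c.index])
    return pd.Series(fam_vals + u_c.to_numpy(), index=u_c.index)


def total_genotypic_met(
    u_s: pd.Series, u_c: pd.Series, family_of_clone: dict
) -> pd.Series:
    """Per-trial composition u_g[trial, clone] = u_s[trial, family] + u_c[trial, clone].

    Inputs are indexed by (trial, level); the trial sets must agree.
    """
    trials_s = set(u_s.index.get_level_values(0))
    trials_c = set(u_c.index.get_level_values(0))
    if trials_s != trials_c:
        raise ValueError(f"trial mismatch between u_s {trials_s} and u_c {trials_c}")
    parts = []
    for tr in sorted(trials_c):
        us_tr = u_s.xs(tr, level=0)
        uc_tr = u_c.xs(tr, level=0)
        g = total_genotypic_st(us_tr, uc_tr, family_of_clone)
        g.index = pd.MultiIndex.from_product([[tr], g.index], names=u_c.index.names)
        parts.append(g)
    return pd.concat(parts)


def total_genotypic(fit: FitResult) -> pd.Series:
    """Total genotypic BLUPs from a fitted family model (ST or MET)."""
    if "family" not in fit.u:
        raise ValueError("total genotypic values need a model with a family term")
    if fit.spec.scope == "MET":
        return total_genotypic_met(
            fit.u["family"], fit.u["clone"], fit.design.family_of_clone
        )
    return total_genotypic_st(
        fit.u["family"], fit.u["clone"], fit.design.family_of_clone
    )


def rho_s(sigma2_s: float, sigma2_c: float) -> float:
    """Family share of the total genetic variance (scale-invariant, so
    percent contributions work as inputs too)."""
    if sigma2_s < 0 or sigma2_c < 0:
        raise ValueError("variances must be nonnegative")
    tot = sigma2_s + sigma2_c
    if tot == 0:
        raise ValueError("rho_S undefined when both variances are zero")
    return sigma2_s / tot


def percent_contributions(fit_or_estimate, trial: str | None = None) -> dict:
    """Each variance component as a percentage of their per-trial sum.

    MET fits use the trial's diagonal of G_ts/G_tc plus its own block and
    residual variances.
    """
    est = getattr(fit_or_estimate, "estimate", fit_or_estimate)
    trials = list(est.sigma2_resid)
    if trial is None:
        if len(trials) != 1:
            raise ValueError("MET estimate: pass trial=...")
        trial = trials[0]
    j = sorted(trials).index(trial)  # trial order = sorted labels (design order)
    comps = {"block": est.sigma2_block[trial]}
    if est.G_ts is not None:
        comps["family"] = float(est.G_ts[j, j])
    comps["clone"] = float(est.G_tc[j, j])
    comps["resid"] = est.sigma2_resid[trial]
    tot = sum(comps.values())
    if tot <= 0:
        raise ValueError("total variance is zero")
    return {k: 100.0 * v / tot for k, v in comps.items()}


def env_genetic_correlations(G_t: np.ndarray, labels=None) -> pd.DataFrame:
    """Correlations between trial pairs, ``sigma_ij / sqrt(sigma2_i sigma2_j)``.

    Pairs involving a zero variance come out as NaN (undefined).
    """
    G = np.asarray(G_t, dtype=float)
    if not np.allclose(G, G.T, atol=1e-10):
        raise ValueError("G_t must be symmetric")
    d = np.diag(G).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(np.outer(d, d))
        R = np.where(denom > 0, G / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(R, np.where(d > 0, 1.0, np.nan))
    labels = labels if labels is not None else range(G.shape[0])
    return pd.DataFrame(R, index=labels, columns=labels)


def accuracy(pev_mean: float, prior_variance: float) -> float:
    """Accuracy of a BLUP, ``sqrt(1 - pev/sigma2)``.

    ``pev_mean`` is the average prediction error variance over the levels
    of the effect; for total genotypic values it must be the joint PEV of
    the summed family+clone effect (error covariance included) and the
    prior variance sigma2_s + sigma2_c.
    """
    if prior_variance <= 0:
        raise ValueError("prior variance must be positive")
    if pev_mean < 0:
        raise ValueError("PEV must be nonnegative")
    if pev_mean > prior_variance:
        warnings.warn("PEV above prior variance; accuracy clipped to 0")
        return 0.0
    return float(np.sqrt(1.0 - pev_mean / prior_variance))


def relative_efficiency(acc_total: float, acc_clone: float) -> float:
    """Selection-efficiency gain of total-genotypic over clone-only ranking."""
    if acc_clone <= 0:
        raise ValueError("clone accuracy must be positive")
    if acc_total < 0:
        raise ValueError("accuracies must be nonnegative")
    return acc_total / acc_clone


@dataclass
class GeneticSummary:
    """Per-trial genetic analytics for one fitted family model."""

    trial: str
    rho_s: float
    percent: dict
    acc_family: float
    acc_clone: float
    acc_total: float
    relative_efficiency: float


def summarize_fit(fit: FitResult) -> list[GeneticSummary]:
    """rho_S, percent contributions, accuracies and RE per trial.

    Requires a family-model fit with PEVs computed.
    """
    est = fit.estimate
    if est.G_ts is None:
        raise ValueError("summaries need the family model (STMpF/METMpF)")
    if fit.pev_g is None or not fit.pev:
        raise ValueError("fit was made without PEVs; refit with compute_pev=True")
    d = fit.design
    met = fit.spec.scope == "MET"
    out = []
    for j, tr in enumerate(d.trials):
        s2s = float(est.G_ts[j, j])
        s2c = float(est.G_tc[j, j])
        if met:
            pev_s = float(fit.pev["family"].xs(tr, level=0).mean())
            pev_c = float(fit.pev["clone"].xs(tr, level=0).mean())
            pev_g = float(fit.pev_g.xs(tr, level=0).mean())
        else:
            pev_s = float(fit.pev["family"].mean())
            pev_c = float(fit.pev["clone"].mean())
            pev_g = float(fit.pev_g.mean())
        out.append(
            GeneticSummary(
                trial=tr,
                rho_s=rho_s(s2s, s2c),
                percent=percent_contributions(est, trial=tr),
                acc_family=accuracy(min(pev_s, s2s), s2s),
                acc_clone=accuracy(min(pev_c, s2c), s2c),
                acc_total=accuracy(min(pev_g, s2s + s2c), s2s + s2c),
                relative_efficiency=np.nan,
            )
        )
        out[-1].relative_efficiency = relative_efficiency(
            out[-1].acc_total, out[-1].acc_clone
        )
    return out
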