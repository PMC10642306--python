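"""End-to-end study orchestration: simulate (or load) -> fit single-trial
models per trial -> fit multi-environment models -> genetic summaries ->
selection-strategy comparison -> report tables.

Analyses are one-stage (raw plot data, not trial means), which tolerates
the unbalance inherent to augmented and p-rep designs.  Every reported
number is regenerable from (config, seed).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import selection, summaries
from .models import (
    corr_ci_normal,
    delta_method_se,
    fit_named_model,
    lrt,
    param_standard_errors,
    satterthwaite_df,
    varcomp_ci_chisq,
)
from .simulate import PHENOTYPE_COLUMNS, default_scenario, simulate_phenotypes
from .summaries import env_genetic_correlations, summarize_fit, total_genotypic

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "StudyReport",
    "read_phenotypes",
    "write_phenotypes",
    "run_st_study",
    "run_met_study",
    "write_report",
]

REQUIRED_COLUMNS = ["trial", "block", "entry", "family", "is_check", "trait", "value"]


@dataclass
class PipelineConfig:
    """Declarative study configuration (YAML round-trippable)."""

    seed: int = 0
    data_path: str | None = None  # if None, simulate the default scenario
    scenario: dict = field(default_factory=dict)  # kwargs of default_scenario
    traits: list | None = None  # None = all traits present
    selection_fraction: float = 0.20
    ci_level: float = 0.95
    compute_cis: bool = False  # normal/chi-square CIs need a numerical Hessian
    n_factors: int | None = None  # FAI-BLUP factors; None = eigenvalue >= 1 rule
    drop_family_if_ns: bool = True  # omit family from MET when no trial supports it
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not (0 < self.selection_fraction <= 1):
            raise ValueError("selection_fraction must be in (0, 1]")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class StudyReport:
    """Tables + notes + provenance produced by one study run."""

    tables: dict
    notes: list
    provenance: dict


# ---------------------------------------------------------------------------
# Phenotype I/O
# ---------------------------------------------------------------------------


def read_phenotypes(path) -> pd.DataFrame:
    """Read a long-format phenotype table (CSV with the documented header).

    Required columns: trial, block, entry, family, is_check, trait, value
    (a plot column is kept if present, otherwise generated).  Malformed
    value rows are reported with their file line numbers; a clone mapped
    to two families is a data error naming the clone.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if len(df) == 0:
        raise ValueError(f"{path}: empty phenotype file")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in REQUIRED_COLUMNS + ["plot"]]
    if unknown:
        log.warning("%s: ignoring unknown column(s) %s", path, unknown)
        df = df.drop(columns=unknown)
    vals = pd.to_numeric(df["value"].replace("", np.nan), errors="coerce")
    bad = df.index[vals.isna() & (df["value"] != "")]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric value(s) at line(s) {lines}")
    df["value"] = vals
    df["is_check"] = df["is_check"].astype(int)
    fam_map = (
        df.loc[df["is_check"] == 0].groupby("entry")["family"].agg(lambda s: set(s))
    )
    multi = fam_map[fam_map.map(len) > 1]
    if len(multi):
        raise ValueError(f"{path}: clone(s) in multiple families: {dict(multi)}")
    if "plot" not in df.columns:
        df["plot"] = [f"P{i + 1:05d}" for i in range(len(df))]
    return df[PHENOTYPE_COLUMNS]


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def _get_table(config: PipelineConfig):
    if config.data_path is not None:
        return read_phenotypes(config.data_path), None
    designs, params = default_scenario(seed=config.seed, **config.scenario)
    table, truth = simulate_phenotypes(designs, params)
    return table, truth


def _traits(config: PipelineConfig, table: pd.DataFrame) -> list[str]:
    avail = sorted(table["trait"].unique())
    if config.traits is None:
        return avail
    missing = set(config.traits) - set(avail)
    if missing:
        raise ValueError(f"trait(s) not in data: {sorted(missing)}")
    return list(config.traits)


def _provenance(config: PipelineConfig) -> dict:
    return {"seed": config.seed, "config_sha256": config.digest()}


# ---------------------------------------------------------------------------
# Single-trial study
# ---------------------------------------------------------------------------


def run_st_study(config: PipelineConfig) -> StudyReport:
    """Fit STMwF and STMpF per trial and trait; compare by AIC/LRT and by
    the concordance of clone rankings with the total genotypic ranking."""
    table, _ = _get_table(config)
    traits = _traits(config, table)
    trials = sorted(table["trial"].unique())
    f = config.selection_fraction

    fits_rows, lrt_rows, pct_rows, acc_rows, sel_rows = [], [], [], [], []
    notes: list[str] = []
    for trait in traits:
        accs = {"family": [], "clone": [], "total": [], "re": []}
        for trial in trials:
            sub = table[table["trial"] == trial]
            fit_wf = fit_named_model(sub, "STMwF", trait=trait)
            fit_pf = fit_named_model(sub, "STMpF", trait=trait)
            for fit in (fit_wf, fit_pf):
                if not fit.estimate.converged:
                    notes.append(f"{fit.spec.name} {trait}/{trial}: not converged")
                fits_rows.append(
                    {
                        "trait": trait,
                        "trial": trial,
                        "model": fit.spec.name,
                        "loglik": fit.loglik,
                        "n_params": fit.estimate.n_params,
                        "aic": fit.aic,
                    }
                )
            cmp_ = lrt(
                fit_wf.loglik, fit_pf.loglik, df=1, model_a="STMwF", model_b="STMpF",
                n_params_reduced=fit_wf.estimate.n_params,
            )
            lrt_rows.append(
                {
                    "trait": trait,
                    "trial": trial,
                    "effect": "family",
                    "lrt_stat": cmp_.lrt_stat,
                    "df": cmp_.df,
                    "p_value": cmp_.p_value,
                    "signif": cmp_.significance,
                }
            )
            for fit, model in ((fit_wf, "STMwF"), (fit_pf, "STMpF")):
                row = {"trait": trait, "trial": trial, "model": model}
                row.update(
                    {k: round(v, 2) for k, v in
                     summaries.percent_contributions(fit.estimate, trial=trial).items()}
                )
                if model == "STMpF":
                    row["rho_s"] = round(
                        summaries.rho_s(
                            fit.estimate.sigma2_family, fit.estimate.sigma2_clone
                        ),
                        2,
                    )
                pct_rows.append(row)

            summ = summarize_fit(fit_pf)[0]
            acc_rows.append(
                {
                    "trait": trait,
                    "trial": trial,
                    "acc_family": round(summ.acc_family, 2),
                    "acc_clone": round(summ.acc_clone, 2),
                    "acc_total": round(summ.acc_total, 2),
                    "relative_efficiency": round(summ.relative_efficiency, 2),
                }
            )
            for key, val in zip(
                ("family", "clone", "total", "re"),
                (summ.acc_family, summ.acc_clone, summ.acc_total,
                 summ.relative_efficiency),
            ):
                accs[key].append(val)

            u_g = total_genotypic(fit_pf)
            for scores, label in (
                (fit_wf.u["clone"], "u_c' vs u_g"),
                (fit_pf.u["clone"], "u_c vs u_g"),
            ):
                rc = selection.compare_strategies(
                    scores, u_g, f=f, name_a=label.split(" ")[0], name_b="u_g"
                )
                sel_rows.append(
                    {
                        "trait": trait,
                        "trial": trial,
                        "strategies": label,
                        "cc": round(rc.cc, 2),
                        "spearman": round(rc.spearman, 2),
                    }
                )
        acc_rows.append(
            {
                "trait": trait,
                "trial": "Average",
                "acc_family": round(float(np.mean(accs["family"])), 2),
                "acc_clone": round(float(np.mean(accs["clone"])), 2),
                "acc_total": round(float(np.mean(accs["total"])), 2),
                "relative_efficiency": round(float(np.mean(accs["re"])), 2),
            }
        )

    tables = {
        "st_fits": pd.DataFrame(fits_rows),
        "st_lrt": pd.DataFrame(lrt_rows),
        "st_variance_pct": pd.DataFrame(pct_rows),
        "st_accuracy": pd.DataFrame(acc_rows),
        "st_selection": pd.DataFrame(sel_rows),
    }
    return StudyReport(tables, notes, _provenance(config))


# ---------------------------------------------------------------------------
# Multi-environment study
# ---------------------------------------------------------------------------


def run_met_study(config: PipelineConfig) -> StudyReport:
    """Fit METMwF/METMpF across trials, summarize per trial, and compare
    FAI-BLUP rankings of the clone-only and total-genotypic strategies."""
    table, _ = _get_table(config)
    traits = _traits(config, table)
    trials = sorted(table["trial"].unique())
    if len(trials) < 2:
        raise ValueError("MET study needs at least two trials")
    f = config.selection_fraction
    notes: list[str] = []

    fits_rows, pct_rows, acc_rows, corr_rows, ci_rows = [], [], [], [], []
    blup_cols: dict[str, dict] = {"u_cprime": {}, "u_c": {}, "u_g": {}}
    family_dropped: dict[str, bool] = {}
    for trait in traits:
        # mirror the single-trial screen: family enters the MET model only
        # if at least one trial supports it
        dropped = False
        if config.drop_family_if_ns:
            sigs = []
            for trial in trials:
                sub = table[table["trial"] == trial]
                l1 = fit_named_model(sub, "STMwF", trait=trait, compute_pev=False).loglik
                l2 = fit_named_model(sub, "STMpF", trait=trait, compute_pev=False).loglik
                sigs.append(lrt(l1, l2, df=1).p_value < 0.05)
            if not any(sigs):
                dropped = True
                notes.append(
                    f"{trait}: family effect not supported in any trial "
                    "(single-trial LRT); dropped from the MET analysis"
                )
        family_dropped[trait] = dropped

        fit_wf = fit_named_model(table, "METMwF", trait=trait)
        fit_pf = None if dropped else fit_named_model(table, "METMpF", trait=trait)
        for fit in filter(None, (fit_wf, fit_pf)):
            if not fit.estimate.converged:
                notes.append(f"{fit.spec.name} {trait}: not converged")
            fits_rows.append(
                {
                    "trait": trait,
                    "model": fit.spec.name,
                    "loglik": fit.loglik,
                    "n_params": fit.estimate.n_params,
                    "aic": fit.aic,
                }
            )
            for trial in trials:
                row = {"trait": trait, "trial": trial, "model": fit.spec.name}
                row.update(
                    {k: round(v, 2) for k, v in
                     summaries.percent_contributions(fit.estimate, trial=trial).items()}
                )
                if fit.spec.with_family:
                    j = trials.index(trial)
                    row["rho_s"] = round(
                        summaries.rho_s(
                            float(fit.estimate.G_ts[j, j]),
                            float(fit.estimate.G_tc[j, j]),
                        ),
                        2,
                    )
                pct_rows.append(row)

        effects = [("clone_prime", fit_wf, "G_tc")]
        if fit_pf is not None:
            effects += [("family", fit_pf, "G_ts"), ("clone", fit_pf, "G_tc")]
        hessians = {}
        if config.compute_cis:
            hessians = {id(ft): param_standard_errors(ft)
                        for ft in {id(ft): ft for _, ft, _ in effects}.values()}
        for eff_name, fit, attr in effects:
            G = getattr(fit.estimate, attr)
            R = env_genetic_correlations(G, labels=trials)
            for i in range(len(trials)):
                for j in range(i + 1, len(trials)):
                    row = {
                        "trait": trait,
                        "effect": eff_name,
                        "trial_i": trials[i],
                        "trial_j": trials[j],
                        "correlation": float(R.iloc[i, j]),
                    }
                    if config.compute_cis and np.isfinite(R.iloc[i, j]):
                        se = delta_method_se(
                            fit,
                            lambda e, a=attr, ii=i, jj=j: _corr_of(e, a, ii, jj),
                            precomputed=hessians[id(fit)],
                        )
                        if se > 0:
                            ci = corr_ci_normal(
                                float(R.iloc[i, j]), se, level=config.ci_level
                            )
                            row.update({"se": se, "lower": ci.lower,
                                        "upper": ci.upper})
                        else:  # flat/ill-conditioned information: no interval
                            row.update({"se": np.nan, "lower": np.nan,
                                        "upper": np.nan})
                    corr_rows.append(row)
            if config.compute_cis:
                for j, trial in enumerate(trials):
                    est_v = float(G[j, j])
                    se = delta_method_se(
                        fit,
                        lambda e, a=attr, jj=j: float(getattr(e, a)[jj, jj]),
                        precomputed=hessians[id(fit)],
                    )
                    if est_v > 0 and se > 0:
                        ci = varcomp_ci_chisq(
                            est_v, satterthwaite_df(est_v, se), level=config.ci_level,
                            parameter=f"{eff_name}[{trial}]",
                        )
                    else:
                        ci = varcomp_ci_chisq(0.0, 0.0, level=config.ci_level,
                                              parameter=f"{eff_name}[{trial}]")
                    ci_rows.append(
                        {
                            "trait": trait,
                            "effect": eff_name,
                            "trial": trial,
                            "estimate": est_v,
                            "se": se,
                            "lower": ci.lower,
                            "upper": ci.upper,
                            "intercepts_zero": ci.intercepts_zero,
                        }
                    )

        if fit_pf is not None:
            accs = {"family": [], "clone": [], "total": [], "re": []}
            for summ in summarize_fit(fit_pf):
                acc_rows.append(
                    {
                        "trait": trait,
                        "trial": summ.trial,
                        "acc_family": round(summ.acc_family, 2),
                        "acc_clone": round(summ.acc_clone, 2),
                        "acc_total": round(summ.acc_total, 2),
                        "relative_efficiency": round(summ.relative_efficiency, 2),
                    }
                )
                accs["family"].append(summ.acc_family)
                accs["clone"].append(summ.acc_clone)
                accs["total"].append(summ.acc_total)
                accs["re"].append(summ.relative_efficiency)
            acc_rows.append(
                {
                    "trait": trait,
                    "trial": "Average",
                    "acc_family": round(float(np.mean(accs["family"])), 2),
                    "acc_clone": round(float(np.mean(accs["clone"])), 2),
                    "acc_total": round(float(np.mean(accs["total"])), 2),
                    "relative_efficiency": round(float(np.mean(accs["re"])), 2),
                }
            )

        # per-(trait, trial) BLUP variables for the factor-analytic index;
        # only traits with the family model retained enter, so the three
        # vectors are indexed over identical variables
        if fit_pf is not None:
            for tr in trials:
                blup_cols["u_cprime"][(trait, tr)] = fit_wf.u["clone"].xs(tr, level=0)
                blup_cols["u_c"][(trait, tr)] = fit_pf.u["clone"].xs(tr, level=0)
                blup_cols["u_g"][(trait, tr)] = total_genotypic(fit_pf).xs(tr, level=0)

    # ---- FAI-BLUP ranking comparison ----------------------------------
    sel_rows, fai_rows = [], []
    fai: dict[str, selection.FAIResult] = {}
    for key, cols in blup_cols.items():
        if not cols:
            continue
        mat = pd.DataFrame(cols)
        mat.columns = [f"{a}:{b}" for a, b in mat.columns]
        fai[key] = selection.fai_blup(mat, n_factors=config.n_factors)
        fai_rows.append(
            {
                "vector": key,
                "n_factors": fai[key].n_factors,
                "mean_communality": round(fai[key].mean_communality, 2),
            }
        )
    if "u_g" in fai:
        for key, label in (("u_cprime", "u_c' vs u_g"), ("u_c", "u_c vs u_g")):
            rc = selection.compare_strategies(
                fai[key].index_scores, fai["u_g"].index_scores, f=f,
                name_a=key, name_b="u_g",
            )
            sel_rows.append(
                {
                    "strategies": label,
                    "cc": round(rc.cc, 2),
                    "spearman": round(rc.spearman, 2),
                }
            )
    else:
        notes.append("family dropped for all traits: no u_g ranking to compare")

    tables = {
        "met_fits": pd.DataFrame(fits_rows),
        "met_variance_pct": pd.DataFrame(pct_rows),
        "met_accuracy": pd.DataFrame(acc_rows),
        "met_genetic_correlations": pd.DataFrame(corr_rows),
        "met_varcomp_ci": pd.DataFrame(ci_rows),
        "met_fai": pd.DataFrame(fai_rows),
        "met_selection": pd.DataFrame(sel_rows),
    }
    report = StudyReport(tables, notes, _provenance(config))
    report.provenance["family_dropped"] = family_dropped
    return report


def _corr_of(est, attr: str, i: int, j: int) -> float:
    G = getattr(est, attr)
    return float(G[i, j] / np.sqrt(G[i, i] * G[j, j]))


def write_report(report: StudyReport, outdir) -> list[Path]:
    """Write every report table as CSV plus a manifest; deterministic for
    a fixed (config, seed)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, tbl in report.tables.items():
        p = out / f"{name}.csv"
        tbl.to_csv(p, index=False, float_format="%.6g")
        written.append(p)
    manifest = {
        "provenance": report.provenance,
        "notes": report.notes,
        "tables": sorted(t.name for t in written),
    }
    p = out / "manifest.yaml"
    p.write_text(yaml.safe_dump(manifest, sort_keys=True))
    written.append(p)
    return written
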