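"""Synthetic phenotype generator for nested family/clone trials.

Phenotypes follow the same data-generating process the analysis models
assume: for a clone plot in trial *j*,

    y = mean_j + family_effect[f, j] + clone_effect[i, j] + block + resid,

with family-effect vectors across trials drawn multivariate normal with
covariance ``G_ts`` (t x t), clone-within-family vectors with ``G_tc``,
and block/residual effects independent per trial with trial-specific
variances.  Check plots carry a fixed per-check (per-trial) effect
instead of a genetic value — checks are fixed effects in the analysis.

Traits are simulated independently (the analysis fits traits separately).
A :class:`TruthRecord` of the realized effects is returned alongside the
phenotypes for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .designs import TrialDesign, make_abd_design, split_families

__all__ = [
    "TraitParams",
    "SimulationParams",
    "TruthRecord",
    "simulate_phenotypes",
    "default_scenario",
    "PHENOTYPE_COLUMNS",
]

PHENOTYPE_COLUMNS = ["trial", "plot", "block", "entry", "family", "is_check", "trait", "value"]


def _check_psd(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(m)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError(f"{name} must be positive semidefinite")
    return m


@dataclass
class TraitParams:
    """Generating parameters for one trait across the simulated trials.

    ``G_ts`` / ``G_tc`` are the across-trial covariance matrices of the
    family and clone-within-family effects (t x t, trial order matching
    ``trial_means``).  ``check_effects`` are fixed offsets from the trial
    mean, keyed ``(check_id, trial_id)`` or ``check_id`` (all trials).
    """

    trial_means: dict[str, float]
    sigma2_block: dict[str, float]
    sigma2_resid: dict[str, float]
    G_ts: np.ndarray
    G_tc: np.ndarray
    check_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = len(self.trial_means)
        self.G_ts = _check_psd(self.G_ts, "G_ts")
        self.G_tc = _check_psd(self.G_tc, "G_tc")
        if self.G_ts.shape[0] != t or self.G_tc.shape[0] != t:
            raise ValueError("G_ts/G_tc dimension must equal the number of trials")
        for d in (self.sigma2_block, self.sigma2_resid):
            if set(d) != set(self.trial_means):
                raise ValueError("per-trial variances must cover exactly the trials")
            if any(v < 0 for v in d.values()):
                raise ValueError("variances must be nonnegative")

    def check_effect(self, check: str, trial: str) -> float:
        if (check, trial) in self.check_effects:
            return float(self.check_effects[(check, trial)])
        return float(self.check_effects.get(check, 0.0))


@dataclass
class SimulationParams:
    """Full generating configuration: one :class:`TraitParams` per trait."""

    traits: dict[str, TraitParams]
    seed: int = 0
    missing_rate: float = 0.0  # uniform plot-wise missingness, default none

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValueError("at least one trait required")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    """Realized effects underlying one simulated dataset.

    Effect frames are indexed by level (family/clone/block label) with one
    column per trial; ``total_genotypic[trait]`` is the family effect of
    the parent family plus the clone effect, per trial.
    """

    family_effects: dict[str, pd.DataFrame]
    clone_effects: dict[str, pd.DataFrame]
    block_effects: dict[str, pd.DataFrame]
    residuals: dict[str, pd.Series]
    family_of_clone: dict[str, str]

    @property
    def total_genotypic(self) -> dict[str, pd.DataFrame]:
        out = {}
        for trait, ce in self.clone_effects.items():
            fe = self.family_effects[trait]
            fam_rows = fe.loc[[self.family_of_clone[c] for c in ce.index]].to_numpy()
            out[trait] = pd.DataFrame(
                fam_rows + ce.to_numpy(), index=ce.index, columns=ce.columns
            )
        return out


def _draw_mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """size x t draws from N(0, cov), tolerant of singular (PSD) cov."""
    t = cov.shape[0]
    if t == 0:
        return np.zeros((size, 0))
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    return rng.standard_normal((size, t)) @ root.T


def simulate_phenotypes(
    designs: Sequence[TrialDesign], params: SimulationParams
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate a long-format phenotype table over one or more trials.

    All designs must share the clone/family catalog (the MET situation);
    deterministic given ``params.seed``.
    """
    if not designs:
        raise ValueError("no designs given")
    trial_ids = [d.trial_id for d in designs]
    if len(set(trial_ids)) != len(trial_ids):
        raise ValueError("duplicate trial ids")
    ref = designs[0]
    for d in designs[1:]:
        if d.clones != ref.clones or d.families != ref.families:
            raise ValueError("designs must share the clone/family catalog")

    clones = ref.clones
    families = ref.families
    fam_of = {c: ref.family_of(c) for c in clones}
    t = len(designs)

    rng = np.random.default_rng(params.seed)
    fam_eff: dict[str, pd.DataFrame] = {}
    clone_eff: dict[str, pd.DataFrame] = {}
    block_eff: dict[str, pd.DataFrame] = {}
    resid: dict[str, pd.Series] = {}
    rows: list[dict] = []

    for trait, tp in params.traits.items():
        if set(tp.trial_means) != set(trial_ids):
            raise ValueError(f"trait {trait!r} parameters do not cover the trials")
        order = trial_ids  # simulation trial order = design order
        idx = {tr: k for k, tr in enumerate(order)}
        Gs = tp.G_ts
        Gc = tp.G_tc

        A = _draw_mvn(rng, Gs, len(families))  # families x t
        C = _draw_mvn(rng, Gc, len(clones))  # clones x t
        fam_idx = {f: i for i, f in enumerate(families)}
        clone_idx = {c: i for i, c in enumerate(clones)}
        fam_eff[trait] = pd.DataFrame(A, index=families, columns=order)
        clone_eff[trait] = pd.DataFrame(C, index=clones, columns=order)

        blocks_rows = []
        res_keys: list[tuple[str, str]] = []
        res_vals: list[float] = []
        for d in designs:
            j = idx[d.trial_id]
            blks = sorted({b for _, b, _ in d.plots})
            beff = rng.normal(0.0, np.sqrt(tp.sigma2_block[d.trial_id]), size=len(blks))
            bmap = dict(zip(blks, beff))
            for b, v in bmap.items():
                blocks_rows.append({"trial": d.trial_id, "block": b, "effect": v})
            eps = rng.normal(0.0, np.sqrt(tp.sigma2_resid[d.trial_id]), size=d.n_plots)
            mean_j = tp.trial_means[d.trial_id]
            for (plot, block, entry), e in zip(d.plots, eps):
                ent = d.entries[entry]
                if ent.kind == "check":
                    g = tp.check_effect(entry, d.trial_id)
                    fam = ""
                else:
                    fam = ent.family_id
                    g = A[fam_idx[fam], j] + C[clone_idx[entry], j]
                rows.append(
                    {
                        "trial": d.trial_id,
                        "plot": plot,
                        "block": block,
                        "entry": entry,
                        "family": fam,
                        "is_check": int(ent.kind == "check"),
                        "trait": trait,
                        "value": mean_j + g + bmap[block] + e,
                    }
                )
                res_keys.append((d.trial_id, plot))
                res_vals.append(e)
        block_eff[trait] = pd.DataFrame(blocks_rows)
        resid[trait] = pd.Series(
            res_vals, index=pd.MultiIndex.from_tuples(res_keys, names=["trial", "plot"])
        )

    table = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    if params.missing_rate > 0:
        keep = rng.random(len(table)) >= params.missing_rate
        table = table.loc[keep].reset_index(drop=True)
    truth = TruthRecord(fam_eff, clone_eff, block_eff, resid, fam_of)
    return table, truth


# ---------------------------------------------------------------------------
# Default study scenario
# ---------------------------------------------------------------------------

#: Across-season genetic correlations: tuber yield shows mostly complex
#: (low-correlation) G-by-E, specific gravity mostly simple (high-correlation).
_TTY_CORR = np.array([[1.0, 0.45, 0.35], [0.45, 1.0, 0.40], [0.35, 0.40, 1.0]])
_SG_CORR = np.array([[1.0, 0.70, 0.60], [0.70, 1.0, 0.65], [0.60, 0.65, 1.0]])


def _cov_from(variances: Sequence[float], corr: np.ndarray) -> np.ndarray:
    s = np.sqrt(np.asarray(variances, dtype=float))
    return corr * np.outer(s, s)


def default_trait_params(trial_ids: Sequence[str] | None = None) -> dict[str, TraitParams]:
    """Generating parameters for the two default traits over three seasons.

    Season order is (WHS, MHS, HHS).  Tuber yield (TTY, Mg/ha): family
    variance halves with increasing heat stress while clone-within-family
    variance grows; the HHS trial mean is ~40% below WHS.  Specific
    gravity (SG): small family/clone variances on the ~1e-4 scale with
    high across-season correlations.
    """
    tid = list(trial_ids) if trial_ids is not None else ["WHS", "MHS", "HHS"]
    if len(tid) != 3:
        raise ValueError("default parameters are defined for three seasons; "
                         "use subset_trait_params to keep fewer")
    tty = TraitParams(
        trial_means=dict(zip(tid, [32.0, 28.0, 18.6])),
        sigma2_block=dict(zip(tid, [5.4, 4.5, 0.5])),
        sigma2_resid=dict(zip(tid, [46.0, 72.0, 25.0])),
        G_ts=_cov_from([11.3, 7.3, 3.6], _TTY_CORR),
        G_tc=_cov_from([35.0, 40.0, 55.0], _TTY_CORR),
        check_effects={"CHK1": 2.0, "CHK2": -1.0},
    )
    sg = TraitParams(
        trial_means=dict(zip(tid, [1.090, 1.085, 1.082])),
        sigma2_block=dict(zip(tid, [8e-6, 3e-6, 6e-6])),
        sigma2_resid=dict(zip(tid, [8.2e-5, 8.7e-5, 6.3e-5])),
        G_ts=_cov_from([2.4e-5, 2.2e-5, 2.1e-5], _SG_CORR),
        G_tc=_cov_from([4.5e-5, 4.8e-5, 7.1e-5], _SG_CORR),
        check_effects={"CHK1": 0.005, "CHK2": -0.003},
    )
    return {"TTY": tty, "SG": sg}


def default_scenario(
    seed: int = 0,
    n_families: int = 30,
    clones_per_family: int = 15,
    n_blocks: int = 20,
    n_checks: int = 2,
    seasons: Sequence[str] = ("WHS", "MHS", "HHS"),
    traits: Sequence[str] = ("TTY", "SG"),
    design_kind: str = "ABD",
    target_p_n: float = 0.22,
) -> tuple[list[TrialDesign], SimulationParams]:
    """Three trials of the same clone set across heat-stress seasons,
    scaled for routine analysis (default 30 families x 15 clones, ABD).

    ``design_kind="PREP"`` lays the trials out as p-rep designs with
    ``target_p_n`` of the plots carrying duplicate clones instead.
    """
    fams = split_families(n_families * clones_per_family, n_families)
    checks = [f"CHK{i + 1}" for i in range(n_checks)]
    if design_kind == "ABD":
        designs = [
            make_abd_design(
                n_blocks, fams, checks, seed=seed + 101 + k, trial_id=season, season=season
            )
            for k, season in enumerate(seasons)
        ]
    elif design_kind == "PREP":
        from .designs import make_prep_design

        designs = [
            make_prep_design(
                n_blocks, fams, checks, target_p_n, seed=seed + 101 + k,
                trial_id=season, season=season,
            )
            for k, season in enumerate(seasons)
        ]
    else:
        raise ValueError("design_kind must be 'ABD' or 'PREP'")
    season_of = {d.trial_id: d.season for d in designs}
    full = default_trait_params(["WHS", "MHS", "HHS"])
    all_traits = {
        name: subset_trait_params(tp, [season_of[d.trial_id] for d in designs],
                                  [d.trial_id for d in designs])
        for name, tp in full.items()
    }
    params = SimulationParams(
        traits={name: all_traits[name] for name in traits}, seed=seed
    )
    return designs, params


def subset_trait_params(
    tp: TraitParams, seasons: Sequence[str], new_ids: Sequence[str]
) -> TraitParams:
    """Restrict/relabel a three-season parameter set to the given seasons."""
    base = list(tp.trial_means)
    idx = [base.index(s) for s in seasons]
    return TraitParams(
        trial_means={n: tp.trial_means[base[i]] for n, i in zip(new_ids, idx)},
        sigma2_block={n: tp.sigma2_block[base[i]] for n, i in zip(new_ids, idx)},
        sigma2_resid={n: tp.sigma2_resid[base[i]] for n, i in zip(new_ids, idx)},
        G_ts=tp.G_ts[np.ix_(idx, idx)],
        G_tc=tp.G_tc[np.ix_(idx, idx)],
        check_effects=dict(tp.check_effects),
    )
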