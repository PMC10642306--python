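"""Linear mixed model machinery: design matrices, structured covariances,
REML, and Henderson's mixed-model equations (MME).

The model is

    y = X beta + Z_s u_s + Z_c u_c + Z_b u_b + e

with families ``u_s``, clones-within-family ``u_c`` and blocks ``u_b``
random.  Single-trial (ST) fits use scalar variances per term; multi-
environment (MET) fits use trial-specific block/residual variances
(direct sums) and unstructured t x t across-trial covariance matrices
``G_ts``/``G_tc`` for the genetic terms (Kronecker with identities over
levels).  Checks are fixed effects and carry no genetic value, so their
rows of ``Z_s``/``Z_c`` are zero.

The residual log-likelihood is evaluated through the MME:

    -2 l = (N - o) log 2pi + log|R| + log|G| + log|C| + y' P y

where ``C`` is the MME coefficient matrix; ``C`` is sparse (clone
equations couple only within a clone across trials) so one sparse LU
factorization per evaluation suffices.  Optimization is bounded
quasi-Newton on log-variances and log-Cholesky factors, which keeps
every iterate in the valid parameter region.

Column ordering for MET genetic terms is trial-major — columns run
(trial 1: level 1..n, trial 2: level 1..n, ...) — so that the genetic
covariance is literally ``G_t (x) I``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "DesignSet",
    "VarianceEstimate",
    "FitResult",
    "build_design_matrices",
    "assemble_covariance",
    "reml_loglik",
    "fit_reml",
    "solve_mme",
    "DataError",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class DataError(ValueError):
    """Inconsistent phenotype data (e.g. a clone in two families)."""


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one analysis model.

    ``scope`` is "ST" or "MET"; ``with_family`` selects the nested
    family + clone-within-family parameterization versus a plain clone
    effect.  Fixed effects are intercept + check for ST, plus environment
    and check-by-environment for MET.  Random-term covariance structures
    follow from the scope: scalar-identity for ST, per-trial direct sums
    (block, residual) and unstructured-Kronecker (genetic terms) for MET.
    """

    scope: str
    with_family: bool
    name: str = ""
    include_block: bool = True  # False for plain one-way validation designs

    def __post_init__(self) -> None:
        if self.scope not in ("ST", "MET"):
            raise ValueError("scope must be 'ST' or 'MET'")
        if not self.name:
            object.__setattr__(self, "name", _spec_name(self.scope, self.with_family))


def _spec_name(scope: str, with_family: bool) -> str:
    return ("STMpF" if with_family else "STMwF") if scope == "ST" else (
        "METMpF" if with_family else "METMwF"
    )


NAMED_SPECS = {
    "STMwF": ModelSpec("ST", False),
    "STMpF": ModelSpec("ST", True),
    "METMwF": ModelSpec("MET", False),
    "METMpF": ModelSpec("MET", True),
}


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


@dataclass
class DesignSet:
    """Realized design matrices for one model on one (single-trait) dataset."""

    spec: ModelSpec
    y: np.ndarray
    X: np.ndarray
    x_labels: list[str]
    Z: dict  # term -> csc_matrix; keys among {"family", "clone", "block"}
    z_labels: dict  # term -> list of labels; genetic MET labels are (trial, level)
    trials: list[str]
    trial_of_obs: np.ndarray  # int codes into ``trials``
    families: list[str]
    clones: list[str]
    family_of_clone: dict
    blocks_per_trial: list[int]

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def terms(self) -> list[str]:
        return list(self.Z)


def _indicator(codes: np.ndarray, n_cols: int) -> sp.csc_matrix:
    """Sparse one-hot matrix; negative codes give an all-zero row."""
    rows = np.flatnonzero(codes >= 0)
    return sp.csc_matrix(
        (np.ones(rows.size), (rows, codes[rows])), shape=(codes.size, n_cols)
    )


def build_design_matrices(
    table: pd.DataFrame, spec: ModelSpec, trait: str | None = None
) -> DesignSet:
    """Construct y, X and the indicator Z matrices for ``spec``.

    ``table`` is long-format phenotype data (one trait, or ``trait``
    given).  Families are sorted by label and clones within family;
    MET genetic columns are trial-major so ``G_t (x) I`` applies.
    """
    df = table
    if trait is not None:
        df = df[df["trait"] == trait]
    elif df["trait"].nunique() > 1:
        raise DataError("table holds several traits; pass trait=...")
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    if len(df) == 0:
        raise DataError("no observations")

    trials = sorted(df["trial"].unique())
    t = len(trials)
    if spec.scope == "MET" and t < 2:
        raise DataError("MET models require at least two trials")
    if spec.scope == "ST" and t != 1:
        raise DataError("ST models require exactly one trial")
    trial_code = df["trial"].map({tr: k for k, tr in enumerate(trials)}).to_numpy()

    is_check = df["is_check"].astype(bool).to_numpy()
    fam_col = df["family"].astype(str).where(~is_check, "")
    clone_map = (
        df.loc[~is_check]
        .groupby("entry")["family"]
        .agg(lambda s: sorted(set(map(str, s))))
    )
    bad = clone_map[clone_map.map(len) > 1]
    if len(bad):
        raise DataError(f"clone(s) mapped to multiple families: {dict(bad)}")
    family_of_clone = {c: fams[0] for c, fams in clone_map.items()}
    clones = sorted(family_of_clone)
    families = sorted(set(family_of_clone.values()))

    y = df["value"].to_numpy(dtype=float)
    n = len(df)

    # ---- fixed effects -------------------------------------------------
    checks = sorted(df.loc[is_check, "entry"].unique())
    cols: list[np.ndarray] = [np.ones(n)]
    labels = ["intercept"]
    entry = df["entry"].to_numpy()
    for chk in checks:
        cols.append((entry == chk).astype(float))
        labels.append(f"check[{chk}]")
    if spec.scope == "MET":
        for k in range(1, t):  # first trial is the reference level
            cols.append((trial_code == k).astype(float))
            labels.append(f"env[{trials[k]}]")
        for chk in checks:
            ind = (entry == chk).astype(float)
            for k in range(1, t):
                cols.append(ind * (trial_code == k))
                labels.append(f"check[{chk}]:env[{trials[k]}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError(
            "fixed-effect design is rank deficient; use full-rank coding "
            "(e.g. drop empty check-by-environment cells)"
        )

    # ---- random-term indicators ---------------------------------------
    s, cs = len(families), len(clones)
    fam_idx = {f: i for i, f in enumerate(families)}
    clone_idx = {c: i for i, c in enumerate(clones)}
    fam_codes = np.array(
        [fam_idx[f] if f else -1 for f in fam_col.to_numpy()], dtype=int
    )
    clone_codes = np.array(
        [clone_idx[e] if not chk else -1 for e, chk in zip(entry, is_check)], dtype=int
    )
    if spec.scope == "MET":  # trial-major column index = trial * levels + level
        fam_cols = np.where(fam_codes >= 0, trial_code * s + fam_codes, -1)
        clone_cols = np.where(clone_codes >= 0, trial_code * cs + clone_codes, -1)
        fam_labels = [(tr, f) for tr in trials for f in families]
        clone_labels = [(tr, c) for tr in trials for c in clones]
        n_fam_cols, n_clone_cols = t * s, t * cs
    else:
        fam_cols, clone_cols = fam_codes, clone_codes
        fam_labels, clone_labels = list(families), list(clones)
        n_fam_cols, n_clone_cols = s, cs

    # blocks: nested in trial, trial-major column groups
    block_labels: list[tuple[str, str]] = []
    blocks_per_trial: list[int] = [0] * t
    if spec.include_block:
        blocks_per_trial = []
        block_col_of: dict[tuple[int, str], int] = {}
        for k, tr in enumerate(trials):
            blks = sorted(df.loc[trial_code == k, "block"].unique())
            blocks_per_trial.append(len(blks))
            for b in blks:
                block_col_of[(k, b)] = len(block_labels)
                block_labels.append((tr, b))
        block_cols = np.array(
            [block_col_of[(k, b)] for k, b in zip(trial_code, df["block"])], dtype=int
        )

    Z = {"clone": _indicator(clone_cols, n_clone_cols)}
    z_labels = {"clone": clone_labels}
    if spec.with_family:
        Z["family"] = _indicator(fam_cols, n_fam_cols)
        z_labels["family"] = fam_labels
    if spec.include_block:
        Z["block"] = _indicator(block_cols, len(block_labels))
        z_labels["block"] = block_labels
    # keep a fixed term order: family, clone, block
    order = [k for k in ("family", "clone", "block") if k in Z]
    Z = {k: Z[k] for k in order}
    z_labels = {k: z_labels[k] for k in order}

    return DesignSet(
        spec=spec,
        y=y,
        X=X,
        x_labels=labels,
        Z=Z,
        z_labels=z_labels,
        trials=trials,
        trial_of_obs=trial_code,
        families=families,
        clones=clones,
        family_of_clone=family_of_clone,
        blocks_per_trial=blocks_per_trial,
    )


# ---------------------------------------------------------------------------
# Variance parameterization
# ---------------------------------------------------------------------------


@dataclass
class VarianceEstimate:
    """REML covariance-parameter estimates for one model fit.

    ``G_ts``/``G_tc`` are t x t across-trial matrices (1 x 1 for ST;
    ``G_ts`` is ``None`` for models without the family term — the clone
    matrix then plays the role of the confounded clone effect).
    """

    sigma2_block: dict
    sigma2_resid: dict
    G_ts: np.ndarray | None
    G_tc: np.ndarray
    loglik: float = np.nan
    n_params: int = 0
    converged: bool = False
    boundary: list = field(default_factory=list)

    # scalar conveniences for ST fits
    @property
    def sigma2_family(self) -> float | None:
        return None if self.G_ts is None else float(self.G_ts[0, 0])

    @property
    def sigma2_clone(self) -> float:
        return float(self.G_tc[0, 0])

    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def _chol_unpack(params: np.ndarray, t: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-Cholesky: diagonal entries exp(.), below-diagonal free.
    Returns (G, L) with G = L L'."""
    L = np.zeros((t, t))
    k = 0
    for j in range(t):
        L[j, j] = np.exp(params[k])
        k += 1
        for i in range(j + 1, t):
            L[i, j] = params[k]
            k += 1
    return L @ L.T, L


def _chol_pack(G: np.ndarray) -> np.ndarray:
    t = G.shape[0]
    scale = np.trace(G) / t
    L = np.linalg.cholesky(G + 1e-10 * scale * np.eye(t))
    out = []
    for j in range(t):
        out.append(np.log(L[j, j]))
        out.extend(L[j + 1 :, j])
    return np.asarray(out)


def _n_chol(t: int) -> int:
    return t * (t + 1) // 2


class _Parameterization:
    """Maps the free parameter vector to a VarianceEstimate and back."""

    def __init__(self, design: DesignSet):
        self.t = design.n_trials
        self.trials = design.trials
        self.with_family = design.spec.with_family
        # genetic Cholesky factors are expressed relative to the phenotypic
        # scale so every free parameter is O(1) regardless of trait units
        self.scale = max(float(np.var(design.y)), 1e-12)
        self._s = float(np.sqrt(self.scale))
        t = self.t
        self.slices = {}
        k = 0
        if "block" in design.Z:
            self.slices["block"] = slice(k, k + t)
            k += t
        self.slices["resid"] = slice(k, k + t)
        k += t
        if self.with_family:
            self.slices["family"] = slice(k, k + _n_chol(t))
            k += _n_chol(t)
        self.slices["clone"] = slice(k, k + _n_chol(t))
        k += _n_chol(t)
        self.n_params = k

    def unpack(self, theta: np.ndarray) -> VarianceEstimate:
        t = self.t
        s2b = (
            dict(zip(self.trials, np.exp(theta[self.slices["block"]])))
            if "block" in self.slices
            else {}
        )
        s2e = dict(zip(self.trials, np.exp(theta[self.slices["resid"]])))
        chol = {}
        G_ts = None
        if self.with_family:
            G_ts, L = _chol_unpack(theta[self.slices["family"]], t)
            G_ts *= self.scale
            chol["family"] = self._s * L
        G_tc, L = _chol_unpack(theta[self.slices["clone"]], t)
        G_tc *= self.scale
        chol["clone"] = self._s * L
        est = VarianceEstimate(s2b, s2e, G_ts, G_tc, n_params=self.n_params)
        # raw factors: logdet/inverse stay finite at any iterate, however
        # ill-conditioned the implied covariance
        est._chol = chol
        return est

    def pack(self, est: VarianceEstimate) -> np.ndarray:
        theta = np.empty(self.n_params)
        if "block" in self.slices:
            theta[self.slices["block"]] = np.log(
                [max(est.sigma2_block[tr], 1e-300) for tr in self.trials]
            )
        theta[self.slices["resid"]] = np.log(
            [max(est.sigma2_resid[tr], 1e-300) for tr in self.trials]
        )
        if self.with_family:
            theta[self.slices["family"]] = _chol_pack(
                np.atleast_2d(est.G_ts) / self.scale
            )
        theta[self.slices["clone"]] = _chol_pack(np.atleast_2d(est.G_tc) / self.scale)
        return theta


# ---------------------------------------------------------------------------
# Covariance assembly
# ---------------------------------------------------------------------------


def assemble_covariance(est: VarianceEstimate, design: DesignSet):
    """Sparse (G_s, G_c, G_b, R) under the documented column ordering.

    G_s = G_ts (x) I_s, G_c = G_tc (x) I_cs, G_b = direct sum of
    sigma2_bj I_bj, R = direct sum of sigma2_j I_Nj (observation order).
    Returned sparse, so products and inverses stay cheap.
    """
    s, cs = len(design.families), len(design.clones)
    G_c = sp.kron(sp.csc_matrix(np.atleast_2d(est.G_tc)), sp.identity(cs), format="csc")
    G_s = None
    if est.G_ts is not None:
        G_s = sp.kron(sp.csc_matrix(np.atleast_2d(est.G_ts)), sp.identity(s), format="csc")
    G_b = None
    if est.sigma2_block:
        gb = np.concatenate(
            [
                np.full(nb, est.sigma2_block[tr])
                for tr, nb in zip(design.trials, design.blocks_per_trial)
            ]
        )
        G_b = sp.diags(gb, format="csc")
    r = np.array([est.sigma2_resid[design.trials[k]] for k in design.trial_of_obs])
    R = sp.diags(r, format="csc")
    return G_s, G_c, G_b, R


def _term_G_and_logdet(est, design, term):
    """(G_inv, logdet G) for one random term, exploiting Kronecker structure."""
    if term == "block":
        gb = np.concatenate(
            [
                np.full(nb, est.sigma2_block[tr])
                for tr, nb in zip(design.trials, design.blocks_per_trial)
            ]
        )
        return sp.diags(1.0 / gb, format="csc"), float(np.sum(np.log(gb)))
    G_t = np.atleast_2d(est.G_ts if term == "family" else est.G_tc)
    m = len(design.families) if term == "family" else len(design.clones)
    # Cholesky-based logdet/inverse: finite at any iterate, however
    # ill-conditioned, which keeps extreme optimizer excursions graded
    # instead of turning them into hard line-search failures
    L = getattr(est, "_chol", {}).get(term)
    if L is None:
        try:
            L = np.linalg.cholesky(G_t)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"{term} covariance not positive definite"
            ) from exc
    logdet_t = 2.0 * float(np.sum(np.log(np.diag(L))))
    Linv = scipy.linalg.solve_triangular(
        L, np.eye(L.shape[0]), lower=True, check_finite=False
    )
    Gt_inv = Linv.T @ Linv
    Ginv = sp.kron(sp.csc_matrix(Gt_inv), sp.identity(m), format="csc")
    return Ginv, m * logdet_t


# ---------------------------------------------------------------------------
# MME workspace: precomputed Gram blocks for fast likelihood evaluation
# ---------------------------------------------------------------------------


class _Workspace:
    """Per-design precomputation: W = [X Z...], per-trial Gram matrices."""

    def __init__(self, design: DesignSet):
        self.design = design
        X = sp.csc_matrix(design.X)
        parts = [X] + [design.Z[k] for k in design.terms]
        self.W = sp.hstack(parts, format="csr")
        self.col_slices = {}
        k = design.n_fixed
        self.col_slices["fixed"] = slice(0, k)
        for term in design.terms:
            w = design.Z[term].shape[1]
            self.col_slices[term] = slice(k, k + w)
            k += w
        self.n_cols = k

        self.M = []  # per-trial W_j' W_j
        self.wy = []  # per-trial W_j' y_j
        self.yy = []  # per-trial y_j' y_j
        self.n_j = []
        for kk in range(design.n_trials):
            rows = np.flatnonzero(design.trial_of_obs == kk)
            Wj = self.W[rows]
            yj = design.y[rows]
            self.M.append((Wj.T @ Wj).tocsc())
            self.wy.append(Wj.T @ yj)
            self.yy.append(float(yj @ yj))
            self.n_j.append(rows.size)

    def coefficient_matrix(self, est: VarianceEstimate):
        """C, rhs, and the log-determinant pieces at the given parameters."""
        d = self.design
        rinv = [1.0 / est.sigma2_resid[tr] for tr in d.trials]
        C = sum(ri * Mj for ri, Mj in zip(rinv, self.M))
        rhs = sum(ri * wj for ri, wj in zip(rinv, self.wy))
        yry = sum(ri * yj for ri, yj in zip(rinv, self.yy))
        logdet_R = float(sum(nj * np.log(est.sigma2_resid[tr])
                             for nj, tr in zip(self.n_j, d.trials)))
        logdet_G = 0.0
        ginv_blocks = [sp.csc_matrix((d.n_fixed, d.n_fixed))]
        for term in d.terms:
            Ginv, ld = _term_G_and_logdet(est, d, term)
            ginv_blocks.append(Ginv)
            logdet_G += ld
        C = (C + sp.block_diag(ginv_blocks, format="csc")).tocsc()
        return C, rhs, yry, logdet_R, logdet_G

    def minus2_reml(self, est: VarianceEstimate) -> tuple[float, np.ndarray]:
        d = self.design
        C, rhs, yry, logdet_R, logdet_G = self.coefficient_matrix(est)
        lu = splu(C, permc_spec="MMD_AT_PLUS_A")
        logdet_C = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        sol = lu.solve(rhs)
        ypy = yry - float(rhs @ sol)
        m2 = (d.n_obs - d.n_fixed) * _LOG2PI + logdet_R + logdet_G + logdet_C + ypy
        return m2, sol


def reml_loglik(est: VarianceEstimate, design: DesignSet) -> float:
    """Residual log-likelihood at the given covariance parameters.

    Convention: includes the -(N-o)/2 log 2pi constant, so AIC values are
    internally consistent (other software may differ by a constant).
    """
    try:
        m2, _ = _Workspace(design).minus2_reml(est)
    except (RuntimeError, np.linalg.LinAlgError) as exc:
        log.debug("singular covariance in reml_loglik: %s", exc)
        return -np.inf
    return -0.5 * m2


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Converged (or flagged) REML fit with BLUPs and prediction error
    variances.

    BLUP series are indexed by level label — ``(trial, level)`` tuples
    for MET genetic terms.  ``pev_g`` is the per-clone joint prediction
    error variance of the summed family + clone effect (including their
    error covariance), used for total-genotypic accuracy.
    """

    spec: ModelSpec
    estimate: VarianceEstimate
    beta: pd.Series
    u: dict  # term -> pd.Series
    pev: dict  # term -> pd.Series
    pev_g: pd.Series | None
    design: DesignSet

    @property
    def loglik(self) -> float:
        return self.estimate.loglik

    @property
    def aic(self) -> float:
        return self.estimate.aic()


def _initial_estimate(design: DesignSet) -> VarianceEstimate:
    """Half the phenotypic variance split equally among the random terms,
    half to the residual; identity-scaled unstructured starts."""
    d = design
    v_j = {}
    for k, tr in enumerate(d.trials):
        yk = d.y[d.trial_of_obs == k]
        v_j[tr] = float(np.var(yk)) if yk.size > 1 else 1.0
        v_j[tr] = max(v_j[tr], 1e-12)
    vbar = float(np.mean(list(v_j.values())))
    n_rand = len(d.terms)
    share = 0.5 / n_rand
    t = d.n_trials
    G_tc = share * vbar * np.eye(t)
    G_ts = share * vbar * np.eye(t) if d.spec.with_family else None
    return VarianceEstimate(
        sigma2_block=(
            {tr: share * v for tr, v in v_j.items()} if "block" in d.Z else {}
        ),
        sigma2_resid={tr: 0.5 * v for tr, v in v_j.items()},
        G_ts=G_ts,
        G_tc=G_tc,
    )


def fit_reml(
    design: DesignSet,
    init: VarianceEstimate | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    compute_pev: bool = True,
) -> FitResult:
    """Maximize the residual likelihood and solve the MME at the optimum.

    Log-scale variances and log-Cholesky factors keep every iterate
    valid; variances that converge to the lower boundary are reported as
    0 and flagged in ``estimate.boundary``.  Non-convergence flags the
    result rather than raising.
    """
    if design.n_obs <= design.n_fixed:
        raise DataError("more fixed effects than observations")
    ws = _Workspace(design)
    par = _Parameterization(design)
    est0 = init if init is not None else _initial_estimate(design)
    theta0 = par.pack(est0)

    # bounds guard against numerical overflow only; 1e4x the phenotypic
    # variance is far beyond any meaningful estimate, and keeping the box
    # tight stops the first projected (Cauchy) step from jumping into
    # degenerate territory
    vbar = par.scale
    lo_var, hi_var = np.log(1e-8 * vbar), np.log(1e4 * vbar)
    lo_rel, hi_rel = np.log(1e-8), np.log(1e4)  # genetic factors are scaled
    bounds = []
    for name, sl in par.slices.items():
        n_here = sl.stop - sl.start
        if name in ("block", "resid"):
            bounds.extend([(lo_var, hi_var)] * n_here)
        else:  # log-Cholesky block: diag entry first, then its column
            for j in range(par.t):
                bounds.append((0.5 * lo_rel, 0.5 * hi_rel))
                for _ in range(j + 1, par.t):
                    bounds.append((-100.0, 100.0))

    def objective(theta: np.ndarray) -> float:
        est = par.unpack(theta)
        try:
            m2, _ = ws.minus2_reml(est)
        except (RuntimeError, np.linalg.LinAlgError):
            return 1e30
        if not np.isfinite(m2):
            return 1e30
        return 0.5 * m2

    # very tight tolerances get central-difference gradients (twice the
    # evaluations, but the forward-difference noise floor is ~1e-6)
    precise = tol <= 1e-10
    res = minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        jac="3-point" if precise else None,
        bounds=bounds,
        options={
            "maxiter": max_iter,
            "ftol": tol,
            "gtol": 1e-9 if precise else 1e-6,
            "eps": 1e-7 if precise else 1e-6,
            "maxcor": 25,
        },
    )
    f0 = objective(theta0)
    if res.fun > f0 + 1e-9:  # never worse than the start
        log.warning("REML optimizer ended above the initial point; keeping start")
        res.x, res.fun, res.success = theta0, f0, False

    est = par.unpack(res.x)
    est.loglik = -float(res.fun)
    est.n_params = par.n_params
    est.converged = bool(res.success)

    # solve the MME at the (strictly positive) converged values, then
    # report lower-boundary variances as 0 with a flag
    beta, u, pev, pev_g = solve_mme(design, est, compute_pev=compute_pev, _ws=ws)
    floor = 1.05 * np.exp(lo_var)
    for tr, v in est.sigma2_block.items():
        if v <= floor:
            est.sigma2_block[tr] = 0.0
            est.boundary.append(f"block[{tr}]")
    for nm, G in (("family", est.G_ts), ("clone", est.G_tc)):
        if G is None:
            continue
        for j in range(G.shape[0]):
            if G[j, j] <= floor:
                est.boundary.append(f"{nm}[{design.trials[j]}]")
    return FitResult(design.spec, est, beta, u, pev, pev_g, design)


def solve_mme(
    design: DesignSet,
    est: VarianceEstimate,
    compute_pev: bool = True,
    _ws: _Workspace | None = None,
):
    """Solve Henderson's equations at fixed covariance parameters.

    Returns ``(beta, u, pev, pev_g)``: GLS fixed effects, BLUPs per term,
    per-level prediction error variances (diagonal of the random-effect
    block of C^-1), and the per-clone joint family+clone PEV (with the
    family-clone error covariance) when the model has a family term.
    """
    ws = _ws if _ws is not None else _Workspace(design)
    C, rhs, _, _, _ = ws.coefficient_matrix(est)
    lu = splu(C, permc_spec="MMD_AT_PLUS_A")
    sol = lu.solve(rhs)

    beta = pd.Series(sol[ws.col_slices["fixed"]], index=design.x_labels)
    u = {}
    for term in design.terms:
        sl = ws.col_slices[term]
        idx = design.z_labels[term]
        index = (
            pd.MultiIndex.from_tuples(idx, names=["trial", term])
            if idx and isinstance(idx[0], tuple)
            else pd.Index(idx, name=term)
        )
        u[term] = pd.Series(sol[sl], index=index)

    pev: dict = {}
    pev_g = None
    if compute_pev:
        Cinv = _spd_inverse(C)
        for term in design.terms:
            sl = ws.col_slices[term]
            vals = np.clip(np.diag(Cinv)[sl], 0.0, None)
            pev[term] = pd.Series(vals, index=u[term].index)
        if "family" in design.terms:
            pev_g = _joint_pev(design, ws, Cinv)
    return beta, u, pev, pev_g


def _spd_inverse(C: sp.csc_matrix) -> np.ndarray:
    dense = C.toarray()
    try:
        cf = scipy.linalg.cho_factor(dense, check_finite=False)
        return scipy.linalg.cho_solve(cf, np.eye(dense.shape[0]), check_finite=False)
    except scipy.linalg.LinAlgError:
        return np.linalg.pinv(dense)


def _joint_pev(design: DesignSet, ws: _Workspace, Cinv: np.ndarray) -> pd.Series:
    """Per-clone PEV of (family effect + clone effect), per trial for MET."""
    d = design
    s, cs, t = len(d.families), len(d.clones), d.n_trials
    fam_idx = {f: i for i, f in enumerate(d.families)}
    fsl, csl = ws.col_slices["family"], ws.col_slices["clone"]
    met = d.spec.scope == "MET"
    keys, vals = [], []
    for k in range(t):
        for i, clone in enumerate(d.clones):
            fi = fam_idx[d.family_of_clone[clone]]
            a = fsl.start + (k * s + fi if met else fi)
            b = csl.start + (k * cs + i if met else i)
            v = Cinv[a, a] + Cinv[b, b] + 2.0 * Cinv[a, b]
            keys.append((d.trials[k], clone))
            vals.append(max(v, 0.0))
    if met:
        index = pd.MultiIndex.from_tuples(keys, names=["trial", "clone"])
    else:
        index = pd.Index([c for _, c in keys], name="clone")
    return pd.Series(vals, index=index)
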