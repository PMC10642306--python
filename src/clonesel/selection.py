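"""Comparison of selection strategies.

Two rankings are compared by the overlap of their top-fraction selected
sets (Czekanowski coefficient, CC = a/(a+b)) and by the tie-aware
Spearman rank correlation.  Multi-trait / multi-season ranking uses the
FAI-BLUP factor-analytic index: a factor analysis (principal-component
extraction, varimax rotation, weighted-least-squares scores) of the
genotype-by-variable BLUP matrix, followed by inverse-distance scoring
of each genotype against the all-desirable ideotype in factor-score
space.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "top_fraction",
    "czekanowski",
    "spearman_rank",
    "RankingComparison",
    "compare_strategies",
    "FAIResult",
    "fai_blup",
    "varimax",
]


def top_fraction(scores: pd.Series, f: float = 0.20) -> set:
    """The ceil(f*n) highest-scored entries; ties at the cutoff are broken
    by entry label so the selection is deterministic."""
    if len(scores) == 0:
        raise ValueError("empty scores")
    if not (0 < f <= 1):
        raise ValueError("fraction must be in (0, 1]")
    k = int(np.ceil(f * len(scores)))
    order = sorted(scores.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return {label for label, _ in order[:k]}


def czekanowski(set_a: set, set_b: set) -> float:
    """Overlap proportion a/(a+b) of two equal-size selected sets."""
    if len(set_a) != len(set_b) or len(set_a) == 0:
        raise ValueError("selected sets must be nonempty and of equal size")
    a = len(set_a & set_b)
    return a / len(set_a)


def spearman_rank(x, y) -> float:
    """Tie-aware Spearman correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    r, _ = stats.spearmanr(x, y)
    return float(r)


@dataclass
class RankingComparison:
    """Concordance report for two ranking strategies."""

    strategy_a: str
    strategy_b: str
    fraction: float
    selected_a: set
    selected_b: set
    n_coincident: int
    n_divergent: int
    cc: float
    spearman: float


def compare_strategies(
    scores_a: pd.Series,
    scores_b: pd.Series,
    f: float = 0.20,
    name_a: str = "A",
    name_b: str = "B",
) -> RankingComparison:
    """Top-fraction overlap (CC) and whole-ranking Spearman correlation."""
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("strategies must rank the same entries")
    scores_b = scores_b.reindex(scores_a.index)
    sa = top_fraction(scores_a, f)
    sb = top_fraction(scores_b, f)
    a = len(sa & sb)
    return RankingComparison(
        strategy_a=name_a,
        strategy_b=name_b,
        fraction=f,
        selected_a=sa,
        selected_b=sb,
        n_coincident=a,
        n_divergent=len(sa) - a,
        cc=czekanowski(sa, sb),
        spearman=spearman_rank(scores_a.to_numpy(), scores_b.to_numpy()),
    )


# ---------------------------------------------------------------------------
# FAI-BLUP factor-analytic index
# ---------------------------------------------------------------------------


def varimax(loadings: np.ndarray, max_iter: int = 1000, tol: float = 1e-10) -> np.ndarray:
    """Varimax rotation (Kaiser-normalized) of a loading matrix."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    h = np.sqrt(np.sum(L**2, axis=1))
    h = np.where(h > 0, h, 1.0)
    L = L / h[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        LR = L @ R
        B = L.T @ (LR**3 - LR @ np.diag(np.mean(LR**2, axis=0)))
        U, S, Vt = np.linalg.svd(B)
        R = U @ Vt
        d = np.sum(S)
        if d_old != 0 and (d - d_old) < tol * d:
            break
        d_old = d
    return (L @ R) * h[:, None]


@dataclass
class FAIResult:
    """Factor analysis and ideotype-distance index for a BLUP matrix."""

    input_matrix: pd.DataFrame
    loadings_unrotated: pd.DataFrame
    loadings: pd.DataFrame  # varimax-rotated
    n_factors: int
    communalities: pd.Series
    mean_communality: float
    scores: pd.DataFrame  # genotype x factor (WLS)
    ideotypes: pd.DataFrame  # ideotype label x factor coordinates
    index: pd.DataFrame  # genotype x ideotype inverse-distance probabilities
    ranking: pd.Series  # index against the all-desirable ideotype, descending

    @property
    def index_scores(self) -> pd.Series:
        """Index values against the all-desirable ideotype."""
        return self.index["ID+all"]


def fai_blup(
    blup_matrix: pd.DataFrame,
    n_factors: int | None = None,
    higher_is_better=None,
) -> FAIResult:
    """Rank genotypes by the FAI-BLUP factor-analytic ideotype index.

    Steps: orient variables so larger is desirable; standardize; factor
    loadings by principal components of the correlation matrix (retain
    eigenvalues >= 1 unless ``n_factors`` is given); varimax rotation;
    weighted-least-squares (Bartlett) factor scores; ideotypes as the 2^k
    sign combinations of the desired factor directions, coordinates at
    the observed extreme score in each direction; index of genotype i for
    ideotype j is (1/d_ij) / sum_i(1/d_ij) with d the Euclidean distance
    in score space.  Ranking is against the all-desirable ideotype
    ("ID+all").
    """
    M = blup_matrix.copy().astype(float)
    n, p = M.shape
    if n < 3 or p < 2:
        raise ValueError("need >= 3 genotypes and >= 2 variables")
    if higher_is_better is not None:
        flip = np.where(np.asarray(higher_is_better, dtype=bool), 1.0, -1.0)
        M = M * flip
    sd = M.std(axis=0, ddof=1)
    if np.any(sd.to_numpy() == 0):
        raise ValueError(f"constant variable(s): {list(sd.index[sd == 0])}")
    Z = (M - M.mean(axis=0)) / sd

    Rm = np.corrcoef(Z.to_numpy(), rowvar=False)
    if np.linalg.matrix_rank(Rm) < p:
        raise ValueError(
            "singular correlation matrix; prune collinear variables before indexing"
        )
    w, V = np.linalg.eigh(Rm)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    k = int(np.sum(w >= 1.0)) if n_factors is None else int(n_factors)
    k = max(1, min(k, p))
    L0 = V[:, :k] * np.sqrt(w[:k])
    # orient components so each has positive loading sum (sign is arbitrary)
    L0 = L0 * np.where(L0.sum(axis=0) >= 0, 1.0, -1.0)
    L = varimax(L0) if k >= 2 else L0.copy()

    communal = np.sum(L**2, axis=1)
    psi = np.clip(1.0 - communal, 1e-6, None)  # uniquenesses
    A = L.T @ (L / psi[:, None])
    scores = (Z.to_numpy() / psi[None, :] @ L) @ np.linalg.inv(A)  # Bartlett/WLS

    # desired direction of each factor: the one its dominant (oriented)
    # variables point to
    desired = np.where(L.sum(axis=0) >= 0, 1.0, -1.0)
    smax, smin = scores.max(axis=0), scores.min(axis=0)

    combos = list(product([1.0, -1.0], repeat=k))
    ideo_rows, ideo_labels = [], []
    for combo in combos:
        sign = np.asarray(combo) * desired
        coord = np.where(sign > 0, smax, smin)
        ideo_rows.append(coord)
        ideo_labels.append("ID" + "".join("+" if c > 0 else "-" for c in combo))
    ideo_labels[0] = "ID+all"  # the all-desirable target
    ideotypes = pd.DataFrame(
        ideo_rows, index=ideo_labels, columns=[f"FA{i+1}" for i in range(k)]
    )

    d = np.sqrt(
        ((scores[:, None, :] - ideotypes.to_numpy()[None, :, :]) ** 2).sum(axis=2)
    )
    d = np.maximum(d, 1e-12)
    inv = 1.0 / d
    P = inv / inv.sum(axis=0, keepdims=True)
    index = pd.DataFrame(P, index=M.index, columns=ideotypes.index)

    facs = [f"FA{i+1}" for i in range(k)]
    return FAIResult(
        input_matrix=blup_matrix,
        loadings_unrotated=pd.DataFrame(L0, index=M.columns, columns=facs),
        loadings=pd.DataFrame(L, index=M.columns, columns=facs),
        n_factors=k,
        communalities=pd.Series(communal, index=M.columns),
        mean_communality=float(np.mean(communal)),
        scores=pd.DataFrame(scores, index=M.index, columns=facs),
        ideotypes=ideotypes,
        index=index,
        ranking=index["ID+all"].sort_values(ascending=False),
    )
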