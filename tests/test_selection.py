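import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonesel.selection import (
    compare_strategies,
    czekanowski,
    fai_blup,
    spearman_rank,
    top_fraction,
    varimax,
)


class TestTopFraction:
    def test_counts(self):
        s = pd.Series(np.arange(10), index=[f"g{i}" for i in range(10)])
        assert len(top_fraction(s, 0.2)) == 2
        assert top_fraction(s, 1.0) == set(s.index)

    def test_tie_rule_is_label_order(self):
        s = pd.Series(1.0, index=["d", "b", "a", "c"])
        assert top_fraction(s, 0.5) == {"a", "b"}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_fraction(pd.Series(dtype=float), 0.2)


class TestCzekanowski:
    def test_identical_and_disjoint(self):
        assert czekanowski({"a", "b"}, {"a", "b"}) == 1.0
        assert czekanowski({"a", "b"}, {"c", "d"}) == 0.0

    def test_partial_overlap(self):
        a = {"a", "b", "c", "d", "e"}
        b = {"a", "b", "c", "d", "x"}
        assert czekanowski(a, b) == pytest.approx(0.8)

    def test_unequal_sizes_rejected(self):
        with pytest.raises(ValueError):
            czekanowski({"a"}, {"a", "b"})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 30), min_size=3, max_size=10),
           st.integers(0, 2**31 - 1))
    def test_symmetry(self, sa, seed):
        rng = np.random.default_rng(seed)
        sb = set(rng.choice(50, size=len(sa), replace=False).tolist())
        assert czekanowski(sa, sb) == czekanowski(sb, sa)

    def test_invariant_to_monotone_transform_of_scores(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.normal(size=40), index=[f"g{i:02d}" for i in range(40)])
        t = np.exp(3 * s)  # strictly increasing transform
        assert top_fraction(s, 0.2) == top_fraction(t, 0.2)


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = np.array([3.0, 1.0, 2.0, 5.0, 4.0])
        assert spearman_rank(x, x) == pytest.approx(1.0)
        assert spearman_rank(x, -x) == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 3.0, 5.0, 6.0])

        def midranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = midranks(x), midranks(y)
        want = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rank(x, y) == pytest.approx(want, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rank([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareStrategies:
    def test_identical_scores(self):
        s = pd.Series(np.arange(20, dtype=float),
                      index=[f"g{i:02d}" for i in range(20)])
        rc = compare_strategies(s, s.copy())
        assert rc.cc == 1.0 and rc.spearman == pytest.approx(1.0)
        assert rc.n_coincident + rc.n_divergent == len(rc.selected_a)

    def test_random_scores_overlap_near_fraction(self):
        """Independent rankings share ~f of their top-f sets on average."""
        n, f, reps = 500, 0.2, 60
        rng = np.random.default_rng(99)
        idx = [f"g{i:03d}" for i in range(n)]
        ccs = []
        for _ in range(reps):
            a = pd.Series(rng.normal(size=n), index=idx)
            b = pd.Series(rng.normal(size=n), index=idx)
            ccs.append(compare_strategies(a, b, f=f).cc)
        assert np.mean(ccs) == pytest.approx(f, abs=0.03)

    def test_different_universes_rejected(self):
        a = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        b = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "d"])
        with pytest.raises(ValueError):
            compare_strategies(a, b)


class TestVarimax:
    def test_preserves_communalities(self):
        rng = np.random.default_rng(5)
        L = rng.normal(size=(8, 3))
        R = varimax(L)
        np.testing.assert_allclose(
            np.sum(R**2, axis=1), np.sum(L**2, axis=1), atol=1e-10
        )

    def test_single_factor_unchanged(self):
        L = np.array([[0.9], [0.8], [0.7]])
        np.testing.assert_allclose(varimax(L), L)


class TestFaiBlup:
    @staticmethod
    def _toy(seed=0, n=12, p=4):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(n, 1))
        M = base + 0.6 * rng.normal(size=(n, p))
        return pd.DataFrame(M, index=[f"g{i:02d}" for i in range(n)],
                            columns=[f"v{j}" for j in range(p)])

    def test_index_sums_to_one_per_ideotype(self):
        res = fai_blup(self._toy(), n_factors=2)
        sums = res.index.sum(axis=0)
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)

    def test_communalities_in_unit_interval(self):
        res = fai_blup(self._toy(3), n_factors=2)
        assert ((res.communalities >= 0) & (res.communalities <= 1 + 1e-9)).all()
        # rotation leaves communalities unchanged
        unrot = np.sum(res.loadings_unrotated.to_numpy() ** 2, axis=1)
        np.testing.assert_allclose(res.communalities.to_numpy(), unrot, atol=1e-10)

    def test_genotype_at_ideotype_dominates(self):
        res = fai_blup(self._toy(4), n_factors=2)
        # plant a pseudo-genotype exactly at the all-desirable ideotype by
        # checking the scoring rule directly: zero distance implies the
        # largest inverse-distance share
        d = np.linalg.norm(
            res.scores.to_numpy() - res.ideotypes.loc["ID+all"].to_numpy(), axis=1
        )
        assert res.index_scores.idxmax() == res.scores.index[np.argmin(d)]

    def test_symmetric_genotypes_score_equally(self):
        # two genotypes mirrored about the ideotype axis get equal scores
        M = pd.DataFrame(
            {
                "v1": [1.0, -1.0, 0.5, -0.5, 2.0, -2.0],
                "v2": [1.0, -1.0, -0.5, 0.5, 2.0, -2.0],
            },
            index=list("abcdef"),
        )
        res = fai_blup(M, n_factors=2)
        sc = res.scores.to_numpy()
        np.testing.assert_allclose(sc[0], -sc[1], atol=1e-8)

    def test_ordering_matches_brute_force_chain(self):
        """End-to-end oracle: an independent standardize -> PCA -> varimax
        (classic pairwise-angle algorithm) -> WLS -> distance chain
        reproduces the index values.  The rotation indeterminacies
        (factor sign/order) do not affect genotype-ideotype distances."""

        def pairwise_varimax(L0, iters=100):
            L = L0.copy()
            h = np.sqrt((L**2).sum(1))
            L = L / h[:, None]
            p, k = L.shape
            for _ in range(iters):
                change = 0.0
                for i in range(k):
                    for j in range(i + 1, k):
                        x, y = L[:, i], L[:, j]
                        u, v = x**2 - y**2, 2 * x * y
                        A, B = u.sum(), v.sum()
                        num = 2 * (u @ v) - 2 * A * B / p
                        den = (u @ u - v @ v) - (A**2 - B**2) / p
                        phi = 0.25 * np.arctan2(num, den)
                        change = max(change, abs(phi))
                        c, s_ = np.cos(phi), np.sin(phi)
                        L[:, i], L[:, j] = c * x + s_ * y, -s_ * x + c * y
                if change < 1e-12:
                    break
            return L * h[:, None]

        M = self._toy(7, n=10, p=3)
        res = fai_blup(M, n_factors=2)

        X = M.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        Rm = np.corrcoef(Z, rowvar=False)
        w, V = np.linalg.eigh(Rm)
        idx = np.argsort(w)[::-1][:2]
        L = V[:, idx] * np.sqrt(w[idx])
        L = pairwise_varimax(L)
        psi = np.clip(1 - (L**2).sum(1), 1e-6, None)
        F = (Z / psi @ L) @ np.linalg.inv(L.T @ (L / psi[:, None]))
        desired = np.where(L.sum(0) >= 0, 1.0, -1.0)
        ideo = np.where(desired > 0, F.max(0), F.min(0))
        d = np.maximum(np.linalg.norm(F - ideo, axis=1), 1e-12)
        P = (1 / d) / (1 / d).sum()
        want = pd.Series(P, index=M.index)
        got = res.index_scores.reindex(want.index)
        # the two rotation algorithms stop at slightly different stationary
        # tolerances; scores agree to ~1e-4
        np.testing.assert_allclose(got.to_numpy(), want.to_numpy(), atol=5e-4)

    def test_input_guards(self):
        with pytest.raises(ValueError):
            fai_blup(self._toy().iloc[:2])  # too few genotypes
        M = self._toy()
        M["v0"] = 1.0
        with pytest.raises(ValueError):
            fai_blup(M)  # constant variable

    def test_higher_is_better_flips_orientation(self):
        M = self._toy(9)
        res_up = fai_blup(M, n_factors=2)
        res_dn = fai_blup(M, n_factors=2,
                          higher_is_better=[False] * M.shape[1])
        # flipping every variable reverses which genotypes sit near the
        # ideotype
        top_up = res_up.ranking.index[0]
        assert res_dn.ranking.index[0] != top_up
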