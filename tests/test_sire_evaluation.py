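"""BLUP sire evaluation and Spearman rank comparison."""

import numpy as np
import pytest

from herdvar.pedigree import build_A_inverse
from herdvar.sire_evaluation import (
    RankComparison,
    evaluate_sires,
    solve_mme_blup,
    spearman_t,
    t_from_r,
)


class TestMMESolver:
    def test_matches_dense_oracle_multitrait(self, random_pedigree_factory, rng):
        ped = random_pedigree_factory(50, seed=11)
        q = ped.q
        Ainv = build_A_inverse(ped)
        n, t, p = 60, 2, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        codes = rng.integers(0, q, n)
        y = rng.normal(size=(n, t)) * [5.0, 2.0]
        G0 = np.array([[2.0, 0.8], [0.8, 1.5]])
        R0 = np.array([[3.0, 0.5], [0.5, 2.0]])
        sol = solve_mme_blup(y, X, codes, G0=G0, R0=R0, A_inverse=Ainv)

        Rinv, Ginv = np.linalg.inv(R0), np.linalg.inv(G0)
        Z = np.zeros((n, q))
        Z[np.arange(n), codes] = 1.0
        A = Ainv.toarray()
        dim = t * (p + q)
        C = np.zeros((dim, dim))
        rhs = np.zeros(dim)
        for t1 in range(t):
            for t2 in range(t):
                C[t1 * p:(t1 + 1) * p, t2 * p:(t2 + 1) * p] += Rinv[t1, t2] * (X.T @ X)
                C[t1 * p:(t1 + 1) * p, t * p + t2 * q:t * p + (t2 + 1) * q] += Rinv[t1, t2] * (X.T @ Z)
                C[t * p + t1 * q:t * p + (t1 + 1) * q, t2 * p:(t2 + 1) * p] += Rinv[t1, t2] * (Z.T @ X)
                C[t * p + t1 * q:t * p + (t1 + 1) * q, t * p + t2 * q:t * p + (t2 + 1) * q] += (
                    Rinv[t1, t2] * (Z.T @ Z) + Ginv[t1, t2] * A
                )
            rhs[t1 * p:(t1 + 1) * p] = sum(Rinv[t1, k] * (X.T @ y[:, k]) for k in range(t))
            rhs[t * p + t1 * q:t * p + (t1 + 1) * q] = sum(
                Rinv[t1, k] * (Z.T @ y[:, k]) for k in range(t)
            )
        dense = np.linalg.solve(C, rhs)
        got = np.concatenate([sol.beta.ravel(), sol.u.T.ravel()])
        assert np.abs(got - dense).max() < 1e-8

    def test_pcg_agrees_with_direct(self, random_pedigree_factory, rng):
        ped = random_pedigree_factory(40, seed=13)
        Ainv = build_A_inverse(ped)
        n = 50
        X = np.ones((n, 1))
        codes = rng.integers(0, ped.q, n)
        y = rng.normal(size=(n, 1))
        a = solve_mme_blup(y, X, codes, G0=1.0, R0=2.0, A_inverse=Ainv, method="direct")
        b = solve_mme_blup(y, X, codes, G0=1.0, R0=2.0, A_inverse=Ainv, method="pcg")
        assert np.allclose(a.u, b.u, atol=1e-7)

    def test_vanishing_genetic_variance_shrinks_ebv_to_zero(self, rng):
        n = 40
        codes = rng.integers(0, 8, n)
        y = rng.normal(size=(n, 1))
        sol = solve_mme_blup(y, np.ones((n, 1)), codes, G0=1e-8, R0=1.0, model="sire")
        assert np.abs(sol.ebv()).max() < 1e-4

    def test_balanced_sire_model_closed_form(self, rng):
        # s sires, n progeny each: sire solution = n(ybar_s - ybar)/(n + lambda)
        s, n = 6, 10
        codes = np.repeat(np.arange(s), n)
        y = rng.normal(size=s * n) + np.repeat(rng.normal(0, 1, s), n)
        sigma_s, sigma_e = 0.5, 2.0
        lam = sigma_e / sigma_s
        sol = solve_mme_blup(
            y[:, None], np.ones((s * n, 1)), codes, G0=sigma_s, R0=sigma_e, model="sire"
        )
        ybar_s = y.reshape(s, n).mean(1)
        expected = n * (ybar_s - y.mean()) / (n + lam)
        assert np.allclose(sol.u[:, 0], expected, atol=1e-8)

    def test_non_pd_components_rejected(self, rng):
        with pytest.raises(ValueError):
            solve_mme_blup(
                np.ones((4, 1)), np.ones((4, 1)), np.arange(4),
                G0=np.array([[1.0, 2.0], [2.0, 1.0]]), R0=np.eye(2),
            )


class TestEvaluateSires:
    def test_progeny_threshold_and_rank_permutation(self):
        ebv = {"S1": 1.0, "S2": 3.0, "S3": 2.0, "S4": 9.0}
        counts = {"S1": 5, "S2": 10, "S3": 4, "S4": 3}  # S4 excluded
        df = evaluate_sires(ebv, counts)
        assert set(df["sire"]) == {"S1", "S2", "S3"}
        assert sorted(df["rank"]) == [1, 2, 3]
        assert df.loc[df.sire == "S2", "rank"].item() == 1

    def test_ebv_scaling_does_not_change_ranking(self):
        ebv = {f"S{i}": v for i, v in enumerate([0.3, -0.1, 0.9, 0.5])}
        counts = {f"S{i}": 6 for i in range(4)}
        r1 = evaluate_sires(ebv, counts)["rank"].to_list()
        r2 = evaluate_sires({k: 2 * v for k, v in ebv.items()}, counts)["rank"].to_list()
        assert r1 == r2

    def test_tie_broken_by_sire_id(self):
        ebv = {"B": 1.0, "A": 1.0, "C": 0.0}
        counts = {"A": 5, "B": 5, "C": 5}
        df = evaluate_sires(ebv, counts).set_index("sire")
        assert df.loc["A", "rank"] == 1 and df.loc["B", "rank"] == 2


class TestSpearmanT:
    @pytest.mark.parametrize(
        "r,n,expected",
        [(0.048, 8, 0.12), (0.39, 8, 1.04), (0.43, 8, 1.17)],
    )
    def test_t_statistic_published_rows(self, r, n, expected):
        assert t_from_r(r, n) == pytest.approx(expected, abs=0.005)

    def test_identical_rankings(self):
        res = spearman_t([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.r == 1.0 and np.isinf(res.t) and res.significant

    def test_reversed_rankings(self):
        res = spearman_t([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.r == -1.0

    def test_self_comparison_any_permutation(self, rng):
        x = rng.permutation(10) + 1
        assert spearman_t(x, x).r == 1.0

    def test_df_is_n_minus_2(self):
        res = spearman_t([1, 2, 3, 4, 5, 6, 7, 8], [2, 1, 3, 5, 4, 7, 8, 6])
        assert res.df == 6


class TestSignalRecovery:
    def test_strong_genetic_signal_ranks_recovered(self, rng):
        # h2 = 0.6 sire families: estimated ranking correlates with true sire
        # merit in nearly all replicates
        h2, s, n = 0.6, 20, 30
        sigma_s = h2 / 4.0
        sigma_e = 1.0 - sigma_s
        lam = sigma_e / sigma_s
        hits = 0
        reps = 50
        for _ in range(reps):
            tbv = rng.normal(0, np.sqrt(sigma_s), s)
            codes = np.repeat(np.arange(s), n)
            y = np.repeat(tbv, n) + rng.normal(0, np.sqrt(sigma_e), s * n)
            sol = solve_mme_blup(
                y[:, None], np.ones((s * n, 1)), codes,
                G0=sigma_s, R0=sigma_e, model="sire",
            )
            res = spearman_t(np.argsort(np.argsort(-tbv)), np.argsort(np.argsort(-sol.u[:, 0])))
            hits += res.r > 0.7
        assert hits >= 0.9 * reps
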