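"""Laplacian-RLS solver against a generic numerical minimizer, plus ranking."""

import numpy as np
import pytest
from scipy.optimize import minimize

from lncsim import (
    AssociationTable,
    LRLSParams,
    NumericalError,
    ParameterError,
    ScoreMatrix,
    SimilarityMatrix,
    ValidationError,
    lrls_solve,
    normalized_laplacian,
    predict,
    rank_candidates,
)


def rand_similarity(rng, n):
    v = rng.uniform(0, 1, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return v


def rand_spd(rng, n):
    a = rng.normal(size=(n, n))
    return a @ a.T / n + np.eye(n)


def objective(f, y, lap, eta):
    return np.sum((y - f) ** 2) + eta * np.trace(f.T @ lap @ f)


class TestNormalizedLaplacian:
    def test_identity_gives_zero(self):
        np.testing.assert_allclose(normalized_laplacian(np.eye(4)), np.zeros((4, 4)))

    def test_all_ones_two_by_two(self):
        got = normalized_laplacian(np.ones((2, 2)))
        np.testing.assert_allclose(got, [[0.5, -0.5], [-0.5, 0.5]])

    def test_spectrum_in_zero_two(self, rng):
        for _ in range(20):
            lap = normalized_laplacian(rand_similarity(rng, 7))
            ev = np.linalg.eigvalsh(lap)
            assert ev.min() >= -1e-8 and ev.max() <= 2 + 1e-8

    def test_zero_degree_row_becomes_identity_row(self):
        s = np.zeros((3, 3))
        s[0, 0] = 1.0
        lap = normalized_laplacian(s)
        np.testing.assert_allclose(lap[1], [0.0, 1.0, 0.0])
        np.testing.assert_allclose(lap[2], [0.0, 0.0, 1.0])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            normalized_laplacian(np.array([[1.0, -0.1], [-0.1, 1.0]]))

    def test_combinatorial_form(self):
        s = np.ones((2, 2))
        np.testing.assert_allclose(
            normalized_laplacian(s, normalized=False), [[1.0, -1.0], [-1.0, 1.0]]
        )


class TestLrlsSolve:
    def test_eta_zero_is_interpolation(self, rng):
        y = rng.normal(size=(6, 3))
        np.testing.assert_array_equal(
            lrls_solve(rand_spd(rng, 6), np.eye(6), y, eta=0.0), y
        )

    def test_identity_kernel_and_laplacian_closed_form(self, rng):
        y = rng.normal(size=(5, 2))
        eta = 0.7
        got = lrls_solve(np.eye(5), np.eye(5), y, eta=eta, jitter=0.0)
        np.testing.assert_allclose(got, y / (1 + eta), atol=1e-12)

    def test_matches_generic_quadratic_minimizer(self, rng):
        """Closed form vs scipy minimization of the stated objective (15x15)."""
        for _ in range(3):
            n, m = 15, 4
            k = rand_spd(rng, n)
            lap = normalized_laplacian(rand_similarity(rng, n))
            y = rng.normal(size=(n, m))
            eta = float(rng.uniform(0.2, 2.0))
            got = lrls_solve(k, lap, y, eta=eta)
            res = minimize(
                lambda x: objective(x.reshape(n, m), y, lap, eta),
                np.zeros(n * m),
                jac=lambda x: (
                    2 * (x.reshape(n, m) - y) + 2 * eta * lap @ x.reshape(n, m)
                ).ravel(),
                method="L-BFGS-B",
                options={"gtol": 1e-12, "ftol": 1e-15, "maxiter": 10000},
            )
            np.testing.assert_allclose(got, res.x.reshape(n, m), atol=1e-6)

    def test_objective_no_worse_than_trivial_candidates(self, rng):
        n = 10
        k = rand_spd(rng, n)
        lap = normalized_laplacian(rand_similarity(rng, n))
        y = rng.normal(size=(n, 3))
        f = lrls_solve(k, lap, y, eta=0.9)
        assert objective(f, y, lap, 0.9) <= objective(y, y, lap, 0.9) + 1e-9
        assert objective(f, y, lap, 0.9) <= objective(np.zeros_like(y), y, lap, 0.9) + 1e-9

    def test_permutation_equivariance(self, rng):
        n = 8
        k = rand_spd(rng, n)
        lap = normalized_laplacian(rand_similarity(rng, n))
        y = rng.normal(size=(n, 3))
        perm = rng.permutation(n)
        f = lrls_solve(k, lap, y, eta=0.5)
        f_perm = lrls_solve(k[np.ix_(perm, perm)], lap[np.ix_(perm, perm)], y[perm], eta=0.5)
        np.testing.assert_allclose(f[perm], f_perm, atol=1e-8)

    def test_negative_eta_rejected(self, rng):
        with pytest.raises(ParameterError):
            lrls_solve(np.eye(3), np.eye(3), np.eye(3), eta=-1.0)

    def test_singular_system_raises_with_advice(self):
        k = np.zeros((3, 3))
        lap = np.zeros((3, 3))
        with pytest.raises((NumericalError, np.linalg.LinAlgError)):
            lrls_solve(k, lap, np.eye(3), eta=1.0, jitter=0.0)


class TestPredict:
    @pytest.fixture
    def small_problem(self, rng):
        m = (rng.random((5, 4)) < 0.4).astype(int)
        assoc = AssociationTable([f"L{k}" for k in range(5)], [f"D{k}" for k in range(4)], m)
        sl = SimilarityMatrix(assoc.lncrna_ids, rand_similarity(rng, 5))
        sd = SimilarityMatrix(assoc.disease_ids, rand_similarity(rng, 4))
        return assoc, sl, sd

    def test_w_extremes_select_single_space(self, small_problem):
        assoc, sl, sd = small_problem
        only_l = predict(assoc, sl, sd, LRLSParams(w=1.0))
        only_d = predict(assoc, sl, sd, LRLSParams(w=0.0))
        half = predict(assoc, sl, sd, LRLSParams(w=0.5))
        np.testing.assert_allclose(
            half.scores, (only_l.scores + only_d.scores) / 2, atol=1e-10
        )

    def test_monotone_in_w(self, small_problem):
        assoc, sl, sd = small_problem
        s0 = predict(assoc, sl, sd, LRLSParams(w=0.0)).scores
        s1 = predict(assoc, sl, sd, LRLSParams(w=1.0)).scores
        sm = predict(assoc, sl, sd, LRLSParams(w=0.3)).scores
        lo, hi = np.minimum(s0, s1), np.maximum(s0, s1)
        assert ((sm >= lo - 1e-10) & (sm <= hi + 1e-10)).all()

    def test_block_structure_recovered(self, rng):
        """Held-out within-cluster pairs outscore cross-cluster pairs."""
        m = np.zeros((10, 10), dtype=int)
        m[:5, :5] = (rng.random((5, 5)) < 0.7).astype(int)
        m[5:, 5:] = (rng.random((5, 5)) < 0.7).astype(int)
        held = (0, 4)
        m[held] = 0
        assoc = AssociationTable(
            [f"L{k}" for k in range(10)], [f"D{k}" for k in range(10)], m
        )
        from lncsim import gaussian_profile_kernel

        sl = gaussian_profile_kernel(assoc, "lncrna")
        sd = gaussian_profile_kernel(assoc, "disease")
        scores = predict(assoc, sl, sd).scores
        cross = scores[:5, 5:].max()
        assert scores[held] > cross

    def test_index_mismatch_rejected(self, small_problem):
        assoc, sl, sd = small_problem
        with pytest.raises(ValidationError):
            predict(assoc, sd, sl)


class TestRankCandidates:
    def _scores(self, values, known):
        values = np.asarray(values, dtype=float)
        known = np.asarray(known)
        ids_l = [f"L{k}" for k in range(values.shape[0])]
        ids_d = [f"D{k}" for k in range(values.shape[1])]
        return (
            ScoreMatrix(ids_l, ids_d, values),
            AssociationTable(ids_l, ids_d, known),
        )

    def test_all_tied_follows_identifier_order(self):
        scores, known = self._scores(np.ones((2, 2)), np.zeros((2, 2), dtype=int))
        df = rank_candidates(scores, known, scope="global")
        assert list(df["lncrna"]) == ["L0", "L0", "L1", "L1"]
        assert list(df["rank"]) == [1, 2, 3, 4]

    def test_single_unknown_pair_gets_rank_one(self):
        known = np.ones((2, 2), dtype=int)
        known[1, 1] = 0
        scores, known_t = self._scores(np.zeros((2, 2)), known)
        df = rank_candidates(scores, known_t, scope="global")
        assert len(df) == 1 and df["rank"].iloc[0] == 1

    def test_matches_sort_oracle(self, rng):
        v = rng.normal(size=(3, 3))
        scores, known = self._scores(v, np.zeros((3, 3), dtype=int))
        df = rank_candidates(scores, known, scope="global")
        assert list(df["score"]) == sorted(v.ravel(), reverse=True)

    def test_per_disease_ranks_within_columns(self, rng):
        v = rng.normal(size=(4, 2))
        scores, known = self._scores(v, np.zeros((4, 2), dtype=int))
        df = rank_candidates(scores, known, scope="per-disease")
        for d, grp in df.groupby("disease"):
            assert list(grp["rank"]) == [1, 2, 3, 4]
            assert list(grp["score"]) == sorted(grp["score"], reverse=True)

    def test_known_pairs_excluded(self):
        known = np.eye(2, dtype=int)
        scores, known_t = self._scores(np.ones((2, 2)), known)
        df = rank_candidates(scores, known_t, scope="global")
        assert set(zip(df["lncrna"], df["disease"])) == {("L0", "D1"), ("L1", "D0")}
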