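"""Pearson correlation maps and SPA band selection."""

import numpy as np
import pytest

import leafspec as ls
from leafspec.screening import spa_chain, spa_select, top_correlated_bands


def _mgs_oracle_chain(X: np.ndarray, start: int, m: int) -> list[int]:
    """Per-step least-squares projection oracle (no deflation reuse).

    At every step the residual of each unselected column is recomputed from
    scratch against the full selected submatrix via lstsq — an independent
    route to the same greedy chain.
    """
    chain = [start]
    for _ in range(m - 1):
        S = X[:, chain]
        norms = np.full(X.shape[1], -1.0)
        for j in range(X.shape[1]):
            if j in chain:
                continue
            beta, *_ = np.linalg.lstsq(S, X[:, j], rcond=None)
            norms[j] = np.linalg.norm(X[:, j] - S @ beta)
        best = int(np.argmax(norms))
        if norms[best] <= 1e-10:
            break
        chain.append(best)
    return chain


def _random_centered(rng, n, J):
    X = rng.normal(size=(n, J))
    return X - X.mean(axis=0)


class TestPearsonMap:
    def _coeffs_from_matrix(self, M):
        wl = np.arange(401.0, 401.0 + M.shape[1])
        from leafspec.cwt import WaveletCoefficients

        return WaveletCoefficients(
            [4], wl, [f"s{i}" for i in range(M.shape[0])], M[None, :, :]
        )

    def test_band_equal_to_trait(self, rng):
        y = rng.normal(size=20)
        M = rng.normal(size=(20, 5))
        M[:, 2] = y
        M[:, 3] = -y
        M[:, 4] = 5.0  # constant
        cmap = ls.pearson_map(self._coeffs_from_matrix(M), y, 4)
        assert cmap.r[2] == pytest.approx(1.0)
        assert cmap.r[3] == pytest.approx(-1.0)
        assert cmap.r[4] == 0.0 and not cmap.valid_mask[4]

    def test_too_few_samples_rejected(self, rng):
        M = rng.normal(size=(2, 3))
        with pytest.raises(ValueError, match="at least 3"):
            ls.pearson_map(self._coeffs_from_matrix(M), np.array([1.0, 2.0]), 4)

    def test_top_correlated_bands_ordering(self, rng):
        y = rng.normal(size=30)
        M = rng.normal(size=(30, 6)) * 0.1
        M[:, 1] = y + rng.normal(size=30) * 0.01
        M[:, 4] = -y + rng.normal(size=30) * 0.05
        cmap = ls.pearson_map(self._coeffs_from_matrix(M), y, 4)
        top = top_correlated_bands(cmap, 2)
        assert top[0] == 1 and top[1] == 4


class TestSpaChain:
    def test_orthogonal_columns_descending_norms(self):
        # hand-checkable 4x3: orthogonal columns with norms 3, 2, 1
        X = np.zeros((4, 3))
        X[0, 0], X[1, 1], X[2, 2] = 3.0, 2.0, 1.0
        assert spa_chain(X, start=2, m=3) == [2, 0, 1]
        assert spa_chain(X, start=0, m=3) == [0, 1, 2]

    def test_duplicate_column_never_chosen(self, rng):
        X = _random_centered(rng, 10, 4)
        X = np.column_stack([X, X[:, 0]])  # column 4 duplicates column 0
        with pytest.warns(UserWarning, match="truncated"):
            chain = spa_chain(X, start=0, m=5)
        assert 4 not in chain

    def test_matches_lstsq_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            X = _random_centered(rng, 6, 5)
            start = int(rng.integers(5))
            assert spa_chain(X, start, 5) == _mgs_oracle_chain(X, start, 5)

    def test_permutation_consistency(self, rng):
        X = _random_centered(rng, 8, 6)
        start = 2
        chain = spa_chain(X, start=start, m=4)
        perm = rng.permutation(6)
        inv = np.argsort(perm)  # Xp[:, inv[j]] == X[:, j]
        Xp = X[:, perm]
        chain_p = spa_chain(Xp, start=int(inv[start]), m=4)
        assert [int(perm[k]) for k in chain_p] == chain

    def test_m_too_large_rejected(self, rng):
        X = _random_centered(rng, 4, 6)
        with pytest.raises(ValueError):
            spa_chain(X, 0, 5)


class TestSpaSelect:
    def _make_problem(self, rng, n=40, J=10):
        X = rng.normal(size=(n, J))
        y = 2.0 * X[:, 3] - 1.5 * X[:, 7] + rng.normal(size=n) * 0.1
        half = n // 2
        return X[:half], y[:half], X[half:], y[half:]

    def test_m_range_one_is_best_single_column(self, rng):
        Xtr, ytr, Xval, yval = self._make_problem(rng)
        pool = list(range(Xtr.shape[1]))
        sel = spa_select(Xtr, ytr, Xval, yval, m_range=[1], start_pool=pool)
        # brute force over the pool
        best = None
        for j in pool:
            A = np.column_stack([np.ones(Xtr.shape[0]), Xtr[:, j]])
            beta, *_ = np.linalg.lstsq(A, ytr, rcond=None)
            pred = np.column_stack([np.ones(Xval.shape[0]), Xval[:, j]]) @ beta
            rmse = np.sqrt(np.mean((pred - yval) ** 2))
            if best is None or rmse < best[0]:
                best = (rmse, j)
        assert sel.selected == [float(best[1])]
        assert min(sel.chain_rmse.values()) == pytest.approx(best[0])

    def test_bigger_start_pool_never_worse(self, rng):
        Xtr, ytr, Xval, yval = self._make_problem(rng)
        small = spa_select(Xtr, ytr, Xval, yval, m_range=range(1, 5), start_pool=[0, 1])
        large = spa_select(
            Xtr, ytr, Xval, yval, m_range=range(1, 5), start_pool=list(range(10))
        )
        assert min(large.chain_rmse.values()) <= min(small.chain_rmse.values()) + 1e-12

    def test_recovers_planted_columns(self, rng):
        Xtr, ytr, Xval, yval = self._make_problem(rng)
        sel = spa_select(
            Xtr, ytr, Xval, yval, m_range=range(1, 5), start_pool=list(range(10))
        )
        assert {3.0, 7.0} <= set(sel.selected)

    def test_selected_design_full_rank(self, rng):
        Xtr, ytr, Xval, yval = self._make_problem(rng)
        sel = spa_select(Xtr, ytr, Xval, yval, m_range=range(1, 6), start_pool=[3])
        assert np.isfinite(sel.condition_number)

    def test_ties_or_beats_chain_enumeration_oracle(self, rng):
        """Winner matches exhaustive search over all SPA-reachable chains."""
        Xtr, ytr, Xval, yval = self._make_problem(rng, n=24, J=8)
        m_range = range(1, 5)
        pool = list(range(8))
        sel = spa_select(Xtr, ytr, Xval, yval, m_range=m_range, start_pool=pool)
        mu = Xtr.mean(axis=0)
        best = np.inf
        for start in pool:
            chain = spa_chain(Xtr - mu, start, max(m_range))
            for m in m_range:
                cols = chain[:m]
                A = np.column_stack([np.ones(Xtr.shape[0]), Xtr[:, cols]])
                beta, *_ = np.linalg.lstsq(A, ytr, rcond=None)
                pred = np.column_stack([np.ones(Xval.shape[0]), Xval[:, cols]]) @ beta
                best = min(best, np.sqrt(np.mean((pred - yval) ** 2)))
        assert min(sel.chain_rmse.values()) == pytest.approx(best)

    def test_empty_start_pool_rejected(self, rng):
        Xtr, ytr, Xval, yval = self._make_problem(rng)
        with pytest.raises(ValueError, match="empty"):
            spa_select(Xtr, ytr, Xval, yval, m_range=[1], start_pool=[])
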