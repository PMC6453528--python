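"""Implicit-ALS solver checks against independent dense-algebra oracles."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from litrank.als import ALSConfig, ImplicitALS, fit_implicit_als, objective
from litrank.relations import GeneIndex, InteractionMatrix, build_matrix
from litrank.synthetic import SyntheticSpec, generate


def matrix_from_dense(a: np.ndarray) -> InteractionMatrix:
    n = max(a.shape)
    sq = np.zeros((n, n), dtype=np.int64)
    sq[: a.shape[0], : a.shape[1]] = a
    idx = GeneIndex([f"g{i}" for i in range(n)])
    return InteractionMatrix(sp.csr_matrix(sq), idx)


def ridge_oracle_rows(counts: np.ndarray, F: np.ndarray, lam: float, alpha: float):
    """Each row's exact weighted ridge solution, formed naively.

    Explicitly builds the full confidence diagonal over every column and
    solves the normal equations with the generic solver.
    """
    m, _ = counts.shape
    k = F.shape[1]
    out = np.empty((m, k))
    for u in range(m):
        c = 1.0 + alpha * counts[u]
        p = (counts[u] > 0).astype(float)
        A = F.T @ np.diag(c) @ F + lam * np.eye(k)
        out[u] = np.linalg.solve(A, F.T @ (c * p))
    return out


def brute_objective(counts, W, H, lam, alpha):
    total = 0.0
    m, n = counts.shape
    for i in range(m):
        for j in range(n):
            c = 1.0 + alpha * counts[i, j]
            p = 1.0 if counts[i, j] > 0 else 0.0
            total += c * (p - W[i] @ H[:, j]) ** 2
    return total + lam * (np.sum(W**2) + np.sum(H**2))


def test_saturated_ones_reconstructs_near_one(saturated_ones):
    res = ImplicitALS(saturated_ones, rank=1, iterations=20, lam=0.01).fit(seed=0)
    surface = res.score_matrix()
    assert surface.min() > 0.9 and surface.max() < 1.01
    # score() follows from the same fit
    assert res.score("A", "C") == pytest.approx(1.0, abs=0.1)


def test_all_zero_matrix_converges_to_null():
    idx = GeneIndex([f"g{i}" for i in range(5)])
    m = InteractionMatrix(sp.csr_matrix((5, 5), dtype=np.int64), idx)
    res = ImplicitALS(m, rank=2, iterations=20).fit(seed=1)
    assert np.max(np.abs(res.score_matrix())) < 0.05


@pytest.mark.parametrize("mshape", [(3, 3), (4, 5), (6, 6)])
@pytest.mark.parametrize("seed", [0, 1])
def test_half_step_equals_ridge_normal_equations(mshape, seed):
    """One ALS half-step must equal the explicitly-formed weighted
    normal-equation solution, row by row, at 1e-8."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 4, size=mshape)
    counts.flat[rng.integers(0, counts.size)] = 5  # ensure a nonzero
    m = matrix_from_dense(counts)
    lam, alpha = 0.1, 0.1
    dense = m.counts.toarray().astype(float)

    H = rng.uniform(0, 1, size=(2, m.shape[1]))
    Ca = m.counts.astype(np.float64).tocsr()
    Ca.data = alpha * Ca.data
    W_step = ImplicitALS._half_step(Ca, H.T, lam)
    W_oracle = ridge_oracle_rows(dense, H.T, lam, alpha)
    np.testing.assert_allclose(W_step, W_oracle, atol=1e-8)

    # theme-side half-step: same oracle on the transposed system
    W = rng.uniform(0, 1, size=(m.shape[0], 2))
    H_step = ImplicitALS._half_step(Ca.T.tocsr(), W, lam).T
    H_oracle = ridge_oracle_rows(dense.T, W, lam, alpha).T
    np.testing.assert_allclose(H_step, H_oracle, atol=1e-8)


def test_objective_closed_forms():
    counts = np.array([[2, 0], [0, 3]])
    m = matrix_from_dense(counts)
    cfg = ALSConfig(rank=2, lam=0.0, alpha=0.5)
    W = np.zeros((2, 2))
    H = np.zeros((2, 2))
    # W=H=0: objective = sum over nonzero cells of c_ij * 1
    assert objective(m, W, H, cfg) == pytest.approx((1 + 0.5 * 2) + (1 + 0.5 * 3))
    # perfect reconstruction of the binary preferences, lam=0
    W = np.eye(2)
    H = np.eye(2)
    assert objective(m, W, H, cfg) == pytest.approx(0.0, abs=1e-12)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_objective_matches_double_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 5, size=(5, 5))
    m = matrix_from_dense(counts)
    k = 3
    W = rng.normal(size=(5, k))
    H = rng.normal(size=(k, 5))
    cfg = ALSConfig(rank=k, lam=0.3, alpha=0.7)
    got = objective(m, W, H, cfg)
    want = brute_objective(m.counts.toarray(), W, H, 0.3, 0.7)
    assert got == pytest.approx(want, rel=1e-10)


def test_objective_shape_mismatch():
    m = matrix_from_dense(np.ones((3, 3), dtype=int))
    with pytest.raises(ValueError, match="conform"):
        objective(m, np.zeros((3, 2)), np.zeros((2, 4)), ALSConfig(rank=2))


@pytest.mark.parametrize("seed", range(5))
def test_loss_trajectory_non_increasing(seed):
    """Exact alternating minimization: the objective can never rise."""
    rng = np.random.default_rng(seed)
    counts = (rng.random((12, 12)) < 0.3) * rng.integers(1, 6, (12, 12))
    m = matrix_from_dense(counts)
    res = ImplicitALS(m, rank=4, iterations=15).fit(seed=seed)
    diffs = np.diff(res.loss_trajectory)
    assert np.all(diffs <= 1e-9 * np.abs(res.loss_trajectory[:-1]))


def test_seed_determinism_bitwise(toy_matrix):
    r1 = ImplicitALS(toy_matrix, rank=2, iterations=5).fit(seed=42)
    r2 = ImplicitALS(toy_matrix, rank=2, iterations=5).fit(seed=42)
    assert np.array_equal(r1.W, r2.W) and np.array_equal(r1.H, r2.H)


def test_seed_stability_spearman(planted):
    """Different seeds give highly correlated score surfaces on planted data."""
    _, matrix = planted
    t = "TGT"
    s = []
    for seed in (0, 1):
        res = fit_implicit_als(matrix, ALSConfig(seed=seed))
        s.append(res.score_downstream(t))
    rho = spearmanr(s[0], s[1]).statistic
    assert rho > 0.9


def test_scores_equal_multiplied_factor_matrices(toy_matrix):
    res = ImplicitALS(toy_matrix, rank=2, iterations=5).fit(seed=0)
    full = res.W @ res.H
    for a in "ABC":
        for b in "ABC":
            i, j = toy_matrix.index.row(a), toy_matrix.index.col(b)
            assert res.score(a, b) == full[i, j]


def test_heldout_positives_outscore_random_zeros():
    """Recovery: deleted true cells score above random empty cells."""
    wins = 0
    for seed in range(5):
        truth = generate(SyntheticSpec(n_genes=100, n_known_downstream=8,
                                       n_heldout_downstream=5, seed=seed))
        m = build_matrix(truth.edges)
        res = fit_implicit_als(m, ALSConfig(rank=5, iterations=10, seed=seed))
        t = "TGT"
        held = [g for g in truth.heldout_positives if g in m.index]
        held_scores = [res.score(t, g) for g in held]
        rng = np.random.default_rng(seed)
        dense = m.counts.toarray()
        ti = m.index.row(t)
        zeros = np.argwhere(dense[ti] == 0).ravel()
        zeros = [j for j in zeros if j != ti and m.index.symbols[j] not in held]
        picks = rng.choice(zeros, size=len(held), replace=False)
        zero_scores = [res.score(t, m.index.symbols[j]) for j in picks]
        wins += np.mean(held_scores) > np.mean(zero_scores)
    assert wins >= 4


def test_rank_exceeding_dimension_rejected(toy_matrix):
    with pytest.raises(ValueError, match="rank"):
        ImplicitALS(toy_matrix, rank=10)


def test_config_validation():
    for kwargs in ({"rank": 0}, {"iterations": 0}, {"lam": -1}, {"init_scale": 0}):
        with pytest.raises(ValueError):
            ALSConfig(**kwargs)


def test_results_save_load_round_trip(toy_matrix, tmp_path):
    res = ImplicitALS(toy_matrix, rank=2, iterations=3).fit(seed=7)
    p = tmp_path / "factors.txt"
    res.save(p)
    from litrank.als import ALSResults

    back = ALSResults.load(p, toy_matrix)
    np.testing.assert_array_equal(back.W, res.W)
    np.testing.assert_array_equal(back.H, res.H)
    assert back.config == res.config


def test_summary_mentions_configuration(toy_matrix):
    res = ImplicitALS(toy_matrix, rank=2, iterations=3).fit(seed=0)
    text = res.summary()
    assert "rank" in text and "lambda" in text and "alpha" in text
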