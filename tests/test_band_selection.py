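"""Wavelength selectors: fitness terms, swarm dynamics, SPA/UVE baselines."""

import numpy as np
import pytest

from hsiquant import (FitnessConfig, SwarmConfig, pairwise_similarity, run_spa,
                      run_uve, run_vspso, update_swarm, vspso_fitness)
from hsiquant._pls import cv_rmse_pls1, kfold_indices, pls1_fit, pls1_predict
from hsiquant.band_selection import Particle, _sigmoid


# --- inner PLS model ----------------------------------------------------------

@pytest.mark.parametrize("n_components", [1, 3, 8])
def test_pls1_predictions_match_sklearn(rng, n_components):
    from sklearn.cross_decomposition import PLSRegression

    X = rng.normal(size=(50, 20))
    y = X @ rng.normal(size=20) + 0.1 * rng.normal(size=50)
    coef, icpt = pls1_fit(X, y, n_components)
    sk = PLSRegression(n_components=n_components, scale=False).fit(X, y[:, None])
    np.testing.assert_allclose(pls1_predict(X, coef, icpt),
                               sk.predict(X).ravel(), atol=1e-8)


def test_pls1_handles_rank_deficiency(rng):
    X = rng.normal(size=(20, 3))
    X = np.hstack([X, X])  # rank 3 with 6 columns
    y = X[:, 0] * 2.0
    coef, icpt = pls1_fit(X, y, 6)  # must truncate, not blow up
    np.testing.assert_allclose(pls1_predict(X, coef, icpt), y, atol=1e-8)


# --- similarity ---------------------------------------------------------------

def test_similarity_identical_columns_is_one(rng):
    col = rng.normal(size=30)
    assert pairwise_similarity(np.column_stack([col, col])) == pytest.approx(1.0)


def test_similarity_single_column_is_zero(rng):
    assert pairwise_similarity(rng.normal(size=(30, 1))) == 0.0


def test_similarity_constant_column_maximally_redundant(rng):
    X = np.column_stack([np.full(30, 2.0), rng.normal(size=30)])
    assert pairwise_similarity(X) == pytest.approx(1.0)


def test_similarity_matches_double_loop(rng):
    X = rng.normal(size=(25, 3))
    ls = 2.5
    mu, sd = X.mean(0), X.std(0)
    Z = (X - mu) / sd
    expected = 0.0
    for a in range(3):
        for b in range(a + 1, 3):
            d2 = float(((Z[:, a] - Z[:, b]) ** 2).sum())
            expected += np.exp(-d2 / (2 * ls**2 * 25))
    assert pairwise_similarity(X, length_scale=ls) == pytest.approx(expected,
                                                                    rel=1e-12)


def test_literal_exponent_variant_grows_with_distance(rng):
    near = np.column_stack([rng.normal(size=30)] * 2) + rng.normal(
        0, 0.01, (30, 2))
    far = rng.normal(size=(30, 2))
    assert (pairwise_similarity(far, similarity="literal_exp")
            > pairwise_similarity(near, similarity="literal_exp"))


# --- fitness ------------------------------------------------------------------

def _toy_problem(rng, n=40, L=12):
    X = rng.normal(size=(n, L))
    y = X[:, 2] - 0.5 * X[:, 7] + 0.05 * rng.normal(size=n)
    return X, y


def test_lambda_zero_fitness_is_exactly_inner_cv_rmse(rng):
    X, y = _toy_problem(rng)
    cfg = FitnessConfig(lam=0.0, cv_seed=5)
    folds = kfold_indices(40, cfg.cv_folds, cfg.cv_seed)
    sd = y.std(ddof=1)
    for _ in range(10):
        pos = (rng.random(12) < 0.5).astype(np.int8)
        if not pos.any():
            pos[0] = 1
        fv = vspso_fitness(pos, X, y, cfg, folds)
        oracle = cv_rmse_pls1(X[:, np.flatnonzero(pos)], y / sd,
                              cfg.n_components, folds)
        assert fv.total == oracle  # bitwise: same folds, same model
        assert fv.penalty == 0.0


def test_single_band_has_zero_penalty(rng):
    X, y = _toy_problem(rng)
    pos = np.zeros(12, dtype=np.int8)
    pos[3] = 1
    fv = vspso_fitness(pos, X, y, FitnessConfig(lam=0.7))
    assert fv.penalty == 0.0
    assert fv.total == fv.rmse


def test_empty_selection_is_infeasible(rng):
    X, y = _toy_problem(rng)
    fv = vspso_fitness(np.zeros(12, dtype=np.int8), X, y, FitnessConfig())
    assert np.isinf(fv.total)


def test_penalty_increases_with_redundancy(rng):
    """Duplicating a selected column (maximal pair similarity) raises the
    penalty term at fixed subset size."""
    X, y = _toy_problem(rng)
    Xdup = X.copy()
    Xdup[:, 5] = Xdup[:, 2]  # two identical selected columns
    pos = np.zeros(12, dtype=np.int8)
    pos[[2, 5, 9]] = 1
    cfg = FitnessConfig(lam=0.3)
    assert (vspso_fitness(pos, Xdup, y, cfg).penalty
            > vspso_fitness(pos, X, y, cfg).penalty)


def test_fitness_decomposition_matches_hand_assembly(rng):
    """Five fixed bands at lambda=0.2: total equals independently computed
    CV RMSE plus the hand-assembled similarity penalty."""
    X, y = _toy_problem(rng, n=50, L=20)
    sel = np.array([1, 4, 8, 13, 17])
    pos = np.zeros(20, dtype=np.int8)
    pos[sel] = 1
    cfg = FitnessConfig(lam=0.2, cv_seed=3)
    folds = kfold_indices(50, 5, 3)
    fv = vspso_fitness(pos, X, y, cfg, folds)
    rmse = cv_rmse_pls1(X[:, sel], y / y.std(ddof=1), cfg.n_components, folds)
    pair_sum = pairwise_similarity(X[:, sel], cfg.length_scale)
    penalty = 0.2 * (5 / 20) * pair_sum / 10  # 10 unordered pairs
    assert fv.rmse == pytest.approx(rmse, rel=1e-14)
    assert fv.penalty == pytest.approx(penalty, rel=1e-14)
    assert fv.total == pytest.approx(rmse + penalty, rel=1e-14)


# --- swarm dynamics -----------------------------------------------------------

def test_velocity_update_arithmetic():
    cfg = SwarmConfig(c1=0.0, c2=0.0, v_max=4.0)
    p = Particle(position=np.array([1, 0, 1], dtype=np.int8),
                 velocity=np.array([2.0, -2.0, 0.5]),
                 pbest_position=np.array([1, 0, 1], dtype=np.int8),
                 pbest_fitness=1.0)
    update_swarm([p], np.array([1, 0, 1], dtype=np.int8), cfg,
                 np.random.default_rng(0), inertia=0.5)
    np.testing.assert_allclose(p.velocity, [1.0, -1.0, 0.25])


def test_single_update_matches_hand_stepped_trace():
    """One full update on a 3-band toy reproduces the velocity/position
    computed by hand from the recorded random draws."""
    cfg = SwarmConfig(c1=2.0, c2=2.0, v_max=4.0,
                      binarization="sigmoid_stochastic")
    x = np.array([1, 0, 1], dtype=np.int8)
    pbest = np.array([0, 1, 1], dtype=np.int8)
    gbest = np.array([1, 1, 0], dtype=np.int8)
    v0 = np.array([0.5, -0.5, 1.0])
    w = 0.7

    seed = 42
    rec = np.random.default_rng(seed)
    r1, r2, u = rec.random(3), rec.random(3), rec.random(3)
    v_hand = np.clip(w * v0 + 2 * r1 * (pbest - x) + 2 * r2 * (gbest - x),
                     -4.0, 4.0)
    pos_hand = (u < 1 / (1 + np.exp(-v_hand))).astype(np.int8)
    assert pos_hand.any()  # no repair draw in this trace

    p = Particle(position=x.copy(), velocity=v0.copy(),
                 pbest_position=pbest.copy(), pbest_fitness=1.0)
    update_swarm([p], gbest, cfg, np.random.default_rng(seed), inertia=w)
    np.testing.assert_allclose(p.velocity, v_hand, rtol=1e-15)
    np.testing.assert_array_equal(p.position, pos_hand)


def test_stochastic_transfer_fixed_point():
    """At pbest = gbest = x with zero velocity the velocity stays zero and
    each bit is resampled fair-coin (sigmoid(0) = 0.5)."""
    L = 2000
    x = (np.random.default_rng(0).random(L) < 0.5).astype(np.int8)
    p = Particle(position=x.copy(), velocity=np.zeros(L),
                 pbest_position=x.copy(), pbest_fitness=1.0)
    cfg = SwarmConfig(binarization="sigmoid_stochastic")
    update_swarm([p], x.copy(), cfg, np.random.default_rng(3), inertia=0.9)
    np.testing.assert_array_equal(p.velocity, np.zeros(L))
    assert abs(p.position.mean() - 0.5) < 0.05


def test_threshold_transfer_is_deterministic():
    x = np.array([1, 0, 1, 0], dtype=np.int8)
    v0 = np.array([1.0, -1.0, 2.0, -2.0])
    expected = (_sigmoid(0.9 * v0) > 0.5).astype(np.int8)
    p = Particle(position=x.copy(), velocity=v0.copy(),
                 pbest_position=x.copy(), pbest_fitness=1.0)
    cfg = SwarmConfig(c1=0.0, c2=0.0, binarization="threshold_half")
    update_swarm([p], x.copy(), cfg, np.random.default_rng(0), inertia=0.9)
    np.testing.assert_array_equal(p.position, expected)


def test_repair_guarantees_nonempty_position():
    p = Particle(position=np.array([1, 0, 0], dtype=np.int8),
                 velocity=np.array([-4.0, -4.0, -4.0]),
                 pbest_position=np.zeros(3, dtype=np.int8),
                 pbest_fitness=1.0)
    cfg = SwarmConfig(c1=0.0, c2=0.0, binarization="threshold_half")
    update_swarm([p], np.zeros(3, dtype=np.int8), cfg,
                 np.random.default_rng(0), inertia=0.9)
    assert p.position.sum() == 1  # all bits off -> one random bit repaired


def test_run_is_deterministic_and_monotone(rng):
    X, y = _toy_problem(rng, n=50, L=15)
    scfg = SwarmConfig(n_particles=10, max_iter=20, seed=9)
    fcfg = FitnessConfig(lam=0.2, cv_seed=9)
    a = run_vspso(X, y, scfg, fcfg)
    b = run_vspso(X, y, scfg, fcfg)
    assert np.array_equal(a.selected_indices, b.selected_indices)
    np.testing.assert_array_equal(a.gbest_trajectory, b.gbest_trajectory)
    assert np.all(np.diff(a.gbest_trajectory) <= 1e-15)
    assert a.n_selected >= 1
    sel = a.selected_indices
    assert np.all(sel == np.sort(sel)) and len(set(sel.tolist())) == sel.size


def test_planted_perfect_predictor_is_selected():
    hits = 0
    for seed in range(5):
        r = np.random.default_rng(100 + seed)
        X = r.normal(size=(60, 30))
        y = 2.0 * X[:, 7] + 0.01 * r.normal(size=60)
        res = run_vspso(X, y, SwarmConfig(n_particles=20, max_iter=50,
                                          seed=seed),
                        FitnessConfig(lam=0.0, cv_seed=seed))
        hits += int(7 in res.selected_indices)
    assert hits == 5


# --- SPA ----------------------------------------------------------------------

def test_spa_orthogonal_design_finds_spanning_column(rng):
    Q, _ = np.linalg.qr(rng.normal(size=(30, 8)))
    y = 5.0 * Q[:, 3]
    sel = run_spa(Q, y, range(1, 4))
    assert sel.tolist() == [3]


def test_spa_never_selects_both_duplicates(rng):
    X = rng.normal(size=(40, 6))
    X[:, 4] = X[:, 1]  # exact duplicate pair
    y = X[:, 1] + 0.5 * X[:, 2] + 0.01 * rng.normal(size=40)
    sel = set(run_spa(X, y, range(1, 5)).tolist())
    assert not ({1, 4} <= sel)


def test_spa_projections_match_gram_schmidt(rng):
    """Chains grown by the implementation equal explicit Gram-Schmidt
    recomputation of the residual-norm argmax at every step."""
    from hsiquant.band_selection import spa_chain

    X = rng.normal(size=(5, 8))
    Xc = X - X.mean(axis=0)
    for start in range(8):
        chain = [start]
        basis = [Xc[:, start] / np.linalg.norm(Xc[:, start])]
        for _ in range(2):
            res_norm = np.zeros(8)
            for j in range(8):
                if j in chain:
                    res_norm[j] = -1
                    continue
                r = Xc[:, j].copy()
                for q in basis:
                    r -= (q @ Xc[:, j]) * q
                res_norm[j] = np.linalg.norm(r)
            nxt = int(np.argmax(res_norm))
            chain.append(nxt)
            r = Xc[:, nxt].copy()
            for q in basis:
                r -= (q @ Xc[:, nxt]) * q
            basis.append(r / np.linalg.norm(r))
        assert spa_chain(Xc, start, 3) == chain


def test_spa_range_validation(rng):
    X = rng.normal(size=(10, 5))
    y = rng.normal(size=10)
    with pytest.raises(ValueError, match="n_vars_range"):
        run_spa(X, y, range(1, 30))


# --- UVE ----------------------------------------------------------------------

def test_uve_keeps_perfect_predictor(rng):
    X = rng.normal(size=(40, 12))
    y = X[:, 5].copy()
    assert 5 in run_uve(X, y, n_components=5, seed=0)


def test_uve_null_retention_is_rare():
    total = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        X = r.normal(size=(40, 30))
        y = r.normal(size=40)
        total += run_uve(X, y, n_components=5, seed=seed).size
    assert total / (20 * 30) <= 0.05


def test_uve_keeps_redundant_block_spa_prunes_it(rng):
    """A block of correlated informative columns: the stability filter (UVE)
    retains several of them, the orthogonal-projection chain (SPA) keeps a
    parsimonious subset - so UVE retains more variables."""
    n = 120
    signal = rng.normal(size=n)
    block = signal[:, None] + 0.15 * rng.normal(size=(n, 15))
    noise = rng.normal(size=(n, 25))
    X = np.hstack([block, noise])
    y = signal + 0.05 * rng.normal(size=n)
    uve = run_uve(X, y, n_components=5, seed=0)
    spa = run_spa(X, y, range(1, 8), cv_seed=0)
    assert uve.size > spa.size
    assert set(uve.tolist()) <= set(range(15))  # only block columns survive
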