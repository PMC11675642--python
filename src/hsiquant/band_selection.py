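"""Key-wavelength selection: variable-similarity binary PSO, SPA and UVE.

The selector of interest (VSPSO) is a binary particle swarm whose fitness
adds a variable-similarity regularization to the cross-validated
prediction error of the candidate band subset:

    f(X_k) = RMSE_cv(selected bands) + lambda * (l / L) * S_bar

where l is the subset size, L the total band count and S_bar aggregates
the pairwise Gaussian similarity of the standardized selected columns.
Minimizing f trades prediction error against spectral redundancy; at
lambda = 0 the algorithm reduces to standard binary PSO.  The velocity
update is canonical PSO,

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x),

with positions re-binarized through a sigmoid transfer function.

SPA (successive projections algorithm) and UVE (uninformative variable
elimination) are provided as the classical wrapper/filter baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from ._pls import cv_rmse_pls1, kfold_indices, pls1_fit, pls1_predict

__all__ = [
    "SwarmConfig",
    "FitnessConfig",
    "Particle",
    "SelectionResult",
    "FitnessValue",
    "pairwise_similarity",
    "vspso_fitness",
    "update_swarm",
    "run_vspso",
    "run_spa",
    "run_uve",
]


@dataclass
class SwarmConfig:
    """Binary-PSO hyperparameters.

    Population 30 and 200 iterations are the study's settings; inertia
    decays linearly from ``inertia_start`` to ``inertia_end`` over the
    run, learning factors and velocity clamp follow standard PSO
    practice.  ``binarization`` is 'threshold_half' (deterministic,
    bit on iff sigmoid(v) > 0.5; the default, as the stochastic
    transfer re-randomizes too many bits per step to converge within
    a few hundred iterations on ~300 bands) or 'sigmoid_stochastic'
    (bit set with probability sigmoid(v)).
    """

    n_particles: int = 30
    max_iter: int = 200
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 4.0
    binarization: str = "threshold_half"
    init_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_particles < 1 or self.max_iter < 1:
            raise ValueError("n_particles and max_iter must be positive")
        for w in (self.inertia_start, self.inertia_end):
            if not 0.0 < w < 1.0:
                raise ValueError("inertia weights must lie in (0, 1)")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.binarization not in {"sigmoid_stochastic", "threshold_half"}:
            raise ValueError(f"unknown binarization {self.binarization!r}")


@dataclass
class FitnessConfig:
    """Fitness settings: lambda weight, inner CV model, similarity kernel.

    The inner model for the RMSE term is PLS1 with ``n_components``
    latent variables (capped by subset size and fold size) under
    ``cv_folds``-fold CV with folds fixed by ``cv_seed`` so every subset
    is scored on identical splits.  With ``normalize_rmse`` (default)
    the inner model scores the SD-standardized target, making the RMSE
    term unit-free so one lambda balances both terms regardless of the
    component's concentration scale.  ``similarity`` is 'gaussian'
    (exp(-d^2 / (2 ls^2 n)), maximal for redundant bands) or
    'literal_exp' (exp(+d^2), audit only).  ``pair_aggregation`` is
    'mean_pairs' (default) or 'sum_scaled_by_l_over_L'.
    """

    lam: float = 0.2
    n_components: int = 10
    cv_folds: int = 5
    cv_seed: int = 0
    similarity: str = "gaussian"
    length_scale: float = 2.5
    pair_aggregation: str = "mean_pairs"
    normalize_rmse: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.lam < 1.0:
            raise ValueError("lambda must lie in [0, 1)")
        if self.similarity not in {"gaussian", "literal_exp"}:
            raise ValueError(f"unknown similarity {self.similarity!r}")
        if self.pair_aggregation not in {"mean_pairs", "sum_scaled_by_l_over_L"}:
            raise ValueError(f"unknown pair aggregation {self.pair_aggregation!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class Particle:
    position: np.ndarray        # binary {0,1}, length L
    velocity: np.ndarray        # real, clamped to [-v_max, v_max]
    pbest_position: np.ndarray
    pbest_fitness: float


class FitnessValue(NamedTuple):
    total: float
    rmse: float
    penalty: float


@dataclass
class SelectionResult:
    selected_indices: np.ndarray
    gbest_trajectory: np.ndarray   # best-ever total fitness per iteration
    rmse_term: float
    penalty_term: float
    lam: float
    method: str = "vspso"

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)

    def to_json_dict(self) -> dict:
        return {
            "method": self.method,
            "lambda": self.lam,
            "selected_indices": self.selected_indices.tolist(),
            "n_selected": self.n_selected,
            "rmse_term": self.rmse_term,
            "penalty_term": self.penalty_term,
            "gbest_trajectory": np.asarray(self.gbest_trajectory).tolist(),
        }


# --- fitness ------------------------------------------------------------------

def pairwise_similarity(X_subset: np.ndarray, length_scale: float = 1.0,
                        similarity: str = "gaussian") -> float:
    """Sum over unordered column pairs of the similarity kernel.

    Columns are standardized to zero mean / unit variance first; the
    squared Euclidean distance is normalized by the sample count so the
    kernel scale does not depend on calibration size.  A zero-variance
    column cannot be standardized; its pairs are assigned similarity 1
    (a constant band is maximally redundant).  Returns 0 for a single
    column.
    """
    X = np.atleast_2d(np.asarray(X_subset, dtype=float))
    n, l = X.shape
    if l < 1:
        raise ValueError("at least one column required")
    if l == 1:
        return 0.0
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd == 0
    sd_safe = np.where(const, 1.0, sd)
    Z = (X - mu) / sd_safe

    sq = np.einsum("ij,ij->j", Z, Z)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (Z.T @ Z)
    np.maximum(D2, 0.0, out=D2)
    if similarity == "gaussian":
        S = np.exp(-D2 / (2.0 * length_scale**2 * n))
    elif similarity == "literal_exp":
        S = np.exp(D2 / n)
    else:
        raise ValueError(f"unknown similarity {similarity!r}")
    if const.any():
        S[const, :] = 1.0
        S[:, const] = 1.0
    iu = np.triu_indices(l, k=1)
    return float(S[iu].sum())


def vspso_fitness(position: np.ndarray, X: np.ndarray, y: np.ndarray,
                  cfg: FitnessConfig,
                  folds: list[tuple[np.ndarray, np.ndarray]] | None = None
                  ) -> FitnessValue:
    """Regularized subset fitness; returns (total, rmse, penalty).

    An empty selection is infeasible and scores +inf.  The penalty term
    is lambda * (l/L) * S_bar with S_bar the mean (default) or sum of
    pairwise similarities; it is exactly 0 for single-band subsets.
    """
    cfg.validate()
    position = np.asarray(position)
    sel = np.flatnonzero(position)
    L = position.size
    if sel.size == 0:
        return FitnessValue(np.inf, np.inf, 0.0)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if folds is None:
        folds = kfold_indices(X.shape[0], cfg.cv_folds, cfg.cv_seed)
    if cfg.normalize_rmse:
        sd = y.std(ddof=1)
        if sd == 0:
            raise ValueError("target has zero variance")
        y = y / sd
    rmse = cv_rmse_pls1(X[:, sel], y, cfg.n_components, folds)

    l = sel.size
    if l == 1 or cfg.lam == 0.0:
        penalty = 0.0
    else:
        pair_sum = pairwise_similarity(X[:, sel], cfg.length_scale, cfg.similarity)
        agg = (pair_sum / (l * (l - 1) / 2)
               if cfg.pair_aggregation == "mean_pairs" else pair_sum)
        penalty = cfg.lam * (l / L) * agg
    return FitnessValue(rmse + penalty, rmse, penalty)


# --- swarm dynamics -----------------------------------------------------------

def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def update_swarm(particles: list[Particle], gbest_position: np.ndarray,
                 cfg: SwarmConfig, rng: np.random.Generator,
                 inertia: float | None = None) -> None:
    """One kinematic update of every particle, in place.

    Per particle the rng is consumed in this order: r1 (L draws), r2 (L
    draws), then for sigmoid_stochastic the binarization uniforms (L
    draws), then one integer draw only if repair is needed.  Positions
    enter Eq.-style arithmetic as 0/1 reals; velocities are clamped to
    [-v_max, v_max]; an all-zero position is repaired by switching on
    one uniformly random band.
    """
    cfg.validate()
    L = gbest_position.size
    g = gbest_position.astype(float)
    w = float(inertia) if inertia is not None else cfg.inertia_start
    for p in particles:
        r1 = rng.random(L)
        r2 = rng.random(L)
        x = p.position.astype(float)
        v = (w * p.velocity
             + cfg.c1 * r1 * (p.pbest_position.astype(float) - x)
             + cfg.c2 * r2 * (g - x))
        np.clip(v, -cfg.v_max, cfg.v_max, out=v)
        p.velocity = v
        if cfg.binarization == "sigmoid_stochastic":
            p.position = (rng.random(L) < _sigmoid(v)).astype(np.int8)
        else:
            p.position = (_sigmoid(v) > 0.5).astype(np.int8)
        if not p.position.any():
            p.position[rng.integers(L)] = 1


def run_vspso(X: np.ndarray, y: np.ndarray, swarm_cfg: SwarmConfig,
              fitness_cfg: FitnessConfig) -> SelectionResult:
    """Full VSPSO run; reproducible from swarm_cfg.seed.

    pbest/gbest update on strict improvement only, so the best-ever
    fitness trajectory is non-increasing.  Fitness values are cached per
    position, as the CV folds are fixed for the whole run.
    """
    swarm_cfg.validate()
    fitness_cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, L = X.shape
    if L == 0:
        raise ValueError("no bands to select from")
    if n < fitness_cfg.cv_folds:
        raise ValueError("fewer samples than CV folds")

    rng = np.random.default_rng(swarm_cfg.seed)
    folds = kfold_indices(n, fitness_cfg.cv_folds, fitness_cfg.cv_seed)
    cache: dict[bytes, FitnessValue] = {}

    def fitness(pos: np.ndarray) -> FitnessValue:
        key = pos.tobytes()
        fv = cache.get(key)
        if fv is None:
            fv = vspso_fitness(pos, X, y, fitness_cfg, folds)
            cache[key] = fv
        return fv

    particles: list[Particle] = []
    for _ in range(swarm_cfg.n_particles):
        pos = (rng.random(L) < swarm_cfg.init_prob).astype(np.int8)
        if not pos.any():
            pos[rng.integers(L)] = 1
        # velocity propensity consistent with the initial bit state, so the
        # deterministic transfer does not wipe consensus bits at step one
        vel = rng.uniform(0.0, 1.0, L) * np.where(pos > 0, 1.0, -1.0)
        fv = fitness(pos)
        particles.append(Particle(position=pos, velocity=vel,
                                  pbest_position=pos.copy(),
                                  pbest_fitness=fv.total))
    g_idx = int(np.argmin([p.pbest_fitness for p in particles]))
    gbest_pos = particles[g_idx].pbest_position.copy()
    gbest_fv = fitness(gbest_pos)

    trajectory = np.empty(swarm_cfg.max_iter)
    for t in range(swarm_cfg.max_iter):
        if swarm_cfg.max_iter > 1:
            inertia = (swarm_cfg.inertia_start
                       + (swarm_cfg.inertia_end - swarm_cfg.inertia_start)
                       * t / (swarm_cfg.max_iter - 1))
        else:
            inertia = swarm_cfg.inertia_start
        update_swarm(particles, gbest_pos, swarm_cfg, rng, inertia)
        for p in particles:
            fv = fitness(p.position)
            if fv.total < p.pbest_fitness:
                p.pbest_fitness = fv.total
                p.pbest_position = p.position.copy()
                if fv.total < gbest_fv.total:
                    gbest_fv = fv
                    gbest_pos = p.position.copy()
        trajectory[t] = gbest_fv.total

    return SelectionResult(
        selected_indices=np.flatnonzero(gbest_pos),
        gbest_trajectory=trajectory,
        rmse_term=gbest_fv.rmse,
        penalty_term=gbest_fv.penalty,
        lam=fitness_cfg.lam,
        method="vspso" if fitness_cfg.lam > 0 else "pso",
    )


# --- SPA baseline -------------------------------------------------------------

def _ols_cv_rmse(X: np.ndarray, y: np.ndarray,
                 folds: list[tuple[np.ndarray, np.ndarray]]) -> float:
    sq = 0.0
    n = 0
    for train, test in folds:
        A = np.column_stack([X[train], np.ones(train.size)])
        coef, *_ = np.linalg.lstsq(A, y[train], rcond=None)
        pred = np.column_stack([X[test], np.ones(test.size)]) @ coef
        resid = y[test] - pred
        sq += float(resid @ resid)
        n += test.size
    return float(np.sqrt(sq / n))


def spa_chain(Xc: np.ndarray, start: int, max_len: int,
              rank_tol: float = 1e-10) -> list[int]:
    """Grow one SPA chain from a centered matrix by orthogonal projections.

    At each step the column with the largest residual norm against the
    orthonormal basis of the chain is appended; the chain stops early
    when the remaining columns fall inside the span (rank deficiency).
    """
    L = Xc.shape[1]
    norm0 = np.linalg.norm(Xc[:, start])
    if norm0 < rank_tol:
        return []
    chain = [start]
    R = Xc.copy()
    q = Xc[:, start] / norm0
    R -= np.outer(q, q @ R)
    while len(chain) < max_len:
        res_norms = np.linalg.norm(R, axis=0)
        res_norms[chain] = -1.0
        j = int(np.argmax(res_norms))
        if res_norms[j] < rank_tol:
            break
        chain.append(j)
        q = R[:, j] / res_norms[j]
        R -= np.outer(q, q @ R)
    return chain


def run_spa(X: np.ndarray, y: np.ndarray,
            n_vars_range: range | None = None,
            cv_folds: int = 5, cv_seed: int = 0,
            rank_tol: float = 1e-10) -> np.ndarray:
    """Successive projections algorithm; returns sorted selected indices.

    For every starting column a chain is grown by repeatedly adding the
    column with the largest norm of its projection onto the orthogonal
    complement of the chain so far (rank deficiency stops a chain
    early).  The final (start, size) pair minimizes cross-validated OLS
    RMSE over ``n_vars_range``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, L = X.shape
    max_allowed = min(n - 1, L)
    if n_vars_range is None:
        n_vars_range = range(1, min(max_allowed, 25) + 1)
    if min(n_vars_range) < 1 or max(n_vars_range) > max_allowed:
        raise ValueError(f"n_vars_range must lie within [1, {max_allowed}]")
    Xc = X - X.mean(axis=0)
    folds = kfold_indices(n, cv_folds, cv_seed)
    max_len = max(n_vars_range)

    best = (np.inf, None)
    for start in range(L):
        chain = spa_chain(Xc, start, max_len, rank_tol)
        if not chain:
            continue
        for m in n_vars_range:
            if m > len(chain):
                break
            score = _ols_cv_rmse(X[:, chain[:m]], y, folds)
            if score < best[0]:
                best = (score, tuple(chain[:m]))
    if best[1] is None:
        raise ValueError("SPA found no usable chain (rank-deficient input)")
    return np.sort(np.array(best[1], dtype=int))


# --- UVE baseline -------------------------------------------------------------

def run_uve(X: np.ndarray, y: np.ndarray, n_components: int = 10,
            noise_amplitude: float | None = None, seed: int = 0,
            cutoff_factor: float = 1.0,
            cutoff_quantile: float = 1.0) -> np.ndarray:
    """Uninformative variable elimination; returns sorted retained indices.

    X is augmented with L uniform noise columns; PLS1 coefficients are
    computed under leave-one-out, and the stability
    c_j = mean(b_j)/std(b_j) of each real variable is compared with the
    ``cutoff_quantile`` of |c| among the noise variables (the default
    1.0 is the strict max; lower it for robustness to the heavy upper
    tail of the stability ratios).  ``noise_amplitude`` defaults to the median
    column standard deviation of X, so the artificial variables mimic
    the data's own uninformative bands.  Variables with zero
    coefficient spread are kept (stability is infinite).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, L = X.shape
    rng = np.random.default_rng(seed)
    if noise_amplitude is None:
        med_sd = float(np.median(X.std(axis=0)))
        noise_amplitude = (med_sd * np.sqrt(12.0)) if med_sd > 0 else 1e-6
    noise = rng.uniform(0.0, noise_amplitude, size=(n, L))
    Z = np.hstack([X, noise])

    B = np.empty((n, 2 * L))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        coef, _ = pls1_fit(Z[keep], y[keep], n_components)
        B[i] = coef
    mean_b = B.mean(axis=0)
    std_b = B.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(std_b == 0, np.inf * np.sign(mean_b), mean_b / std_b)
        c = np.where((std_b == 0) & (mean_b == 0), np.inf, c)
    stability = np.abs(c)
    cutoff = cutoff_factor * float(np.quantile(stability[L:], cutoff_quantile))
    return np.flatnonzero(stability[:L] > cutoff)
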