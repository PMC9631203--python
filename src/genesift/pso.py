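"""Stage 2 — particle-swarm search over subsets of the filtered candidates.

Particles move in the continuous unit cube [0, 1]^D (one dimension per
candidate gene) with the classic update rules

    v <- w*v + c1*rand1*(pbest - x) + c2*rand2*(gbest - x)
    x <- x + v

with rand1, rand2 drawn fresh per component from U[0, 1], velocities clamped
to [-v_max, v_max] and positions clipped to [0, 1].  A position decodes to a
gene subset by thresholding (gene j in iff x_j >= threshold); an all-excluded
decode is repaired by including the single gene with the largest component,
so the fitness classifier always has at least one feature.

Fitness of a subset combines the cross-validated accuracy (ACC) and mean
squared error (MSE) of the internal sigmoid MLP with a mild subset-size
penalty:

    composite = ACC - lambda_mse * MSE - lambda_size * size / D,

so accuracy dominates while ties resolve toward smaller, lower-error
subsets.  Fitness evaluations are cached per decoded mask within a run, and
the evaluation RNG is derived deterministically from (seed, mask) so a
subset's fitness is stable within a run.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, check_X_y

from .mlp import SigmoidMLPClassifier

__all__ = [
    "SwarmConfig",
    "FitnessValue",
    "SelectionResult",
    "update_velocity",
    "update_position",
    "decode_subset",
    "evaluate_fitness",
    "pso_search",
    "PSOMLPSelector",
]


@dataclass
class SwarmConfig:
    """Swarm hyperparameters; c1 = c2 = 2 follows the usual PSO convention.

    ``turbulence`` is the per-component probability that a velocity entry is
    re-drawn from U[-v_max, v_max] after the standard update.  Because
    fitness is flat inside each decode cell, a converged swarm (pbest =
    gbest = x) otherwise has geometrically decaying velocities and can stall
    one bit-flip short of the optimum; the turbulence term keeps a small
    amount of per-dimension exploration alive.  Set 0 to disable.
    """

    n_particles: int = 30
    n_iterations: int = 100
    omega: float = 0.7
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 0.6
    decode_threshold: float = 0.5
    turbulence: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.omega <= 1.0):
            raise ValueError("omega must lie in (0, 1]")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if not (0.0 < self.decode_threshold < 1.0):
            raise ValueError("decode_threshold must lie in (0, 1)")


@dataclass
class FitnessValue:
    accuracy: float
    mse: float
    subset_size: int
    composite: float


@dataclass
class SelectionResult:
    """Outcome of a swarm run: the decoded gbest subset and its history."""

    selected_genes: list
    selected_mask: np.ndarray
    gbest_fitness: FitnessValue
    gbest_fitness_history: list = field(default_factory=list)  # composite per iteration
    gbest_detail_history: list = field(default_factory=list)  # FitnessValue per iteration
    candidate_genes: list = field(default_factory=list)
    config: SwarmConfig | None = None


def update_velocity(velocity, position, pbest, gbest, cfg: SwarmConfig, rng) -> np.ndarray:
    """One velocity update, component-wise, clamped to [-v_max, v_max]."""
    v = np.asarray(velocity, dtype=float)
    x = np.asarray(position, dtype=float)
    pb = np.asarray(pbest, dtype=float)
    gb = np.asarray(gbest, dtype=float)
    if not (v.shape == x.shape == pb.shape == gb.shape):
        raise ValueError("velocity/position/pbest/gbest must share one shape")
    r1 = rng.uniform(0.0, 1.0, size=v.shape)
    r2 = rng.uniform(0.0, 1.0, size=v.shape)
    new_v = cfg.omega * v + cfg.c1 * r1 * (pb - x) + cfg.c2 * r2 * (gb - x)
    return np.clip(new_v, -cfg.v_max, cfg.v_max)


def update_position(position, velocity) -> np.ndarray:
    """x + v, clipped to the unit cube."""
    x = np.asarray(position, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if x.shape != v.shape:
        raise ValueError("position and velocity must share one shape")
    return np.clip(x + v, 0.0, 1.0)


def decode_subset(position, threshold: float = 0.5) -> np.ndarray:
    """Threshold a position into a boolean inclusion mask, with repair.

    Gene j is included iff x_j >= threshold; if that excludes everything the
    single largest component is included instead.
    """
    x = np.asarray(position, dtype=float)
    mask = x >= threshold
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(x))] = True
    return mask


def _mask_seed(seed: int | None, mask: np.ndarray) -> int:
    """Deterministic per-subset seed below 2**31, from (run seed, mask)."""
    crc = zlib.crc32(np.packbits(mask).tobytes())
    return (crc ^ ((seed or 0) * 2654435761)) % (2**31 - 1)


def evaluate_fitness(
    mask,
    X,
    y,
    mlp_config: dict | None = None,
    cv: int = 5,
    lambda_mse: float = 0.1,
    lambda_size: float = 0.05,
    seed: int | None = None,
) -> FitnessValue:
    """Cross-validated MLP fitness of one decoded gene subset.

    ACC and MSE come from stratified ``cv``-fold out-of-fold predictions of
    the sigmoid MLP restricted to the subset's columns; MSE is the mean
    squared gap between predicted probability and the 0/1 label.
    """
    mask = np.asarray(mask, dtype=bool)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if mask.shape[0] != X.shape[1]:
        raise ValueError("mask length does not match gene count")
    if not mask.any():
        raise ValueError("empty subset; repair with decode_subset first")
    size = int(mask.sum())
    D = mask.shape[0]
    sub = X[:, mask]
    eval_seed = _mask_seed(seed, mask)
    folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=eval_seed)
    proba = np.empty(len(y))
    pred = np.empty(len(y), dtype=int)
    for f, (tr, te) in enumerate(folds.split(sub, y)):
        clf = SigmoidMLPClassifier(
            random_state=(eval_seed + f) % (2**31 - 1), **(mlp_config or {})
        )
        clf.fit(sub[tr], y[tr])
        p = clf.predict_proba(sub[te])[:, 1]
        proba[te] = p
        pred[te] = (p >= 0.5).astype(int)
    acc = float(np.mean(pred == y))
    mse = float(np.mean((proba - y) ** 2))
    composite = acc - lambda_mse * mse - lambda_size * (size / D)
    return FitnessValue(accuracy=acc, mse=mse, subset_size=size, composite=composite)


def pso_search(
    candidate_genes,
    X,
    y,
    cfg: SwarmConfig | None = None,
    mlp_config: dict | None = None,
    cv: int = 5,
    lambda_mse: float = 0.1,
    lambda_size: float = 0.05,
    fitness_fn=None,
) -> SelectionResult:
    """Run the swarm over subsets of ``candidate_genes`` (columns of X).

    ``fitness_fn(mask) -> float`` may be injected to replace the MLP-based
    fitness entirely (used for validating the search against exhaustive
    enumeration); the returned FitnessValue then carries only the composite.
    The whole run is reproducible from ``cfg.seed``.
    """
    cfg = cfg or SwarmConfig()
    candidate_genes = list(candidate_genes)
    D = len(candidate_genes)
    if D == 0:
        raise ValueError("Stage 1 returned no candidates; lower delta")
    if fitness_fn is None:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != D:
            raise ValueError("X column count must equal the candidate count")

    rng = np.random.default_rng(cfg.seed)
    positions = rng.uniform(0.0, 1.0, size=(cfg.n_particles, D))
    velocities = rng.uniform(-cfg.v_max / 2.0, cfg.v_max / 2.0, size=(cfg.n_particles, D))

    cache: dict[bytes, FitnessValue] = {}

    def fitness_of(mask: np.ndarray) -> FitnessValue:
        key = mask.tobytes()
        if key not in cache:
            if fitness_fn is not None:
                comp = float(fitness_fn(mask))
                cache[key] = FitnessValue(
                    accuracy=float("nan"), mse=float("nan"),
                    subset_size=int(mask.sum()), composite=comp,
                )
            else:
                cache[key] = evaluate_fitness(
                    mask, X, y, mlp_config=mlp_config, cv=cv,
                    lambda_mse=lambda_mse, lambda_size=lambda_size, seed=cfg.seed,
                )
        return cache[key]

    pbest_pos = positions.copy()
    pbest_fit = [fitness_of(decode_subset(positions[i], cfg.decode_threshold))
                 for i in range(cfg.n_particles)]
    g_idx = int(np.argmax([f.composite for f in pbest_fit]))
    gbest_pos = pbest_pos[g_idx].copy()
    gbest_fit = pbest_fit[g_idx]
    history = [gbest_fit.composite]
    detail = [gbest_fit]

    for _ in range(cfg.n_iterations):
        for i in range(cfg.n_particles):
            v = update_velocity(
                velocities[i], positions[i], pbest_pos[i], gbest_pos, cfg, rng
            )
            if cfg.turbulence > 0.0:
                turb = rng.uniform(0.0, 1.0, size=D) < cfg.turbulence
                if turb.any():
                    v[turb] = rng.uniform(-cfg.v_max, cfg.v_max, size=int(turb.sum()))
            velocities[i] = v
            positions[i] = update_position(positions[i], velocities[i])
            fit = fitness_of(decode_subset(positions[i], cfg.decode_threshold))
            if fit.composite > pbest_fit[i].composite:
                pbest_fit[i] = fit
                pbest_pos[i] = positions[i].copy()
                if fit.composite > gbest_fit.composite:
                    gbest_fit = fit
                    gbest_pos = positions[i].copy()
        history.append(gbest_fit.composite)
        detail.append(gbest_fit)

    final_mask = decode_subset(gbest_pos, cfg.decode_threshold)
    selected = [g for g, m in zip(candidate_genes, final_mask) if m]
    return SelectionResult(
        selected_genes=selected,
        selected_mask=final_mask,
        gbest_fitness=gbest_fit,
        gbest_fitness_history=history,
        gbest_detail_history=detail,
        candidate_genes=candidate_genes,
        config=cfg,
    )


class PSOMLPSelector(SelectorMixin, BaseEstimator):
    """Particle-swarm subset selector with an MLP cross-validation fitness.

    Treats every column of the fitted X as one candidate gene (run it on the
    output of :class:`~genesift.fcbf.FCBFSelector` for the full two-stage
    algorithm).

    Attributes
    ----------
    result_ : SelectionResult with the gbest subset and fitness history.
    support_ : boolean mask over the candidate columns.
    """

    def __init__(
        self,
        n_particles: int = 30,
        n_iterations: int = 100,
        omega: float = 0.7,
        c1: float = 2.0,
        c2: float = 2.0,
        v_max: float = 0.6,
        decode_threshold: float = 0.5,
        turbulence: float = 0.05,
        cv: int = 5,
        lambda_mse: float = 0.1,
        lambda_size: float = 0.05,
        mlp_config: dict | None = None,
        fitness_fn=None,
        random_state=None,
    ):
        self.n_particles = n_particles
        self.n_iterations = n_iterations
        self.omega = omega
        self.c1 = c1
        self.c2 = c2
        self.v_max = v_max
        self.decode_threshold = decode_threshold
        self.turbulence = turbulence
        self.cv = cv
        self.lambda_mse = lambda_mse
        self.lambda_size = lambda_size
        self.mlp_config = mlp_config
        self.fitness_fn = fitness_fn
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        cfg = SwarmConfig(
            n_particles=self.n_particles,
            n_iterations=self.n_iterations,
            omega=self.omega,
            c1=self.c1,
            c2=self.c2,
            v_max=self.v_max,
            decode_threshold=self.decode_threshold,
            turbulence=self.turbulence,
            seed=self.random_state,
        )
        genes = list(range(X.shape[1]))
        self.result_ = pso_search(
            genes, X, y, cfg=cfg, mlp_config=self.mlp_config, cv=self.cv,
            lambda_mse=self.lambda_mse, lambda_size=self.lambda_size,
            fitness_fn=self.fitness_fn,
        )
        self.support_ = self.result_.selected_mask.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
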