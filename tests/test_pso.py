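"""Particle-swarm subset search: update rules, decoding, fitness, search."""

import numpy as np
import pytest

import genesift as gs
from genesift.pso import (
    PSOMLPSelector,
    SwarmConfig,
    decode_subset,
    evaluate_fitness,
    pso_search,
    update_position,
    update_velocity,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def test_velocity_identity_when_attraction_vanishes(rng):
    cfg = SwarmConfig(omega=1.0, c1=0.0, c2=0.0, v_max=10.0)
    v = np.array([0.2, -0.3, 0.1])
    out = update_velocity(v, np.zeros(3), np.ones(3), np.ones(3), cfg, rng)
    assert np.allclose(out, v)


def test_velocity_reduces_to_inertia_at_converged_point(rng):
    cfg = SwarmConfig(omega=0.5, v_max=10.0)
    x = np.array([0.4, 0.6])
    v = np.array([0.2, -0.2])
    out = update_velocity(v, x, x, x, cfg, rng)
    assert np.allclose(out, 0.5 * v)


def test_velocity_always_clamped(rng):
    cfg = SwarmConfig(v_max=0.3)
    for _ in range(50):
        v = rng.normal(size=5)
        out = update_velocity(
            v, rng.uniform(0, 1, 5), rng.uniform(0, 1, 5), rng.uniform(0, 1, 5), cfg, rng
        )
        assert np.all(np.abs(out) <= cfg.v_max + 1e-15)


def test_velocity_shape_mismatch(rng):
    cfg = SwarmConfig()
    with pytest.raises(ValueError):
        update_velocity(np.zeros(3), np.zeros(2), np.zeros(3), np.zeros(3), cfg, rng)


@pytest.mark.parametrize(
    "x, v, expected",
    [
        ([0.3, 0.7], [0.0, 0.0], [0.3, 0.7]),
        ([0.9], [0.5], [1.0]),
        ([0.3], [-0.1], [0.2]),
    ],
)
def test_position_update(x, v, expected):
    assert np.allclose(update_position(x, v), expected)


def test_decode_rule_and_repair():
    assert list(decode_subset([0.9, 0.2, 0.5], 0.5)) == [True, False, True]
    assert list(decode_subset([0.1, 0.4], 0.5)) == [False, True]  # argmax repair
    assert decode_subset([0.6, 0.9, 0.75], 0.5).all()


def test_fitness_on_label_copy_gene():
    """A gene equal to the label gives perfect CV accuracy and ~0 MSE."""
    rng = np.random.default_rng(2)
    y = np.r_[np.zeros(30, int), np.ones(30, int)]
    X = np.column_stack([y.astype(float), rng.normal(size=60)])
    fit = evaluate_fitness([True, False], X, y, cv=5, seed=0)
    assert fit.accuracy == 1.0
    assert fit.mse < 0.1  # probabilities near but not at 0/1 after finite training
    assert fit.composite == pytest.approx(
        fit.accuracy - 0.1 * fit.mse - 0.05 * (1 / 2), abs=1e-12
    )


def test_fitness_null_accuracy_near_chance():
    rng = np.random.default_rng(3)
    y = np.r_[np.zeros(200, int), np.ones(200, int)]
    X = rng.normal(size=(400, 3))
    fit = evaluate_fitness([True, True, True], X, y, cv=5, seed=1)
    assert abs(fit.accuracy - 0.5) < 0.12  # ~4.8 binomial SDs at n=400


def test_size_penalty_orders_equal_performance_subsets():
    f_small = gs.FitnessValue(0.9, 0.1, 2, 0.9 - 0.01 - 0.05 * 2 / 10)
    f_large = gs.FitnessValue(0.9, 0.1, 5, 0.9 - 0.01 - 0.05 * 5 / 10)
    assert f_small.composite > f_large.composite


def test_fitness_validation():
    X = np.zeros((10, 2))
    y = np.r_[np.zeros(5, int), np.ones(5, int)]
    with pytest.raises(ValueError, match="mask length"):
        evaluate_fitness([True], X, y)
    with pytest.raises(ValueError, match="empty subset"):
        evaluate_fitness([False, False], X, y)


def _planted_problem(seed):
    rng = np.random.default_rng(1000 + seed)
    target = rng.integers(0, 2, size=10).astype(bool)
    if not target.any():
        target[0] = True
    return target, lambda m: float((m == target).sum())


def test_injected_fitness_recovers_planted_masks():
    for s in range(5):
        target, fn = _planted_problem(s)
        res = pso_search(
            list(range(10)), None, None,
            cfg=SwarmConfig(n_particles=20, n_iterations=50, seed=s),
            fitness_fn=fn,
        )
        assert np.array_equal(res.selected_mask, target)


def test_zero_iterations_history_length_one():
    target, fn = _planted_problem(0)
    res = pso_search(
        list(range(10)), None, None,
        cfg=SwarmConfig(n_particles=10, n_iterations=0, seed=1),
        fitness_fn=fn,
    )
    assert len(res.gbest_fitness_history) == 1


def test_search_seed_determinism():
    target, fn = _planted_problem(3)
    cfg = SwarmConfig(n_particles=15, n_iterations=20, seed=9)
    a = pso_search(list(range(10)), None, None, cfg=cfg, fitness_fn=fn)
    b = pso_search(list(range(10)), None, None, cfg=cfg, fitness_fn=fn)
    assert np.array_equal(a.selected_mask, b.selected_mask)
    assert a.gbest_fitness_history == b.gbest_fitness_history


def test_gbest_history_non_decreasing():
    for s in range(5):
        _, fn = _planted_problem(s)
        res = pso_search(
            list(range(10)), None, None,
            cfg=SwarmConfig(n_particles=10, n_iterations=30, seed=s),
            fitness_fn=fn,
        )
        hist = res.gbest_fitness_history
        assert all(b >= a for a, b in zip(hist, hist[1:]))


def test_velocity_decays_without_attraction():
    """With c1 = c2 = 0, omega < 1 and no turbulence, speed decays to ~0."""
    cfg = SwarmConfig(omega=0.6, c1=0.0, c2=0.0, v_max=1.0, turbulence=0.0)
    rng = np.random.default_rng(0)
    v = np.array([0.8, -0.5, 0.3])
    x = np.full(3, 0.5)
    for _ in range(60):
        v = update_velocity(v, x, x, x, cfg, rng)
    assert np.all(np.abs(v) < 1e-12)


def test_empty_candidate_set_rejected():
    with pytest.raises(ValueError, match="no candidates"):
        pso_search([], None, None, fitness_fn=lambda m: 0.0)


def test_selector_estimator_contract():
    rng = np.random.default_rng(4)
    y = np.r_[np.zeros(25, int), np.ones(25, int)]
    X = np.column_stack([y + 0.1 * rng.normal(size=50), rng.normal(size=(50, 3))])
    sel = PSOMLPSelector(
        n_particles=8, n_iterations=10, mlp_config={"epochs": 100}, random_state=0
    ).fit(X, y)
    assert sel.support_.any()
    assert sel.support_[0]  # the informative column must be kept
    assert sel.transform(X).shape[1] == sel.support_.sum()
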