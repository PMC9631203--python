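"""Entropy, conditional entropy, symmetrical uncertainty and discretization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genesift.infotheory import (
    conditional_entropy,
    discretize,
    entropy,
    symmetrical_uncertainty,
)
from oracle_utils import oracle_conditional_entropy, oracle_entropy, oracle_su

discrete_vec = st.lists(st.integers(0, 2), min_size=1, max_size=12)


@pytest.mark.parametrize(
    "x, expected",
    [
        ([0, 0, 1, 1], 1.0),
        ([1, 1, 1, 1], 0.0),
        ([0, 0, 1], 0.918296),
    ],
)
def test_entropy_known_values(x, expected):
    assert entropy(x) == pytest.approx(expected, abs=1e-6)


def test_entropy_rejects_empty():
    with pytest.raises(ValueError):
        entropy([])


def test_entropy_bounded_by_log_alphabet():
    rng = np.random.default_rng(0)
    for _ in range(50):
        x = rng.integers(0, 4, size=rng.integers(1, 30))
        assert entropy(x) <= np.log2(len(np.unique(x))) + 1e-12


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([0, 1, 2, 0, 1], [0, 1, 2, 0, 1], 0.0),  # self-conditioning
        ([0, 0, 1, 1], [0, 1, 0, 1], 1.0),  # empirically independent
        ([0, 0, 1, 1], [0, 0, 0, 1], 0.688722),
    ],
)
def test_conditional_entropy_known_values(x, y, expected):
    assert conditional_entropy(x, y) == pytest.approx(expected, abs=1e-6)


def test_conditional_entropy_length_mismatch():
    with pytest.raises(ValueError, match="length mismatch"):
        conditional_entropy([0, 1], [0, 1, 1])


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([0, 1, 0, 1, 1], [0, 1, 0, 1, 1], 1.0),  # identity
        ([0, 0, 1, 1], [0, 1, 0, 1], 0.0),  # independence
        ([0, 0, 1, 1], [0, 0, 0, 1], 0.343712),
    ],
)
def test_su_known_values(x, y, expected):
    assert symmetrical_uncertainty(x, y) == pytest.approx(expected, abs=1e-6)


def test_su_constant_conventions():
    assert symmetrical_uncertainty([3, 3, 3], [3, 3, 3]) == 0.0
    assert symmetrical_uncertainty([3, 3, 3], [0, 1, 0]) == 0.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(discrete_vec, discrete_vec)
def test_su_bounds_symmetry_and_chain(x, y):
    """SU in [0,1], symmetric; H(x|y) <= H(x)."""
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    su = symmetrical_uncertainty(x, y)
    assert 0.0 <= su <= 1.0
    assert su == pytest.approx(symmetrical_uncertainty(y, x), abs=1e-12)
    assert conditional_entropy(x, y) <= entropy(x) + 1e-12


@settings(max_examples=100, deadline=None, derandomize=True)
@given(discrete_vec, st.randoms(use_true_random=False))
def test_su_invariant_to_relabeling(x, rnd):
    labels = list(set(x))
    perm = labels[:]
    rnd.shuffle(perm)
    relabel = dict(zip(labels, perm))
    y = [xi % 2 for xi in range(len(x))]
    su1 = symmetrical_uncertainty(x, y)
    su2 = symmetrical_uncertainty([relabel[v] for v in x], y)
    assert su1 == pytest.approx(su2, abs=1e-12)


def test_against_brute_force_oracle_small_vectors():
    """Plug-in estimates match an explicit joint-table oracle."""
    rng = np.random.default_rng(3)
    for _ in range(300):
        n = rng.integers(1, 7)
        x = rng.integers(0, 3, size=n)
        y = rng.integers(0, 3, size=n)
        assert entropy(x) == pytest.approx(oracle_entropy(tuple(x)), abs=1e-12)
        assert conditional_entropy(x, y) == pytest.approx(
            oracle_conditional_entropy(tuple(x), tuple(y)), abs=1e-12
        )
        assert symmetrical_uncertainty(x, y) == pytest.approx(
            oracle_su(tuple(x), tuple(y)), abs=1e-12
        )


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


def test_equal_frequency_median_split():
    d = discretize(np.array([[1.0], [2.0], [3.0], [4.0]]), method="equal_frequency", n_bins=2)
    assert list(d.codes[:, 0]) == [0, 0, 1, 1]
    assert d.n_bins[0] == 2


@pytest.mark.parametrize("method", ["mdl", "equal_frequency", "equal_width"])
def test_constant_gene_single_bin(method):
    d = discretize(
        np.array([[5.0], [5.0], [5.0], [5.0]]), labels=[0, 0, 1, 1], method=method, n_bins=4
    )
    assert d.n_bins[0] == 1
    assert list(d.codes[:, 0]) == [0, 0, 0, 0]
    assert d.bin_edges[0].size == 0


def test_mdl_accepts_perfectly_separating_cut():
    d = discretize(
        np.array([[1.0], [1.0], [2.0], [2.0]]), labels=[0, 0, 1, 1], method="mdl"
    )
    assert d.n_bins[0] == 2  # exactly one accepted cut
    assert list(d.codes[:, 0]) == [0, 0, 1, 1]


def test_mdl_rejects_uninformative_cut():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 1))
    y = rng.integers(0, 2, size=40)
    d = discretize(X, labels=y, method="mdl")
    assert d.n_bins[0] == 1  # label-independent gene collapses


def test_codes_within_bin_range():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(50, 8))
    y = rng.integers(0, 2, size=50)
    for method in ("mdl", "equal_frequency", "equal_width"):
        d = discretize(X, labels=y, method=method, n_bins=5)
        for j in range(8):
            assert d.codes[:, j].min() >= 0
            assert d.codes[:, j].max() < d.n_bins[j]


def test_discretize_determinism():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(30, 5))
    y = rng.integers(0, 2, size=30)
    a = discretize(X, labels=y, method="mdl")
    b = discretize(X.copy(), labels=y.copy(), method="mdl")
    assert np.array_equal(a.codes, b.codes)
    assert np.array_equal(a.n_bins, b.n_bins)


def test_discretize_input_validation():
    with pytest.raises(ValueError, match="gene column 1"):
        discretize(np.array([[1.0, np.nan], [2.0, 3.0]]), method="equal_width", n_bins=2)
    with pytest.raises(ValueError, match="n_bins"):
        discretize(np.array([[1.0], [2.0]]), method="equal_frequency", n_bins=1)
    with pytest.raises(ValueError, match="labels"):
        discretize(np.array([[1.0], [2.0]]), method="mdl")
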