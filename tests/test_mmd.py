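"""Multi-kernel Gaussian MMD: kernel, bank, estimator, oracle, loss."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegtransfer import (KernelBank, MMDConfig, ParameterError,
                         build_kernel_bank, empirical_mmd2, gaussian_kernel,
                         mmd2_oracle, mmd_loss)
from eegtransfer.autograd import Tensor

RNG = np.random.default_rng(2024)
DEFAULT_BANK = build_kernel_bank(MMDConfig())


def random_instance(rng):
    m, n = rng.integers(1, 21, size=2)
    dim = rng.integers(1, 9)
    X = rng.normal(scale=rng.uniform(0.5, 3.0), size=(m, dim))
    Y = rng.normal(loc=rng.uniform(-1, 1), size=(n, dim))
    cfg = MMDConfig(kernel_num=int(rng.integers(1, 6)),
                    kernel_width=float(rng.uniform(0.3, 4.0)))
    return X, Y, build_kernel_bank(cfg)


# ----------------------------------------------------------- gaussian kernel

def test_kernel_at_zero_distance_is_one():
    x = RNG.normal(size=5)
    assert gaussian_kernel(x, x, sigma=0.7) == 1.0


def test_kernel_closed_form():
    assert math.isclose(gaussian_kernel([0.0], [1.0], 1.0),
                        math.exp(-0.5), rel_tol=1e-12)


def test_kernel_wide_limit():
    assert abs(gaussian_kernel([0.0], [1.0], 1e6) - 1.0) < 1e-9


def test_kernel_validation():
    with pytest.raises(ParameterError):
        gaussian_kernel([0.0], [1.0], 0.0)
    with pytest.raises(ParameterError):
        gaussian_kernel([0.0], [1.0, 2.0], 1.0)


def test_kernel_symmetry():
    x, y = RNG.normal(size=4), RNG.normal(size=4)
    assert gaussian_kernel(x, y, 1.3) == gaussian_kernel(y, x, 1.3)


# -------------------------------------------------------------- kernel bank

def test_bank_single_kernel():
    bank = build_kernel_bank(MMDConfig(kernel_num=1, kernel_width=2.0))
    assert bank.widths == (2.0,) and bank.weights == (1.0,)


def test_bank_default_ladder():
    bank = build_kernel_bank(MMDConfig(kernel_num=5, kernel_width=2.0,
                                       ladder_factor=2.0))
    np.testing.assert_allclose(bank.widths, [0.5, 1.0, 2.0, 4.0, 8.0])
    np.testing.assert_allclose(bank.weights, [0.2] * 5)


@given(num=st.integers(1, 9), width=st.floats(0.1, 10.0),
       factor=st.floats(1.1, 4.0))
@settings(max_examples=50, derandomize=True)
def test_bank_weights_always_convex(num, width, factor):
    bank = build_kernel_bank(MMDConfig(kernel_num=num, kernel_width=width,
                                       ladder_factor=factor))
    assert abs(sum(bank.weights) - 1.0) <= 1e-12
    assert all(w > 0 for w in bank.widths)


def test_bank_validation():
    with pytest.raises(ParameterError):
        KernelBank((1.0, 2.0), (0.6, 0.6))      # weights don't sum to 1
    with pytest.raises(ParameterError):
        KernelBank((-1.0,), (1.0,))
    with pytest.raises(ParameterError):
        MMDConfig(kernel_num=0)


# ---------------------------------------------------------- empirical MMD²

def test_identical_multisets_give_zero():
    X = RNG.normal(size=(7, 3))
    assert abs(empirical_mmd2(X, X.copy(), DEFAULT_BANK)) < 1e-12


def test_single_point_closed_form():
    bank = build_kernel_bank(MMDConfig(kernel_num=1, kernel_width=1.0))
    val = empirical_mmd2([[0.0]], [[1.0]], bank)
    assert math.isclose(val, 2 - 2 * math.exp(-0.5), rel_tol=1e-12)


def test_permutation_invariance_and_symmetry():
    X, Y, bank = random_instance(np.random.default_rng(5))
    v = empirical_mmd2(X, Y, bank)
    perm = np.random.default_rng(6).permutation(len(X))
    assert empirical_mmd2(X[perm], Y, bank) == pytest.approx(v, abs=1e-12)
    assert empirical_mmd2(Y, X, bank) == pytest.approx(v, abs=1e-12)


def test_biased_estimator_nonnegative():
    rng = np.random.default_rng(8)
    for _ in range(20):
        X, Y, bank = random_instance(rng)
        assert empirical_mmd2(X, Y, bank) >= -1e-14


def test_single_kernel_bank_equals_direct_kernel_computation():
    """Convexity degenerate case: a 1-kernel bank must equal the plain
    Gaussian-kernel expansion."""
    rng = np.random.default_rng(9)
    X, Y = rng.normal(size=(4, 2)), rng.normal(size=(5, 2))
    sigma = 1.7
    bank = KernelBank((sigma,), (1.0,))
    M, N = len(X), len(Y)
    direct = (
        sum(gaussian_kernel(a, b, sigma) for a in X for b in X) / M ** 2
        + sum(gaussian_kernel(a, b, sigma) for a in Y for b in Y) / N ** 2
        - 2 * sum(gaussian_kernel(a, b, sigma) for a in X for b in Y) / (M * N))
    assert empirical_mmd2(X, Y, bank) == pytest.approx(direct, abs=1e-12)


def test_mmd_decreases_as_samples_converge():
    """Replacing Y by copies of X point-by-point drives MMD² to 0,
    non-increasingly."""
    rng = np.random.default_rng(10)
    X = rng.normal(size=(6, 3))
    Y = rng.normal(loc=3.0, size=(6, 3))
    vals = []
    for k in range(7):
        Yk = np.vstack([X[:k], Y[k:]])
        vals.append(empirical_mmd2(X, Yk, DEFAULT_BANK))
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
    assert vals[-1] < 1e-12


def test_estimator_validation():
    with pytest.raises(ParameterError):
        empirical_mmd2(np.empty((0, 2)), np.ones((3, 2)), DEFAULT_BANK)
    with pytest.raises(ParameterError):
        empirical_mmd2(np.ones((3, 2)), np.ones((3, 4)), DEFAULT_BANK)


def test_unbiased_option():
    rng = np.random.default_rng(11)
    X, Y = rng.normal(size=(8, 2)), rng.normal(size=(9, 2))
    biased = empirical_mmd2(X, Y, DEFAULT_BANK)
    unbiased = empirical_mmd2(X, Y, DEFAULT_BANK, unbiased=True)
    assert biased != unbiased                 # diagonal terms differ
    with pytest.raises(ParameterError):
        empirical_mmd2(X[:1], Y, DEFAULT_BANK, unbiased=True)


# ------------------------------------------------------------------- oracle

def test_estimator_agrees_with_bruteforce_oracle():
    rng = np.random.default_rng(123)
    for _ in range(50):
        X, Y, bank = random_instance(rng)
        assert abs(empirical_mmd2(X, Y, bank)
                   - mmd2_oracle(X, Y, bank)) < 1e-10


def test_oracle_identical_sets_and_closed_form():
    X = RNG.normal(size=(5, 2))
    assert abs(mmd2_oracle(X, X.copy(), DEFAULT_BANK)) < 1e-12
    bank = KernelBank((1.0,), (1.0,))
    assert mmd2_oracle([[0.0]], [[1.0]], bank) == pytest.approx(
        2 - 2 * math.exp(-0.5), abs=1e-12)


# --------------------------------------------------------------------- loss

def test_loss_zero_for_identical_batches_with_finite_gradient():
    X = RNG.normal(size=(6, 4))
    xs = Tensor(X, requires_grad=True)
    ys = Tensor(X.copy(), requires_grad=True)
    loss = mmd_loss(xs, ys)
    assert abs(loss.item()) < 1e-12
    loss.backward()
    assert np.isfinite(xs.grad).all() and np.isfinite(ys.grad).all()


def test_loss_matches_empirical_value():
    rng = np.random.default_rng(13)
    X, Y = rng.normal(size=(7, 5)), rng.normal(loc=1.0, size=(9, 5))
    cfg = MMDConfig()
    loss = mmd_loss(Tensor(X, requires_grad=True), Tensor(Y))
    assert abs(loss.item()
               - empirical_mmd2(X, Y, build_kernel_bank(cfg))) < 1e-6


def test_loss_grows_with_mean_gap():
    """Monte-Carlo monotonicity: a mean gap of 3 yields a larger loss than a
    gap of 0, on average over 10 seeds."""
    gaps = {0.0: [], 3.0: []}
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 4))
        for gap in gaps:
            Y = rng.normal(loc=gap, size=(10, 4))
            gaps[gap].append(mmd_loss(Tensor(X), Tensor(Y)).item())
    assert np.mean(gaps[3.0]) > np.mean(gaps[0.0])


def test_loss_gradient_descends_toward_alignment():
    """A few gradient steps on the features must reduce the loss."""
    rng = np.random.default_rng(14)
    X = Tensor(rng.normal(loc=2.0, size=(8, 3)), requires_grad=True)
    Y = Tensor(rng.normal(size=(8, 3)))
    start = mmd_loss(X, Y).item()
    for _ in range(20):
        loss = mmd_loss(X, Y)
        X.zero_grad()
        loss.backward()
        X.data -= 0.5 * X.grad
    assert mmd_loss(X, Y).item() < start
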