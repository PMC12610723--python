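"""Multi-kernel Gaussian Maximum Mean Discrepancy (MMD).

MMD measures the distance between two distributions as the RKHS norm of the
gap between their kernel mean embeddings.  With the kernel trick the biased
(V-statistic) empirical estimator on samples X = {x_i}_1^M, Y = {y_j}_1^N is

    MMD²(X, Y) = (1/M²) Σ_ij k(x_i, x_j) + (1/N²) Σ_ij k(y_i, y_j)
               − (2/MN) Σ_ij k(x_i, y_j),

where k is a convex combination of L Gaussian base kernels
k_l(x, y) = exp(−‖x−y‖² / (2σ_l²)), with weights β_l ≥ 0, Σβ_l = 1.  The
widths form a geometric ladder centred on a base width (multi-kernel MMD
practice); the weights stay fixed at 1/L.  Used here purely as a training
loss that aligns source- and target-domain feature distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .eeg_core import ParameterError

__all__ = ["KernelBank", "MMDConfig", "gaussian_kernel", "build_kernel_bank",
           "empirical_mmd2", "mmd2_oracle", "mmd_loss"]


@dataclass(frozen=True)
class KernelBank:
    """L Gaussian widths σ_l with convex weights β_l."""

    widths: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.widths) != len(self.weights):
            raise ParameterError("widths and weights must have equal length")
        if any(w <= 0 for w in self.widths):
            raise ParameterError("all kernel widths must be positive")
        if any(b < 0 for b in self.weights):
            raise ParameterError("kernel weights must be nonnegative")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ParameterError("kernel weights must sum to 1")

    @property
    def L(self) -> int:
        return len(self.widths)


@dataclass(frozen=True)
class MMDConfig:
    """Kernel-family hyperparameters (defaults follow the grid-search optimum)."""

    kernel_num: int = 5
    kernel_width: float = 2.0
    ladder_factor: float = 2.0
    unbiased: bool = False

    def __post_init__(self):
        if self.kernel_num < 1:
            raise ParameterError("kernel_num must be >= 1")
        if not self.kernel_width > 0:
            raise ParameterError("kernel_width must be positive")


def gaussian_kernel(x, y, sigma: float) -> float:
    """Gaussian base kernel k(x, y) = exp(−‖x−y‖² / (2σ²))."""
    if not sigma > 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError(f"dimension mismatch: {x.shape} vs {y.shape}")
    d2 = float(np.sum((x - y) ** 2))
    return math.exp(-d2 / (2.0 * sigma * sigma))


def build_kernel_bank(cfg: MMDConfig) -> KernelBank:
    """Geometric width ladder centred on ``kernel_width``, equal weights.

    σ_l = kernel_width · ladder_factor^(l − (L−1)/2) for l = 0..L−1, so for
    the defaults (L=5, width 2, factor 2) the widths are 0.5, 1, 2, 4, 8.
    """
    L = cfg.kernel_num
    widths = tuple(cfg.kernel_width * cfg.ladder_factor ** (l - (L - 1) / 2.0)
                   for l in range(L))
    return KernelBank(widths, tuple(1.0 / L for _ in range(L)))


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] == 0:
        raise ParameterError("need a nonempty 2-D sample set (n, dim)")
    return X


def _combined_gram(D2: np.ndarray, bank: KernelBank) -> np.ndarray:
    G = np.zeros_like(D2)
    for sigma, beta in zip(bank.widths, bank.weights):
        G += beta * np.exp(-D2 / (2.0 * sigma * sigma))
    return G


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    aa = (A * A).sum(axis=1)[:, None]
    bb = (B * B).sum(axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * A @ B.T, 0.0)


def empirical_mmd2(X, Y, bank: KernelBank, unbiased: bool = False) -> float:
    """Empirical MMD² between sample sets X (M, d) and Y (N, d).

    Default is the biased V-statistic (the squared mean-embedding gap); with
    ``unbiased=True`` the diagonal terms are excluded (U-statistic), which
    requires M, N ≥ 2 and can be negative.
    """
    X, Y = _as_2d(X), _as_2d(Y)
    if X.shape[1] != Y.shape[1]:
        raise ParameterError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    M, N = X.shape[0], Y.shape[0]
    Kxx = _combined_gram(_sq_dists(X, X), bank)
    Kyy = _combined_gram(_sq_dists(Y, Y), bank)
    Kxy = _combined_gram(_sq_dists(X, Y), bank)
    if unbiased:
        if M < 2 or N < 2:
            raise ParameterError("unbiased estimator needs M, N >= 2")
        term_x = (Kxx.sum() - np.trace(Kxx)) / (M * (M - 1))
        term_y = (Kyy.sum() - np.trace(Kyy)) / (N * (N - 1))
    else:
        term_x = Kxx.sum() / (M * M)
        term_y = Kyy.sum() / (N * N)
    return float(term_x + term_y - 2.0 * Kxy.sum() / (M * N))


def mmd2_oracle(X, Y, bank: KernelBank) -> float:
    """Brute-force double-loop reference for :func:`empirical_mmd2`.

    Deliberately scalar, unvectorised and free of shared code with the fast
    path; used as the independent cross-check in tests.
    """
    X, Y = _as_2d(X), _as_2d(Y)
    if X.shape[1] != Y.shape[1]:
        raise ParameterError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    M, N = X.shape[0], Y.shape[0]
    sxx = 0.0
    for i in range(M):
        for j in range(M):
            for sigma, beta in zip(bank.widths, bank.weights):
                sxx += beta * gaussian_kernel(X[i], X[j], sigma)
    syy = 0.0
    for i in range(N):
        for j in range(N):
            for sigma, beta in zip(bank.widths, bank.weights):
                syy += beta * gaussian_kernel(Y[i], Y[j], sigma)
    sxy = 0.0
    for i in range(M):
        for j in range(N):
            for sigma, beta in zip(bank.widths, bank.weights):
                sxy += beta * gaussian_kernel(X[i], Y[j], sigma)
    return sxx / (M * M) + syy / (N * N) - 2.0 * sxy / (M * N)


def mmd_loss(source_features: Tensor, target_features: Tensor,
             cfg: MMDConfig = MMDConfig()) -> Tensor:
    """Differentiable biased MMD² on autograd feature batches.

    Equals :func:`empirical_mmd2` on the detached values; its gradient with
    respect to both feature batches exists and is finite, so it can join a
    gradient-based training objective.
    """
    if not isinstance(source_features, Tensor):
        source_features = Tensor(source_features)
    if not isinstance(target_features, Tensor):
        target_features = Tensor(target_features)
    if source_features.shape[0] == 0 or target_features.shape[0] == 0:
        raise ParameterError("feature batches must be nonempty")
    if source_features.shape[1] != target_features.shape[1]:
        raise ParameterError("feature dimension mismatch")
    bank = build_kernel_bank(cfg)
    M, N = source_features.shape[0], target_features.shape[0]

    def sq_dists(A: Tensor, B: Tensor) -> Tensor:
        aa = (A * A).sum(axis=1, keepdims=True)          # (m, 1)
        bb = (B * B).sum(axis=1, keepdims=True).transpose(1, 0)  # (1, n)
        return aa + bb - 2.0 * (A @ B.transpose(1, 0))

    def gram(D2: Tensor) -> Tensor:
        parts = None
        for sigma, beta in zip(bank.widths, bank.weights):
            term = (D2 * (-1.0 / (2.0 * sigma * sigma))).exp() * beta
            parts = term if parts is None else parts + term
        return parts

    kxx = gram(sq_dists(source_features, source_features)).sum() * (1.0 / (M * M))
    kyy = gram(sq_dists(target_features, target_features)).sum() * (1.0 / (N * N))
    kxy = gram(sq_dists(source_features, target_features)).sum() * (2.0 / (M * N))
    return kxx + kyy - kxy
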