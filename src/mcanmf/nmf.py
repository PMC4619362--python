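"""Nonnegative matrix factorization under the generalized KL (I-)divergence.

The factorization V ≈ W·H is fitted with Lee–Seung multiplicative updates,
which keep both factors entrywise nonnegative and monotonically non-increase
the I-divergence

    D_I(A‖B) = Σ_ij ( A_ij·ln(A_ij / B_ij) − A_ij + B_ij ),

with the convention 0·ln(0/b) = 0.  Columns of V are sample histograms,
columns of W are learned components, and columns of H are the per-sample
coefficient (internal-representation) vectors.

``infer_coefficients`` solves the coefficient-only problem
argmin_h D_I(v‖W·h) for a frozen dictionary W by iterating only the H update;
this is what enables coding an observation from a subset of modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FitConfig",
    "i_divergence",
    "update_h",
    "update_w",
    "fit",
    "infer_coefficients",
]


@dataclass(frozen=True)
class FitConfig:
    """Hyper-parameters of a factorization run.

    Parameters
    ----------
    k : int
        Number of dictionary components (factorization rank).
    max_iter : int
        Iteration budget; each iteration is one H update followed by one
        W update.  Ten iterations are typically close to convergence; the
        default of 50 is conservative.
    tol : float
        Relative change of the loss below which the run stops early.
    eps : float
        Positivity floor applied to denominators (and to the reconstruction
        inside logs) to keep the multiplicative updates finite.
    seed : int
        Seed of the uniform-positive random initialization.
    """

    k: int = 50
    max_iter: int = 50
    tol: float = 1e-6
    eps: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


def _as_nonneg(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    if (a < 0).any():
        raise ValueError(f"{name} contains negative entries")
    return a


def i_divergence(a, b) -> float:
    """Generalized Kullback-Leibler (I-)divergence between two arrays.

    Returns ``+inf`` when some A_ij > 0 has B_ij = 0; uses 0·ln(0/b) = 0.
    Nonnegative, and zero iff the arrays are equal.
    """
    a = _as_nonneg(a, "A")
    b = _as_nonneg(b, "B")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    pos = a > 0
    if np.any(b[pos] == 0):
        return float("inf")
    av, bv = a[pos], b[pos]
    val = float(np.sum(av * np.log(av / bv)) - av.sum() + b.sum())
    # rounding can push the exact-match case a hair below zero
    return max(val, 0.0)


def _floored_divergence(v: np.ndarray, wh: np.ndarray, eps: float) -> float:
    """Loss used inside fitting: reconstruction floored at eps so the trace
    stays finite even when some component momentarily vanishes."""
    return i_divergence(v, np.maximum(wh, eps))


def update_h(v, w, h, eps: float = 1e-12) -> np.ndarray:
    """One multiplicative H update: H ⊛ (Wᵀ(V ⊘ WH)) ⊘ (Wᵀ·1)."""
    v = np.asarray(v, float)
    w = np.asarray(w, float)
    h = np.asarray(h, float)
    if eps <= 0 and np.any(w.sum(axis=0) == 0):
        raise ValueError("zero dictionary column with eps=0 makes the update undefined")
    ratio = v / np.maximum(w @ h, eps)
    denom = np.maximum(w.sum(axis=0), eps)
    return h * (w.T @ ratio) / denom[:, None]


def update_w(v, w, h, eps: float = 1e-12) -> np.ndarray:
    """One multiplicative W update: W ⊛ ((V ⊘ WH)Hᵀ) ⊘ (1·Hᵀ)."""
    v = np.asarray(v, float)
    w = np.asarray(w, float)
    h = np.asarray(h, float)
    if eps <= 0 and np.any(h.sum(axis=1) == 0):
        raise ValueError("zero coefficient row with eps=0 makes the update undefined")
    ratio = v / np.maximum(w @ h, eps)
    denom = np.maximum(h.sum(axis=1), eps)
    return w * (ratio @ h.T) / denom[None, :]


def fit(v, config: FitConfig) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Factorize ``v`` (d×n) into nonnegative W (d×k) and H (k×n).

    Both factors start from seeded entrywise Uniform(eps, 1) draws, so the
    run is reproducible given the seed.  Returns ``(W, H, loss_trace)`` where
    the trace holds the I-divergence before updating and after every
    iteration; it is non-increasing up to floating-point rounding.
    """
    v = _as_nonneg(v, "V")
    d, n = v.shape
    if config.k > min(d, n):
        warnings.warn(
            f"rank k={config.k} exceeds min(d, n)={min(d, n)}; the factorization "
            "is over-complete",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    w = rng.uniform(config.eps, 1.0, size=(d, config.k))
    h = rng.uniform(config.eps, 1.0, size=(config.k, n))

    loss = _floored_divergence(v, w @ h, config.eps)
    trace = [loss]
    for _ in range(config.max_iter):
        h = update_h(v, w, h, config.eps)
        w = update_w(v, w, h, config.eps)
        new_loss = _floored_divergence(v, w @ h, config.eps)
        if np.isnan(new_loss):
            raise FloatingPointError("NaN loss encountered during fitting")
        trace.append(new_loss)
        if loss > 0 and abs(loss - new_loss) / max(loss, config.eps) < config.tol:
            break
        loss = new_loss
    return w, h, trace


def infer_coefficients(v, w, config: FitConfig) -> np.ndarray:
    """Code observations against a frozen dictionary.

    Iterates only the H update to approximate argmin_h D_I(v‖W·h) for each
    column of ``v`` (d×m), returning a k×m coefficient matrix.  Deterministic
    given ``config.seed``.
    """
    v = _as_nonneg(v, "v")
    w = _as_nonneg(w, "W")
    if v.shape[0] != w.shape[0]:
        raise ValueError(
            f"observation dimension {v.shape[0]} does not match dictionary rows {w.shape[0]}"
        )
    k = w.shape[1]
    rng = np.random.default_rng(config.seed)
    h = rng.uniform(config.eps, 1.0, size=(k, v.shape[1]))
    loss = _floored_divergence(v, w @ h, config.eps)
    for _ in range(config.max_iter):
        h = update_h(v, w, h, config.eps)
        new_loss = _floored_divergence(v, w @ h, config.eps)
        if loss > 0 and abs(loss - new_loss) / max(loss, config.eps) < config.tol:
            break
        loss = new_loss
    return h
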