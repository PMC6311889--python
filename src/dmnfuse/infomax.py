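"""Infomax ICA with natural-gradient updates.

The unmixing matrix W of pre-whitened data Z (shape K x n_samples) is
estimated by stochastic natural-gradient ascent of the information-maximation
objective with the logistic nonlinearity g(u) = 1 / (1 + exp(-u)):

    W  <-  W + lr * (B*I + (1 - 2 g(U)) U^T) W,     U = W Z_block,

over randomly permuted sample blocks of size B.  The learning rate is
annealed by a fixed factor whenever successive weight updates oscillate
(angle above ``anneal_deg``), and the pass loop stops when the per-pass
weight change drops below ``tol``.  On numerical blow-up the estimate is
restarted with a smaller rate.  Plain (non-extended) Infomax: suited to
super-Gaussian sources.
"""

from __future__ import annotations

import warnings

import numpy as np

MAX_WEIGHT = 1e8


class InfomaxWarning(UserWarning):
    """Raised when the pass limit is reached before the tolerance."""


def infomax(
    Z: np.ndarray,
    rng: np.random.Generator,
    l_rate: float = 1e-3,
    max_iter: int = 512,
    tol: float = 1e-7,
    anneal_deg: float = 60.0,
    anneal_step: float = 0.9,
    block: int | None = None,
) -> tuple[np.ndarray, bool, int]:
    """Estimate the K x K unmixing matrix of whitened data Z (K x n).

    Returns ``(W, converged, n_iter)``.  Deterministic given ``rng``.
    """
    Z = np.ascontiguousarray(Z, dtype=float)
    k, n = Z.shape
    if n < k:
        raise ValueError(f"need at least {k} samples, got {n}")
    if block is None:
        # at least sqrt(n/3) samples per update, at most ~32 updates per pass
        block = int(min(max(np.floor(np.sqrt(n / 3.0)), n // 32, 8), n))

    # random orthonormal start, reproducible from rng
    W0 = np.linalg.qr(rng.standard_normal((k, k)))[0]
    W = W0.copy()
    eye = np.eye(k)
    lr = l_rate
    prev_delta = None
    converged = False
    n_iter = 0

    for it in range(max_iter):
        n_iter = it + 1
        Zp = np.ascontiguousarray(Z[:, rng.permutation(n)])
        W_prev = W.copy()
        blowup = False
        for start in range(0, n - block + 1, block):
            u = W @ Zp[:, start : start + block]
            y = 1.0 / (1.0 + np.exp(-u))
            W = W + lr * ((block * eye + (1.0 - 2.0 * y) @ u.T) @ W)
            if not np.isfinite(W).all() or np.abs(W).max() > MAX_WEIGHT:
                blowup = True
                break
        if blowup:
            lr *= 0.5
            W = W0.copy()
            prev_delta = None
            continue

        delta = W - W_prev
        change = np.linalg.norm(delta)
        if prev_delta is not None:
            prev_change = np.linalg.norm(prev_delta)
            oscillating = change > prev_change  # overshoot: step grew
            denom = prev_change * change
            if denom > 0:
                cos = float(np.sum(prev_delta * delta)) / denom
                cos = min(1.0, max(-1.0, cos))
                oscillating = oscillating or np.degrees(np.arccos(cos)) > anneal_deg
            if oscillating:
                lr *= anneal_step
        prev_delta = delta
        if change < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"Infomax did not reach tol={tol:g} within {max_iter} passes "
            f"(last weight change {np.linalg.norm(W - W_prev):.3g}); "
            "returning the final iterate",
            InfomaxWarning,
            stacklevel=2,
        )
    return W, converged, n_iter


def amari_index(W: np.ndarray, A: np.ndarray) -> float:
    """Amari permutation/scale-invariant error of unmixing W against mixing A.

    0 means W recovers inv(A) up to row permutation and scaling; normalized
    to [0, 1] by the 2*K*(K-1) worst case.
    """
    P = np.abs(W @ A)
    k = P.shape[0]
    rows = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    cols = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((rows + cols) / (2.0 * k * (k - 1)))
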