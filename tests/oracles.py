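"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: exhaustive active-set
enumeration for NNLS, pairwise concordance counting for AUC, and a
straight-line transcription of the regularized multiplicative updates.
"""

from itertools import combinations

import numpy as np


def brute_force_nnls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Global NNLS optimum by enumerating every zero-set (d <= ~10)."""
    d = A.shape[1]
    best_obj, best_x = np.inf, np.zeros(d)
    for k in range(d + 1):
        for zeros in combinations(range(d), k):
            free = [i for i in range(d) if i not in zeros]
            x = np.zeros(d)
            if free:
                sol, *_ = np.linalg.lstsq(A[:, free], b, rcond=None)
                x[np.array(free)] = sol
            if np.all(x >= -1e-12):
                obj = float(np.sum((A @ x - b) ** 2))
                if obj < best_obj - 1e-12:
                    best_obj, best_x = obj, np.clip(x, 0.0, None)
    return best_x


def pairwise_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney concordance over all (positive, negative) pairs; ties 1/2."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (pos.size * neg.size)


def pnmf_reference(V, W, H, alpha, beta, iters, eps=1e-12):
    """Straight-line regularized multiplicative updates, no shared helpers."""
    V = np.asarray(V, float)
    W = np.asarray(W, float).copy()
    H = np.asarray(H, float).copy()
    for _ in range(iters):
        num = V @ H.T
        den = W @ (H @ H.T) + alpha * W + eps
        W = W * num / den
        num = W.T @ V
        den = (W.T @ W) @ H + beta * H + eps
        H = H * num / den
    obj = np.sum((V - W @ H) ** 2) + alpha * np.sum(W**2) + beta * np.sum(H**2)
    return W, H, float(obj)
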