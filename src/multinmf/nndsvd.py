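"""Deterministic SVD-based initialization for NMF (nonnegative double SVD).

Random NMF starts land in different local minima run to run; initializing
from the nonnegative sections of the leading singular triplets gives a
deterministic start that already approximates the data, so all five solvers
in this package share it. The leading triplet is nonnegative outright
(Perron-Frobenius); each later rank-1 term sigma_j * u_j v_j^T is split into
its positive and negative sections and the section with the larger mass is
kept as that component's factor pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg


@dataclass
class InitPair:
    """Nonnegative starting factors (W0, H0) with the singular values used."""

    W0: np.ndarray
    H0: np.ndarray
    singular_values_used: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.W0 < 0) or np.any(self.H0 < 0):
            raise ValueError("initialization factors must be nonnegative")


def nndsvd(V, r: int, scale: str = "sqrt") -> InitPair:
    """Build nonnegative starting factors from the top ``r`` singular triplets.

    ``scale='sqrt'`` (default) distributes each component's weight as
    sqrt(sigma) on both factors so W0 @ H0 approximates V; ``scale='sigma'``
    places the full singular value on both factors (an alternative reading of
    the construction, kept for comparison).
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be 2-D")
    if np.any(V < 0):
        raise ValueError("V must be nonnegative")
    m, n = V.shape
    if not (1 <= r <= min(m, n)):
        raise ValueError(f"rank r={r} out of range [1, {min(m, n)}]")
    if scale not in ("sqrt", "sigma"):
        raise ValueError("scale must be 'sqrt' or 'sigma'")

    U, S, Vt = scipy.linalg.svd(V, full_matrices=False)
    W = np.zeros((m, r))
    H = np.zeros((r, n))

    # leading triplet: nonnegative up to a global sign flip
    u, v = U[:, 0], Vt[0]
    if u.sum() + v.sum() < 0:
        u, v = -u, -v
    u = np.clip(u, 0.0, None)  # remove tiny negative fp noise
    v = np.clip(v, 0.0, None)
    c = np.sqrt(S[0]) if scale == "sqrt" else S[0]
    W[:, 0] = c * u
    H[0] = c * v

    for j in range(1, r):
        x, y = U[:, j], Vt[j]
        xp, xn = np.clip(x, 0, None), np.clip(-x, 0, None)
        yp, yn = np.clip(y, 0, None), np.clip(-y, 0, None)
        xpn, xnn = np.linalg.norm(xp), np.linalg.norm(xn)
        ypn, ynn = np.linalg.norm(yp), np.linalg.norm(yn)
        mp, mn = xpn * ypn, xnn * ynn
        if mp >= mn:
            if mp == 0:
                continue  # component contributes nothing nonnegative
            uu, vv, sig = xp / xpn, yp / ypn, mp
        else:
            uu, vv, sig = xn / xnn, yn / ynn, mn
        if scale == "sqrt":
            c = np.sqrt(S[j] * sig)
            W[:, j] = c * uu
            H[j] = c * vv
        else:
            W[:, j] = S[j] * uu
            H[j] = S[j] * vv
    return InitPair(W0=W, H0=H, singular_values_used=S[:r].copy())


def perturb_zeros(pair: InitPair, eps: float) -> InitPair:
    """Replace exact zeros by ``eps`` (multiplicative updates cannot leave 0)."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    W = np.where(pair.W0 == 0, eps, pair.W0)
    H = np.where(pair.H0 == 0, eps, pair.H0)
    return replace(pair, W0=W, H0=H)


def default_perturbation(V) -> float:
    """Zero-replacement scale used for multiplicative solvers: 1e-6 * mean(V)."""
    mean = float(np.mean(V))
    return 1e-6 * mean if mean > 0 else 1e-6
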