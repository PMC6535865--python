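"""Attention-weighted fusion of the five per-solver feature vectors.

Each sample i has five candidate feature vectors F_j(x_i) (one per NMF
solver) and a clinical vector C(x_i). A single trainable bilinear matrix X
scores each solver for each sample,

    w_ij = F_j(x_i)^T X C(x_i),

the scores are softmax-normalized across the five solvers, and the fused
representation is the resulting convex combination, optionally concatenated
with the clinical features for the downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nmf import SOLVER_ORDER, Factorization


@dataclass
class FeatureStack:
    """Samples x solvers x features tensor; solver axis in the fixed order."""

    values: np.ndarray  # (m, 5, r)
    solver_names: tuple[str, ...] = SOLVER_ORDER
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("feature stack must be 3-D (samples, solvers, features)")
        if self.values.shape[1] != len(self.solver_names):
            raise ValueError("solver axis does not match solver_names")
        if np.any(self.values < 0):
            raise ValueError("NMF feature vectors must be nonnegative")

    @classmethod
    def from_factorizations(cls, facts: dict[str, Factorization],
                            sample_ids: list[str] | None = None) -> "FeatureStack":
        missing = [s for s in SOLVER_ORDER if s not in facts]
        if missing:
            raise ValueError(f"missing solver factorizations: {missing}")
        return cls(
            values=np.stack([facts[s].W for s in SOLVER_ORDER], axis=1),
            solver_names=SOLVER_ORDER,
            sample_ids=sample_ids,
        )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]


def init_attention(r: int, d_c: int, seed: int = 0) -> np.ndarray:
    """Small uniform init for X in [-s, s], s = 1/sqrt(r * d_c).

    Raw scores start near zero, so the softmax starts near the uniform 1/5
    weighting and training moves it away only where the clinical data
    justifies it.
    """
    s = 1.0 / np.sqrt(r * d_c)
    rng = np.random.default_rng(seed)
    return rng.uniform(-s, s, size=(r, d_c))


def raw_weights(stack, clinical_values, X: np.ndarray) -> np.ndarray:
    """Bilinear attention scores w[i, j] = F_j(x_i)^T X C(x_i), shape (m, 5)."""
    S = stack.values if isinstance(stack, FeatureStack) else np.asarray(stack, float)
    C = np.asarray(clinical_values, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape != (S.shape[2], C.shape[1]):
        raise ValueError(
            f"attention matrix must be {(S.shape[2], C.shape[1])}, got {X.shape}"
        )
    if S.shape[0] != C.shape[0]:
        raise ValueError("feature stack and clinical matrix sample counts differ")
    return np.einsum("ijr,rd,id->ij", S, X, C)


def normalize_weights(raw: np.ndarray) -> np.ndarray:
    """Rowwise softmax with max subtraction; rows sum to 1."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw attention weights must be finite")
    shifted = raw - raw.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def fuse(stack, weights: np.ndarray) -> np.ndarray:
    """Convex combination of the per-solver feature vectors, shape (m, r)."""
    S = stack.values if isinstance(stack, FeatureStack) else np.asarray(stack, float)
    w = np.asarray(weights, dtype=float)
    if w.shape != S.shape[:2]:
        raise ValueError("weights shape must be (samples, solvers)")
    if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("weight rows must sum to 1")
    return np.einsum("ij,ijr->ir", w, S)


def concat_clinical(F: np.ndarray, clinical, fused_ids=None) -> np.ndarray:
    """Concatenate fused features with clinical features, sample order preserved."""
    F = np.asarray(F, dtype=float)
    C = clinical.values if hasattr(clinical, "values") else np.asarray(clinical, float)
    if F.shape[0] != C.shape[0]:
        raise ValueError("fused and clinical sample counts differ")
    if fused_ids is not None and hasattr(clinical, "sample_ids"):
        if list(fused_ids) != list(clinical.sample_ids):
            raise ValueError("sample IDs misaligned between fused and clinical data")
    return np.concatenate([F, C], axis=1)


def attention_fused(stack, clinical_values, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: (fused features, normalized weights) for attention matrix X."""
    w_hat = normalize_weights(raw_weights(stack, clinical_values, X))
    return fuse(stack, w_hat), w_hat
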