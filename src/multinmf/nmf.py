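"""Five NMF solvers behind one interface, sharing a deterministic SVD init.

Given a nonnegative samples x genes matrix V and a rank r << min(m, n), each
solver produces V ~= W H with W (m x r), H (r x n) >= 0; row i of W is sample
i's low-dimensional feature vector. The variants differ in how the
alternating subproblems are solved:

* ``mu``     - multiplicative updates (Euclidean or generalized-KL cost)
* ``als``    - alternating exact nonnegative least squares per column
* ``alsobs`` - ALS where each column's nonnegativity is enforced by
               Hessian-based saliency pruning (optimal-brain-surgery style):
               the negative coefficient with the smallest saliency
               w_i^2 / (2 [G^-1]_ii) is zeroed and the remaining coefficients
               receive the correction -(w_i / [G^-1]_ii) G^-1 e_i
* ``pg``     - projected gradient with Armijo backtracking on the step size
* ``pnmf``   - multiplicative updates for the Frobenius cost with ridge
               penalties alpha ||W||_F^2 + beta ||H||_F^2 (a "probabilistic"
               NMF formulation that damps measurement noise)
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .nndsvd import InitPair, default_perturbation, nndsvd, perturb_zeros

SOLVER_ORDER = ("mu", "als", "alsobs", "pg", "pnmf")

_TINY = 1e-300


@dataclass
class SolverConfig:
    max_outer_iter: int = 200
    rel_tol: float = 1e-4
    epsilon_guard: float = 1e-12
    cost: str = "euclidean"  # for mu: 'euclidean' or 'kl'
    pg_beta: float = 0.1
    pg_sigma: float = 0.01
    pg_eps: float = 1e-4
    pg_max_inner: int = 50
    pnmf_alpha: float = 0.1
    pnmf_beta: float = 0.1
    ridge: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pg_beta < 1) or not (0 < self.pg_sigma < 1):
            raise ValueError("pg_beta and pg_sigma must lie in (0, 1)")
        if self.pnmf_alpha < 0 or self.pnmf_beta < 0:
            raise ValueError("pnmf penalties must be >= 0")
        if self.cost not in ("euclidean", "kl"):
            raise ValueError("cost must be 'euclidean' or 'kl'")


@dataclass
class Factorization:
    W: np.ndarray
    H: np.ndarray
    r: int
    objective_trace: list[float]
    solver_name: str
    converged: bool
    iterations: int

    def relative_error(self, V) -> float:
        V = np.asarray(V, dtype=float)
        return float(
            np.linalg.norm(V - self.W @ self.H) / max(np.linalg.norm(V), _TINY)
        )

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.W).to_csv(outdir / "W.tsv", sep="\t", index=False)
        pd.DataFrame(self.H).to_csv(outdir / "H.tsv", sep="\t", index=False)
        pd.DataFrame({"objective": self.objective_trace}).to_csv(
            outdir / "trace.tsv", sep="\t", index=False
        )
        meta = {
            "solver_name": self.solver_name,
            "r": self.r,
            "converged": self.converged,
            "iterations": self.iterations,
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, outdir) -> "Factorization":
        outdir = Path(outdir)
        meta = json.loads((outdir / "meta.json").read_text())
        return cls(
            W=pd.read_csv(outdir / "W.tsv", sep="\t").to_numpy(float),
            H=pd.read_csv(outdir / "H.tsv", sep="\t").to_numpy(float),
            r=meta["r"],
            objective_trace=list(
                pd.read_csv(outdir / "trace.tsv", sep="\t")["objective"]
            ),
            solver_name=meta["solver_name"],
            converged=meta["converged"],
            iterations=meta["iterations"],
        )


def objective(V, W, H, kind: str = "euclidean_sq", alpha: float = 0.0,
              beta: float = 0.0) -> float:
    """Scalar factorization cost: squared Frobenius, generalized KL, or the
    ridge-regularized Frobenius cost used by the pnmf solver."""
    V, W, H = (np.asarray(a, dtype=float) for a in (V, W, H))
    if W.shape[0] != V.shape[0] or H.shape[1] != V.shape[1] or W.shape[1] != H.shape[0]:
        raise ValueError("shape mismatch between V, W, H")
    WH = W @ H
    if kind == "euclidean_sq":
        return float(np.sum((V - WH) ** 2))
    if kind == "kl":
        # convention: 0 log 0 = 0; V_ij > 0 with (WH)_ij = 0 -> +inf
        pos = V > 0
        if np.any(WH[pos] == 0):
            return float("inf")
        with np.errstate(divide="ignore", invalid="ignore"):
            lg = np.zeros_like(V)
            lg[pos] = V[pos] * np.log(V[pos] / WH[pos])
        return float(np.sum(lg - V + WH))
    if kind == "pnmf_regularized":
        return float(
            np.sum((V - WH) ** 2) + alpha * np.sum(W**2) + beta * np.sum(H**2)
        )
    raise ValueError(f"unknown objective kind {kind!r}")


# ---------------------------------------------------------------------------
# shared plumbing


def _validate(V, r) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be 2-D")
    if np.any(V < 0):
        raise ValueError("V must be nonnegative")
    if not np.any(V > 0):
        raise ValueError("V must not be identically zero")
    if r >= min(V.shape) or r < 1:
        raise ValueError(f"rank r={r} must satisfy 1 <= r < min(m, n)")
    return V


def _resolve_init(V, r, init, perturb: bool, cfg: SolverConfig):
    if init is None:
        pair = nndsvd(V, r)
    elif isinstance(init, InitPair):
        pair = init
    else:
        W0, H0 = init
        pair = InitPair(
            W0=np.asarray(W0, float), H0=np.asarray(H0, float),
            singular_values_used=np.array([]),
        )
    if perturb:
        pair = perturb_zeros(pair, default_perturbation(V))
    return pair.W0.copy(), pair.H0.copy()


def _converged(trace: list[float], rel_tol: float) -> bool:
    if len(trace) < 2:
        return False
    prev, cur = trace[-2], trace[-1]
    return abs(prev - cur) <= rel_tol * max(abs(prev), _TINY)


# ---------------------------------------------------------------------------
# multiplicative updates


def solve_mu(V, r: int, init=None, cfg: SolverConfig | None = None) -> Factorization:
    """Lee-Seung multiplicative updates; cost selected by ``cfg.cost``."""
    cfg = cfg or SolverConfig()
    V = _validate(V, r)
    W, H = _resolve_init(V, r, init, perturb=True, cfg=cfg)
    eps = cfg.epsilon_guard
    kind = "euclidean_sq" if cfg.cost == "euclidean" else "kl"
    trace = [objective(V, W, H, kind)]
    it = 0
    for it in range(1, cfg.max_outer_iter + 1):
        if cfg.cost == "euclidean":
            W *= (V @ H.T) / (W @ (H @ H.T) + eps)
            H *= (W.T @ V) / ((W.T @ W) @ H + eps)
        else:
            WH = W @ H + eps
            W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + eps)
            WH = W @ H + eps
            H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + eps)
        trace.append(objective(V, W, H, kind))
        if _converged(trace, cfg.rel_tol):
            break
    return Factorization(W, H, r, trace, "mu", _converged(trace, cfg.rel_tol), it)


# ---------------------------------------------------------------------------
# alternating nonnegative least squares


def _nnls_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min_{x>=0} ||A x - b||_2 for every column b of B."""
    out = np.empty((A.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        out[:, j], _ = _scipy_nnls(A, B[:, j])
    return out


def solve_als(V, r: int, init=None, cfg: SolverConfig | None = None) -> Factorization:
    """Alternate exact nonnegative least squares for H (W fixed) and W (H fixed)."""
    cfg = cfg or SolverConfig()
    V = _validate(V, r)
    W, H = _resolve_init(V, r, init, perturb=False, cfg=cfg)
    trace = [objective(V, W, H)]
    it = 0
    for it in range(1, cfg.max_outer_iter + 1):
        H = _nnls_columns(W, V)
        W = _nnls_columns(H.T, V.T).T
        trace.append(objective(V, W, H))
        if _converged(trace, cfg.rel_tol):
            break
    return Factorization(W, H, r, trace, "als", _converged(trace, cfg.rel_tol), it)


# ---------------------------------------------------------------------------
# ALS with OBS saliency pruning


def obs_nnls(G: np.ndarray, x0: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Enforce nonnegativity on a least-squares solution by saliency pruning.

    ``G`` is the (ridge-stabilized) Gram matrix of the subproblem and ``x0``
    its unconstrained minimizer G^-1 b. While negative coefficients remain,
    the negative coefficient with minimal saliency x_i^2 / (2 [G^-1]_ii)
    (restricted to the free set) is fixed at zero and the others receive the
    second-order correction -(x_i / [G^-1]_ii) * G^-1 e_i, which lands the
    free set exactly on its reduced unconstrained optimum.
    """
    x = np.asarray(x0, dtype=float).copy()
    free = np.arange(x.size)
    while free.size:
        neg_mask = x[free] < -tol
        if not neg_mask.any():
            break
        Gff = G[np.ix_(free, free)]
        Ginv = np.linalg.inv(Gff)
        diag = np.diag(Ginv)
        sal = np.full(free.size, np.inf)
        sal[neg_mask] = x[free][neg_mask] ** 2 / (2.0 * diag[neg_mask])
        jl = int(np.argmin(sal))
        j = free[jl]
        delta = -(x[j] / Ginv[jl, jl]) * Ginv[:, jl]
        x[free] += delta
        x[j] = 0.0
        free = free[free != j]
    np.clip(x, 0.0, None, out=x)
    return x


def _obs_solve(A: np.ndarray, B: np.ndarray, ridge: float) -> np.ndarray:
    """OBS-pruned least squares min_{X>=0} ||A X - B||_F column by column."""
    d = A.shape[1]
    G = A.T @ A + ridge * np.eye(d)
    try:
        unconstrained = np.linalg.solve(G, A.T @ B)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular Gram matrix in OBS subproblem; increase cfg.ridge"
        ) from exc
    X = unconstrained.copy()
    for j in range(B.shape[1]):
        if np.any(X[:, j] < 0):
            X[:, j] = obs_nnls(G, unconstrained[:, j])
        else:
            np.clip(X[:, j], 0.0, None, out=X[:, j])
    return X


def _keep_better_columns(V, A, X_new, X_old) -> np.ndarray:
    """Per-column safeguard: retain the old column when pruning worsened it."""
    res_new = np.sum((V - A @ X_new) ** 2, axis=0)
    res_old = np.sum((V - A @ X_old) ** 2, axis=0)
    worse = res_new > res_old
    if worse.any():
        X_new = X_new.copy()
        X_new[:, worse] = X_old[:, worse]
    return X_new


def solve_alsobs(V, r: int, init=None, cfg: SolverConfig | None = None) -> Factorization:
    """ALS outer loop with OBS saliency pruning solving each column subproblem."""
    cfg = cfg or SolverConfig()
    V = _validate(V, r)
    W, H = _resolve_init(V, r, init, perturb=False, cfg=cfg)
    trace = [objective(V, W, H)]
    it = 0
    for it in range(1, cfg.max_outer_iter + 1):
        H = _keep_better_columns(V, W, _obs_solve(W, V, cfg.ridge), H)
        Wt = _keep_better_columns(V.T, H.T, _obs_solve(H.T, V.T, cfg.ridge), W.T)
        W = Wt.T
        trace.append(objective(V, W, H))
        if _converged(trace, cfg.rel_tol):
            break
    return Factorization(W, H, r, trace, "alsobs", _converged(trace, cfg.rel_tol), it)


# ---------------------------------------------------------------------------
# projected gradient


def pg_subproblem(
    VtA: np.ndarray, AtA: np.ndarray, X0: np.ndarray, cfg: SolverConfig
) -> tuple[np.ndarray, int]:
    """Solve min_{X>=0} 0.5 ||A X - B||_F^2 by projected gradient.

    ``AtA`` = A^T A and ``VtA`` = A^T B; the objective is evaluated through
    the Gram form (up to the constant 0.5||B||^2, which cancels in the Armijo
    test). Steps are x <- P[x - alpha grad] with alpha = beta^t, t = 1, 2, ...
    the first power passing the sufficient-decrease test
    f(x_new) - f(x) <= sigma * grad . (x_new - x). The loop stops when the
    projected-gradient norm falls below pg_eps times the initial full
    gradient norm, or after pg_max_inner iterations.
    """
    X = X0.copy()

    def half_obj(Xc, AtAXc):
        return 0.5 * np.sum(Xc * AtAXc) - np.sum(Xc * VtA)

    AtAX = AtA @ X
    grad = AtAX - VtA
    grad0_norm = np.linalg.norm(grad)
    if not np.all(np.isfinite(grad)):
        raise ValueError("non-finite gradient in projected-gradient subproblem")
    inner = 0
    for inner in range(cfg.pg_max_inner):
        pgrad = np.where(X > 0, grad, np.minimum(grad, 0.0))
        if np.linalg.norm(pgrad) <= cfg.pg_eps * grad0_norm:
            break
        f_cur = half_obj(X, AtAX)
        accepted = False
        for t in range(1, 26):
            alpha = cfg.pg_beta**t
            Xn = np.maximum(X - alpha * grad, 0.0)
            AtAXn = AtA @ Xn
            d = Xn - X
            if half_obj(Xn, AtAXn) - f_cur <= cfg.pg_sigma * np.sum(grad * d):
                accepted = True
                break
        if not accepted or not np.any(Xn != X):
            break  # step size underflow: already (numerically) stationary
        X, AtAX = Xn, AtAXn
        grad = AtAX - VtA
    else:
        inner += 1
    return X, inner


def solve_pg(V, r: int, init=None, cfg: SolverConfig | None = None) -> Factorization:
    """Alternating projected-gradient solves for H (W fixed) and W (H fixed)."""
    cfg = cfg or SolverConfig()
    V = _validate(V, r)
    W, H = _resolve_init(V, r, init, perturb=False, cfg=cfg)
    trace = [objective(V, W, H)]
    it = 0
    for it in range(1, cfg.max_outer_iter + 1):
        H, _ = pg_subproblem(W.T @ V, W.T @ W, H, cfg)
        Wt, _ = pg_subproblem(H @ V.T, H @ H.T, W.T, cfg)
        W = Wt.T
        trace.append(objective(V, W, H))
        if _converged(trace, cfg.rel_tol):
            break
    return Factorization(W, H, r, trace, "pg", _converged(trace, cfg.rel_tol), it)


# ---------------------------------------------------------------------------
# regularized ("probabilistic") multiplicative updates


def solve_pnmf(V, r: int, init=None, cfg: SolverConfig | None = None) -> Factorization:
    """Multiplicative updates for ||V - WH||_F^2 + alpha||W||_F^2 + beta||H||_F^2."""
    cfg = cfg or SolverConfig()
    V = _validate(V, r)
    W, H = _resolve_init(V, r, init, perturb=True, cfg=cfg)
    eps = cfg.epsilon_guard
    a, b = cfg.pnmf_alpha, cfg.pnmf_beta
    kind = "pnmf_regularized"
    trace = [objective(V, W, H, kind, a, b)]
    it = 0
    for it in range(1, cfg.max_outer_iter + 1):
        W *= (V @ H.T) / (W @ (H @ H.T) + a * W + eps)
        H *= (W.T @ V) / ((W.T @ W) @ H + b * H + eps)
        trace.append(objective(V, W, H, kind, a, b))
        if _converged(trace, cfg.rel_tol):
            break
    return Factorization(W, H, r, trace, "pnmf", _converged(trace, cfg.rel_tol), it)


_SOLVERS = {
    "mu": solve_mu,
    "als": solve_als,
    "alsobs": solve_alsobs,
    "pg": solve_pg,
    "pnmf": solve_pnmf,
}


def factorize_all(
    V, r: int, cfg: SolverConfig | None = None
) -> dict[str, Factorization]:
    """Run all five solvers from the same deterministic SVD initialization.

    Returns a dict keyed by solver name in the fixed order
    ``('mu', 'als', 'alsobs', 'pg', 'pnmf')``.
    """
    cfg = cfg or SolverConfig()
    V = _validate(V, r)
    pair = nndsvd(V, r)
    out: dict[str, Factorization] = {}
    for name in SOLVER_ORDER:
        out[name] = _SOLVERS[name](V, r, init=pair, cfg=cfg)
    return out


def project_new_samples(H: np.ndarray, V_new) -> np.ndarray:
    """Project unseen samples onto a fitted coefficient matrix H.

    Each row of the result solves min_{w>=0} ||v - w H||_2, i.e. the same
    per-sample nonnegative least-squares subproblem the ALS solver uses, so
    features for held-out samples can be computed without refitting.
    """
    H = np.asarray(H, dtype=float)
    V_new = np.atleast_2d(np.asarray(V_new, dtype=float))
    if V_new.shape[1] != H.shape[1]:
        raise ValueError(
            f"V_new has {V_new.shape[1]} columns but H has {H.shape[1]}"
        )
    return _nnls_columns(H.T, V_new.T).T
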