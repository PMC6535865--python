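"""End-to-end survival classifier: attention fusion + feed-forward network.

The model maps (five per-solver NMF feature vectors, clinical vector) to a
5-year survival probability. For the full model the bilinear attention
matrix X and the network weights are trained jointly by minimizing binary
cross-entropy with Adam; the NMF factorizations themselves are computed once
and frozen. Ablation variants reuse the same machinery:

* ``amnd``            attention-fused features concatenated with clinical
* ``clinical_first``  attention-fused features only (clinical data only
                      steers the attention weights)
* ``clinical_second`` uniform 1/5 fusion concatenated with clinical
* ``only_clinical``   clinical features only
* ``only_exp``        uniform 1/5 fusion only
* ``single:<solver>`` one solver's features concatenated with clinical

The forward/backward passes are written directly in NumPy; gradients
(including the path through softmax attention into X) are validated against
central finite differences in the test suite.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .fusion import FeatureStack, init_attention
from .nmf import SOLVER_ORDER

VARIANTS = ("amnd", "clinical_first", "clinical_second", "only_clinical", "only_exp")


@dataclass
class ModelConfig:
    hidden_layers: tuple[int, ...] = (128, 32)
    activation: str = "relu"
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0
    variant: str = "amnd"
    class_weighting: bool = False

    def __post_init__(self) -> None:
        self.hidden_layers = tuple(int(h) for h in self.hidden_layers)
        if self.activation not in ("relu", "tanh"):
            raise ValueError("activation must be 'relu' or 'tanh'")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("invalid learning_rate or batch_size")
        _variant_flags(self.variant)  # validates the variant string


def _variant_flags(variant: str) -> dict:
    """Which modalities/parameters a variant uses."""
    if variant.startswith("single:"):
        solver = variant.split(":", 1)[1]
        if solver not in SOLVER_ORDER:
            raise ValueError(f"unknown solver in variant {variant!r}")
        return {"attention": False, "stack": "single", "solver": solver,
                "concat": True}
    table = {
        "amnd": {"attention": True, "stack": "attention", "concat": True},
        "clinical_first": {"attention": True, "stack": "attention", "concat": False},
        "clinical_second": {"attention": False, "stack": "uniform", "concat": True},
        "only_clinical": {"attention": False, "stack": None, "concat": True},
        "only_exp": {"attention": False, "stack": "uniform", "concat": False},
    }
    if variant not in table:
        raise ValueError(f"unknown variant {variant!r}")
    return dict(table[variant], solver=None)


def input_width(variant: str, r: int, d_c: int) -> int:
    f = _variant_flags(variant)
    return (r if f["stack"] else 0) + (d_c if f["concat"] else 0)


def build_inputs(variant: str, stack, clinical, X: np.ndarray | None = None
                 ) -> np.ndarray:
    """Assemble the per-sample classifier input for a variant.

    Attention variants require the bilinear matrix ``X``; static variants use
    a uniform 1/5 fusion, a single solver's features, or the clinical vector
    alone, per the variant definition.
    """
    f = _variant_flags(variant)
    S = stack.values if isinstance(stack, FeatureStack) else stack
    C = clinical.values if hasattr(clinical, "values") else clinical
    if f["stack"] is None:
        if C is None:
            raise ValueError(f"variant {variant!r} requires clinical data")
        return np.asarray(C, dtype=float).copy()
    if S is None:
        raise ValueError(f"variant {variant!r} requires NMF features")
    S = np.asarray(S, dtype=float)
    if f["stack"] == "attention":
        if X is None:
            raise ValueError(f"variant {variant!r} requires an attention matrix X")
        from .fusion import attention_fused

        F, _ = attention_fused(S, np.asarray(C, float), X)
    elif f["stack"] == "uniform":
        F = S.mean(axis=1)
    else:  # single solver
        F = S[:, SOLVER_ORDER.index(f["solver"]), :]
    if f["concat"]:
        if C is None:
            raise ValueError(f"variant {variant!r} requires clinical data")
        return np.concatenate([F, np.asarray(C, float)], axis=1)
    return F.copy()


# ---------------------------------------------------------------------------
# parameters, forward, backward


def init_params(variant: str, r: int, d_c: int, cfg: ModelConfig) -> dict:
    """He/Xavier-style layer init plus a near-zero attention matrix."""
    f = _variant_flags(variant)
    rng = np.random.default_rng(cfg.seed)
    params: dict[str, np.ndarray] = {}
    if f["attention"]:
        params["X"] = init_attention(r, d_c, seed=cfg.seed)
    dims = [input_width(variant, r, d_c), *cfg.hidden_layers, 1]
    for l in range(len(dims) - 1):
        fan_in = dims[l]
        if cfg.activation == "relu":
            sd = np.sqrt(2.0 / fan_in)
        else:
            sd = np.sqrt(1.0 / fan_in)
        params[f"W{l}"] = rng.normal(0.0, sd, size=(dims[l], dims[l + 1]))
        params[f"b{l}"] = np.zeros(dims[l + 1])
    return params


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(z, 0.0) if kind == "relu" else np.tanh(z)


def _n_layers(params: dict) -> int:
    return sum(1 for k in params if k.startswith("W") and k != "X")


def forward(params: dict, variant: str, stack_b, clin_b, cfg: ModelConfig,
            train: bool = False, drop_rng: np.random.Generator | None = None):
    """Return (logits, cache). Dropout (inverted) is applied only in training."""
    f = _variant_flags(variant)
    cache: dict = {"flags": f}
    if f["stack"] == "attention":
        S = np.asarray(stack_b, float)
        C = np.asarray(clin_b, float)
        raw = np.einsum("ijr,rd,id->ij", S, params["X"], C)
        shifted = raw - raw.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        w_hat = e / e.sum(axis=1, keepdims=True)
        F = np.einsum("ij,ijr->ir", w_hat, S)
        cache.update(S=S, C=C, w_hat=w_hat)
        x = np.concatenate([F, C], axis=1) if f["concat"] else F
    else:
        x = build_inputs(variant, stack_b, clin_b)
    cache["x0"] = x
    L = _n_layers(params)
    a = x
    zs, acts, masks = [], [x], []
    keep = 1.0 - cfg.dropout
    for l in range(L):
        z = a @ params[f"W{l}"] + params[f"b{l}"]
        if l < L - 1:
            a = _act(z, cfg.activation)
            if train and cfg.dropout > 0:
                mask = (drop_rng.random(a.shape) < keep) / keep
                a = a * mask
            else:
                mask = None
            masks.append(mask)
        else:
            a = z  # final logit
        zs.append(z)
        acts.append(a)
    cache.update(zs=zs, acts=acts, masks=masks)
    return acts[-1][:, 0], cache


def loss_and_grads(params: dict, variant: str, stack_b, clin_b, y,
                   cfg: ModelConfig, sample_weight=None, train: bool = False,
                   drop_rng: np.random.Generator | None = None):
    """Mean weighted binary cross-entropy and gradients for every parameter."""
    y = np.asarray(y, dtype=float)
    logits, cache = forward(params, variant, stack_b, clin_b, cfg, train, drop_rng)
    w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
    wsum = w.sum()
    # numerically stable BCE with logits
    loss = float(
        np.sum(w * (np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))))
        / wsum
    )
    probs = 1.0 / (1.0 + np.exp(-logits))
    dlogits = w * (probs - y) / wsum

    grads: dict[str, np.ndarray] = {}
    L = _n_layers(params)
    delta = dlogits[:, None]  # dL/d(pre-activation) of the current layer
    for l in range(L - 1, -1, -1):
        grads[f"W{l}"] = cache["acts"][l].T @ delta
        grads[f"b{l}"] = delta.sum(axis=0)
        delta = delta @ params[f"W{l}"].T
        if l > 0:
            if cache["masks"][l - 1] is not None:
                delta = delta * cache["masks"][l - 1]
            z_prev = cache["zs"][l - 1]
            if cfg.activation == "relu":
                delta = delta * (z_prev > 0)
            else:
                delta = delta * (1.0 - np.tanh(z_prev) ** 2)
    # after the loop, delta is dL/d(input row)

    f = cache["flags"]
    if f["attention"]:
        r = cache["S"].shape[2]
        dF = delta[:, :r]
        S, C, w_hat = cache["S"], cache["C"], cache["w_hat"]
        dw_hat = np.einsum("ir,ijr->ij", dF, S)
        dot = np.sum(dw_hat * w_hat, axis=1, keepdims=True)
        draw = w_hat * (dw_hat - dot)
        grads["X"] = np.einsum("ij,ijr,id->rd", draw, S, C)
    return loss, grads, probs


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    params: dict
    cfg: ModelConfig
    r: int
    d_c: int
    history: list[dict]
    best_epoch: int
    best_val_auc: float

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez(outdir / "params.npz", **self.params)
        meta = {
            "config": {**self.cfg.__dict__, "hidden_layers": list(self.cfg.hidden_layers)},
            "r": self.r,
            "d_c": self.d_c,
            "best_epoch": self.best_epoch,
            "best_val_auc": self.best_val_auc,
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, outdir) -> "TrainedModel":
        outdir = Path(outdir)
        meta = json.loads((outdir / "meta.json").read_text())
        with np.load(outdir / "params.npz") as z:
            params = {k: z[k] for k in z.files}
        cfg = ModelConfig(**meta["config"])
        return cls(params=params, cfg=cfg, r=meta["r"], d_c=meta["d_c"],
                   history=[], best_epoch=meta["best_epoch"],
                   best_val_auc=meta["best_val_auc"])


@dataclass
class PredictionSet:
    probabilities: np.ndarray
    labels: np.ndarray
    sample_ids: list[str] | None = None


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _slice_modalities(variant: str, stack, clinical, idx):
    f = _variant_flags(variant)
    S = stack.values if isinstance(stack, FeatureStack) else stack
    C = clinical.values if hasattr(clinical, "values") else clinical
    S_b = None if (S is None or f["stack"] is None) else np.asarray(S, float)[idx]
    C_b = None if C is None else np.asarray(C, float)[idx]
    return S_b, C_b


def train(stack, clinical, labels, split, cfg: ModelConfig) -> TrainedModel:
    """Train a variant end-to-end with Adam, early-stopping on validation AUC.

    The epoch with the best validation AUC is restored; with attention
    variants the gradients flow into the bilinear matrix X as well. Fully
    deterministic for a fixed (data, config, seed).
    """
    y = labels.labels if hasattr(labels, "labels") else np.asarray(labels, int)
    f = _variant_flags(cfg.variant)
    S = stack.values if isinstance(stack, FeatureStack) else stack
    C = clinical.values if hasattr(clinical, "values") else clinical
    if f["stack"] is not None and S is None:
        raise ValueError(f"variant {cfg.variant!r} needs NMF features")
    if (f["concat"] or f["attention"]) and C is None:
        raise ValueError(f"variant {cfg.variant!r} needs clinical data")
    r = S.shape[2] if S is not None else 0
    d_c = C.shape[1] if C is not None else 0
    for part, name in ((split.train_idx, "training"), (split.val_idx, "validation")):
        if np.unique(y[part]).size < 2:
            raise ValueError(f"{name} set contains a single class")

    params = init_params(cfg.variant, r, d_c, cfg)
    opt = _Adam(params, cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 9151]))

    sw = None
    if cfg.class_weighting:
        n_pos = y[split.train_idx].sum()
        n_tot = split.train_idx.size
        w_pos, w_neg = n_tot / (2.0 * n_pos), n_tot / (2.0 * (n_tot - n_pos))
        sw_full = np.where(y == 1, w_pos, w_neg)
    else:
        sw_full = np.ones_like(y, dtype=float)

    val_S, val_C = _slice_modalities(cfg.variant, stack, clinical, split.val_idx)
    y_val = y[split.val_idx]

    best = {"auc": -np.inf, "epoch": 0, "params": copy.deepcopy(params)}
    history: list[dict] = []
    stall = 0
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(split.train_idx)
        losses = []
        for start in range(0, perm.size, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            S_b, C_b = _slice_modalities(cfg.variant, stack, clinical, idx)
            loss, grads, _ = loss_and_grads(
                params, cfg.variant, S_b, C_b, y[idx], cfg,
                sample_weight=sw_full[idx], train=True, drop_rng=rng,
            )
            opt.step(params, grads)
            losses.append(loss)
        logits, _ = forward(params, cfg.variant, val_S, val_C, cfg, train=False)
        val_auc = float(roc_auc_score(y_val, logits))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_auc": val_auc}
        )
        if val_auc > best["auc"]:
            best = {"auc": val_auc, "epoch": epoch, "params": copy.deepcopy(params)}
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return TrainedModel(
        params=best["params"], cfg=cfg, r=r, d_c=d_c, history=history,
        best_epoch=best["epoch"], best_val_auc=best["auc"],
    )


def predict(model: TrainedModel, stack, clinical, idx=None,
            sample_ids: list[str] | None = None) -> PredictionSet:
    """Deterministic inference (dropout off); labels thresholded at 0.5."""
    S = stack.values if isinstance(stack, FeatureStack) else stack
    C = clinical.values if hasattr(clinical, "values") else clinical
    if idx is not None:
        S_b, C_b = _slice_modalities(model.cfg.variant, stack, clinical, idx)
    else:
        f = _variant_flags(model.cfg.variant)
        S_b = None if (S is None or f["stack"] is None) else np.asarray(S, float)
        C_b = None if C is None else np.asarray(C, float)
    logits, _ = forward(model.params, model.cfg.variant, S_b, C_b, model.cfg,
                        train=False)
    probs = 1.0 / (1.0 + np.exp(-logits))
    return PredictionSet(
        probabilities=probs, labels=(probs >= 0.5).astype(int), sample_ids=sample_ids
    )


def attention_weight_table(model: TrainedModel, stack, clinical) -> np.ndarray:
    """Per-sample normalized attention weights (m x 5) for a trained model."""
    if "X" not in model.params:
        raise ValueError("model variant has no attention parameters")
    from .fusion import attention_fused

    S = stack.values if isinstance(stack, FeatureStack) else stack
    C = clinical.values if hasattr(clinical, "values") else clinical
    _, w_hat = attention_fused(np.asarray(S, float), np.asarray(C, float),
                               model.params["X"])
    return w_hat
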