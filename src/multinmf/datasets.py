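"""Cohort containers, preprocessing, splitting, I/O and synthetic cohorts.

The pipeline works on three aligned tables: a nonnegative samples x genes
expression matrix, a samples x clinical-features matrix scaled to [0, 1],
and a binary 5-year survival label per sample (1 = long-term survivor).
Because the real cohort this emulates (a large breast-cancer study with
~1980 patients, ~25 clinical covariates and a 75/25 long/short split) is
access-restricted, the module also generates synthetic cohorts with planted
low-rank expression structure and partially informative clinical features so
the whole pipeline can be exercised and tested offline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit


class DataValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass
class ExpressionMatrix:
    """Nonnegative samples x genes matrix (the factorization target V)."""

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataValidationError("expression values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("expression matrix contains non-finite values")
        if np.any(self.values < 0):
            raise DataValidationError(
                "expression matrix must be nonnegative; found negative entries"
            )
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        m, n = self.values.shape
        if m != len(self.sample_ids) or n != len(self.gene_ids):
            raise DataValidationError("expression shape does not match identifiers")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class ClinicalMatrix:
    """Samples x clinical-features matrix with entries in [0, 1]."""

    values: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataValidationError("clinical values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("clinical matrix contains non-finite values")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise DataValidationError(
                "clinical matrix entries must lie in [0, 1]; normalize first "
                "(see minmax_normalize)"
            )
        self.values = np.clip(self.values, 0.0, 1.0)
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.feature_names = _check_ids(self.feature_names, "feature")
        m, d = self.values.shape
        if m != len(self.sample_ids) or d != len(self.feature_names):
            raise DataValidationError("clinical shape does not match identifiers")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SurvivalLabels:
    """Binary 5-year survival outcome; 1 = long-term, 0 = short-term."""

    labels: np.ndarray
    sample_ids: list[str] | None = None
    survival_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or not np.isin(self.labels, (0, 1)).all():
            raise DataValidationError("labels must be a 1-D vector of 0/1")
        if self.sample_ids is not None:
            self.sample_ids = _check_ids(self.sample_ids, "sample")
            if len(self.sample_ids) != self.labels.size:
                raise DataValidationError("label/sample-id length mismatch")
        if self.survival_times is not None:
            self.survival_times = np.asarray(self.survival_times, dtype=float)
            if self.survival_times.shape != self.labels.shape:
                raise DataValidationError("survival time length mismatch")
            if np.any(~np.isfinite(self.survival_times)) or np.any(
                self.survival_times < 0
            ):
                raise DataValidationError("survival times must be finite and >= 0")

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class DatasetSplit:
    """Disjoint train/val/test index sets from a stratified 80/10/10 split."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.val_idx = np.asarray(self.val_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if np.unique(all_idx).size != all_idx.size:
            raise DataValidationError("split parts are not disjoint")


@dataclass
class SyntheticCohortConfig:
    """Generator settings for a planted-structure multimodal cohort.

    ``class_balance`` is the expected short-term (label 0) fraction; the
    default 491/1980 reproduces the prevalence of the cohort this package
    emulates. ``clinical_signal`` in [0, 1] controls both how many clinical
    columns carry outcome information (round(clinical_signal * d_c)) and the
    weight of the clinical-only latent factor in the outcome model.
    """

    m: int = 400
    n: int = 500
    d_c: int = 25
    r0: int = 6
    noise_sd: float = 1.0
    class_balance: float = 491 / 1980
    clinical_signal: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m <= 0 or self.d_c <= 0:
            raise DataValidationError("m and d_c must be positive")
        if not (0 < self.r0 < self.n):
            raise DataValidationError("need n > r0 > 0")
        if self.noise_sd < 0:
            raise DataValidationError("noise_sd must be >= 0")
        if not (0 < self.class_balance < 1):
            raise DataValidationError("class_balance must lie in (0, 1)")
        if not (0 <= self.clinical_signal <= 1):
            raise DataValidationError("clinical_signal must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Labeling, normalization, splitting


def label_by_threshold(times, threshold: float = 5.0) -> SurvivalLabels:
    """Dichotomize survival times: time >= threshold years -> long-term (1)."""
    times = np.asarray(times, dtype=float)
    if threshold <= 0:
        raise DataValidationError("threshold must be positive")
    if times.ndim != 1:
        raise DataValidationError("times must be a 1-D vector")
    if np.any(~np.isfinite(times)) or np.any(times < 0):
        raise DataValidationError("survival times must be finite and >= 0")
    labels = (times >= threshold).astype(int)
    return SurvivalLabels(labels=labels, survival_times=times)


def minmax_normalize(
    M, mins: np.ndarray | None = None, maxs: np.ndarray | None = None
) -> np.ndarray:
    """Rescale each column to [0, 1] by (x - min) / (max - min).

    Constant columns map to 0. When ``mins``/``maxs`` are supplied (e.g.
    statistics computed on the training portion only), they are applied and
    the result is clipped to [0, 1] so out-of-range validation/test values
    cannot escape the unit interval.
    """
    M = np.asarray(M, dtype=float)
    if np.any(~np.isfinite(M)):
        raise DataValidationError("matrix contains missing or non-finite values")
    fit = mins is None
    if fit:
        mins = M.min(axis=0)
        maxs = M.max(axis=0)
    span = np.asarray(maxs, dtype=float) - np.asarray(mins, dtype=float)
    safe = np.where(span > 0, span, 1.0)
    out = (M - mins) / safe
    out[:, span <= 0] = 0.0
    if not fit:
        out = np.clip(out, 0.0, 1.0)
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    labels, seed: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> DatasetSplit:
    """Per-class 80/10/10 split: val = test = round(0.1 * class size).

    The remainder of each class goes to training; membership within a class
    is a uniformly random permutation driven by ``seed``.
    """
    y = labels.labels if isinstance(labels, SurvivalLabels) else np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        m_c = idx.size
        n_val = _round_half_up(fractions[1] * m_c)
        n_test = _round_half_up(fractions[2] * m_c)
        if n_val == 0 or n_test == 0 or m_c - n_val - n_test <= 0:
            raise DataValidationError(
                f"class {cls} has {m_c} members, too few for a stratified split"
            )
        perm = rng.permutation(idx)
        val.append(perm[:n_val])
        test.append(perm[n_val : n_val + n_test])
        train.append(perm[n_val + n_test :])
    return DatasetSplit(
        train_idx=np.sort(np.concatenate(train)),
        val_idx=np.sort(np.concatenate(val)),
        test_idx=np.sort(np.concatenate(test)),
        fractions=fractions,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Synthetic cohort


def generate_synthetic_cohort(
    cfg: SyntheticCohortConfig,
) -> tuple[ExpressionMatrix, ClinicalMatrix, SurvivalLabels]:
    """Generate a reproducible multimodal cohort with planted structure.

    Expression: V = clip(W0 H0 + eps, 0) with gamma-distributed nonnegative
    factors of rank ``r0`` and Gaussian noise. Clinical: the first
    round(clinical_signal * d_c) columns are noisy monotone transforms of
    latent-factor combinations plus a clinical-only factor g; the rest are
    uniform noise; all columns are min-max scaled. Outcome: Bernoulli with
    p = sigmoid(kappa * (z + clinical_signal * g) + b), with the intercept b
    calibrated so the expected positive fraction equals 1 - class_balance.
    Survival times consistent with the labels (>= 5 years iff label 1) are
    attached so threshold relabeling reproduces the labels.
    """
    rng = np.random.default_rng(cfg.seed)
    m, n, r0, d_c = cfg.m, cfg.n, cfg.r0, cfg.d_c

    W0 = rng.gamma(shape=2.0, scale=1.0, size=(m, r0))
    H0 = rng.gamma(shape=2.0, scale=1.0, size=(r0, n))
    V = W0 @ H0
    if cfg.noise_sd > 0:
        V = V + rng.normal(0.0, cfg.noise_sd, size=(m, n))
    V = np.clip(V, 0.0, None)

    # standardized latent factors drive both outcome and clinical columns
    Z = (W0 - W0.mean(axis=0)) / W0.std(axis=0)
    g = rng.standard_normal(m)  # clinical-only prognostic factor
    u = rng.standard_normal(r0)
    u /= np.linalg.norm(u)
    z_score = Z @ u
    sd = z_score.std()
    if sd <= 0:
        raise DataValidationError("degenerate latent signal; cannot calibrate labels")
    z_score = z_score / sd

    score = z_score + cfg.clinical_signal * g
    kappa = 2.0
    p_target = 1.0 - cfg.class_balance

    def excess(b: float) -> float:
        return float(np.mean(expit(kappa * score + b))) - p_target

    try:
        b = brentq(excess, -60.0, 60.0)
    except ValueError as exc:  # pragma: no cover - degenerate calibration
        raise DataValidationError(f"label calibration infeasible: {exc}") from exc
    p = expit(kappa * score + b)
    labels = (rng.random(m) < p).astype(int)
    if labels.min() == labels.max():
        raise DataValidationError("degenerate cohort: a single outcome class")

    times = np.where(
        labels == 1,
        5.0 + rng.exponential(scale=4.0, size=m),
        rng.uniform(0.0, 5.0, size=m) * (1 - 1e-12),
    )

    n_inf = int(round(cfg.clinical_signal * d_c))
    C = np.empty((m, d_c))
    for k in range(d_c):
        if k < n_inf:
            v = rng.standard_normal(r0)
            v /= np.linalg.norm(v)
            raw = 0.8 * (Z @ v) + 0.8 * g + 0.6 * rng.standard_normal(m)
        else:
            raw = rng.uniform(0.0, 1.0, size=m)
        C[:, k] = raw
    C = minmax_normalize(C)

    sample_ids = [f"S{i:04d}" for i in range(m)]
    expr = ExpressionMatrix(
        values=V, sample_ids=sample_ids, gene_ids=[f"G{j:04d}" for j in range(n)]
    )
    clin = ClinicalMatrix(
        values=C,
        sample_ids=list(sample_ids),
        feature_names=[f"clin_{k:02d}" for k in range(d_c)],
    )
    surv = SurvivalLabels(
        labels=labels, sample_ids=list(sample_ids), survival_times=times
    )
    return expr, clin, surv


# ---------------------------------------------------------------------------
# Delimited-text I/O (TSV default, CSV accepted)


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def write_matrix(path, mat: ExpressionMatrix | ClinicalMatrix) -> None:
    path = Path(path)
    cols = mat.gene_ids if isinstance(mat, ExpressionMatrix) else mat.feature_names
    df = pd.DataFrame(mat.values, index=mat.sample_ids, columns=cols)
    df.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_matrix(path, kind: str) -> ExpressionMatrix | ClinicalMatrix:
    """Read a delimited matrix (row 1 = feature names, column 1 = sample IDs)."""
    if kind not in ("expression", "clinical"):
        raise ValueError("kind must be 'expression' or 'clinical'")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.ParserError as exc:
        raise DataValidationError(f"malformed table {path}: {exc}") from exc
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise DataValidationError(f"duplicate sample ID in {path}: {dup[0]!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        raise DataValidationError(f"missing values in {path}")
    ids = [str(i) for i in df.index]
    names = [str(c) for c in df.columns]
    if kind == "expression":
        if np.any(values < 0):
            raise DataValidationError(
                f"expression matrix {path} violates nonnegativity"
            )
        return ExpressionMatrix(values=values, sample_ids=ids, gene_ids=names)
    return ClinicalMatrix(values=values, sample_ids=ids, feature_names=names)


def write_labels(path, labels: SurvivalLabels) -> None:
    path = Path(path)
    ids = labels.sample_ids or [f"S{i:04d}" for i in range(len(labels))]
    data = {"sample_id": ids, "label": labels.labels}
    if labels.survival_times is not None:
        data["time_years"] = labels.survival_times
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False)


def read_labels(path) -> SurvivalLabels:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "label" not in df.columns or "sample_id" not in df.columns:
        raise DataValidationError(f"{path} must have sample_id and label columns")
    times = df["time_years"].to_numpy(float) if "time_years" in df.columns else None
    return SurvivalLabels(
        labels=df["label"].to_numpy(int),
        sample_ids=[str(i) for i in df["sample_id"]],
        survival_times=times,
    )


def write_cohort(outdir, cfg: SyntheticCohortConfig) -> dict[str, Path]:
    """Generate a cohort and write expression/clinical/labels + config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, clin, surv = generate_synthetic_cohort(cfg)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "labels": outdir / "labels.tsv",
        "config": outdir / "cohort_config.json",
    }
    write_matrix(paths["expression"], expr)
    write_matrix(paths["clinical"], clin)
    write_labels(paths["labels"], surv)
    paths["config"].write_text(
        json.dumps(dataclasses.asdict(cfg), indent=2, sort_keys=True) + "\n"
    )
    return paths
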