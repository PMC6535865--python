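"""Glue between preprocessing, factorization and the classifier.

Two normalization/factorization scopes are supported:

* ``global`` - min-max normalize and factorize the whole cohort once, then
  split (how the original study protocol appears to operate; the default for
  the repeated-split experiments, where refactorizing per repeat would be
  wasteful and the factorization is unsupervised anyway);
* ``train_only`` - compute normalization statistics and factorizations on
  the training rows only, then map validation/test rows with the frozen
  statistics and project them onto each solver's fitted H by nonnegative
  least squares (strict leakage hygiene for a single split).
"""

from __future__ import annotations

import numpy as np

from .datasets import ClinicalMatrix, DatasetSplit, ExpressionMatrix, minmax_normalize
from .fusion import FeatureStack
from .nmf import SOLVER_ORDER, SolverConfig, factorize_all, project_new_samples


def normalize_cohort(
    expr: ExpressionMatrix, clin: ClinicalMatrix,
    mode: str = "global", split: DatasetSplit | None = None,
) -> tuple[ExpressionMatrix, ClinicalMatrix]:
    """Column-wise min-max scale both modalities to [0, 1]."""
    if mode not in ("global", "train_only"):
        raise ValueError("mode must be 'global' or 'train_only'")
    if mode == "train_only":
        if split is None:
            raise ValueError("train_only normalization requires a split")
        tr = split.train_idx
        Ve = minmax_normalize(
            expr.values, mins=expr.values[tr].min(axis=0),
            maxs=expr.values[tr].max(axis=0),
        )
        Vc = minmax_normalize(
            clin.values, mins=clin.values[tr].min(axis=0),
            maxs=clin.values[tr].max(axis=0),
        )
    else:
        Ve = minmax_normalize(expr.values)
        Vc = minmax_normalize(clin.values)
    return (
        ExpressionMatrix(Ve, list(expr.sample_ids), list(expr.gene_ids)),
        ClinicalMatrix(Vc, list(clin.sample_ids), list(clin.feature_names)),
    )


def build_feature_stack(
    expr: ExpressionMatrix, r: int, cfg: SolverConfig | None = None,
    split: DatasetSplit | None = None,
) -> tuple[FeatureStack, dict]:
    """Run the five solvers and stack their W matrices into (m, 5, r).

    With a ``split``, factorization sees only the training rows and the
    remaining rows are projected onto each fitted H (leakage-free mode).
    """
    if split is None:
        facts = factorize_all(expr.values, r, cfg)
        stack = FeatureStack.from_factorizations(facts, sample_ids=expr.sample_ids)
        return stack, facts

    m = expr.n_samples
    train = split.train_idx
    rest = np.setdiff1d(np.arange(m), train)
    facts = factorize_all(expr.values[train], r, cfg)
    stacked = np.empty((m, len(SOLVER_ORDER), r))
    for j, name in enumerate(SOLVER_ORDER):
        f = facts[name]
        stacked[train, j, :] = f.W
        if rest.size:
            stacked[rest, j, :] = project_new_samples(f.H, expr.values[rest])
    return FeatureStack(values=stacked, sample_ids=expr.sample_ids), facts
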