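import numpy as np
import pytest

from multinmf import (
    SolverConfig,
    SyntheticCohortConfig,
    build_feature_stack,
    generate_synthetic_cohort,
    normalize_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact multimodal cohort shared across tests (120 samples)."""
    cfg = SyntheticCohortConfig(m=120, n=80, r0=4, d_c=10, clinical_signal=0.5, seed=3)
    return generate_synthetic_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Normalized cohort + five-solver feature stack at rank 6."""
    expr, clin, surv = small_cohort
    expr_n, clin_n = normalize_cohort(expr, clin)
    stack, facts = build_feature_stack(expr_n, 6, SolverConfig(max_outer_iter=60))
    return {"stack": stack, "clinical": clin_n, "labels": surv,
            "facts": facts, "expr": expr_n}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
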