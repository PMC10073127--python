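import math
from fractions import Fraction

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Independent two-sided Fisher p-value by exact integer enumeration.

    Table weights C(a+b, k) * C(c+d, (a+c)-k) are exact integers, so the
    minimum-likelihood tie comparison is exact; the final division is the
    only floating-point step.
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    weights = {k: math.comb(row1, k) * math.comb(c + d, col1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(num, math.comb(n, col1)))


@pytest.fixture
def tiny_config():
    """Small, fast cohort for pipeline-level tests (seconds, not minutes)."""
    from cnvburden.simulate import default_config, default_risk_deletions

    return default_config(
        seed=7,
        n_case_batch1=30,
        n_case_batch2=20,
        n_control_primary=20,
        n_case_secondary=20,
        n_control_secondary=20,
        background_rate=1.0,
        planted=tuple(default_risk_deletions(2, case_freq=0.9, control_freq=0.05)),
    )


@pytest.fixture
def noiseless_config():
    """Perfect callers: downstream output must equal truth exactly."""
    from cnvburden.simulate import default_config, perfect_caller_models

    return default_config(
        seed=11,
        n_case_batch1=20,
        n_case_batch2=10,
        n_control_primary=10,
        n_case_secondary=10,
        n_control_secondary=10,
        background_rate=1.0,
        callers=tuple(perfect_caller_models()),
    )
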