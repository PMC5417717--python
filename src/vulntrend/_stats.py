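"""Shared two-sample test helpers with explicit zero-variance conventions.

scipy returns NaN for a t-test on two constant samples; for pipeline purposes
we need the conventions "no difference -> p = 1" and "deterministic
difference -> p = 0", applied uniformly across modules.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["two_sample_test", "sem"]


def two_sample_test(a, b, *, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch by default).

    Returns ``(t, p)``. Degenerate cases: if both samples have zero variance,
    equal means give ``(0, 1)`` and unequal means ``(±inf, 0)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test requires at least 2 observations per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        diff = a.mean() - b.mean()
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff)) * float("inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def sem(x) -> float:
    """Standard error of the mean (ddof=1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("SEM requires at least 2 observations")
    return float(x.std(ddof=1) / np.sqrt(x.size))
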