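"""Thin statistical-test utilities: Student t-tests in the variants used
throughout the analyses, plus simple effect sizes."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["t_test", "effect_size_d"]


def t_test(a, b=None, paired: bool = False, alternative: str = "two-sided",
           popmean: float = 0.0):
    """Student's t-test: one/two-sample, paired/independent, one/two-sided.

    Returns (t statistic, p value).  `alternative` in {'two-sided', 'greater',
    'less'} refers to `a` (or `a - b`).
    """
    a = np.asarray(a, dtype=np.float64)
    if b is None:
        res = sps.ttest_1samp(a, popmean, alternative=alternative)
    elif paired:
        res = sps.ttest_rel(a, np.asarray(b, dtype=np.float64),
                            alternative=alternative)
    else:
        res = sps.ttest_ind(a, np.asarray(b, dtype=np.float64),
                            alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def effect_size_d(a, b) -> float:
    """|mean difference| / pooled standard deviation."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        return np.inf if a.mean() != b.mean() else 0.0
    return float(abs(a.mean() - b.mean()) / pooled)
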