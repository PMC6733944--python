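"""Shared statistical core: pooled-variance t-test and Pearson correlation.

The two-tailed unpaired Student's t-test (pooled variance) is the
significance test used across the package — for replicate qPCR
comparisons and for the feature-proximal vs feature-distal contrast.
The degenerate zero-variance cases have defined behaviour: equal constant
vectors give (t=0, p=1); unequal means with zero pooled variance raise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class DegenerateTestError(ValueError):
    """Zero pooled variance with unequal means: the t statistic is undefined."""


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    df: float
    p_value: float


def pooled_ttest(a, b, welch: bool = False) -> TTestResult:
    """Two-tailed unpaired Student's t-test with pooled variance.

    Parameters are the two replicate vectors (each of length >= 2).
    ``welch=True`` switches to the unequal-variance form with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0.0:
            if diff == 0.0:
                return TTestResult(0.0, float(na + nb - 2), 1.0)
            raise DegenerateTestError(
                "zero variance with unequal means; t-test undefined"
            )
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = diff / np.sqrt(se2)
    else:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0.0:
            if diff == 0.0:
                return TTestResult(0.0, float(df), 1.0)
            raise DegenerateTestError(
                "zero pooled variance with unequal means; t-test undefined"
            )
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def pearson_r(xs, ys) -> float:
    """Sample Pearson correlation coefficient.

    Requires at least 3 paired values and non-zero variance in both
    vectors; zero variance raises rather than returning NaN.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size:
        raise ValueError("xs and ys must have equal length")
    if xs.size < 3:
        raise ValueError("need at least 3 pairs")
    if xs.var() == 0.0 or ys.var() == 0.0:
        raise DegenerateTestError("zero variance: correlation undefined")
    return float(sps.pearsonr(xs, ys).statistic)


def permutation_pvalue(a, b, n_shuffles: int = 10_000, seed: int = 0) -> float:
    """Permutation null for the two-sample mean difference (testing aid).

    Shuffles group labels and counts |mean difference| at least as extreme,
    with the +1 small-sample correction.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_shuffles):
        rng.shuffle(pooled)
        if abs(pooled[: a.size].mean() - pooled[a.size :].mean()) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_shuffles + 1)
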