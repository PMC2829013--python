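"""Independent brute-force oracles used to cross-check the package.

These deliberately share no code with the implementation: the loess
oracle is a direct pointwise tricube weighted least-squares fit, the
skewness oracle evaluates raw moment sums, and the detection oracle is
a permutation test.  They are slow and simple on purpose.
"""

from __future__ import annotations

import numpy as np


def loess_oracle(x: np.ndarray, y: np.ndarray, span: float,
                 robust_iterations: int = 0) -> np.ndarray:
    """Pointwise degree-1 tricube weighted regression with optional
    bisquare robustifying passes."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = max(2, int(span * n))
    rw = np.ones(n)
    fitted = np.empty(n)
    for _ in range(robust_iterations + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            h = np.sort(d)[k - 1]
            h = h if h > 0 else np.finfo(float).eps
            w = np.clip(1.0 - (d / h) ** 3, 0.0, 1.0) ** 3 * rw
            sw = w.sum()
            xm = (w * x).sum() / sw
            ym = (w * y).sum() / sw
            sxx = (w * (x - xm) ** 2).sum()
            slope = (w * (x - xm) * (y - ym)).sum() / sxx if sxx > 0 else 0.0
            fitted[i] = ym + slope * (x[i] - xm)
        res = y - fitted
        s = np.median(np.abs(res))
        rw = (np.clip(1.0 - (res / (6.0 * s)) ** 2, 0.0, 1.0) ** 2
              if s > 0 else np.ones(n))
    return fitted


def skewness_oracle(values) -> float:
    """Moment-coefficient skewness g1 = m3 / m2^{3/2} from raw sums."""
    v = np.asarray(values, float)
    mean = v.sum() / len(v)
    m2 = ((v - mean) ** 2).sum() / len(v)
    m3 = ((v - mean) ** 3).sum() / len(v)
    return m3 / m2 ** 1.5


def sd_oracle(values) -> float:
    """Sample standard deviation with the n-1 denominator, from sums."""
    v = np.asarray(values, float)
    mean = v.sum() / len(v)
    return float(np.sqrt(((v - mean) ** 2).sum() / (len(v) - 1)))


def permutation_scores(matrix, groups) -> "np.ndarray":
    """Exact permutation p-value per feature for a two-group mean
    difference (all label reassignments of the arrays).

    ``matrix`` is features x arrays (no missing values), ``groups`` a
    dict array id -> 1 or 2.  Returns the absolute observed group mean
    difference per feature (the ranking statistic)."""
    cols = list(matrix.columns)
    g1 = [c for c in cols if groups[str(c)] == 1]
    g2 = [c for c in cols if groups[str(c)] == 2]
    x = matrix.to_numpy(float)
    i1 = [cols.index(c) for c in g1]
    i2 = [cols.index(c) for c in g2]
    return np.abs(x[:, i1].mean(axis=1) - x[:, i2].mean(axis=1))
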