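"""Between-array cyclic loess normalisation.

Per-array log-ratio vectors L = log2(R/G) from a common-reference
design form a pseudo-direct comparison between any two arrays a and b:

    M_ab = L_a - L_b          (intensity log-ratio)
    A_ab = (L_a + L_b) / 2    (mean log intensity)

A degree-1 loess curve fitted to the MA scatter captures the
intensity-dependent bias (the "banana") between the pair, and the
normalised log-ratio is the residual N_ab = M_ab - loess(A_ab).  The
reverse orientation is N_ba = -N_ab by construction, never refitted.

Running the fit over every unique pair of k arrays (k(k-1)/2 fits) and
averaging, per array a and feature f,

    x_a(f) = (1/n) * sum over b != a of N_ab(f)

where n counts the pairs in which f was measured on both arrays, gives
a single comparable expression matrix.  Cells with n = 0 are missing
(NA).  A final per-array median centering restores M = 0 under the
majority-unchanged assumption.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

logger = logging.getLogger(__name__)

# Counts loess fits performed since the last reset (pair-count audits).
_FIT_COUNT = 0


def fit_count() -> int:
    """Number of loess fits performed since :func:`reset_fit_count`."""
    return _FIT_COUNT


def reset_fit_count() -> None:
    global _FIT_COUNT
    _FIT_COUNT = 0


@dataclass
class CyclicConfig:
    """Parameters of the between-array steps.

    span
        Fraction of the data used for each local loess estimate
        (default 0.3, i.e. 30%).
    robust_iterations
        Bisquare re-weighting passes that downweight outliers —
        differentially expressed genes — so they do not bend the trend.
    min_pair_size
        Smallest feature intersection for which a pairwise fit is
        attempted; smaller pairs are skipped and contribute nothing.
    """

    span: float = 0.3
    do_cyclic_loess: bool = True
    do_final_centering: bool = True
    robust_iterations: int = 3
    min_pair_size: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError("span must lie in (0, 1]")
        if self.robust_iterations < 0:
            raise ValueError("robust_iterations must be >= 0")


@dataclass
class PairwiseResult:
    """MA data and normalised log-ratios for one array pair.

    Orientation is a-over-b; the reverse comparison is -N_ab and is
    never stored.
    """

    array_a: str
    array_b: str
    features: pd.Index
    M: np.ndarray
    A: np.ndarray
    N_ab: np.ndarray


@dataclass
class CyclicResult:
    """Output of :func:`cyclic_normalise`.

    ``matrix`` is the feature x array log2-ratio matrix (NaN = missing);
    ``n`` the per-cell count of pairwise comparisons averaged into it;
    ``pairs`` the fitted :class:`PairwiseResult` objects and
    ``skipped`` the (a, b, shared-feature-count) triples of pairs too
    small to fit.
    """

    matrix: pd.DataFrame
    n: pd.DataFrame
    pairs: list[PairwiseResult] = field(default_factory=list)
    skipped: list[tuple[str, str, int]] = field(default_factory=list)


def loess_fit(x: np.ndarray, y: np.ndarray, span: float = 0.3,
              robust_iterations: int = 3) -> np.ndarray:
    """Loess central trend of y on x, evaluated at each x.

    Degree-1 locally weighted regression with tricube weights over the
    span-fraction nearest neighbours, with ``robust_iterations``
    bisquare re-weighting passes.  Local linear regression reproduces
    any affine trend exactly.  If all x are identical the trend is the
    plain mean of y.
    """
    global _FIT_COUNT
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    _FIT_COUNT += 1
    if np.ptp(x) == 0:
        return np.full_like(y, y.mean())
    # Interpolation grid (delta) only for large inputs, where it is a
    # pure speed optimisation; exactness on affine trends is preserved.
    delta = 0.01 * np.ptp(x) if x.size >= 500 else 0.0
    return _sm_lowess(y, x, frac=span, it=robust_iterations, delta=delta,
                      return_sorted=False)


def ma_transform(L_a: pd.Series, L_b: pd.Series) -> tuple[pd.Index, np.ndarray, np.ndarray]:
    """Shared features and their (M, A) values for an array pair."""
    shared = L_a.index.intersection(L_b.index).sort_values()
    a = L_a.loc[shared].to_numpy(dtype=float)
    b = L_b.loc[shared].to_numpy(dtype=float)
    return shared, a - b, (a + b) / 2.0


def pairwise_normalise(L_a: pd.Series, L_b: pd.Series,
                       config: CyclicConfig = CyclicConfig()) -> PairwiseResult | None:
    """MA-plot loess normalisation of one array pair.

    Returns None (pair skipped) when the feature intersection is
    smaller than ``config.min_pair_size``.
    """
    shared, M, A = ma_transform(L_a, L_b)
    if len(shared) < config.min_pair_size:
        logger.warning("pair (%s, %s) skipped: only %d shared features",
                       L_a.name, L_b.name, len(shared))
        return None
    trend = loess_fit(A, M, span=config.span,
                      robust_iterations=config.robust_iterations)
    return PairwiseResult(array_a=str(L_a.name), array_b=str(L_b.name),
                          features=shared, M=M, A=A, N_ab=M - trend)


def cyclic_normalise(vectors: list[pd.Series],
                     config: CyclicConfig = CyclicConfig()) -> CyclicResult:
    """All-pairs cyclic loess over k preprocessed array vectors.

    Every unordered pair is fitted once in a canonical orientation
    (lexicographically smaller array id first) so that N_ba = -N_ab
    holds identically and results do not depend on input order.  With
    ``do_cyclic_loess`` disabled the input vectors are assembled into a
    matrix unchanged (absent features = NA).
    """
    if len(vectors) < 2:
        raise ValueError("cyclic normalisation needs at least 2 arrays")
    ids = [str(v.name) for v in vectors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate array ids in input vectors")
    features = pd.Index(sorted(set().union(*[v.index for v in vectors])),
                        name="feature_id")

    if not config.do_cyclic_loess:
        matrix = pd.DataFrame(np.nan, index=features, columns=ids)
        n = pd.DataFrame(0, index=features, columns=ids, dtype=int)
        for v in vectors:
            matrix.loc[v.index, str(v.name)] = v.to_numpy(dtype=float)
            n.loc[v.index, str(v.name)] = 1
        return CyclicResult(matrix=matrix, n=n)

    by_id = {str(v.name): v for v in vectors}
    sums = pd.DataFrame(0.0, index=features, columns=ids)
    counts = pd.DataFrame(0, index=features, columns=ids, dtype=int)
    pairs: list[PairwiseResult] = []
    skipped: list[tuple[str, str, int]] = []

    for id_a, id_b in itertools.combinations(sorted(ids), 2):
        res = pairwise_normalise(by_id[id_a], by_id[id_b], config)
        if res is None:
            shared = by_id[id_a].index.intersection(by_id[id_b].index)
            skipped.append((id_a, id_b, len(shared)))
            continue
        pairs.append(res)
        n_ab = pd.Series(res.N_ab, index=res.features)
        sums.loc[res.features, id_a] += n_ab
        sums.loc[res.features, id_b] -= n_ab  # N_ba = -N_ab
        counts.loc[res.features, id_a] += 1
        counts.loc[res.features, id_b] += 1

    with np.errstate(invalid="ignore"):
        matrix = sums / counts.where(counts > 0)
    logger.info("cyclic loess: %d pairs fitted, %d skipped",
                len(pairs), len(skipped))
    return CyclicResult(matrix=matrix, n=counts, pairs=pairs, skipped=skipped)


def center_arrays(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each array's median so every array has median M = 0.

    Medians are taken over non-missing values; missing cells stay
    missing.  An all-missing array is an error.
    """
    empty = matrix.columns[matrix.isna().all(axis=0)]
    if len(empty):
        raise ValueError("array(s) with no non-missing values: "
                         + ", ".join(map(str, empty)))
    return matrix - matrix.median(axis=0, skipna=True)
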