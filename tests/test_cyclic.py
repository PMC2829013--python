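"""Between-array cyclic loess: the loess primitive, pairwise MA
normalisation, all-pairs averaging with NA bookkeeping, and final
centering."""

import numpy as np
import pandas as pd
import pytest

from cycloess.cyclic import (
    CyclicConfig,
    center_arrays,
    cyclic_normalise,
    fit_count,
    loess_fit,
    ma_transform,
    pairwise_normalise,
    reset_fit_count,
)

from conftest import random_vectors
from oracles import loess_oracle


class TestLoessFit:
    def test_zero_function(self):
        x = np.linspace(-3, 3, 30)
        assert np.allclose(loess_fit(x, np.zeros_like(x)), 0.0)

    def test_affine_trend_exact(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(-10, 10, 60))
        y = 2.0 * x + 1.0
        assert np.allclose(loess_fit(x, y, span=0.4), y, atol=1e-9)

    def test_constant_x_falls_back_to_mean(self):
        x = np.full(12, 3.0)
        y = np.arange(12.0)
        assert np.allclose(loess_fit(x, y), y.mean())

    @pytest.mark.parametrize("span,it", [(0.9, 0), (0.3, 0), (0.4, 3)])
    def test_matches_weighted_regression_oracle(self, span, it):
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(-50, 50, 90))
        y = 0.01 * x ** 2 + np.sin(x / 8) + rng.normal(0, 0.3, 90)
        fitted = loess_fit(x, y, span=span, robust_iterations=it)
        oracle = loess_oracle(x, y, span=span, robust_iterations=it)
        assert np.abs(fitted - oracle).max() < 1e-8

    def test_quadratic_small_grid_vs_oracle(self):
        x = np.linspace(-2, 2, 21)
        y = x ** 2
        fitted = loess_fit(x, y, span=0.9, robust_iterations=0)
        oracle = loess_oracle(x, y, span=0.9, robust_iterations=0)
        assert np.abs(fitted - oracle).max() < 1e-10


class TestPairwise:
    def test_identical_arrays_normalise_to_zero(self):
        v = random_vectors(1, 50, seed=2)[0]
        w = v.copy()
        w.name = "arr_b"
        res = pairwise_normalise(v, w)
        assert np.allclose(res.N_ab, 0.0, atol=1e-12)

    def test_constant_offset_removed(self):
        v = random_vectors(1, 50, seed=3)[0]
        w = v + 0.75
        w.name = "arr_b"
        res = pairwise_normalise(v, w)
        assert np.allclose(res.M, -0.75)
        assert np.allclose(res.N_ab, 0.0, atol=1e-9)

    def test_antisymmetry_by_independent_recomputation(self):
        a, b = random_vectors(2, 80, seed=4)
        n_ab = pairwise_normalise(a, b).N_ab
        n_ba = pairwise_normalise(b, a).N_ab
        # both orientations refitted independently: M and A are exact
        # mirrors, so the fits coincide and N_ab + N_ba = 0
        assert np.abs(n_ab + n_ba).max() == 0.0

    def test_ma_quantities(self):
        a = pd.Series([2.0], index=["f"], name="a")
        b = pd.Series([1.0], index=["f"], name="b")
        _, M, A = ma_transform(a, b)
        assert M[0] == 1.0 and A[0] == 1.5

    def test_small_intersection_skipped(self):
        a = pd.Series([1.0, 2.0], index=["f1", "f2"], name="a")
        b = pd.Series([1.0, 2.0], index=["f1", "f3"], name="b")
        assert pairwise_normalise(a, b, CyclicConfig(min_pair_size=5)) is None


class TestCyclicNormalise:
    def test_pair_count_k_choose_2(self):
        for k in (2, 3, 5):
            vectors = random_vectors(k, 40, seed=k)
            reset_fit_count()
            res = cyclic_normalise(vectors)
            assert fit_count() == k * (k - 1) // 2
            assert len(res.pairs) == k * (k - 1) // 2

    def test_three_array_n_bookkeeping(self):
        # feature set: 30 shared everywhere, one feature only on a and b
        vectors = random_vectors(3, 30, seed=6)
        a, b, c = vectors
        a.loc["only_ab"] = 0.3
        b.loc["only_ab"] = -0.2
        res = cyclic_normalise([a, b, c])
        # shared features: two comparisons each
        assert (res.n.loc["g0000"] == 2).all()
        # feature on a and b only: n=1 there, NA on c
        assert res.n.loc["only_ab", "arr_a"] == 1
        assert res.n.loc["only_ab", "arr_b"] == 1
        assert res.n.loc["only_ab", "arr_c"] == 0
        assert np.isnan(res.matrix.loc["only_ab", "arr_c"])
        # and the averaging matches the stored pairwise results
        by_pair = {(p.array_a, p.array_b): p for p in res.pairs}
        n_ab = pd.Series(by_pair[("arr_a", "arr_b")].N_ab,
                         index=by_pair[("arr_a", "arr_b")].features)
        n_ac = pd.Series(by_pair[("arr_a", "arr_c")].N_ab,
                         index=by_pair[("arr_a", "arr_c")].features)
        f = "g0005"
        expected = (n_ab[f] + n_ac[f]) / 2
        assert res.matrix.loc[f, "arr_a"] == pytest.approx(expected, abs=1e-12)

    def test_n_matches_brute_force_presence_count(self):
        rng = np.random.default_rng(9)
        vectors = random_vectors(4, 60, seed=9)
        # drop random feature subsets per array
        vectors = [v.drop(v.sample(frac=0.3, random_state=i).index)
                   for i, v in enumerate(vectors)]
        res = cyclic_normalise(vectors, CyclicConfig(min_pair_size=2))
        presence = {str(v.name): set(v.index) for v in vectors}
        ids = list(presence)
        for f in res.n.index:
            for a in ids:
                expected = sum(
                    1 for b in ids if b != a
                    and f in presence[a] and f in presence[b])
                assert res.n.loc[f, a] == expected
                assert np.isnan(res.matrix.loc[f, a]) == (expected == 0)

    def test_array_order_invariance(self):
        vectors = random_vectors(4, 50, seed=11)
        m1 = cyclic_normalise(vectors).matrix
        m2 = cyclic_normalise(vectors[::-1]).matrix
        pd.testing.assert_frame_equal(m1, m2[m1.columns])

    def test_disabled_cyclic_passes_vectors_through(self):
        vectors = random_vectors(3, 30, seed=12)
        res = cyclic_normalise(vectors, CyclicConfig(do_cyclic_loess=False))
        for v in vectors:
            assert np.allclose(res.matrix.loc[v.index, str(v.name)], v.values)

    def test_fewer_than_two_arrays_rejected(self):
        with pytest.raises(ValueError):
            cyclic_normalise(random_vectors(1, 30))

    def test_results_vary_smoothly_with_span(self):
        vectors = random_vectors(3, 200, seed=13)
        mats = {s: cyclic_normalise(vectors, CyclicConfig(span=s)).matrix
                for s in (0.2, 0.3, 0.5)}
        d_near = np.nanmax(np.abs(mats[0.2] - mats[0.3]).to_numpy())
        d_far = np.nanmax(np.abs(mats[0.2] - mats[0.5]).to_numpy())
        assert d_near < 0.5 and d_near <= d_far + 1e-12


class TestCenterArrays:
    def test_median_subtracted(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0]}, index=list("xyz"))
        out = center_arrays(m)
        assert list(out["a"]) == [-1.0, 0.0, 1.0]

    def test_missing_aware_median(self):
        m = pd.DataFrame({"a": [0.5, np.nan, 1.5]}, index=list("xyz"))
        out = center_arrays(m)
        assert out["a"].iloc[0] == -0.5 and np.isnan(out["a"].iloc[1])

    def test_idempotent_on_centred_data(self):
        m = pd.DataFrame({"a": [-1.0, 0.0, 1.0]}, index=list("xyz"))
        pd.testing.assert_frame_equal(center_arrays(m), m)

    def test_all_missing_array_raises(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]},
                         index=list("xy"))
        with pytest.raises(ValueError, match="b"):
            center_arrays(m)

    def test_every_array_median_zero_after(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(1, 2, (41, 5)))
        out = center_arrays(m)
        assert np.abs(out.median(axis=0).to_numpy()).max() == 0.0
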