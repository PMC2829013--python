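"""Within-array preprocessing: correction, filtering, channel roles,
block centering and duplicate averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cycloess.arrayio import (
    EXCL_BACKGROUND,
    EXCL_EMPTY_NAME,
    EXCL_NONPOSITIVE,
    EXCL_SOFTWARE_FLAG,
    read_bluefuse,
    read_genepix,
)
from cycloess.preprocess import (
    PreprocessConfig,
    apply_exclusions,
    average_duplicates,
    background_correct,
    center_blocks,
    compute_log_ratios,
    detect_reference_channel,
    preprocess_array,
)

from conftest import make_bluefuse, make_gpr


def gpr_array(rows, **kw):
    return read_genepix(make_gpr(rows, **kw), "test")


class TestBackgroundCorrect:
    def test_subtraction_per_channel(self):
        t = gpr_array([(1, 1, 1, "g1", 1000, 100, 10, 800, 50, 5, 0)])
        c = background_correct(t)
        assert c.data.loc[0, "fg1"] == 900 and c.data.loc[0, "fg2"] == 750

    def test_bluefuse_passthrough(self):
        t = read_bluefuse(make_bluefuse([(1, 1, 1, "g1", 400.0, 300.0, "A")]))
        c = background_correct(t)
        assert (c.data.loc[0, "fg1"], c.data.loc[0, "fg2"]) == (400.0, 300.0)

    def test_correction_may_go_negative(self):
        t = gpr_array([(1, 1, 1, "g1", 90, 100, 10, 500, 50, 5, 0)])
        c = background_correct(t)
        assert c.data.loc[0, "fg1"] == -10


class TestExclusions:
    def test_background_filter_threshold(self):
        # F=400 < B + 3*SD = 100 + 330 -> excluded
        t = gpr_array([(1, 1, 1, "g1", 400, 100, 110, 5000, 100, 10, 0)])
        e = apply_exclusions(background_correct(t), PreprocessConfig(k_sd=3))
        assert e.data.loc[0, "exclusion_reason"] == EXCL_BACKGROUND

    def test_control_prefix_name(self):
        t = gpr_array([(1, 1, 1, "ctrl-spike7", 5000, 100, 10, 5000, 100, 10, 0)])
        e = apply_exclusions(background_correct(t))
        assert e.data.loc[0, "exclusion_reason"] == EXCL_EMPTY_NAME

    def test_software_flag_wins(self):
        t = gpr_array([(1, 1, 1, "g1", 9000, 100, 10, 9000, 100, 10, -75)])
        e = apply_exclusions(background_correct(t))
        assert e.data.loc[0, "exclusion_reason"] == EXCL_SOFTWARE_FLAG

    def test_bluefuse_quality_E(self):
        t = read_bluefuse(make_bluefuse([(1, 1, 1, "g1", 400.0, 300.0, "E"),
                                         (1, 2, 1, "g2", 400.0, 300.0, "A")]))
        e = apply_exclusions(background_correct(t))
        assert e.data.loc[0, "exclusion_reason"] == EXCL_SOFTWARE_FLAG
        assert not e.data.loc[1, "excluded"]

    def test_exact_empty_name_not_prefix(self):
        # 'EMPTY' matches exactly; 'EMPTY2' does not
        rows = [(1, 1, 1, "EMPTY", 5000, 100, 10, 5000, 100, 10, 0),
                (1, 2, 1, "EMPTY2", 5000, 100, 10, 6000, 100, 10, 0)]
        e = apply_exclusions(background_correct(gpr_array(rows)))
        assert e.data.loc[0, "excluded"] and not e.data.loc[1, "excluded"]

    @settings(max_examples=30, deadline=None)
    @given(
        fg=st.floats(150, 5000), bg=st.floats(10, 140),
        bg_sd=st.floats(1, 100),
        k1=st.floats(0.5, 5), delta=st.floats(0.1, 5),
    )
    def test_raising_k_sd_never_unexcludes(self, fg, bg, bg_sd, k1, delta):
        rows = [(1, 1, 1, "g1", fg, bg, bg_sd, 5000, 10, 1, 0)]
        t = background_correct(gpr_array(rows))
        lo = apply_exclusions(t, PreprocessConfig(k_sd=k1))
        hi = apply_exclusions(t, PreprocessConfig(k_sd=k1 + delta))
        if lo.data.loc[0, "excluded"]:
            assert hi.data.loc[0, "excluded"]


class TestReferenceDetection:
    rows_ref_ch1 = [
        (1, 1, 1, "g1", 5100, 100, 10, 900, 100, 10, 0),
        (1, 2, 1, "g2", 5200, 100, 10, 950, 100, 10, 0),
        (1, 3, 1, "g3", 4900, 100, 10, 800, 100, 10, 0),
    ]

    def test_higher_median_is_reference(self):
        t = detect_reference_channel(
            apply_exclusions(background_correct(gpr_array(self.rows_ref_ch1))))
        assert t.reference_channel == 1 and t.signal_channel == 2

    def test_dye_swap_detected(self):
        swapped = [(b, c, r, n, f2, b2, s2, f1, b1, s1, fl)
                   for (b, c, r, n, f1, b1, s1, f2, b2, s2, fl)
                   in self.rows_ref_ch1]
        t = detect_reference_channel(
            apply_exclusions(background_correct(gpr_array(swapped))))
        assert t.reference_channel == 2

    def test_swapping_channels_gives_identical_vectors(self):
        straight = preprocess_array(gpr_array(self.rows_ref_ch1)).vector
        swapped_rows = [(b, c, r, n, f2, b2, s2, f1, b1, s1, fl)
                        for (b, c, r, n, f1, b1, s1, f2, b2, s2, fl)
                        in self.rows_ref_ch1]
        swapped = preprocess_array(gpr_array(swapped_rows)).vector
        pd.testing.assert_series_equal(straight, swapped)

    def test_median_tie_raises(self):
        rows = [(1, 1, 1, "g1", 1100, 100, 10, 1100, 100, 10, 0)]
        with pytest.raises(ValueError, match="fixed_reference_channel"):
            detect_reference_channel(
                apply_exclusions(background_correct(gpr_array(rows))))

    def test_fixed_reference_channel(self):
        t = detect_reference_channel(
            apply_exclusions(background_correct(gpr_array(self.rows_ref_ch1))),
            PreprocessConfig(auto_reference=False, fixed_reference_channel=2))
        assert t.reference_channel == 2 and t.signal_channel == 1


class TestLogRatiosAndBlocks:
    def test_log2_of_two_is_one(self):
        rows = [(1, 1, 1, "g1", 900, 100, 10, 8100, 100, 10, 0),
                (1, 2, 1, "g2", 4100, 100, 10, 8100, 100, 10, 0)]
        t = detect_reference_channel(
            apply_exclusions(background_correct(gpr_array(rows))))
        t, ratios = compute_log_ratios(t)
        # reference is channel 2 (brighter); g2: log2(4000/8000) = -1
        vals = dict(zip(ratios["feature_id"], ratios["value"]))
        assert vals["g2"] == pytest.approx(-1.0)

    def test_nonpositive_intensity_excluded(self):
        # BlueFuse amplitudes can be <= 0 (no background filter there)
        t = read_bluefuse(make_bluefuse([(1, 1, 1, "g1", -10.0, 400.0, "A"),
                                         (1, 2, 1, "g2", 200.0, 400.0, "A"),
                                         (1, 3, 1, "g3", 100.0, 400.0, "A")]))
        t = detect_reference_channel(
            apply_exclusions(background_correct(t)))
        t, ratios = compute_log_ratios(t)
        assert t.data.loc[0, "exclusion_reason"] == EXCL_NONPOSITIVE
        assert "g1" not in set(ratios["feature_id"])

    def test_block_median_subtraction(self):
        df = pd.DataFrame({"block": [1, 1, 1], "feature_id": list("abc"),
                           "value": [1.0, 2.0, 3.0]})
        out = center_blocks(df)
        assert list(out["value"]) == [-1.0, 0.0, 1.0]

    def test_blocks_centred_independently(self):
        df = pd.DataFrame({
            "block": [1, 1, 1, 2, 2, 2],
            "feature_id": list("abcdef"),
            "value": [0.0, 0.0, 4.0, 10.0, 10.0, 10.0],
        })
        out = center_blocks(df)
        assert list(out["value"]) == [0.0, 0.0, 4.0, 0.0, 0.0, 0.0]

    def test_singleton_block_centres_to_zero(self):
        df = pd.DataFrame({"block": [3], "feature_id": ["a"], "value": [5.0]})
        assert center_blocks(df)["value"].iloc[0] == 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-8, 8), min_size=1, max_size=40),
           st.integers(1, 4))
    def test_every_block_median_exactly_zero(self, values, n_blocks):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "block": rng.integers(1, n_blocks + 1, len(values)),
            "feature_id": [f"g{i}" for i in range(len(values))],
            "value": values,
        })
        out = center_blocks(df)
        for _, grp in out.groupby("block"):
            assert grp["value"].median() == pytest.approx(0.0, abs=1e-12)


class TestAverageDuplicates:
    def test_mean_singleton_and_absent(self):
        df = pd.DataFrame({
            "block": [1] * 3, "feature_id": ["X", "X", "Y"],
            "value": [1.0, 3.0, 0.7],
        })
        vec = average_duplicates(df, "a1")
        assert vec["X"] == 2.0 and vec["Y"] == 0.7
        assert "Z" not in vec.index
        assert vec.name == "a1"

    def test_output_size_counts_distinct_surviving_features(self):
        rows = [(1, 1, 1, "gA", 900, 100, 10, 8100, 100, 10, 0),
                (1, 2, 1, "gA", 1100, 100, 10, 8100, 100, 10, 0),
                (1, 3, 1, "gB", 2100, 100, 10, 8100, 100, 10, 0),
                (1, 4, 1, "gC", 2100, 100, 10, 8100, 100, 10, -100)]
        res = preprocess_array(gpr_array(rows))
        assert set(res.vector.index) == {"gA", "gB"}
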