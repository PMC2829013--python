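"""Shared fixture builders: tiny vendor files generated in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def make_gpr(rows, wavelengths=("635", "532"), n_header_records=2):
    """Render spot rows as a GPR (ATF 1.0) text.

    Each row: (block, column, row, name, f1, b1, sd1, f2, b2, sd2, flag)
    with channel 1 written under the first wavelength in ``wavelengths``.
    """
    w1, w2 = wavelengths
    cols = ["Block", "Column", "Row", "Name",
            f"F{w1} Median", f"B{w1} Median", f"B{w1} SD",
            f"F{w2} Median", f"B{w2} Median", f"B{w2} SD", "Flags"]
    lines = ["ATF\t1.0", f"{n_header_records}\t{len(cols)}"]
    lines += ['"Type=GenePix Results 3"', '"Scanner=test"'][:n_header_records]
    lines.append("\t".join(cols))
    for r in rows:
        lines.append("\t".join(str(v) for v in r))
    return "\n".join(lines) + "\n"


def make_bluefuse(rows, preamble=True, name_col="NAME", qual_col="FLAG"):
    """Render spot rows as BlueFuse text.

    Each row: (block, col, row, name, amp1, amp2, quality_letter).
    """
    lines = []
    if preamble:
        lines += ["SlideName\ttest_slide", "Version\t3.2"]
    lines.append("\t".join(["BLOCK", "SUBGRIDCOL", "SUBGRIDROW",
                            name_col, "AMPCH1", "AMPCH2", qual_col]))
    for r in rows:
        lines.append("\t".join(str(v) for v in r))
    return "\n".join(lines) + "\n"


def gpr_rows_from_vector(values, reference=4000.0, bg=100.0, bg_sd=10.0):
    """Spot rows whose preprocessed log2 ratios reproduce ``values``.

    ``values`` maps feature_id -> desired log2(signal/reference) before
    block centering; everything lands in block 1.
    """
    rows = []
    for i, (feat, v) in enumerate(values.items()):
        sig = reference * 2.0 ** v
        rows.append((1, i % 100 + 1, i // 100 + 1, feat,
                     sig + bg, bg, bg_sd, reference + bg, bg, bg_sd, 0))
    return rows


@pytest.fixture
def simple_gpr():
    """A 4-spot single-block GenePix file with one flagged spot."""
    rows = [
        (1, 1, 1, "geneA", 1000, 100, 10, 4100, 100, 10, 0),
        (1, 2, 1, "geneB", 2100, 100, 10, 4100, 100, 10, 0),
        (1, 1, 2, "geneC", 8100, 100, 10, 4100, 100, 10, 0),
        (1, 2, 2, "geneD", 1600, 100, 10, 4100, 100, 10, -50),
    ]
    return make_gpr(rows)


def random_vectors(n_arrays=4, n_features=120, seed=0, sd=0.5):
    """Preprocessed-style feature vectors with random values."""
    rng = np.random.default_rng(seed)
    feats = [f"g{i:04d}" for i in range(n_features)]
    return [pd.Series(rng.normal(0, sd, n_features), index=feats,
                      name=f"arr_{chr(97 + i)}") for i in range(n_arrays)]
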