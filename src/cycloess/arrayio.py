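"""Readers and writers for two-colour microarray image-analysis files.

Supports GenePix Results files (GPR, in Axon Text File format) and
BlueFuse tab-delimited output, parsed into a common spot-level table so
that downstream normalisation never needs a gene-array-layout (.gal)
file: the spatial information (block / column / row) is taken from the
result files themselves.

From a GPR file only the per-channel median foreground, median
background and background SD columns are read, together with Block,
Column, Row, the feature name and the Flags column.  From a BlueFuse
file the AMPCH1/AMPCH2 amplitudes (already background-corrected by the
BlueFuse software) are read together with BLOCK, SUBGRIDCOL and
SUBGRIDROW, the feature name and the spot-quality letter.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass
from typing import Iterator, Optional, TextIO, Union

import numpy as np
import pandas as pd

GENEPIX = "genepix"
BLUEFUSE = "bluefuse"

#: exclusion_reason vocabulary
EXCL_NONE = "none"
EXCL_SOFTWARE_FLAG = "software_flag"
EXCL_EMPTY_NAME = "empty_name"
EXCL_BACKGROUND = "background_filter"
EXCL_NONPOSITIVE = "nonpositive_intensity"


class FormatError(ValueError):
    """Raised when a file cannot be recognised as GenePix or BlueFuse."""


class ParseError(ValueError):
    """Raised when a recognised file violates its dialect."""


@dataclass
class SpotRecord:
    """One physical spot on an array.

    ``fg`` holds the two foreground channel intensities (for BlueFuse
    these are the background-corrected amplitudes and ``bg``/``bg_sd``
    are ``None``).  Coordinates are 1-based, matching both vendors.
    """

    block: int
    column: int
    row: int
    feature_id: str
    fg: tuple[float, float]
    bg: Optional[tuple[float, float]] = None
    bg_sd: Optional[tuple[float, float]] = None
    flag: Union[int, str] = 0
    excluded: bool = False
    exclusion_reason: str = EXCL_NONE


# Canonical column set of ArrayTable.data.  fg1/fg2 are mutated in place
# by background correction; fg1_raw/fg2_raw keep the as-read values for
# the background filter.
_COLUMNS = [
    "block", "column", "row", "feature_id",
    "fg1", "fg2", "bg1", "bg2", "bg_sd1", "bg_sd2",
    "flag", "excluded", "exclusion_reason",
]


@dataclass
class ArrayTable:
    """All spots of one scanned array plus metadata.

    ``data`` is a DataFrame with one row per spot (columns listed in
    ``_COLUMNS``); ``signal_channel``/``reference_channel`` are None
    until channel roles are assigned by the preprocessing step.
    """

    array_id: str
    format: str
    data: pd.DataFrame
    signal_channel: Optional[int] = None
    reference_channel: Optional[int] = None

    def __post_init__(self) -> None:
        dup = self.data.duplicated(subset=["block", "column", "row"])
        if dup.any():
            first = self.data.loc[dup, ["block", "column", "row"]].iloc[0]
            raise ParseError(
                f"{self.array_id}: duplicated spot coordinates "
                f"(block={first['block']}, column={first['column']}, "
                f"row={first['row']})"
            )

    @property
    def n_spots(self) -> int:
        return len(self.data)

    def spots(self) -> Iterator[SpotRecord]:
        """Yield the table as SpotRecord objects (convenience view)."""
        has_bg = self.format == GENEPIX
        for rec in self.data.itertuples(index=False):
            yield SpotRecord(
                block=int(rec.block), column=int(rec.column), row=int(rec.row),
                feature_id=rec.feature_id,
                fg=(float(rec.fg1), float(rec.fg2)),
                bg=(float(rec.bg1), float(rec.bg2)) if has_bg else None,
                bg_sd=(float(rec.bg_sd1), float(rec.bg_sd2)) if has_bg else None,
                flag=rec.flag, excluded=bool(rec.excluded),
                exclusion_reason=rec.exclusion_reason,
            )

    def copy(self) -> "ArrayTable":
        return ArrayTable(
            array_id=self.array_id, format=self.format,
            data=self.data.copy(),
            signal_channel=self.signal_channel,
            reference_channel=self.reference_channel,
        )


def _first_header_line(content: str) -> str:
    for line in content.splitlines():
        if line.strip():
            return line
    return ""


def detect_format(content: str) -> str:
    """Classify file content as ``genepix`` or ``bluefuse``.

    GenePix results are recognised by the ATF signature (or a header row
    with GenePix column names); BlueFuse by its AMPCH1/AMPCH2 +
    BLOCK/SUBGRIDCOL/SUBGRIDROW column header.
    """
    first = _first_header_line(content)
    if not first:
        raise FormatError("empty file: cannot detect format")
    if first.startswith("ATF"):
        return GENEPIX
    for line in content.splitlines():
        fields = {f.strip().strip('"').upper() for f in line.split("\t")}
        if {"AMPCH1", "AMPCH2", "BLOCK", "SUBGRIDCOL", "SUBGRIDROW"} <= fields:
            return BLUEFUSE
        if {"BLOCK", "COLUMN", "ROW", "FLAGS"} <= fields and any(
            re.match(r"F\S+ MEDIAN", f) for f in fields
        ):
            return GENEPIX
    raise FormatError(
        f"unrecognised microarray file format; first header line: {first!r}"
    )


def _read_table(content: str, header_idx: int) -> pd.DataFrame:
    buf = _io.StringIO("\n".join(content.splitlines()[header_idx:]))
    df = pd.read_csv(buf, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().strip('"') for c in df.columns]
    return df


def _numeric(df: pd.DataFrame, col: str, fname: str) -> np.ndarray:
    vals = pd.to_numeric(df[col].str.strip(), errors="coerce")
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna())[0])
        raise ParseError(
            f"{fname}: non-numeric value {df[col].iloc[row]!r} in column "
            f"{col!r} at data row {row + 1}"
        )
    return vals.to_numpy(dtype=float)


def read_genepix(content: str, array_id: str = "array") -> ArrayTable:
    """Parse a GenePix GPR (ATF) file into an :class:`ArrayTable`.

    Channel 1 is the first wavelength encountered in header order
    (whatever its name: ``F635 Median`` or ``F Cy5 Median`` etc.),
    channel 2 the second.  Flags are preserved verbatim; no exclusion
    decisions are taken here.
    """
    lines = content.splitlines()
    if not lines or not lines[0].strip():
        raise FormatError(f"{array_id}: empty file")
    header_idx = 0
    if lines[0].startswith("ATF"):
        # ATF preamble: "ATF<TAB>1.0", then "<n optional records><TAB><n cols>"
        try:
            n_opt = int(lines[1].split("\t")[0])
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{array_id}: malformed ATF count line") from exc
        header_idx = 2 + n_opt
    df = _read_table(content, header_idx)

    def find(*names: str) -> Optional[str]:
        lower = {c.lower(): c for c in df.columns}
        for n in names:
            if n.lower() in lower:
                return lower[n.lower()]
        return None

    block, col, row = find("Block"), find("Column"), find("Row")
    name = find("Name", "ID", "Gene")
    flags = find("Flags", "Flag")
    fg_cols = [c for c in df.columns if re.fullmatch(r"F(.+) Median", c)]
    missing = [lbl for lbl, c in
               [("Block", block), ("Column", col), ("Row", row),
                ("Name/ID", name), ("Flags", flags)] if c is None]
    if len(fg_cols) < 2:
        missing.append("two 'F<wavelength> Median' columns")
    if missing:
        raise ParseError(f"{array_id}: missing required column(s): "
                         + ", ".join(missing))
    waves = [re.fullmatch(r"F(.+) Median", c).group(1) for c in fg_cols[:2]]
    bg_cols, sd_cols = [], []
    for w in waves:
        b, s = find(f"B{w} Median"), find(f"B{w} SD")
        if b is None or s is None:
            raise ParseError(
                f"{array_id}: missing background column(s) for wavelength {w}"
            )
        bg_cols.append(b)
        sd_cols.append(s)

    out = pd.DataFrame({
        "block": _numeric(df, block, array_id).astype(int),
        "column": _numeric(df, col, array_id).astype(int),
        "row": _numeric(df, row, array_id).astype(int),
        "feature_id": df[name].str.strip().str.strip('"'),
        "fg1": _numeric(df, fg_cols[0], array_id),
        "fg2": _numeric(df, fg_cols[1], array_id),
        "bg1": _numeric(df, bg_cols[0], array_id),
        "bg2": _numeric(df, bg_cols[1], array_id),
        "bg_sd1": _numeric(df, sd_cols[0], array_id),
        "bg_sd2": _numeric(df, sd_cols[1], array_id),
        "flag": pd.to_numeric(df[flags].str.strip(), errors="coerce")
                  .fillna(0).astype(int),
        "excluded": False,
        "exclusion_reason": EXCL_NONE,
    })
    return ArrayTable(array_id=array_id, format=GENEPIX, data=out)


def read_bluefuse(content: str, array_id: str = "array") -> ArrayTable:
    """Parse a BlueFuse results file into an :class:`ArrayTable`.

    An optional ``key<TAB>value`` preamble is skipped; the column-header
    line is the first line containing a BLOCK field.  ``fg`` holds the
    (AMPCH1, AMPCH2) amplitudes; background columns are absent because
    BlueFuse background-corrects internally.
    """
    lines = content.splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        fields = {f.strip().strip('"').upper() for f in line.split("\t")}
        if "BLOCK" in fields and "AMPCH1" in fields:
            header_idx = i
            break
    if header_idx is None:
        raise FormatError(
            f"{array_id}: no BlueFuse column header (BLOCK + AMPCH1) found"
        )
    df = _read_table(content, header_idx)
    upper = {c.upper(): c for c in df.columns}

    def find(*names: str) -> Optional[str]:
        for n in names:
            if n in upper:
                return upper[n]
        return None

    required = ["BLOCK", "SUBGRIDCOL", "SUBGRIDROW", "AMPCH1", "AMPCH2"]
    missing = [n for n in required if n not in upper]
    name = find("NAME", "ID", "GENE")
    qual = find("FLAG", "CONFIDENCE", "QUALITY")
    if name is None:
        missing.append("NAME/ID/GENE")
    if qual is None:
        missing.append("FLAG/CONFIDENCE/QUALITY")
    if missing:
        raise ParseError(f"{array_id}: missing required column(s): "
                         + ", ".join(missing))

    out = pd.DataFrame({
        "block": _numeric(df, upper["BLOCK"], array_id).astype(int),
        "column": _numeric(df, upper["SUBGRIDCOL"], array_id).astype(int),
        "row": _numeric(df, upper["SUBGRIDROW"], array_id).astype(int),
        "feature_id": df[name].str.strip().str.strip('"'),
        "fg1": _numeric(df, upper["AMPCH1"], array_id),
        "fg2": _numeric(df, upper["AMPCH2"], array_id),
        "bg1": np.nan, "bg2": np.nan, "bg_sd1": np.nan, "bg_sd2": np.nan,
        "flag": df[qual].str.strip(),
        "excluded": False,
        "exclusion_reason": EXCL_NONE,
    })
    return ArrayTable(array_id=array_id, format=BLUEFUSE, data=out)


def read_array(content: str, array_id: str = "array") -> ArrayTable:
    """Detect the format of ``content`` and dispatch to the right parser."""
    fmt = detect_format(content)
    reader = read_genepix if fmt == GENEPIX else read_bluefuse
    return reader(content, array_id=array_id)


def write_matrix(matrix: pd.DataFrame,
                 destination: Union[str, TextIO]) -> None:
    """Write a feature x array log2-ratio matrix as tab-separated text.

    The header row carries the array IDs (first cell names the feature
    column); missing cells are rendered as the literal ``NA``.  The
    rendering round-trips losslessly through :func:`read_matrix`.
    """
    out = matrix.copy()
    out.index.name = "Feature"
    out.to_csv(destination, sep="\t", na_rep="NA")


def read_matrix(source: Union[str, TextIO]) -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix` (NA -> NaN)."""
    df = pd.read_csv(source, sep="\t", index_col=0,
                     na_values=["NA"], keep_default_na=False)
    df.index.name = "Feature"
    df.index = df.index.astype(str)
    return df
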