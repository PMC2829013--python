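"""Within-array preprocessing for common-reference two-colour arrays.

Five steps, applied per array:

1. background correction (GenePix only: median foreground minus median
   background per channel; BlueFuse amplitudes arrive already corrected),
2. exclusion of unusable spots (vendor software flags, empty/control
   feature names, and a statistical background filter that keeps only
   spots whose foreground exceeds the background by ``k_sd`` background
   standard deviations),
3. automatic reference-channel detection — the common genomic-DNA
   reference channel has the higher median intensity, which makes
   log-ratios orientation-consistent even across accidental dye-swaps,
4. log2(signal/reference) per spot, median-centred block by block
   (print-tip group by print-tip group), under the assumption that the
   majority of genes are unchanged,
5. averaging of duplicate features so each feature appears once per array.

The result is one feature -> log2-ratio vector per array, ready for
between-array cyclic loess normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .arrayio import (
    ArrayTable,
    EXCL_BACKGROUND,
    EXCL_EMPTY_NAME,
    EXCL_NONE,
    EXCL_NONPOSITIVE,
    EXCL_SOFTWARE_FLAG,
    GENEPIX,
)

logger = logging.getLogger(__name__)

#: GenePix software flags meaning "not found" / "absent" / "bad"
GENEPIX_BAD_FLAGS = (-50, -75, -100)

#: BlueFuse spot-quality letter marking the lowest quality class
BLUEFUSE_BAD_QUALITY = "E"

DEFAULT_EMPTY_PATTERNS = ("EMPTY", "empty", "ctrl-", "Ctrl-")


@dataclass
class PreprocessConfig:
    """Tunable parameters of the within-array steps.

    k_sd
        Width of the background filter in background standard
        deviations; 3 keeps spots significant at ~99.73% confidence.
    auto_reference
        Detect the reference channel per array by the higher-median
        rule; set False (with ``fixed_reference_channel``) when the
        reference-brighter assumption does not hold.
    empty_name_patterns
        Feature names excluded as empty/control spots.  Patterns ending
        in ``-`` are prefix matches, others exact matches.
    """

    k_sd: float = 3.0
    auto_reference: bool = True
    fixed_reference_channel: Optional[int] = None
    empty_name_patterns: Sequence[str] = DEFAULT_EMPTY_PATTERNS

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        if not self.auto_reference and self.fixed_reference_channel not in (1, 2):
            raise ValueError(
                "fixed_reference_channel must be 1 or 2 when "
                "auto_reference is disabled"
            )


@dataclass
class PreprocessResult:
    """Per-array preprocessing output and bookkeeping.

    ``vector`` is the step-5 feature vector (block-centred,
    duplicate-averaged log2 ratios, indexed by feature_id, named by
    array_id).  ``raw_ratios`` / ``centred_ratios`` are the spot-level
    log2 ratios before and after block centering (for diagnostics), and
    ``exclusion_tally`` counts spots per exclusion reason.
    """

    array: ArrayTable
    vector: pd.Series
    raw_ratios: pd.DataFrame
    centred_ratios: pd.DataFrame
    exclusion_tally: dict[str, int] = field(default_factory=dict)


def background_correct(array: ArrayTable) -> ArrayTable:
    """Subtract median background from median foreground (GenePix only).

    BlueFuse arrays pass through unchanged: the BlueFuse software
    background-corrects internally.  The as-read foregrounds are kept
    in ``fg1_raw``/``fg2_raw`` for the background filter, which compares
    raw quantities.  Corrected values may be non-positive; those spots
    are excluded later when log-ratios are formed.
    """
    out = array.copy()
    if array.format == GENEPIX:
        out.data["fg1_raw"] = out.data["fg1"]
        out.data["fg2_raw"] = out.data["fg2"]
        out.data["fg1"] = out.data["fg1"] - out.data["bg1"]
        out.data["fg2"] = out.data["fg2"] - out.data["bg2"]
    return out


def _empty_name_mask(names: pd.Series, patterns: Sequence[str]) -> pd.Series:
    mask = pd.Series(False, index=names.index)
    for pat in patterns:
        if pat.endswith("-"):
            mask |= names.str.startswith(pat)
        else:
            mask |= names == pat
    return mask


def apply_exclusions(array: ArrayTable,
                     config: PreprocessConfig = PreprocessConfig()) -> ArrayTable:
    """Mark unusable spots with their exclusion reason.

    A spot is excluded if ANY of:

    * (GenePix) software flag in {-50, -75, -100},
    * (both formats) feature name matches an empty/control pattern,
    * (BlueFuse) spot-quality letter 'E',
    * (GenePix) in either channel the raw foreground median lies within
      ``k_sd`` background standard deviations of the background median,
      i.e. ``F < B + k_sd * B_SD``.

    Reasons are assigned with priority software_flag > empty_name >
    background_filter, so a spot failing several tests reports the
    first.  Requires :func:`background_correct` to have run for GenePix
    arrays (it stores the raw foregrounds used by the filter).
    """
    out = array.copy()
    d = out.data
    if array.format == GENEPIX:
        if "fg1_raw" not in d.columns:
            raise ValueError(
                f"{array.array_id}: background_correct must run before "
                "apply_exclusions on GenePix arrays"
            )
        soft = d["flag"].isin(GENEPIX_BAD_FLAGS)
        weak = (
            (d["fg1_raw"] < d["bg1"] + config.k_sd * d["bg_sd1"])
            | (d["fg2_raw"] < d["bg2"] + config.k_sd * d["bg_sd2"])
        )
    else:
        soft = d["flag"].astype(str).str.strip() == BLUEFUSE_BAD_QUALITY
        weak = pd.Series(False, index=d.index)
    empty = _empty_name_mask(d["feature_id"], config.empty_name_patterns)

    for mask, reason in [(soft, EXCL_SOFTWARE_FLAG),
                         (empty, EXCL_EMPTY_NAME),
                         (weak, EXCL_BACKGROUND)]:
        hit = mask & ~d["excluded"]
        d.loc[hit, "excluded"] = True
        d.loc[hit, "exclusion_reason"] = reason
    return out


def detect_reference_channel(
    array: ArrayTable,
    config: PreprocessConfig = PreprocessConfig(),
) -> ArrayTable:
    """Assign signal/reference channel roles for one array.

    With ``auto_reference`` the reference channel is the one with the
    higher median background-corrected intensity over non-excluded
    spots (the common gDNA reference hybridises brightly on every
    array).  An exact median tie violates that assumption and raises,
    instructing the user to set ``fixed_reference_channel``.
    """
    out = array.copy()
    if not config.auto_reference:
        out.reference_channel = config.fixed_reference_channel
        out.signal_channel = 2 if out.reference_channel == 1 else 1
        return out
    ok = ~out.data["excluded"]
    if not ok.any():
        raise ValueError(f"{array.array_id}: no non-excluded spots, cannot "
                         "detect reference channel")
    med1 = float(out.data.loc[ok, "fg1"].median())
    med2 = float(out.data.loc[ok, "fg2"].median())
    if med1 == med2:
        raise ValueError(
            f"{array.array_id}: channel medians tie ({med1}); the "
            "reference-brighter assumption is violated — set "
            "fixed_reference_channel explicitly"
        )
    out.reference_channel = 1 if med1 > med2 else 2
    out.signal_channel = 2 if out.reference_channel == 1 else 1
    logger.debug("%s: reference channel %d (medians %.1f / %.1f)",
                 array.array_id, out.reference_channel, med1, med2)
    return out


def compute_log_ratios(array: ArrayTable) -> tuple[ArrayTable, pd.DataFrame]:
    """log2(signal/reference) per non-excluded spot.

    Spots with a non-positive corrected intensity in either channel are
    excluded with reason ``nonpositive_intensity``.  Returns the
    updated array and a spot-level table with columns
    ``block``, ``feature_id``, ``value``.
    """
    if array.signal_channel is None or array.reference_channel is None:
        raise ValueError(f"{array.array_id}: channel roles not assigned")
    out = array.copy()
    d = out.data
    sig = d[f"fg{out.signal_channel}"]
    ref = d[f"fg{out.reference_channel}"]
    nonpos = (~d["excluded"]) & ((sig <= 0) | (ref <= 0))
    d.loc[nonpos, "excluded"] = True
    d.loc[nonpos, "exclusion_reason"] = EXCL_NONPOSITIVE
    ok = ~d["excluded"]
    ratios = pd.DataFrame({
        "block": d.loc[ok, "block"].to_numpy(),
        "feature_id": d.loc[ok, "feature_id"].to_numpy(),
        "value": np.log2(sig[ok].to_numpy() / ref[ok].to_numpy()),
    })
    return out, ratios


def center_blocks(ratios: pd.DataFrame) -> pd.DataFrame:
    """Set the median log2 ratio of every block (sub-array) to zero.

    Print-tip blocks carry spatial artefacts of the arrayer pin that
    printed them; under the majority-unchanged assumption each block's
    median is a bias estimate and is subtracted.  Blocks with a single
    spot centre to exactly zero.
    """
    out = ratios.copy()
    out["value"] = out["value"] - out.groupby("block")["value"].transform("median")
    return out


def average_duplicates(ratios: pd.DataFrame, array_id: str) -> pd.Series:
    """Mean log2 ratio per feature so each feature appears once.

    Features whose every spot was excluded are simply absent from the
    result (they never reach this table).
    """
    vec = ratios.groupby("feature_id")["value"].mean().sort_index()
    vec.name = array_id
    vec.index.name = "feature_id"
    return vec


def preprocess_array(
    array: ArrayTable,
    config: PreprocessConfig = PreprocessConfig(),
) -> PreprocessResult:
    """Run the full within-array pipeline (steps 1-5) on one array."""
    corrected = background_correct(array)
    flagged = apply_exclusions(corrected, config)
    assigned = detect_reference_channel(flagged, config)
    assigned, raw = compute_log_ratios(assigned)
    centred = center_blocks(raw)
    vector = average_duplicates(centred, array.array_id)
    tally = assigned.data["exclusion_reason"].value_counts().to_dict()
    tally.setdefault(EXCL_NONE, 0)
    logger.info(
        "%s: %d spots, %d excluded (%s), %d unique features",
        array.array_id, assigned.n_spots,
        int(assigned.data["excluded"].sum()),
        ", ".join(f"{k}={v}" for k, v in sorted(tally.items()) if k != EXCL_NONE),
        len(vector),
    )
    return PreprocessResult(
        array=assigned, vector=vector,
        raw_ratios=raw, centred_ratios=centred,
        exclusion_tally=tally,
    )
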