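"""Synthetic two-colour common-reference microarray datasets.

Generates desk-scale datasets with known ground truth, written as valid
GenePix GPR and/or BlueFuse result files, for exercising and
benchmarking the normalisation pipeline.  The generative model emulates
the features of real common-reference data:

* a high, flat genomic-DNA reference channel shared by all arrays,
* per-feature signal log-ratios with biological baseline + noise,
* spiked differentially expressed genes between two array groups,
* per-array scale multipliers (the heterogeneous "problem" archetype),
* per-array quadratic intensity-dependent curvature (the "banana"),
* asymmetric (skewed) noise,
* spot backgrounds, vendor flags / 'E'-quality spots, empty/control
  spots, duplicate features, and block (print-tip) layout,
* optionally several partially overlapping feature layouts.

The ground truth (DE membership, true log2 fold changes, per-array
technical parameters) is returned alongside, enabling power and type-I
error evaluation of the full pipeline.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .arrayio import BLUEFUSE, GENEPIX

__all__ = [
    "SimConfig", "SimTruth", "DetectionResult",
    "simulate_dataset", "evaluate_detection",
    "simulation_preset", "problem_preset",
]


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    The default preset mirrors the benchmark layout this simulator is
    pitched at: 6 arrays of 5000 genes in a 4 x 4 block grid, two
    groups of 3 arrays, 118 differentially expressed genes.  See
    docs/methods.md for the generative model and the rationale for
    every default.
    """

    n_arrays: int = 6
    n_genes: int = 5000
    block_grid: tuple[int, int] = (4, 4)
    n_de: int = 118
    de_log2fc: float = 1.0
    group_split: tuple[int, int] = (3, 3)
    reference_level: float = 10000.0
    signal_noise_sd: float = 0.35
    background_mean: float = 150.0
    background_sd: float = 30.0
    scale_multipliers: Optional[Sequence[float]] = None
    curvature_coeff: float = 0.0
    #: scalar (same asymmetric-noise weight on every array) or one
    #: value per array (heterogeneous skewness, the "problem" shape)
    skew_coeff: float | Sequence[float] = 0.0
    flagged_rate: float = 0.01
    duplicate_rate: float = 0.02
    n_controls: int = 0
    layouts: Optional[Sequence[Sequence[str]]] = None
    seed: int = 0
    # generative-model parameters beyond the headline study conditions
    expr_mean: float = -2.0   # keeps the reference channel brighter
    expr_sd: float = 1.0
    brightness_sd: float = 1.0
    channel_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if sum(self.group_split) != self.n_arrays:
            raise ValueError("group_split must sum to n_arrays")
        for name in ("flagged_rate", "duplicate_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.scale_multipliers is not None and \
                len(self.scale_multipliers) != self.n_arrays:
            raise ValueError("scale_multipliers must have one entry per array")


@dataclass
class SimTruth:
    """Ground truth for a simulated dataset.

    ``true_log2fc`` is the group-2 minus group-1 expression difference
    per feature (0 for non-DE features); ``per_array_params`` maps each
    array id to its (scale, curvature, skew) technical parameters;
    ``groups`` maps array id -> 1 or 2; ``written_tables`` holds, per
    array, the spot table exactly as rendered into the files (post
    rounding) for round-trip checks.
    """

    de_features: set[str]
    true_log2fc: pd.Series
    per_array_params: dict[str, tuple[float, float, float]]
    groups: dict[str, int]
    written_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class DetectionResult:
    """Detection rates against ground truth, in both vocabularies.

    ``power``, ``type_i_error`` and ``fdr`` are the conventional
    quantities (TP/(number of DE genes tested), FP/(number of null
    genes tested), FP/discoveries).  Some benchmark write-ups instead
    call 1 - FDR "power" and the false-negative rate "type I error";
    those are reported as ``power_one_minus_fdr`` and
    ``false_negative_rate``, explicitly labelled, never silently
    substituted.
    """

    power: float
    type_i_error: float
    fdr: float
    power_one_minus_fdr: float
    false_negative_rate: float
    n_tested: int
    n_discoveries: int


def _scaled_n_de(overrides: dict) -> dict:
    # keep the DE fraction (118/5000) when the gene count is shrunk
    # and the caller did not pin n_de explicitly
    if "n_genes" in overrides and "n_de" not in overrides:
        overrides = dict(overrides,
                         n_de=round(overrides["n_genes"] * 118 / 5000))
    return overrides


def simulation_preset(**overrides) -> SimConfig:
    """The benchmark preset: 6 arrays x 5000 genes in 4 x 4 blocks."""
    return replace(SimConfig(), **_scaled_n_de(overrides))


def problem_preset(**overrides) -> SimConfig:
    """Heterogeneous 'problem' archetype: discordant per-array M-value
    scales, intensity-dependent curvature and skewed noise, as seen in
    datasets built from variable-quality RNA."""
    n = overrides.get("n_arrays", 6)
    kwargs = dict(
        n_arrays=n,
        group_split=(n // 2, n - n // 2),
        # log-spread scales mirror the observed several-fold spread of
        # M-value s.d. between arrays of a problem dataset
        scale_multipliers=((0.5, 0.8, 1.0, 1.3, 1.7, 2.2) if n == 6
                           else tuple(np.geomspace(0.5, 2.2, n))),
        curvature_coeff=0.25,
        # skewness concentrated in half the arrays, as in datasets where
        # one experiment's RNA quality drove asymmetric labelling noise
        skew_coeff=tuple(0.8 if i < n // 2 else 0.2 for i in range(n)),
    )
    kwargs.update(_scaled_n_de(overrides))
    return SimConfig(**kwargs)


def _block_layout(n_spots: int, grid: tuple[int, int]) -> pd.DataFrame:
    """Deal spots row-major into the block grid; block sizes differ by
    at most one.  Within a block spots fill a near-square grid."""
    n_blocks = grid[0] * grid[1]
    base, extra = divmod(n_spots, n_blocks)
    sizes = [base + (1 if b < extra else 0) for b in range(n_blocks)]
    ncols = max(1, math.ceil(math.sqrt(max(sizes))))
    blocks, cols, rows = [], [], []
    for b, size in enumerate(sizes, start=1):
        idx = np.arange(size)
        blocks.extend([b] * size)
        cols.extend((idx % ncols + 1).tolist())
        rows.extend((idx // ncols + 1).tolist())
    return pd.DataFrame({"block": blocks, "column": cols, "row": rows})


def _per_array_curvature(coeff: float, n_arrays: int) -> np.ndarray:
    # A scalar coefficient is spread over arrays as a [-c, c] ramp so
    # that array pairs genuinely differ in curvature (a shared curvature
    # would cancel in every M_ab).
    if n_arrays == 1:
        return np.array([coeff])
    return coeff * np.linspace(-1.0, 1.0, n_arrays)


def _render_genepix(table: pd.DataFrame, array_id: str) -> str:
    """Render a spot table as a GPR (ATF 1.0) file.

    Channel 1 (signal) is written as the 635 nm wavelength, channel 2
    (reference) as 532 nm; intensities are integers, as scanners emit.
    """
    cols = ["Block", "Column", "Row", "Name",
            "F635 Median", "B635 Median", "B635 SD",
            "F532 Median", "B532 Median", "B532 SD", "Flags"]
    lines = ["ATF\t1.0", f"2\t{len(cols)}",
             '"Type=GenePix Results 3"',
             f'"ArrayName={array_id}"',
             "\t".join(cols)]
    for r in table.itertuples(index=False):
        lines.append("\t".join([
            str(r.block), str(r.column), str(r.row), r.feature_id,
            str(int(r.fg1)), str(int(r.bg1)), str(int(r.bg_sd1)),
            str(int(r.fg2)), str(int(r.bg2)), str(int(r.bg_sd2)),
            str(int(r.flag)),
        ]))
    return "\n".join(lines) + "\n"


def _render_bluefuse(table: pd.DataFrame, array_id: str) -> str:
    """Render a spot table as a BlueFuse results file.

    AMPCH1/AMPCH2 hold the background-corrected amplitudes (BlueFuse
    corrects internally); a key<TAB>value preamble precedes the header.
    """
    lines = [f"SlideName\t{array_id}",
             "Software\tsimulated",
             "BLOCK\tSUBGRIDCOL\tSUBGRIDROW\tNAME\tAMPCH1\tAMPCH2\tFLAG"]
    for r in table.itertuples(index=False):
        amp1 = r.fg1 - r.bg1
        amp2 = r.fg2 - r.bg2
        lines.append("\t".join([
            str(r.block), str(r.column), str(r.row), r.feature_id,
            f"{amp1:.2f}", f"{amp2:.2f}", r.bf_flag,
        ]))
    return "\n".join(lines) + "\n"


def simulate_dataset(
    config: SimConfig,
    out_dir: Optional[str] = None,
    formats: Sequence[str] = (GENEPIX,),
) -> tuple[dict[str, dict[str, str]], SimTruth]:
    """Generate a dataset; optionally write vendor files to ``out_dir``.

    Returns ``(files, truth)`` where ``files[format][array_id]`` is the
    rendered file content (and, when ``out_dir`` is given, the files
    are also written there as ``<array_id>.gpr`` / ``<array_id>_bluefuse.txt``).
    Deterministic given ``config.seed``; per-array random streams are
    derived from (seed, array index) so adding arrays does not perturb
    earlier ones.
    """
    cfg = config
    n = cfg.n_genes
    feat_rng = np.random.default_rng([cfg.seed, 982451653])

    gene_ids = np.array([f"gene_{i:05d}" for i in range(1, n + 1)])
    brightness = feat_rng.normal(0.0, cfg.brightness_sd, n)
    baseline = feat_rng.normal(cfg.expr_mean, cfg.expr_sd, n)
    de_idx = np.sort(feat_rng.choice(n, size=cfg.n_de, replace=False))
    fc = np.zeros(n)
    signs = np.where(np.arange(cfg.n_de) % 2 == 0, 1.0, -1.0)
    fc[de_idx] = signs * cfg.de_log2fc

    scales = (np.asarray(cfg.scale_multipliers, dtype=float)
              if cfg.scale_multipliers is not None
              else np.ones(cfg.n_arrays))
    curvatures = _per_array_curvature(cfg.curvature_coeff, cfg.n_arrays)
    truth = SimTruth(
        de_features=set(gene_ids[de_idx]),
        true_log2fc=pd.Series(fc, index=gene_ids, name="true_log2fc"),
        per_array_params={}, groups={},
    )
    files: dict[str, dict[str, str]] = {f: {} for f in formats}
    feature_pos = {g: i for i, g in enumerate(gene_ids)}

    for i in range(cfg.n_arrays):
        rng = np.random.default_rng([cfg.seed, i])
        array_id = f"sim_{i + 1:02d}"
        group = 1 if i < cfg.group_split[0] else 2
        scale, curv = float(scales[i]), float(curvatures[i])
        if np.ndim(cfg.skew_coeff) == 0:
            skew = float(cfg.skew_coeff)
        else:
            if len(cfg.skew_coeff) != cfg.n_arrays:
                raise ValueError("skew_coeff sequence must have one entry "
                                 "per array")
            skew = float(cfg.skew_coeff[i])
        truth.per_array_params[array_id] = (scale, curv, skew)
        truth.groups[array_id] = group

        if cfg.layouts is not None:
            layout = [g for g in cfg.layouts[i % len(cfg.layouts)]]
        else:
            layout = list(gene_ids)
        pos = np.array([feature_pos[g] for g in layout])

        n_dup = int(round(cfg.duplicate_rate * len(layout)))
        dup_pos = rng.choice(pos, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
        spot_pos = np.concatenate([pos, dup_pos]).astype(int)
        names = list(gene_ids[spot_pos])
        # empty/control spots carry no biology; weak signal on purpose
        n_ctl = cfg.n_controls
        names += ["EMPTY" if j % 2 == 0 else f"ctrl-{j}" for j in range(n_ctl)]
        n_spots = len(names)
        n_gene_spots = len(spot_pos)

        noise = rng.normal(0.0, cfg.signal_noise_sd, n_gene_spots)
        if skew:
            noise = noise + skew * (rng.exponential(1.0, n_gene_spots) - 1.0)
        expr = baseline[spot_pos] + (fc[spot_pos] if group == 2 else 0.0)
        b = brightness[spot_pos]
        # Intensity-dependent curvature ("banana"): a quadratic in the
        # baseline log-ratio, which is what the pairwise A-value tracks,
        # centred so it adds no net offset.
        bend = (baseline[spot_pos] - cfg.expr_mean) ** 2 - cfg.expr_sd ** 2
        log_ratio = scale * (expr + noise) + curv * bend

        ref = cfg.reference_level * np.power(
            2.0, b + rng.normal(0.0, cfg.channel_noise_sd, n_gene_spots))
        sig = ref * np.power(2.0, log_ratio)
        if n_ctl:
            ctl_ref = rng.uniform(5.0, 30.0, n_ctl)
            ctl_sig = rng.uniform(5.0, 30.0, n_ctl)
            ref = np.concatenate([ref, ctl_ref])
            sig = np.concatenate([sig, ctl_sig])

        bg = np.maximum(rng.normal(cfg.background_mean, cfg.background_sd,
                                   (2, n_spots)), 1.0)
        bg_sd = np.maximum(rng.normal(cfg.background_sd, cfg.background_sd / 5,
                                      (2, n_spots)), 1.0)
        flags = np.zeros(n_spots, dtype=int)
        flag_mask = rng.random(n_spots) < cfg.flagged_rate
        flags[flag_mask] = rng.choice([-50, -75, -100], size=int(flag_mask.sum()))

        layout_df = _block_layout(n_spots, cfg.block_grid)
        table = pd.DataFrame({
            "block": layout_df["block"], "column": layout_df["column"],
            "row": layout_df["row"], "feature_id": names,
            # foreground = signal + background, rounded as vendors do
            "fg1": np.rint(sig + bg[0]), "bg1": np.rint(bg[0]),
            "bg_sd1": np.rint(bg_sd[0]),
            "fg2": np.rint(ref + bg[1]), "bg2": np.rint(bg[1]),
            "bg_sd2": np.rint(bg_sd[1]),
            "flag": flags,
            "bf_flag": np.where(flag_mask, "E", "A"),
        })
        truth.written_tables[array_id] = table

        for fmt in formats:
            if fmt == GENEPIX:
                files[fmt][array_id] = _render_genepix(table, array_id)
            elif fmt == BLUEFUSE:
                files[fmt][array_id] = _render_bluefuse(table, array_id)
            else:
                raise ValueError(f"unknown format {fmt!r}")

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for fmt, by_array in files.items():
            suffix = ".gpr" if fmt == GENEPIX else "_bluefuse.txt"
            for array_id, content in by_array.items():
                with open(os.path.join(out_dir, array_id + suffix), "w") as fh:
                    fh.write(content)
    return files, truth


def evaluate_detection(
    matrix: pd.DataFrame,
    groups: Mapping[str, int],
    truth: SimTruth,
    alpha: float = 0.05,
) -> DetectionResult:
    """Per-feature two-sample t-test with Benjamini-Hochberg control.

    Features with fewer than 2 non-missing values in either group are
    untestable and excluded from every rate.  Rates are reported both
    conventionally and in the 1-FDR / false-negative vocabulary (see
    :class:`DetectionResult`).
    """
    g1 = [a for a in matrix.columns if groups[str(a)] == 1]
    g2 = [a for a in matrix.columns if groups[str(a)] == 2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 arrays")

    x1, x2 = matrix[g1], matrix[g2]
    ok = (x1.notna().sum(axis=1) >= 2) & (x2.notna().sum(axis=1) >= 2)
    tested = matrix.index[ok]
    if len(tested) == 0:
        raise ValueError("no testable features")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = _stats.ttest_ind(
            x1.loc[tested].to_numpy(dtype=float).T,
            x2.loc[tested].to_numpy(dtype=float).T,
            nan_policy="omit", equal_var=True,
        )
    pvals = np.asarray(pvals, dtype=float)
    pvals[~np.isfinite(pvals)] = 1.0
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")

    is_de = tested.isin(truth.de_features)
    tp = int(np.sum(reject & is_de))
    fp = int(np.sum(reject & ~is_de))
    fn = int(np.sum(~reject & is_de))
    n_de, n_null = int(is_de.sum()), int((~is_de).sum())
    n_disc = tp + fp

    power = tp / n_de if n_de else float("nan")
    type_i = fp / n_null if n_null else float("nan")
    fdr = fp / n_disc if n_disc else 0.0
    return DetectionResult(
        power=power, type_i_error=type_i, fdr=fdr,
        power_one_minus_fdr=1.0 - fdr,
        false_negative_rate=fn / n_de if n_de else float("nan"),
        n_tested=len(tested), n_discoveries=n_disc,
    )
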