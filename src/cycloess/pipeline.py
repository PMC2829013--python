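"""End-to-end orchestration: files in, normalised matrix out.

Reads any mixture of GenePix and BlueFuse files (any number of array
layouts), runs the within-array steps per array, the between-array
cyclic loess, the final median correction, and writes the expression
matrix plus optional per-stage diagnostics tables.
"""

from __future__ import annotations

import glob as _glob
import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import arrayio, diagnostics
from .cyclic import CyclicConfig, CyclicResult, center_arrays, cyclic_normalise
from .preprocess import PreprocessConfig, PreprocessResult, preprocess_array

logger = logging.getLogger(__name__)

#: labels of the four diagnostic stages (raw log-ratios, after block
#: centering/duplicate averaging, after cyclic loess averaging, final)
STAGES = ("raw", "block_centred", "cyclic", "final")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_paths: Sequence[str]
    output_path: str
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cyclic: CyclicConfig = field(default_factory=CyclicConfig)
    emit_diagnostics: bool = False
    diagnostics_dir: Optional[str] = None


@dataclass
class PipelineResult:
    matrix: pd.DataFrame
    preprocessed: list[PreprocessResult]
    cyclic: CyclicResult
    stage_matrices: dict[str, pd.DataFrame]


def resolve_inputs(paths: Sequence[str]) -> list[str]:
    """Expand globs, keep order, require >= 2 files."""
    resolved: list[str] = []
    for p in paths:
        hits = sorted(_glob.glob(p)) if _glob.has_magic(p) else [p]
        for h in hits:
            if not os.path.isfile(h):
                raise FileNotFoundError(h)
            resolved.append(h)
    if len(resolved) < 2:
        raise ValueError(f"need at least 2 input files, got {len(resolved)}")
    return resolved


def _array_ids(paths: Sequence[str]) -> list[str]:
    """File basenames (sans extension); collisions get numeric suffixes."""
    ids, seen = [], {}
    for p in paths:
        base = os.path.splitext(os.path.basename(p))[0]
        if base in seen:
            seen[base] += 1
            new = f"{base}_{seen[base]}"
            logger.warning("array id collision: %s -> %s", base, new)
            base = new
        else:
            seen[base] = 0
        ids.append(base)
    return ids


def _vectors_matrix(vectors: list[pd.Series]) -> pd.DataFrame:
    features = sorted(set().union(*[v.index for v in vectors]))
    return pd.DataFrame(
        {str(v.name): v.reindex(features) for v in vectors},
        index=pd.Index(features, name="feature_id"),
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full normalisation pipeline.

    Stage matrices for diagnostics:

    * ``raw``           — per-spot log2 ratios before block centering,
                          duplicate-averaged per feature,
    * ``block_centred`` — the step-4/5 feature vectors,
    * ``cyclic``        — after all-pairs loess and averaging,
    * ``final``         — after the per-array median correction.

    The output file is written atomically (temp file + rename) so a
    failure leaves no partial output behind.
    """
    paths = resolve_inputs(config.input_paths)
    ids = _array_ids(paths)

    results: list[PreprocessResult] = []
    for path, array_id in zip(paths, ids):
        with open(path) as fh:
            content = fh.read()
        table = arrayio.read_array(content, array_id=array_id)
        logger.info("read %s (%s, %d spots)", path, table.format, table.n_spots)
        results.append(preprocess_array(table, config.preprocess))

    raw_vectors = [
        r.raw_ratios.groupby("feature_id")["value"].mean().rename(r.array.array_id)
        for r in results
    ]
    vectors = [r.vector for r in results]
    cyc = cyclic_normalise(vectors, config.cyclic)
    matrix = cyc.matrix
    if config.cyclic.do_final_centering:
        matrix = center_arrays(matrix)

    stage_matrices = {
        "raw": _vectors_matrix(raw_vectors),
        "block_centred": _vectors_matrix(vectors),
        "cyclic": cyc.matrix,
        "final": matrix,
    }

    out_dir = os.path.dirname(os.path.abspath(config.output_path))
    os.makedirs(out_dir, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=out_dir, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            arrayio.write_matrix(matrix, fh)
        os.replace(tmp, config.output_path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    logger.info("wrote %s (%d features x %d arrays)",
                config.output_path, *matrix.shape)

    if config.emit_diagnostics:
        ddir = config.diagnostics_dir or out_dir
        emit_diagnostics(stage_matrices, ddir)
    return PipelineResult(matrix=matrix, preprocessed=results,
                          cyclic=cyc, stage_matrices=stage_matrices)


def emit_diagnostics(stage_matrices: dict[str, pd.DataFrame],
                     out_dir: str, render_plots: bool = False) -> None:
    """Write per-stage boxplot and distribution tables (TSV), and
    optionally the stage boxplot panels as a PNG."""
    os.makedirs(out_dir, exist_ok=True)
    box = pd.concat([diagnostics.boxplot_table(m, stage=s)
                     for s, m in stage_matrices.items()], ignore_index=True)
    dist = pd.concat([diagnostics.distribution_table(m, stage=s)
                      for s, m in stage_matrices.items()], ignore_index=True)
    box.to_csv(os.path.join(out_dir, "boxplot_stats.tsv"),
               sep="\t", index=False)
    dist.to_csv(os.path.join(out_dir, "distribution_stats.tsv"),
                sep="\t", index=False)
    if render_plots:
        diagnostics.plot_stage_boxplots(
            stage_matrices, os.path.join(out_dir, "stage_boxplots.png"))
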