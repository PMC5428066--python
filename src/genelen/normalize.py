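"""Platform-level normalization to comparable per-gene log expression.

Two entry points depending on platform: microarray intensities are collapsed
from probes to genes (mean of log2 values over probes that map to a single
gene), RNA-seq counts are divided by the exon-union length to give exon
density (reads per base). Either path is followed by quantile normalization
across samples and, for linear-scale data, a log transform.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneAnnotation, _sep_for


def read_probe_map(path) -> dict[str, frozenset]:
    """Read a two-column TSV ``probe_id<TAB>gene1,gene2,...``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#",
                     dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs two columns")
    if df.iloc[0, 0].lower() in ("probe", "probe_id"):
        df = df.iloc[1:]
    out = {}
    for probe, genes in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if probe in out:
            raise ValueError(f"{path}: duplicate probe id {probe!r}")
        genes = frozenset(g.strip() for g in str(genes).split(",") if g.strip())
        if not genes:
            raise ValueError(f"{path}: probe {probe!r} maps to no genes")
        out[probe] = genes
    return out


def collapse_probes(matrix: ExpressionMatrix,
                    probe_map: Mapping[str, frozenset]) -> ExpressionMatrix:
    """Collapse a probe-level log2 matrix to gene level.

    Probes mapping to more than one gene are discarded entirely; each gene's
    row is the arithmetic mean of its remaining probes' log2 rows. Output
    rows are ordered by gene id.
    """
    if matrix.scale != "log2":
        raise ValueError(
            f"collapse_probes expects log2 values, got {matrix.scale!r}; "
            "log-transform first"
        )
    single = {p: next(iter(gs)) for p, gs in probe_map.items()
              if len(gs) == 1}
    probes = [p for p in matrix.values.index if p in single]
    if not probes:
        raise ValueError("no probe in the matrix maps to a single gene")
    rows = matrix.values.loc[probes]
    collapsed = rows.groupby(rows.index.map(single)).mean()
    return matrix.with_values(collapsed)


def exon_density_normalize(counts: ExpressionMatrix,
                           annot: GeneAnnotation) -> ExpressionMatrix:
    """Convert read counts to exon density: counts / exon_length (reads/bp).

    Every matrix gene must have a positive exon_length in the annotation.
    The output scale is ``linear``.
    """
    if counts.scale != "counts":
        raise ValueError(
            f"exon_density_normalize expects counts, got {counts.scale!r}"
        )
    exon = annot.table["exon_length"].reindex(counts.values.index)
    missing = exon.index[exon.isna()].tolist()
    if missing:
        raise ValueError(
            f"missing exon_length for {len(missing)} genes, e.g. "
            f"{missing[:5]}"
        )
    if (exon <= 0).any():
        bad = exon.index[exon <= 0].tolist()
        raise ValueError(f"non-positive exon_length for genes {bad[:5]}")
    density = counts.values.div(exon, axis=0)
    return counts.with_values(density, scale="linear")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share the same value distribution.

    The reference distribution is the across-sample mean of order
    statistics; each sample's values are replaced by the reference value at
    their within-sample rank. Tied values within a sample receive the mean
    of the reference values over their tied rank span (ties=average).
    Within-sample rank order is preserved.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = matrix.values.to_numpy(dtype=float)
    n = vals.shape[0]
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        assigned = ref.copy()
        # average the reference over each run of tied input values
        breaks = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        if breaks.size < n - 1:
            bounds = np.concatenate(([0], breaks, [n]))
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b - a > 1:
                    assigned[a:b] = assigned[a:b].mean()
        out[order, j] = assigned
    frame = pd.DataFrame(out, index=matrix.values.index,
                         columns=matrix.values.columns)
    return matrix.with_values(frame)


def log_transform(matrix: ExpressionMatrix, base: int = 2,
                  pseudocount: float | None = None) -> ExpressionMatrix:
    """Apply ``log_base(value + pseudocount)`` elementwise.

    ``pseudocount`` defaults to 1 for counts and 0 for linear data; it must
    be positive when the matrix contains zeros.
    """
    if matrix.scale not in ("counts", "linear"):
        raise ValueError(
            f"log_transform expects counts or linear values, got "
            f"{matrix.scale!r}"
        )
    if base not in (2, 10):
        raise ValueError("base must be 2 or 10")
    if pseudocount is None:
        pseudocount = 1.0 if matrix.scale == "counts" else 0.0
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    arr = matrix.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    if pseudocount == 0 and (arr == 0).any():
        raise ValueError("matrix contains zeros; use a positive pseudocount")
    fn = np.log2 if base == 2 else np.log10
    frame = pd.DataFrame(fn(arr + pseudocount), index=matrix.values.index,
                         columns=matrix.values.columns)
    return matrix.with_values(frame, scale=f"log{base}")
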