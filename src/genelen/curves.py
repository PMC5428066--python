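"""Per-gene log fold changes and length-ordered sliding-window curves.

This is the central statistic of the pipeline: genes are sorted by genomic
length and a per-gene statistic (log2 fold change between conditions, or
mean log expression within a cell group) is averaged over sliding windows
of 200 consecutive genes advanced in steps of 40, giving a curve of the
statistic as a function of gene length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneAnnotation

logger = logging.getLogger("genelen")

WINDOW_DEFAULT = 200
STEP_DEFAULT = 40

#: Columns of a binned curve frame.
CURVE_COLUMNS = ("window_start", "mean_length", "mean_stat", "sem", "n_genes")


@dataclass(frozen=True)
class ConditionContrast:
    """A case/control sample split: two disjoint, non-empty sample sets."""

    case: tuple[str, ...]
    control: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.case or not self.control:
            raise ValueError("case and control sample sets must be non-empty")
        overlap = set(self.case) & set(self.control)
        if overlap:
            raise ValueError(
                f"samples in both case and control: {sorted(overlap)[:5]}"
            )

    @classmethod
    def from_labels(cls, matrix: ExpressionMatrix, case_label: str,
                    control_label: str) -> "ConditionContrast":
        case = tuple(matrix.samples_for(case_label))
        control = tuple(matrix.samples_for(control_label))
        if not case or not control:
            raise ValueError(
                f"labels {case_label!r}/{control_label!r} select "
                f"{len(case)}/{len(control)} samples"
            )
        return cls(case, control)


def compute_fold_change(matrix: ExpressionMatrix,
                        contrast: ConditionContrast,
                        annot: GeneAnnotation) -> pd.DataFrame:
    """Per-gene log2 fold change profile for a case/control contrast.

    Expression is averaged per gene within each condition on the log2
    scale; ``logfc = mean(case) - mean(control)``. The per-gene variance is
    the sum of the two within-condition sample variances (ddof=1, zero for
    a single sample). Genes without a length in the annotation are dropped
    with a logged count.

    Returns a DataFrame indexed by gene id with columns
    ``logfc``, ``variance``, ``length``.
    """
    if matrix.scale != "log2":
        raise ValueError(
            f"fold change is computed on log2 values, got {matrix.scale!r}"
        )
    missing = [s for s in (*contrast.case, *contrast.control)
               if s not in matrix.values.columns]
    if missing:
        raise ValueError(f"contrast samples absent from matrix: {missing[:5]}")
    case = matrix.values[list(contrast.case)]
    ctrl = matrix.values[list(contrast.control)]
    logfc = case.mean(axis=1) - ctrl.mean(axis=1)
    variance = (case.var(axis=1, ddof=1).fillna(0.0)
                + ctrl.var(axis=1, ddof=1).fillna(0.0))
    lengths = annot.lengths.reindex(matrix.values.index)
    keep = lengths.notna()
    if (~keep).any():
        logger.info("compute_fold_change: dropping %d genes without a "
                    "length annotation", int((~keep).sum()))
    profile = pd.DataFrame({
        "logfc": logfc[keep],
        "variance": variance[keep],
        "length": lengths[keep].astype(float),
    })
    if profile.empty:
        raise ValueError("no gene has a length annotation")
    return profile


def sliding_windows(n_genes: int, window: int = WINDOW_DEFAULT,
                    step: int = STEP_DEFAULT) -> np.ndarray:
    """Start indices of full sliding windows over ``n_genes`` sorted genes.

    Starts are ``0, step, 2*step, ...`` while ``start + window <= n_genes``;
    a trailing partial window is never emitted.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if n_genes < window:
        raise ValueError(
            f"need at least window={window} genes, got {n_genes}"
        )
    return np.arange(0, n_genes - window + 1, step)


def _sort_by_length(lengths: pd.Series) -> pd.Index:
    """Length-sorted gene order, ties broken by gene id (stable)."""
    frame = lengths.sort_index(kind="mergesort")
    return frame.sort_values(kind="mergesort").index


def _window_means(values: np.ndarray, starts: np.ndarray,
                  window: int) -> np.ndarray:
    """Means over sliding windows of an already length-sorted vector."""
    cs = np.concatenate(([0.0], np.cumsum(values)))
    return (cs[starts + window] - cs[starts]) / window


def _bin_statistic(stat: pd.Series, lengths: pd.Series, window: int,
                   step: int) -> pd.DataFrame:
    order = _sort_by_length(lengths)
    x = stat.loc[order].to_numpy(dtype=float)
    ln = lengths.loc[order].to_numpy(dtype=float)
    starts = sliding_windows(x.size, window, step)
    mean_stat = _window_means(x, starts, window)
    mean_length = _window_means(ln, starts, window)
    if window > 1:
        windows = np.lib.stride_tricks.sliding_window_view(x, window)[starts]
        sem = windows.std(axis=1, ddof=1) / np.sqrt(window)
    else:
        sem = np.zeros_like(mean_stat)
    return pd.DataFrame({
        "window_start": starts,
        "mean_length": mean_length,
        "mean_stat": mean_stat,
        "sem": sem,
        "n_genes": np.full(starts.size, window),
        "mean_log10_length": _window_means(np.log10(ln), starts, window),
    })


def bin_curve(profile: pd.DataFrame, window: int = WINDOW_DEFAULT,
              step: int = STEP_DEFAULT) -> pd.DataFrame:
    """Sliding-window curve of log fold change against gene length.

    Genes are sorted ascending by length (ties broken by gene id); for each
    full window of ``window`` genes advanced by ``step`` the mean member
    length, mean logfc and its SEM (sample sd / sqrt(window)) are reported.
    Input row order is irrelevant.
    """
    if profile.empty:
        raise ValueError("empty fold-change profile")
    return _bin_statistic(profile["logfc"], profile["length"], window, step)


def mean_expression_curve(matrix: ExpressionMatrix,
                          groups: Mapping[str, str],
                          annot: GeneAnnotation,
                          window: int = WINDOW_DEFAULT,
                          step: int = STEP_DEFAULT) -> dict[str, pd.DataFrame]:
    """One mean-expression-vs-length curve per sample group.

    The windowed statistic is each gene's mean log expression over the
    samples of one group (no contrast); all groups share the same
    length-sorted gene order. Every matrix sample must appear in
    ``groups``.
    """
    if matrix.scale not in ("log2", "log10"):
        raise ValueError(
            f"mean expression curves expect log-scale values, got "
            f"{matrix.scale!r}"
        )
    unlabelled = [s for s in matrix.values.columns if s not in groups]
    if unlabelled:
        raise ValueError(f"samples without a group label: {unlabelled[:5]}")
    lengths = annot.lengths.reindex(matrix.values.index)
    keep = lengths.notna()
    values = matrix.values.loc[keep]
    lengths = lengths[keep].astype(float)
    curves = {}
    for label in dict.fromkeys(groups[s] for s in matrix.values.columns):
        samples = [s for s in matrix.values.columns if groups[s] == label]
        stat = values[samples].mean(axis=1)
        curves[label] = _bin_statistic(stat, lengths, window, step)
    return curves


def curve_slope(curve: pd.DataFrame) -> float:
    """OLS slope of the window means against window mean log10 length."""
    if "mean_log10_length" in curve.columns:
        x = curve["mean_log10_length"].to_numpy()
    else:
        x = np.log10(curve["mean_length"].to_numpy())
    return float(stats.linregress(x, curve["mean_stat"].to_numpy()).slope)


def curve_spearman(curve: pd.DataFrame) -> float:
    """Spearman correlation of window mean length with the window mean."""
    rho = stats.spearmanr(curve["mean_length"], curve["mean_stat"]).statistic
    return float(rho)


def write_curve_tsv(curve: pd.DataFrame, path,
                    metadata: Mapping[str, object] | None = None) -> None:
    """Serialize a binned curve as TSV with '#'-prefixed metadata lines.

    The x-axis column is the mean (not median) member length of each
    window, as recorded in the header.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# binned length curve; x = mean member length (bp)\n")
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        out = curve[list(CURVE_COLUMNS)].rename(
            columns={"mean_length": "mean_length_bp"})
        out.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_curve_tsv(path) -> pd.DataFrame:
    curve = pd.read_csv(path, sep="\t", comment="#")
    return curve.rename(columns={"mean_length_bp": "mean_length"})
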