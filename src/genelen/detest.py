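"""Threshold-based differential expression and the length-shift test.

Genes are called differentially expressed by a per-gene two-sample t-test
at an uncorrected threshold (default p < 0.01), split into up- and
down-regulated sets by the sign of the mean difference. Each set's gene
lengths are then compared with the lengths of all analyzed genes by a
two-sample t-test with Bonferroni correction over the family of tests,
asking whether the DE sets are shifted toward longer or shorter genes.

Welch's unequal-variance t-test is the default throughout; a
pooled-variance option exists. The reference group for the length shift is
all analyzed genes (the tested set included); a set-vs-complement variant
is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .curves import ConditionContrast
from .io import ExpressionMatrix, GeneAnnotation

DE_ALPHA_DEFAULT = 0.01


@dataclass
class DEResult:
    """Per-gene differential-expression calls.

    ``table`` is indexed by gene id with columns ``mean_diff`` (case minus
    control mean log2), ``p_value`` and ``direction`` in
    {'up', 'down', 'none'}.
    """

    table: pd.DataFrame
    de_alpha: float

    @property
    def up_genes(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "up"]

    @property
    def down_genes(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "down"]


def per_gene_ttest(matrix: ExpressionMatrix, contrast: ConditionContrast,
                   de_alpha: float = DE_ALPHA_DEFAULT,
                   equal_var: bool = False) -> DEResult:
    """Two-sided two-sample t-test of case vs control per gene.

    Genes with p < ``de_alpha`` are split into up/down by the sign of the
    mean difference; no multiple-testing correction is applied at this
    stage. Each condition needs at least 2 samples. A gene with zero
    variance in both groups gets p = 1 (direction 'none') when the means
    are equal and p = 0 when they differ.
    """
    if matrix.scale != "log2":
        raise ValueError(f"per-gene t-test expects log2 values, got "
                         f"{matrix.scale!r}")
    if len(contrast.case) < 2 or len(contrast.control) < 2:
        raise ValueError("each condition needs at least 2 samples for the "
                         "per-gene t-test")
    missing = [s for s in (*contrast.case, *contrast.control)
               if s not in matrix.values.columns]
    if missing:
        raise ValueError(f"contrast samples absent from matrix: {missing[:5]}")
    case = matrix.values[list(contrast.case)].to_numpy(dtype=float)
    ctrl = matrix.values[list(contrast.control)].to_numpy(dtype=float)
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), \
            warnings.catch_warnings():
        # zero-variance genes raise a precision warning inside scipy; their
        # p-values are overridden below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (case.var(axis=1, ddof=1) == 0) & (ctrl.var(axis=1, ddof=1) == 0)
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0)] = 0.0
    direction = np.where(p < de_alpha,
                         np.where(diff > 0, "up",
                                  np.where(diff < 0, "down", "none")),
                         "none")
    table = pd.DataFrame({
        "mean_diff": diff,
        "p_value": p,
        "direction": direction,
    }, index=matrix.values.index)
    return DEResult(table, de_alpha)


def length_shift_test(de: DEResult, annot: GeneAnnotation,
                      family_size: int = 2,
                      reference: str = "all",
                      equal_var: bool = False,
                      log_length: bool = False) -> pd.DataFrame:
    """Test whether the up/down DE sets are length-shifted.

    For each direction, a two-sided two-sample t-test compares the lengths
    of the set with the lengths of all analyzed genes (the set is included
    in the reference, ``reference='all'``; ``'complement'`` excludes it).
    Bonferroni correction multiplies the raw p by ``family_size``, capped
    at 1. A set with fewer than 2 genes is reported untestable (NaN p).

    Lengths enter the test in base pairs by default; ``log_length`` tests
    on log10 length instead.
    """
    if reference not in ("all", "complement"):
        raise ValueError("reference must be 'all' or 'complement'")
    lengths = annot.lengths.reindex(de.table.index).dropna().astype(float)
    rows = []
    for label, genes in (("up", de.up_genes), ("down", de.down_genes)):
        set_len = lengths.reindex(genes).dropna()
        if reference == "all":
            ref_len = lengths
        else:
            ref_len = lengths.drop(set_len.index)
        row = {
            "direction": label,
            "n_set": int(set_len.size),
            "mean_length_set": float(set_len.mean()) if set_len.size else np.nan,
            "mean_length_all": float(ref_len.mean()),
            "n_tests_in_family": family_size,
        }
        if set_len.size < 2:
            row.update(t=np.nan, p_raw=np.nan, p_bonferroni=np.nan,
                       testable=False)
        else:
            a, b = set_len.to_numpy(), ref_len.to_numpy()
            if log_length:
                a, b = np.log10(a), np.log10(b)
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            row.update(t=float(t), p_raw=float(p),
                       p_bonferroni=float(min(1.0, p * family_size)),
                       testable=True)
        rows.append(row)
    return pd.DataFrame(rows)


def boxplot_summary(values: pd.Series) -> dict:
    """Boxplot statistics for one set of gene lengths.

    Quartiles use linear interpolation (quantile type 7); whiskers extend
    to the most extreme data point within 1.5 x IQR of the box; the notch
    half-width is 1.58 x IQR / sqrt(n).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        return {"n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan,
                "iqr": np.nan, "whisker_low": np.nan, "whisker_high": np.nan,
                "notch_halfwidth": np.nan}
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    low_fence, high_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {
        "n": int(n),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": float(x[x >= low_fence].min()),
        "whisker_high": float(x[x <= high_fence].max()),
        "notch_halfwidth": float(1.58 * iqr / np.sqrt(n)),
    }


def de_length_pipeline(matrix: ExpressionMatrix, contrast: ConditionContrast,
                       annot: GeneAnnotation,
                       de_alpha: float = DE_ALPHA_DEFAULT,
                       family_size: int | None = None,
                       reference: str = "all",
                       equal_var: bool = False,
                       log_length: bool = False,
                       ) -> tuple[DEResult, pd.DataFrame, pd.DataFrame]:
    """Run DE calling, the length-shift tests, and boxplot summaries.

    ``family_size`` defaults to the number of direction tests performed in
    this run (2: up and down for one contrast); override it when combining
    contrasts into one test family. The boxplot table has one row per set
    ('up', 'down', 'all') with the statistics needed to draw notched
    boxplots of gene length.
    """
    de = per_gene_ttest(matrix, contrast, de_alpha, equal_var=equal_var)
    if family_size is None:
        family_size = 2
    shift = length_shift_test(de, annot, family_size=family_size,
                              reference=reference, equal_var=equal_var,
                              log_length=log_length)
    lengths = annot.lengths.reindex(de.table.index).dropna().astype(float)
    summaries = []
    for label, genes in (("up", de.up_genes), ("down", de.down_genes),
                         ("all", lengths.index)):
        row = {"set": label}
        row.update(boxplot_summary(lengths.reindex(genes).dropna()))
        summaries.append(row)
    return de, shift, pd.DataFrame(summaries)


def write_de_tables(de: DEResult, shift: pd.DataFrame, boxstats: pd.DataFrame,
                    outdir, metadata: Mapping[str, object] | None = None,
                    ) -> dict[str, Path]:
    """Write the DE gene table, the length-shift table and boxplot stats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = "".join(f"# {k}={v}\n" for k, v in (metadata or {}).items())
    paths = {}

    def _write(name: str, frame: pd.DataFrame, index: bool,
               extra: str = "") -> None:
        path = outdir / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header + extra)
            frame.to_csv(fh, sep="\t", index=index, float_format="%.10g")
        paths[name] = path

    _write("de_genes.tsv", de.table.rename_axis("gene_id"), True,
           extra=f"# de_alpha={de.de_alpha} test=welch\n")
    _write("length_shift.tsv", shift, False,
           extra="# length shift t-test vs all analyzed genes\n")
    _write("boxplot_stats.tsv", boxstats, False,
           extra="# quartiles: linear interpolation (type 7)\n")
    return paths
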