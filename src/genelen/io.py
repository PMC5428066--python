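"""Expression matrices, gene annotation, and the protein-coding filter.

Expression data enter the pipeline as delimited text (TSV or CSV), genes in
rows and samples in columns, with the first column holding gene identifiers.
Gene annotation is either a delimited table with columns
``gene_id, gene_length[, exon_length, biotype]`` or an Ensembl-dialect GTF
from which the same quantities are derived: ``gene_length`` is the genomic
span of the gene feature (end - start + 1, strand ignored) and
``exon_length`` is the length of the union of the gene's exon intervals
with overlaps merged.

Analysis is restricted to protein-coding genes present in both the matrix
and the annotation; genes without annotation are dropped with a logged
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("genelen")

#: Recognised value scales for an expression matrix.
SCALES = ("counts", "linear", "log2", "log10")

PROTEIN_CODING = "protein_coding"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a declared value scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. Values must
        be finite, and non-negative when ``scale`` is ``counts`` or
        ``linear``.
    scale
        One of ``counts``, ``linear``, ``log2``, ``log10``.
    conditions
        Optional map ``sample_id -> condition label``. Every key must be a
        column of ``values``.
    """

    values: pd.DataFrame
    scale: str
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(
                f"unknown scale {self.scale!r}; expected one of {SCALES}"
            )
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {v.index[i]!r}, sample "
                f"{v.columns[j]!r}"
            )
        if self.scale in ("counts", "linear") and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value on {self.scale} scale at gene "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )
        unknown = set(self.conditions) - set(v.columns)
        if unknown:
            raise ValueError(
                f"condition map names samples absent from the matrix: "
                f"{sorted(unknown)[:5]}"
            )

    @property
    def gene_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_for(self, condition: str) -> list[str]:
        """Sample ids carrying the given condition label, in column order."""
        return [s for s in self.values.columns
                if self.conditions.get(s) == condition]

    def with_values(self, values: pd.DataFrame,
                    scale: str | None = None) -> "ExpressionMatrix":
        """Copy of this matrix with new values (and optionally a new scale)."""
        cond = {s: c for s, c in self.conditions.items()
                if s in values.columns}
        return ExpressionMatrix(values, scale or self.scale, cond)


@dataclass
class GeneAnnotation:
    """Per-gene annotation: genomic length, exon-union length, biotype.

    ``table`` is indexed by gene id with columns ``gene_length`` (bp, >= 1),
    ``exon_length`` (bp, NaN when unknown, else 1 <= exon_length <=
    gene_length) and ``biotype`` (string label, may be missing).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in annotation: {dups[:5]}")
        if "gene_length" not in t.columns:
            raise ValueError("annotation requires a gene_length column")
        t = t.copy()
        t["gene_length"] = pd.to_numeric(t["gene_length"])
        if "exon_length" not in t.columns:
            t["exon_length"] = np.nan
        else:
            t["exon_length"] = pd.to_numeric(t["exon_length"])
        if "biotype" not in t.columns:
            t["biotype"] = PROTEIN_CODING
        if (t["gene_length"] < 1).any():
            bad = t.index[t["gene_length"] < 1].tolist()
            raise ValueError(f"gene_length < 1 bp for genes {bad[:5]}")
        exon = t["exon_length"]
        bad = exon.notna() & ((exon < 1) | (exon > t["gene_length"]))
        if bad.any():
            raise ValueError(
                "exon_length outside [1, gene_length] for genes "
                f"{t.index[bad].tolist()[:5]}"
            )
        self.table = t

    @property
    def lengths(self) -> pd.Series:
        return self.table["gene_length"]

    @property
    def gene_ids(self) -> list:
        return self.table.index.tolist()

    def protein_coding_ids(self) -> pd.Index:
        return self.table.index[self.table["biotype"] == PROTEIN_CODING]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    """Infer the delimiter: tab unless the first line is comma-delimited."""
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    return "\t"


def read_condition_map(path) -> dict[str, str]:
    """Read a two-column TSV ``sample_id<TAB>condition`` into a dict."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#",
                     dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: condition map needs two columns")
    # tolerate an optional header row
    if df.iloc[0, 0].lower() in ("sample", "sample_id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_expression_matrix(path, scale: str,
                           condition_map: Mapping[str, str] | str | Path | None = None,
                           transpose: bool = False) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix.

    Parameters
    ----------
    path
        TSV/CSV file; first column gene ids, header row sample ids.
    scale
        Declared scale of the stored values.
    condition_map
        Either a mapping ``sample_id -> condition``, or a path to a
        two-column TSV with that content.
    transpose
        Set for files stored samples-in-rows.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#",
                      float_precision="round_trip")
    if transpose:
        raw = raw.T
    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iloc[i, j]!r} at gene "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    conditions: dict[str, str] = {}
    if condition_map is not None:
        if isinstance(condition_map, (str, Path)):
            condition_map = read_condition_map(condition_map)
        missing = set(condition_map) - set(num.columns)
        if missing:
            raise ValueError(
                f"{path}: samples in condition map missing from header: "
                f"{sorted(missing)[:5]}"
            )
        conditions = dict(condition_map)
    return ExpressionMatrix(num, scale, conditions)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV, gene ids in the first column.

    Floats are written with shortest round-tripping repr, so
    read -> write -> read is value-identical.
    """
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation_table(path) -> GeneAnnotation:
    """Read annotation from a delimited table with a header row.

    Required column ``gene_length``; optional ``exon_length``, ``biotype``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#",
                     float_precision="round_trip")
    return GeneAnnotation(df)


def write_annotation(annot: GeneAnnotation, path) -> None:
    annot.table.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# GTF-derived lengths
# ---------------------------------------------------------------------------

def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def merged_interval_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    total += cur_end - cur_start + 1
    return total


def gene_lengths_from_gtf(path) -> GeneAnnotation:
    """Derive per-gene lengths from a GTF file.

    ``gene_length`` is the genomic span of the ``gene`` feature
    (end - start + 1); ``exon_length`` the union of the gene's exon
    intervals with overlaps merged, strand ignored. ``biotype`` comes from
    the ``gene_biotype`` attribute when present. Exons whose ``gene_id``
    matches no gene feature are skipped with a warning.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            feature, start, end, attr = fields[2], fields[3], fields[4], fields[8]
            if feature not in ("gene", "exon"):
                continue
            start, end = int(start), int(end)
            attrs = _parse_attributes(attr)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                if end < start:
                    raise ValueError(
                        f"{path}:{lineno}: gene {gene_id} has end < start"
                    )
                genes[gene_id] = {
                    "gene_length": end - start + 1,
                    "biotype": attrs.get("gene_biotype", PROTEIN_CODING),
                }
            else:
                exons.setdefault(gene_id, []).append((start, end))
    orphans = set(exons) - set(genes)
    if orphans:
        logger.warning("GTF %s: skipping exons for %d gene ids without a "
                       "gene feature", path.name, len(orphans))
    rows = {}
    for gid, info in genes.items():
        exon_len = merged_interval_length(exons.get(gid, []))
        rows[gid] = {
            "gene_length": info["gene_length"],
            "exon_length": exon_len if exon_len else np.nan,
            "biotype": info["biotype"],
        }
    if not rows:
        raise ValueError(f"{path}: no gene features found")
    table = pd.DataFrame.from_dict(rows, orient="index")
    return GeneAnnotation(table)


# ---------------------------------------------------------------------------
# protein-coding filter
# ---------------------------------------------------------------------------

def filter_protein_coding(matrix: ExpressionMatrix,
                          annot: GeneAnnotation) -> ExpressionMatrix:
    """Restrict the matrix to annotated protein-coding genes.

    Keeps exactly the genes that are protein_coding in the annotation and
    present in the matrix, preserving matrix row order and the full sample
    set. Genes missing from the annotation are dropped; the count is logged.
    Raises if no gene survives.
    """
    pc = set(annot.protein_coding_ids())
    keep = [g for g in matrix.values.index if g in pc]
    n_unannotated = sum(g not in set(annot.table.index)
                        for g in matrix.values.index)
    if n_unannotated:
        logger.info("filter_protein_coding: %d matrix genes had no "
                    "annotation entry", n_unannotated)
    if not keep:
        raise ValueError("no protein-coding genes shared between matrix "
                         "and annotation; nothing to analyze")
    logger.info("filter_protein_coding: %d -> %d genes",
                matrix.n_genes, len(keep))
    return ExpressionMatrix(matrix.values.loc[keep], matrix.scale,
                            dict(matrix.conditions))
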