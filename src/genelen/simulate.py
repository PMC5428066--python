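"""Synthetic datasets with planted gene-length structure.

Every stage of the pipeline is testable without external downloads: the
generator plants a known length-dependent log-fold-change slope (beta, in
log2 units per log10 bp) into a two-condition design, on either a
microarray-style log-intensity platform or an RNA-seq-style count platform,
and can compose tissue samples as linear-scale mixtures of cell-type
profiles whose proportions shift between conditions — the composition
mechanism by which neuronal loss produces a tissue-level down-shift of
long genes even when individual cells up-shift them.

Gene lengths follow a truncated log-normal spanning roughly 1 kb – 1 Mb,
matching the span of human protein-coding genes. All generators are pure
functions of their configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import (ExpressionMatrix, GeneAnnotation, PROTEIN_CODING,
                 write_annotation, write_matrix)


@dataclass
class SyntheticConfig:
    """Parameters of the two-condition planted-slope generator.

    Lengths are drawn log-normal on log10 scale (mean ``length_log10_mean``,
    sd ``length_log10_sd``) truncated to ``[length_min, length_max]`` bp.
    Baseline log2 expression is Gaussian per gene; case samples add
    ``beta * (log10 length - mean log10 length)`` so that the planted
    fold-change slope is ``beta`` (log2 units per log10 bp) with mean
    logfc ~ 0. Per-sample noise is Gaussian on the log2 scale for the
    intensity platform; the counts platform exponentiates the expected
    profile, scales each sample to ``count_depth`` expected reads, and
    draws Poisson counts.
    """

    n_genes: int = 5000
    length_log10_mean: float = 4.3
    length_log10_sd: float = 0.6
    length_min: float = 1e3
    length_max: float = 1e6
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    beta: float = 0.0
    noise_sd: float = 0.5
    n_case: int = 10
    n_control: int = 10
    platform: str = "intensity"
    count_depth: float = 2e6
    noncoding_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.platform not in ("intensity", "counts"):
            raise ValueError("platform must be 'intensity' or 'counts'")
        if not 0 <= self.noncoding_fraction < 1:
            raise ValueError("noncoding_fraction must be in [0, 1)")


@dataclass
class CellType:
    """One cell type of a tissue mixture.

    ``slope`` is the type's intrinsic length slope of mean log2 expression
    (neurons positive, glia ~0); ``case_shift_slope`` is an additional
    length-dependent shift planted in case-condition cells of this type
    (e.g. tangle-bearing neurons up-regulating long genes).
    """

    name: str
    slope: float = 0.0
    baseline_shift: float = 0.0
    case_shift_slope: float = 0.0


@dataclass
class MixtureConfig:
    """Cell types and their per-condition mixing proportions."""

    cell_types: tuple[CellType, ...]
    fraction_case: dict[str, float] = field(default_factory=dict)
    fraction_control: dict[str, float] = field(default_factory=dict)
    n_cells_per_type: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        names = [ct.name for ct in self.cell_types]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell type names")
        for label, frac in (("case", self.fraction_case),
                            ("control", self.fraction_control)):
            if set(frac) != set(names):
                raise ValueError(f"fraction_{label} must cover exactly the "
                                 f"cell types {names}")
            vals = np.array([frac[n] for n in names], dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"fraction_{label} outside [0, 1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"fraction_{label} must sum to 1, got "
                                 f"{vals.sum():.6f}")


def simulate_lengths(config: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> GeneAnnotation:
    """Draw per-gene lengths from the truncated log-normal.

    Exon length is a uniform fraction of the gene length (at least 1 bp).
    All genes are protein_coding except an optional non-coding spike-in
    fraction used to exercise the biotype filter.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = np.log10(config.length_min), np.log10(config.length_max)
    if hi < lo:
        raise ValueError("length_max below length_min")
    if lo == hi:
        log10_len = np.full(config.n_genes, lo)
    else:
        mu, sd = config.length_log10_mean, config.length_log10_sd
        if sd == 0:
            if not lo <= mu <= hi:
                raise ValueError("degenerate length distribution falls "
                                 "outside the truncation bounds")
            log10_len = np.full(config.n_genes, mu)
        else:
            a, b = (lo - mu) / sd, (hi - mu) / sd
            if b <= a:
                raise ValueError("truncation bounds exclude all mass")
            log10_len = stats.truncnorm.rvs(a, b, loc=mu, scale=sd,
                                            size=config.n_genes,
                                            random_state=rng)
    gene_length = np.maximum(np.round(10.0 ** log10_len), 1.0)
    exon_frac = rng.uniform(0.02, 1.0, size=config.n_genes)
    exon_length = np.maximum(np.round(exon_frac * gene_length), 1.0)
    biotype = np.full(config.n_genes, PROTEIN_CODING, dtype=object)
    n_nc = int(round(config.noncoding_fraction * config.n_genes))
    if n_nc:
        biotype[rng.choice(config.n_genes, size=n_nc, replace=False)] = \
            "lincRNA"
    ids = [f"G{i:06d}" for i in range(config.n_genes)]
    table = pd.DataFrame({
        "gene_length": gene_length,
        "exon_length": exon_length,
        "biotype": biotype,
    }, index=pd.Index(ids, name="gene_id"))
    return GeneAnnotation(table)


def _sample_names(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    case = [f"case_{i + 1}" for i in range(config.n_case)]
    ctrl = [f"control_{i + 1}" for i in range(config.n_control)]
    return case, ctrl


def expected_log2_profiles(config: SyntheticConfig, annot: GeneAnnotation,
                           rng: np.random.Generator,
                           ) -> tuple[pd.Series, pd.Series, float]:
    """Per-gene expected log2 expression for control and case conditions.

    Returns (control expectation, case expectation, length center); the
    case expectation adds beta * (log10 length - center) with the center at
    the mean log10 length, so the planted logfc averages ~0 over genes.
    """
    log10_len = np.log10(annot.lengths.to_numpy(dtype=float))
    center = float(log10_len.mean())
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=len(annot.table))
    ctrl = pd.Series(baseline, index=annot.table.index)
    case = ctrl + config.beta * (log10_len - center)
    return ctrl, case, center


def simulate_expression(config: SyntheticConfig, annot: GeneAnnotation,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[ExpressionMatrix, dict]:
    """Simulate a two-condition expression matrix with a planted slope.

    Returns the matrix (scale ``log2`` for intensity, ``counts`` for the
    count platform) and a truth record with the planted beta, the length
    center, and the per-gene expected logfc.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ctrl_mean, case_mean, center = expected_log2_profiles(config, annot, rng)
    case_names, ctrl_names = _sample_names(config)
    n_genes = len(annot.table)
    expect = np.column_stack(
        [case_mean.to_numpy()] * config.n_case
        + [ctrl_mean.to_numpy()] * config.n_control)
    log2_vals = expect + rng.normal(0.0, config.noise_sd, size=expect.shape)
    columns = case_names + ctrl_names
    conditions = {s: "case" for s in case_names}
    conditions.update({s: "control" for s in ctrl_names})
    truth = {
        "beta": config.beta,
        "center_log10_length": center,
        "expected_logfc": pd.Series(
            case_mean.to_numpy() - ctrl_mean.to_numpy(),
            index=annot.table.index),
        "seed": config.seed,
    }
    if config.platform == "intensity":
        frame = pd.DataFrame(log2_vals, index=annot.table.index,
                             columns=columns)
        return ExpressionMatrix(frame, "log2", conditions), truth
    # counts: exponentiate, rescale each sample to the target depth, then
    # multiply back by exon length so exon-density normalization recovers
    # the planted per-base profile
    linear = 2.0 ** log2_vals
    exon = annot.table["exon_length"].to_numpy(dtype=float)[:, None]
    lam = linear * exon
    lam *= config.count_depth / lam.sum(axis=0, keepdims=True)
    counts = rng.poisson(lam).astype(float)
    frame = pd.DataFrame(counts, index=annot.table.index, columns=columns)
    return ExpressionMatrix(frame, "counts", conditions), truth


def mix_profiles(profiles: dict[str, np.ndarray],
                 fractions: dict[str, float]) -> np.ndarray:
    """Proportion-weighted sum of linear-scale cell-type profiles."""
    keys = sorted(profiles)
    if set(fractions) != set(keys):
        raise ValueError("fractions must cover exactly the given profiles")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {total:.6f}")
    return sum(fractions[k] * np.asarray(profiles[k], dtype=float)
               for k in keys)


def simulate_cell_mixture(mix: MixtureConfig, config: SyntheticConfig,
                          annot: GeneAnnotation,
                          ) -> tuple[dict[str, ExpressionMatrix],
                                     ExpressionMatrix, dict]:
    """Simulate per-cell-type matrices and a tissue-level mixture.

    Each cell type's mean log2 profile is a shared per-gene baseline plus
    its own length slope; case cells of a type additionally receive that
    type's ``case_shift_slope``. Tissue samples mix the cell-type profiles
    on the linear scale with the per-condition proportions (physical mRNA
    pools add linearly), then return to log2; per-sample Gaussian log2
    noise is added at both levels.

    Returns (per-type matrices with case/control cells, tissue matrix,
    truth record).
    """
    rng = np.random.default_rng(mix.seed)
    log10_len = np.log10(annot.lengths.to_numpy(dtype=float))
    center = float(log10_len.mean())
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=len(annot.table))
    type_mean_ctrl: dict[str, np.ndarray] = {}
    type_mean_case: dict[str, np.ndarray] = {}
    for ct in mix.cell_types:
        mean = baseline + ct.baseline_shift + ct.slope * (log10_len - center)
        type_mean_ctrl[ct.name] = mean
        type_mean_case[ct.name] = mean + ct.case_shift_slope * (log10_len
                                                                - center)
    index = annot.table.index
    cells: dict[str, ExpressionMatrix] = {}
    for ct in mix.cell_types:
        cols, conds, mats = [], {}, []
        for cond, mean in (("case", type_mean_case[ct.name]),
                           ("control", type_mean_ctrl[ct.name])):
            for i in range(mix.n_cells_per_type):
                name = f"{ct.name}_{cond}_{i + 1}"
                cols.append(name)
                conds[name] = cond
                mats.append(mean + rng.normal(0.0, config.noise_sd,
                                              size=mean.size))
        frame = pd.DataFrame(np.column_stack(mats), index=index,
                             columns=cols)
        cells[ct.name] = ExpressionMatrix(frame, "log2", conds)
    # tissue: mix expected linear profiles, then add sample-level noise
    tissue_cols, tissue_conds, tissue_mat = [], {}, []
    for cond, fractions, means in (
            ("case", mix.fraction_case, type_mean_case),
            ("control", mix.fraction_control, type_mean_ctrl)):
        linear = mix_profiles({k: 2.0 ** v for k, v in means.items()},
                              fractions)
        log2_mean = np.log2(linear)
        n = config.n_case if cond == "case" else config.n_control
        for i in range(n):
            name = f"tissue_{cond}_{i + 1}"
            tissue_cols.append(name)
            tissue_conds[name] = cond
            tissue_mat.append(log2_mean + rng.normal(0.0, config.noise_sd,
                                                     size=log2_mean.size))
    tissue = ExpressionMatrix(
        pd.DataFrame(np.column_stack(tissue_mat), index=index,
                     columns=tissue_cols),
        "log2", tissue_conds)
    truth = {
        "center_log10_length": center,
        "cell_types": {ct.name: asdict(ct) for ct in mix.cell_types},
        "fraction_case": dict(mix.fraction_case),
        "fraction_control": dict(mix.fraction_control),
        "seed": mix.seed,
    }
    return cells, tissue, truth


def write_fixture_bundle(outdir, config: SyntheticConfig,
                         mix: MixtureConfig | None = None) -> dict[str, Path]:
    """Write a complete synthetic dataset bundle to ``outdir``.

    Emits matrix.tsv, annotation.tsv, conditions.tsv and truth.json;
    deterministic under the config seeds. With a mixture config the matrix
    is the tissue-level mixture, otherwise the plain two-condition design.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annot = simulate_lengths(config)
    rng = np.random.default_rng(config.seed + 1)
    if mix is None:
        matrix, truth = simulate_expression(config, annot, rng)
    else:
        _, matrix, truth = simulate_cell_mixture(mix, config, annot)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "annotation": outdir / "annotation.tsv",
        "conditions": outdir / "conditions.tsv",
        "truth": outdir / "truth.json",
    }
    write_matrix(matrix, paths["matrix"])
    write_annotation(annot, paths["annotation"])
    with open(paths["conditions"], "w", encoding="utf-8") as fh:
        for sample in matrix.sample_ids:
            fh.write(f"{sample}\t{matrix.conditions[sample]}\n")
    record = {k: v for k, v in truth.items() if k != "expected_logfc"}
    record["config"] = asdict(config)
    if mix is not None:
        record["mixture"] = {
            "cell_types": [asdict(ct) for ct in mix.cell_types],
            "fraction_case": mix.fraction_case,
            "fraction_control": mix.fraction_control,
        }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
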