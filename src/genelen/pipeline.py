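"""End-to-end pipeline driver: filter, normalize, curve, envelope, DE test.

Stages run in a fixed order: protein-coding filter -> platform
normalization (probe collapsing for intensities, exon-density for counts)
-> quantile normalization -> log fold change -> length-sorted window curve
-> shuffle null envelope and window flags -> per-gene DE calling and the
length-shift test. Every output TSV embeds the configuration and seed in
'#'-prefixed header lines, and a run log records the gene counts surviving
each stage so the filtering bookkeeping is auditable on any input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import curves, detest, envelope, io, normalize

logger = logging.getLogger("genelen")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults follow the analysis conventions throughout the package:
    windows of 200 length-consecutive genes advanced by 40, 100 shuffle
    iterations for a 95% envelope, and an uncorrected per-gene DE threshold
    of p < 0.01.
    """

    matrix: str = ""
    annotation: str = ""
    condition_map: str = ""
    outdir: str = "genelen_out"
    platform: str = "intensity"        # intensity | counts
    probe_map: str | None = None       # optional probe->gene TSV (intensity)
    quantile_on: str = "auto"          # auto | log | linear
    case_label: str = "case"
    control_label: str = "control"
    window: int = 200
    step: int = 40
    n_iterations: int = 100
    ci: float = 0.95
    de_alpha: float = 0.01
    family_size: int | None = None
    pseudocount: float | None = None
    with_replacement: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if not 0 < self.step <= self.window:
            raise ValueError("step must satisfy 0 < step <= window")
        if not 0 < self.ci < 1:
            raise ValueError("ci must be in (0, 1)")
        if self.platform not in ("intensity", "counts"):
            raise ValueError("platform must be 'intensity' or 'counts'")
        if self.quantile_on not in ("auto", "log", "linear"):
            raise ValueError("quantile_on must be auto, log or linear")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def metadata(self) -> dict:
        meta = asdict(self)
        meta.pop("outdir")
        return meta


@dataclass
class PipelineResult:
    """Outputs of one pipeline run, in memory and on disk."""

    curve: object
    envelope: object
    flags: object
    distance_summary: float
    de: object
    length_shift: object
    boxplot_stats: object
    paths: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                    from exc
            return False
    return _Ctx()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write the result bundle.

    Writes curve.tsv, envelope.tsv, de_genes.tsv, length_shift.tsv,
    boxplot_stats.tsv and run.log under ``config.outdir`` and returns the
    in-memory results. Deterministic for a fixed seed and inputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    with _stage("load"):
        scale = "log2" if config.platform == "intensity" else "counts"
        matrix = io.read_expression_matrix(config.matrix, scale=scale,
                                           condition_map=config.condition_map)
        annot_path = str(config.annotation)
        if annot_path.endswith((".gtf", ".gff")):
            annot = io.gene_lengths_from_gtf(annot_path)
        else:
            annot = io.read_annotation_table(annot_path)
        note(f"loaded matrix: {matrix.n_genes} genes x "
             f"{matrix.n_samples} samples ({config.platform})")
        note(f"loaded annotation: {len(annot.table)} genes")

    with _stage("probe_collapse"):
        if config.probe_map:
            pmap = normalize.read_probe_map(config.probe_map)
            matrix = normalize.collapse_probes(matrix, pmap)
            note(f"collapsed probes -> {matrix.n_genes} genes")

    with _stage("protein_coding_filter"):
        matrix = io.filter_protein_coding(matrix, annot)
        note(f"protein-coding filter -> {matrix.n_genes} genes")

    with _stage("normalize"):
        if config.platform == "counts":
            matrix = normalize.exon_density_normalize(matrix, annot)
            note("exon-density normalization (reads per exonic base)")
            qn_on = "linear" if config.quantile_on == "auto" \
                else config.quantile_on
            if qn_on == "log":
                matrix = normalize.log_transform(matrix, base=2,
                                                 pseudocount=config.pseudocount
                                                 if config.pseudocount
                                                 is not None else 1.0)
                matrix = normalize.quantile_normalize(matrix)
            else:
                matrix = normalize.quantile_normalize(matrix)
                matrix = normalize.log_transform(matrix, base=2,
                                                 pseudocount=config.pseudocount
                                                 if config.pseudocount
                                                 is not None else 1.0)
            note(f"quantile normalization on {qn_on} scale, then log2")
        else:
            matrix = normalize.quantile_normalize(matrix)
            note("quantile normalization on log2 intensities")

    with _stage("fold_change"):
        contrast = curves.ConditionContrast.from_labels(
            matrix, config.case_label, config.control_label)
        profile = curves.compute_fold_change(matrix, contrast, annot)
        note(f"fold change: {len(profile)} genes, "
             f"{len(contrast.case)} case vs {len(contrast.control)} control")

    with _stage("curve"):
        curve = curves.bin_curve(profile, config.window, config.step)
        note(f"binned curve: {len(curve)} windows "
             f"(window={config.window}, step={config.step})")

    with _stage("envelope"):
        env = envelope.bootstrap_envelope(
            profile, config.window, config.step,
            n_iterations=config.n_iterations, ci=config.ci,
            seed=config.seed, with_replacement=config.with_replacement)
        flags = envelope.call_significant_windows(curve, env)
        _, dist = envelope.envelope_distance(curve, env)
        counts = flags.value_counts().to_dict()
        note(f"envelope flags: {counts}; mean exceedance {dist:.4g}")

    with _stage("de_length_test"):
        de, shift, boxstats = detest.de_length_pipeline(
            matrix, contrast, annot, de_alpha=config.de_alpha,
            family_size=config.family_size)
        note(f"DE: {len(de.up_genes)} up, {len(de.down_genes)} down at "
             f"p < {config.de_alpha}")

    with _stage("write"):
        meta = config.metadata()
        paths = {"curve": outdir / "curve.tsv",
                 "envelope": outdir / "envelope.tsv"}
        curves.write_curve_tsv(curve, paths["curve"], meta)
        envelope.write_envelope_tsv(env, curve, flags, paths["envelope"],
                                    {"window": config.window,
                                     "step": config.step})
        paths.update(detest.write_de_tables(de, shift, boxstats, outdir,
                                            meta))
        log_path = outdir / "run.log"
        with open(log_path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(log_lines) + "\n")
        paths["log"] = log_path

    return PipelineResult(curve=curve, envelope=env, flags=flags,
                          distance_summary=dist, de=de, length_shift=shift,
                          boxplot_stats=boxstats, paths=paths)
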