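"""End-to-end orchestration: filter -> score -> compare, with a run manifest.

``run_pipeline`` reads two cohort variant tables and an interpreter-call
table, applies the pre-filters, computes per-gene accumulation scores for
each cohort, aggregates them over gene sets, computes the gene x sample
pathogenicity matrix for cohort A (with cohort-B counts alongside), extracts
the two recurrence lists, and writes everything as TSV plus a JSON manifest
(config hash, mapping hash, seed, package version). All randomness in a run
comes from the synthetic generator; the pipeline itself is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .accumulation import score_cohort, score_gene_sets
from .pathogenicity import (
    load_mapping,
    mapping_hash,
    read_interpreter_calls,
    recurrent_mutated_genes,
    recurrent_pathogenic_genes,
    score_pathogenicity,
)
from .variant_io import (
    DEFAULT_KEEP_CONSEQUENCES,
    DEFAULT_MAF_THRESHOLD,
    filter_variants,
    read_gene_sets,
    read_variant_table,
    summarize_counts,
    write_variant_table,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("mutacc")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    """Settings of one comparison run (defaults follow the study's filters)."""

    cohort_a_path: str
    cohort_b_path: str
    calls_path: str
    outdir: str
    format: str = "tsv"
    cohort_a_label: str = "cohort_A"
    cohort_b_label: str = "cohort_B"
    maf_threshold: float = DEFAULT_MAF_THRESHOLD
    keep_consequences: tuple[str, ...] = tuple(sorted(DEFAULT_KEEP_CONSEQUENCES))
    log_base: str = "e"
    mapping_path: str | None = None
    gene_sets_path: str | None = None
    min_samples: int = 5
    seed: int = 0
    make_figures: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()


def _samples_of(records) -> list[str]:
    return sorted({r.sample_id for r in records})


def _stage(name: str, path: str | None = None):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(
                f"stage {name!r} failed"
                + (f" on {path}" if path else "") + f": {exc}"
            ) from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return result
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run the full comparison; returns the manifest dict (also written)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    partial = True

    def emit(name: str, filename: str, frame: pd.DataFrame) -> None:
        path = outdir / filename
        frame.to_csv(path, sep="\t", index=False)
        outputs[name] = str(path)

    try:
        raw_a = _stage("read_a", config.cohort_a_path)(
            read_variant_table, config.cohort_a_path, config.format)
        raw_b = _stage("read_b", config.cohort_b_path)(
            read_variant_table, config.cohort_b_path, config.format)
        keep = frozenset(config.keep_consequences)
        filt_a = _stage("filter_a")(
            filter_variants, raw_a, config.maf_threshold, keep)
        filt_b = _stage("filter_b")(
            filter_variants, raw_b, config.maf_threshold, keep)
        write_variant_table(filt_a, outdir / "filtered_a.tsv")
        write_variant_table(filt_b, outdir / "filtered_b.tsv")
        outputs["filtered_a"] = str(outdir / "filtered_a.tsv")
        outputs["filtered_b"] = str(outdir / "filtered_b.tsv")

        samples_a, samples_b = _samples_of(raw_a), _samples_of(raw_b)
        scores_a = _stage("score_acc_a")(
            score_cohort, filt_a, samples_a, config.cohort_a_label,
            config.log_base)
        scores_b = _stage("score_acc_b")(
            score_cohort, filt_b, samples_b, config.cohort_b_label,
            config.log_base)
        emit("acc_scores_a", "acc_scores_a.tsv", scores_a)
        emit("acc_scores_b", "acc_scores_b.tsv", scores_b)

        if config.gene_sets_path:
            sets = _stage("gene_sets", config.gene_sets_path)(
                read_gene_sets, config.gene_sets_path)
            per_gene, set_summary = _stage("score_sets")(
                score_gene_sets, scores_a, scores_b, sets)
            emit("set_scores", "set_scores.tsv", per_gene)
            emit("set_summary", "set_summary.tsv", set_summary)
            if config.make_figures:
                from .plotting import gene_set_boxplot
                fig = gene_set_boxplot(per_gene)
                fig.savefig(outdir / "set_boxplot.png", dpi=150)
                outputs["set_boxplot"] = str(outdir / "set_boxplot.png")

        mapping = load_mapping(config.mapping_path)
        calls = _stage("read_calls", config.calls_path)(
            read_interpreter_calls, config.calls_path, mapping)
        path_a = _stage("score_path_a")(score_pathogenicity, calls, filt_a)
        path_b = _stage("score_path_b")(score_pathogenicity, calls, filt_b)
        emit("path_scores_a", "path_scores_a.tsv", path_a)
        emit("path_scores_b", "path_scores_b.tsv", path_b)

        genes_path, matrix, counts = _stage("recurrent_pathogenic")(
            recurrent_pathogenic_genes, path_a, config.min_samples, path_b)
        matrix.to_csv(outdir / "path_matrix_a.tsv", sep="\t")
        outputs["path_matrix_a"] = str(outdir / "path_matrix_a.tsv")
        emit("recurrent_pathogenic_counts", "recurrent_pathogenic_counts.tsv",
             counts)
        pd.DataFrame({"gene_symbol": genes_path}).to_csv(
            outdir / "recurrent_pathogenic_genes.tsv", sep="\t", index=False)
        outputs["recurrent_pathogenic_genes"] = str(
            outdir / "recurrent_pathogenic_genes.tsv")

        genes_mut, flags = _stage("recurrent_mutated")(
            recurrent_mutated_genes, filt_a, config.min_samples)
        flags.to_csv(outdir / "mutation_flags_a.tsv", sep="\t")
        outputs["mutation_flags_a"] = str(outdir / "mutation_flags_a.tsv")
        pd.DataFrame({"gene_symbol": genes_mut}).to_csv(
            outdir / "recurrent_mutated_genes.tsv", sep="\t", index=False)
        outputs["recurrent_mutated_genes"] = str(
            outdir / "recurrent_mutated_genes.tsv")

        if config.make_figures:
            from .plotting import pathogenicity_matrix_plot
            if not matrix.empty:
                fig = pathogenicity_matrix_plot(
                    matrix.loc[matrix.index.intersection(genes_path)])
                fig.savefig(outdir / "path_matrix.png", dpi=150)
                outputs["path_matrix_fig"] = str(outdir / "path_matrix.png")

        summary_rows = []
        for label, recs in ((config.cohort_a_label, filt_a),
                            (config.cohort_b_label, filt_b)):
            counts_summary = summarize_counts(recs)
            for kind in ("snv", "indel"):
                row = {"cohort": label, "kind": kind}
                row.update(counts_summary[kind])
                summary_rows.append(row)
        emit("count_summary", "count_summary.tsv", pd.DataFrame(summary_rows))
        partial = False
    finally:
        manifest = {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "mapping_hash": mapping_hash(load_mapping(config.mapping_path)),
            "seed": config.seed,
            "version": __version__,
            "outputs": outputs,
            "partial": partial,
        }
        with open(outdir / "manifest.json", "w", encoding="utf-8") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest
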