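"""Two-cohort synthetic somatic-variant generator with ground-truth labels.

Emulates the study design the scoring pipeline targets: a small
effusion-like cohort (A, default 9 samples) contrasted with a larger
comparison cohort (B, default 22 samples). "Hot" genes are planted with the
two signals the scores exploit — tightly clustered positions (within a
10 bp span, kataegis-style) carried recurrently at high VAF in cohort A,
plus majority-pathogenic interpreter verdicts — while background genes
receive sporadic, widely spaced, low-VAF mutations symmetrically in both
cohorts with benign/VUS verdicts.

The generator also plants the two kinds of records the pre-filter must
remove — common-polymorphism contamination (population MAF > 1%) and
synonymous calls — and bookkeeps exactly which rows it contaminated, so the
filter can be audited record-for-record. Contamination is confined to
background genes so the planted signal is not eroded by filtering.

Everything is deterministic given the spec's seed; per-gene substreams keep
outputs stable under unrelated spec edits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .pathogenicity import InterpreterCall, write_interpreter_calls
from .variant_io import VariantRecord, write_variant_table, write_vcf

__all__ = ["SyntheticSpec", "SyntheticCohorts", "generate_cohorts", "record_id"]

_BASES = ("A", "C", "G", "T")


@dataclass
class SyntheticSpec:
    """Parameters of the two-cohort simulation.

    VAFs are drawn from Beta distributions: hot-gene carriers around mean
    0.45 (clonal-ish), background around mean 0.15 (subclonal). Background
    mutations are spaced at least ``background_spacing_bp`` apart so their
    clustering term stays small; hot-gene clusters fit in
    ``hot_cluster_span_bp``.
    """

    n_cohort_a: int = 9
    n_cohort_b: int = 22
    n_genes: int = 30
    hot_genes: tuple[str, ...] = ("G001", "G002", "G003", "G004")
    hot_cluster_span_bp: int = 10
    hot_vaf: tuple[float, float] = (9.0, 11.0)  # Beta(a, b), mean 0.45
    background_vaf: tuple[float, float] = (3.0, 17.0)  # Beta(a, b), mean 0.15
    background_spacing_bp: int = 10_000
    hot_recurrence: float = 7 / 9
    interpreter_concordance: float = 0.8
    maf_contamination: float = 0.1
    synonymous_fraction: float = 0.1
    seed: int = 0

    def gene_universe(self) -> list[str]:
        background = [f"G{i:03d}" for i in range(1, self.n_genes + 1)
                      if f"G{i:03d}" not in self.hot_genes]
        return list(self.hot_genes) + background[: self.n_genes - len(self.hot_genes)]

    def validate(self) -> None:
        if self.n_cohort_a < 1 or self.n_cohort_b < 1:
            raise ValueError("cohort sizes must be >= 1")
        for name in ("hot_recurrence", "interpreter_concordance",
                     "maf_contamination", "synonymous_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hot_recurrence * self.n_cohort_a < 1:
            raise ValueError(
                "infeasible spec: hot_recurrence x n_cohort_a < 1 "
                "(no cohort-A sample would carry a hot-gene mutation)"
            )
        if len(self.hot_genes) >= self.n_genes:
            raise ValueError("hot_genes must leave room for background genes")
        if self.hot_cluster_span_bp < 1:
            raise ValueError("hot_cluster_span_bp must be >= 1")


@dataclass
class SyntheticCohorts:
    """Generated variant tables, interpreter calls and ground truth."""

    spec: SyntheticSpec
    samples_a: list[str]
    samples_b: list[str]
    cohort_a: list[VariantRecord]
    cohort_b: list[VariantRecord]
    calls: list[InterpreterCall]
    truth: dict

    def write(self, outdir: str | Path, vcf: bool = False) -> dict[str, str]:
        """Write TSV tables, the call table and the truth JSON; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cohort_a": str(outdir / "cohort_a.tsv"),
            "cohort_b": str(outdir / "cohort_b.tsv"),
            "calls": str(outdir / "interpreter_calls.tsv"),
            "truth": str(outdir / "truth.json"),
        }
        write_variant_table(self.cohort_a, paths["cohort_a"])
        write_variant_table(self.cohort_b, paths["cohort_b"])
        write_interpreter_calls(self.calls, paths["calls"])
        with open(paths["truth"], "w", encoding="utf-8") as handle:
            json.dump(self.truth, handle, indent=2, sort_keys=True)
        if vcf:
            paths["cohort_a_vcf"] = str(outdir / "cohort_a.vcf")
            paths["cohort_b_vcf"] = str(outdir / "cohort_b.vcf")
            write_vcf(self.cohort_a, paths["cohort_a_vcf"], self.samples_a)
            write_vcf(self.cohort_b, paths["cohort_b_vcf"], self.samples_b)
        return paths


def record_id(cohort: str, r: VariantRecord) -> str:
    """Stable bookkeeping identifier for one sample-variant row."""
    return "|".join(
        [cohort, r.sample_id, r.gene_symbol, r.chrom, str(r.pos), r.ref, r.alt]
    )


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _indel_alleles(rng: np.random.Generator) -> tuple[str, str, str]:
    anchor = _BASES[rng.integers(4)]
    inserted = "".join(_BASES[rng.integers(4)] for _ in range(1 + rng.integers(3)))
    if rng.random() < 0.5:
        return anchor, anchor + inserted, "insertion"
    return anchor + inserted, anchor, "deletion"


def _pathogenic_raws(rng: np.random.Generator) -> dict[str, object]:
    return {
        "InterVar": "Pathogenic",
        "ClinVar": rng.choice(["Pathogenic", "Likely_pathogenic"]),
        "SIFT": round(float(rng.uniform(0.0, 0.04)), 4),
        "CADD": round(float(rng.uniform(20.0, 35.0)), 2),
    }


def _benign_raws(rng: np.random.Generator) -> dict[str, object]:
    return {
        "InterVar": rng.choice(["Benign", "Likely_benign"]),
        "ClinVar": rng.choice(["Benign", "Likely_benign"]),
        "SIFT": round(float(rng.uniform(0.2, 1.0)), 4),
        "CADD": round(float(rng.uniform(0.0, 10.0)), 2),
    }


def _vus_raws(rng: np.random.Generator) -> dict[str, object]:
    return {
        "InterVar": "Uncertain_significance",
        "ClinVar": "Uncertain_significance",
        "SIFT": round(float(rng.uniform(0.05, 0.15)), 4),
        "CADD": round(float(rng.uniform(12.0, 15.0)), 2),
    }


def _calls_for(
    r: VariantRecord, raws: dict[str, object]
) -> list[InterpreterCall]:
    return [
        InterpreterCall.from_raw(
            r.gene_symbol, r.chrom, r.pos, r.ref, r.alt, r.sample_id,
            channel, raw,
        )
        for channel, raw in raws.items()
    ]


def _spaced_positions(
    rng: np.random.Generator, start: int, k: int, spacing: int
) -> list[int]:
    positions = []
    pos = start + int(rng.integers(0, 1000))
    for _ in range(k):
        positions.append(pos)
        pos += spacing + int(rng.integers(1, 1000))
    return positions


def generate_cohorts(spec: SyntheticSpec) -> SyntheticCohorts:
    """Simulate both cohorts, interpreter verdicts and the truth labels."""
    spec.validate()
    genes = spec.gene_universe()
    hot = set(spec.hot_genes)
    samples_a = [f"A{j:02d}" for j in range(1, spec.n_cohort_a + 1)]
    samples_b = [f"B{j:02d}" for j in range(1, spec.n_cohort_b + 1)]

    cohort_a: list[VariantRecord] = []
    cohort_b: list[VariantRecord] = []
    calls: list[InterpreterCall] = []
    contaminated: list[str] = []
    synonymous: list[str] = []
    planted_pathogenic: list[str] = []

    for gidx, gene in enumerate(genes):
        chrom = f"chr{(gidx % 22) + 1}"
        gene_start = 1_000_000 + gidx * 1_000_000
        struct_rng = np.random.default_rng([spec.seed, gidx])

        if gene in hot:
            _plant_hot_gene(
                spec, gene, chrom, gene_start, struct_rng,
                samples_a, samples_b, cohort_a, cohort_b, calls,
                planted_pathogenic,
            )
        else:
            for cohort_label, samples, records in (
                ("A", samples_a, cohort_a),
                ("B", samples_b, cohort_b),
            ):
                rng = np.random.default_rng(
                    [spec.seed, gidx, 0 if cohort_label == "A" else 1]
                )
                _plant_background_gene(
                    spec, gene, chrom, gene_start, rng, samples, records,
                    cohort_label, calls, contaminated, synonymous,
                )

    truth = {
        "hot_genes": sorted(hot),
        "background_genes": sorted(set(genes) - hot),
        "samples_a": samples_a,
        "samples_b": samples_b,
        "contaminated": sorted(contaminated),
        "synonymous": sorted(synonymous),
        "planted_pathogenic": sorted(planted_pathogenic),
        "seed": spec.seed,
    }
    return SyntheticCohorts(
        spec=spec, samples_a=samples_a, samples_b=samples_b,
        cohort_a=cohort_a, cohort_b=cohort_b, calls=calls, truth=truth,
    )


def _plant_hot_gene(
    spec, gene, chrom, gene_start, rng,
    samples_a, samples_b, cohort_a, cohort_b, calls, planted_pathogenic,
) -> None:
    # clustered distinct mutations within the span; index 0 is the anchor
    # shared by most carriers, so recurrence concentrates on one mutation
    n_distinct = int(rng.integers(2, 5))
    offsets = rng.choice(spec.hot_cluster_span_bp + 1, size=n_distinct,
                         replace=False)
    cluster_pos = sorted(gene_start + 200_000 + int(o) for o in offsets)
    mutations = []
    for i, pos in enumerate(cluster_pos):
        if i > 0 and rng.random() < 0.2:
            ref, alt, klass = _indel_alleles(rng)
            consequence = "frameshift"
        else:
            ref, alt = _snv_alleles(rng)
            klass = "SNV"
            consequence = str(rng.choice(["missense", "stop_gain", "splice"]))
        mutations.append((pos, ref, alt, klass, consequence))

    n_carriers = max(1, round(spec.hot_recurrence * spec.n_cohort_a))
    carriers = rng.choice(spec.n_cohort_a, size=n_carriers, replace=False)
    n_anchor = max(1, int(np.ceil(0.6 * n_carriers)))
    for rank, j in enumerate(sorted(int(c) for c in carriers)):
        mi = 0 if rank < n_anchor else int(rng.integers(1, len(mutations)))
        pos, ref, alt, klass, consequence = mutations[mi]
        vaf = float(rng.beta(*spec.hot_vaf))
        rec = VariantRecord(
            sample_id=samples_a[j], gene_symbol=gene, chrom=chrom, pos=pos,
            ref=ref, alt=alt, variant_class=klass, consequence=consequence,
            tumor_af=round(vaf, 4), population_maf=None,
        )
        cohort_a.append(rec)
        planted_pathogenic.append(record_id("A", rec))
        raws = _pathogenic_raws(rng)
        if rng.random() >= spec.interpreter_concordance:
            # discordant verdict: flip 1-3 channels to benign, keeping >=1
            # pathogenic so the most-pathogenic-wins consensus stays positive
            benign = _benign_raws(rng)
            n_flip = int(rng.integers(1, 4))
            for ch in rng.choice(list(raws), size=n_flip, replace=False):
                raws[ch] = benign[ch]
        calls.extend(_calls_for(rec, raws))

    # sparse presence in cohort B: 0-2 isolated low-VAF carriers
    n_b = int(rng.integers(0, 3))
    if n_b:
        positions = _spaced_positions(rng, gene_start, n_b,
                                      spec.background_spacing_bp)
        b_carriers = rng.choice(spec.n_cohort_b, size=n_b, replace=False)
        for pos, j in zip(positions, sorted(int(c) for c in b_carriers)):
            ref, alt = _snv_alleles(rng)
            rec = VariantRecord(
                sample_id=samples_b[j], gene_symbol=gene, chrom=chrom, pos=pos,
                ref=ref, alt=alt, variant_class="SNV", consequence="missense",
                tumor_af=round(float(rng.beta(*spec.background_vaf)), 4),
                population_maf=None,
            )
            cohort_b.append(rec)
            calls.extend(_calls_for(rec, _benign_raws(rng)))


def _plant_background_gene(
    spec, gene, chrom, gene_start, rng, samples, records,
    cohort_label, calls, contaminated, synonymous,
) -> None:
    # sporadic: at most 4 carriers per cohort, so a background gene can
    # never reach the 5-sample recurrence threshold in the default cohorts
    k = int(rng.integers(0, 5))
    if not k:
        return
    positions = _spaced_positions(rng, gene_start, k, spec.background_spacing_bp)
    carriers = rng.choice(len(samples), size=k, replace=False)
    for pos, j in zip(positions, sorted(int(c) for c in carriers)):
        if rng.random() < 0.15:
            ref, alt, klass = _indel_alleles(rng)
            consequence = "frameshift"
        else:
            ref, alt = _snv_alleles(rng)
            klass = "SNV"
            consequence = "missense"

        pop_maf = None
        is_syn = klass == "SNV" and rng.random() < spec.synonymous_fraction
        if is_syn:
            consequence = "synonymous"
        elif rng.random() < spec.maf_contamination:
            pop_maf = round(float(rng.uniform(0.011, 0.2)), 4)
        elif rng.random() < 0.2:
            # a benign, sub-threshold population frequency: retained
            pop_maf = round(float(rng.uniform(0.0, 0.01)), 4)

        rec = VariantRecord(
            sample_id=samples[j], gene_symbol=gene, chrom=chrom, pos=pos,
            ref=ref, alt=alt, variant_class=klass, consequence=consequence,
            tumor_af=round(float(rng.beta(*spec.background_vaf)), 4),
            population_maf=pop_maf,
        )
        records.append(rec)
        if is_syn:
            synonymous.append(record_id(cohort_label, rec))
        elif pop_maf is not None and pop_maf > 0.01:
            contaminated.append(record_id(cohort_label, rec))

        u = rng.random()
        if u < 0.05:
            raws = _pathogenic_raws(rng)
            benign = _benign_raws(rng)
            # lone pathogenic channel amid benign ones
            keep = rng.choice(list(raws))
            raws = {ch: (raws[ch] if ch == keep else benign[ch]) for ch in raws}
        elif u < 0.25:
            raws = _vus_raws(rng)
        else:
            raws = _benign_raws(rng)
        calls.extend(_calls_for(rec, raws))
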