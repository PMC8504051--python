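"""Reading, writing and pre-filtering of somatic variant tables and gene sets.

The analysis starts from *annotated* somatic calls: every record carries the
gene symbol, functional consequence and tumor variant allele fraction (VAF).
Two on-disk representations are supported and interconvertible:

* a tab-separated dialect (UTF-8, mandatory header, ``.`` for missing values)
  with one row per sample-variant pair, and
* VCF 4.x with per-sample ``AF`` or ``AD`` FORMAT fields and ``GENE`` /
  ``CONSEQUENCE`` / ``POP_MAF`` INFO keys.

Pre-filtering follows the germline-likelihood and consequence rules used for
cohort comparison: variants with population minor-allele frequency strictly
above the threshold are removed, and only protein-changing / splice
consequences are kept (synonymous calls are dropped by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

__all__ = [
    "VariantRecord",
    "GeneSetCollection",
    "ParseError",
    "RecordError",
    "VARIANT_CLASSES",
    "CONSEQUENCES",
    "DEFAULT_KEEP_CONSEQUENCES",
    "DEFAULT_MAF_THRESHOLD",
    "read_variant_table",
    "write_variant_table",
    "write_vcf",
    "filter_variants",
    "read_gene_sets",
    "summarize_counts",
]

VARIANT_CLASSES = frozenset({"SNV", "insertion", "deletion"})
CONSEQUENCES = frozenset(
    {
        "missense",
        "stop_gain",
        "stop_loss",
        "splice",
        "frameshift",
        "inframe_indel",
        "synonymous",
        "other",
    }
)

#: Consequences retained by default: exonic protein-changing or splice calls.
#: Synonymous SNVs and non-exonic ("other") calls are removed.
DEFAULT_KEEP_CONSEQUENCES = frozenset(
    {"missense", "stop_gain", "stop_loss", "splice", "frameshift", "inframe_indel"}
)

#: Population-MAF cutoff: variants with MAF strictly above 1% are treated as
#: likely germline polymorphisms and removed.
DEFAULT_MAF_THRESHOLD = 0.01

TSV_COLUMNS = [
    "sample_id",
    "gene_symbol",
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_class",
    "consequence",
    "tumor_af",
    "population_maf",
]


class ParseError(ValueError):
    """A variant or gene-set file could not be parsed (names the offending line)."""


class RecordError(ValueError):
    """A single record violates the variant-record invariants."""


def infer_variant_class(ref: str, alt: str) -> str:
    """Classify a ref/alt pair as SNV, insertion or deletion.

    Equal-length multi-base substitutions (MNVs) are not representable in the
    three-class scheme and raise :class:`RecordError`; they should be
    decomposed upstream.
    """
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(alt) < len(ref):
        return "deletion"
    raise RecordError(f"cannot classify equal-length substitution {ref}>{alt}")


@dataclass
class VariantRecord:
    """One called somatic variant in one sample.

    ``tumor_af`` is the variant allele fraction in the sample's reads;
    ``population_maf`` is the (optional) population minor-allele frequency
    used only by the germline-likelihood filter.
    """

    sample_id: str
    gene_symbol: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    consequence: str
    tumor_af: float
    population_maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise RecordError(f"{self.key()}: pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.tumor_af <= 1.0:
            raise RecordError(
                f"{self.key()}: tumor_af must be in [0, 1], got {self.tumor_af}"
            )
        if self.ref == self.alt:
            raise RecordError(f"{self.key()}: ref equals alt ({self.ref})")
        if self.variant_class not in VARIANT_CLASSES:
            raise RecordError(
                f"{self.key()}: unknown variant_class {self.variant_class!r}"
            )
        if self.consequence not in CONSEQUENCES:
            raise RecordError(
                f"{self.key()}: unknown consequence {self.consequence!r}"
            )
        expected = infer_variant_class(self.ref, self.alt)
        if self.variant_class != expected:
            raise RecordError(
                f"{self.key()}: variant_class {self.variant_class!r} inconsistent "
                f"with ref/alt lengths (expected {expected!r})"
            )
        if self.population_maf is not None and not 0.0 <= self.population_maf <= 1.0:
            raise RecordError(
                f"{self.key()}: population_maf must be in [0, 1], "
                f"got {self.population_maf}"
            )

    def key(self) -> tuple[str, str, int, str, str]:
        """Mutation identity: (gene, chrom, pos, ref, alt)."""
        return (self.gene_symbol, self.chrom, self.pos, self.ref, self.alt)

    def is_snv(self) -> bool:
        return self.variant_class == "SNV"

    def is_indel(self) -> bool:
        return self.variant_class in ("insertion", "deletion")


@dataclass
class GeneSetCollection:
    """Named gene lists (pathways or functional groups) for score aggregation."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            # dedup, preserving first-seen order
            self.sets[name] = list(dict.fromkeys(genes))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        if name not in self.sets:
            raise KeyError(f"unknown gene set {name!r}")
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# Tab-separated dialect


def _parse_tsv_row(row: pd.Series, lineno: int) -> VariantRecord:
    def missing(v) -> bool:
        return v is None or (isinstance(v, float) and math.isnan(v)) or v == "."

    try:
        maf = row["population_maf"]
        return VariantRecord(
            sample_id=str(row["sample_id"]),
            gene_symbol=str(row["gene_symbol"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            variant_class=str(row["variant_class"]),
            consequence=str(row["consequence"]),
            tumor_af=float(row["tumor_af"]),
            population_maf=None if missing(maf) else float(maf),
        )
    except (RecordError, ValueError, KeyError) as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def _read_tsv(path: Path) -> list[VariantRecord]:
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            dtype=str,
            na_values=["."],
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing_cols = [c for c in TSV_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ParseError(f"{path}: header missing columns {missing_cols}")
    records = []
    for i, row in frame.iterrows():
        # +2: header line plus 1-based numbering
        records.append(_parse_tsv_row(row, lineno=i + 2))
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records in the tab-separated dialect (``.`` for missing MAF)."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "gene_symbol": r.gene_symbol,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "variant_class": r.variant_class,
                "consequence": r.consequence,
                "tumor_af": repr(r.tumor_af),
                "population_maf": "." if r.population_maf is None else repr(r.population_maf),
            }
        )
    frame = pd.DataFrame(rows, columns=TSV_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF


def _vcf_sample_vaf(sample_data, alt_index: int, where: str) -> float | None:
    """Per-sample VAF for one alt allele: FORMAT AF, else derived from AD.

    Returns None when the sample does not carry the allele (VAF 0 or no data).
    Raises :class:`RecordError` when read depths are present but uninformative.
    """
    af = sample_data.get("AF")
    if af is not None:
        value = af[alt_index - 1] if isinstance(af, (tuple, list)) else af
        if value is None:
            return None
        return float(value)
    ad = sample_data.get("AD")
    if ad is None:
        return None
    if isinstance(ad, (tuple, list)):
        ref_depth, alt_depth = ad[0], ad[alt_index]
    else:  # single value is ambiguous
        raise RecordError(f"{where}: AD field has a single value; VAF underivable")
    if ref_depth is None or alt_depth is None:
        return None
    denom = ref_depth + alt_depth
    if denom == 0:
        raise RecordError(f"{where}: AD depths sum to zero; VAF underivable")
    return alt_depth / denom


def _info_scalar(value, alt_index: int):
    if isinstance(value, (tuple, list)):
        return value[alt_index - 1]
    return value


def _read_vcf(path: Path) -> list[VariantRecord]:
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    records: list[VariantRecord] = []
    has_pop_maf = "POP_MAF" in vcf.header.info
    with vcf:
        for rec in vcf:
            where = f"{rec.chrom}:{rec.pos}"
            gene_info = rec.info.get("GENE")
            if gene_info is None:
                raise ParseError(f"{where}: missing GENE INFO field")
            if isinstance(gene_info, (tuple, list)):
                gene_info = ",".join(gene_info)
            genes = [g for g in str(gene_info).split(",") if g]
            consequence = rec.info.get("CONSEQUENCE")
            if consequence is None:
                raise ParseError(f"{where}: missing CONSEQUENCE INFO field")
            pop_maf = rec.info.get("POP_MAF") if has_pop_maf else None
            # multi-allelic sites: one record per alt allele
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                maf = _info_scalar(pop_maf, alt_index)
                for sample_name, sample_data in rec.samples.items():
                    vaf = _vcf_sample_vaf(sample_data, alt_index, where)
                    if vaf is None or vaf == 0.0:
                        continue
                    for gene in genes:
                        records.append(
                            VariantRecord(
                                sample_id=sample_name,
                                gene_symbol=gene,
                                chrom=rec.chrom,
                                pos=rec.pos,
                                ref=rec.ref,
                                alt=alt,
                                variant_class=infer_variant_class(rec.ref, alt),
                                consequence=str(
                                    _info_scalar(consequence, alt_index)
                                ),
                                tumor_af=vaf,
                                population_maf=None if maf is None else float(maf),
                            )
                        )
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    samples: Sequence[str] | None = None,
) -> None:
    """Write records as an uncompressed multi-sample VCF 4.2.

    One VCF row per distinct (chrom, pos, ref, alt, gene); carriers get their
    VAF in the per-sample ``AF`` FORMAT field, non-carriers get ``AF=0``.
    """
    if samples is None:
        samples = sorted({r.sample_id for r in records})
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line(
        '##INFO=<ID=CONSEQUENCE,Number=1,Type=String,Description="Functional consequence">'
    )
    header.add_line(
        '##INFO=<ID=POP_MAF,Number=1,Type=Float,Description="Population minor allele frequency">'
    )
    header.add_line(
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Variant allele fraction">'
    )
    for chrom in sorted({r.chrom for r in records}):
        header.add_line(f"##contig=<ID={chrom}>")
    for s in samples:
        header.add_sample(s)

    grouped: dict[tuple, list[VariantRecord]] = {}
    for r in records:
        grouped.setdefault((r.chrom, r.pos, r.ref, r.alt, r.gene_symbol), []).append(r)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos, ref, alt, gene), group in sorted(grouped.items()):
            rec = out.new_record(
                contig=chrom, start=pos - 1, alleles=(ref, alt), filter="PASS"
            )
            first = group[0]
            rec.info["GENE"] = gene
            rec.info["CONSEQUENCE"] = first.consequence
            if first.population_maf is not None:
                rec.info["POP_MAF"] = first.population_maf
            vafs = {g.sample_id: g.tumor_af for g in group}
            for s in samples:
                rec.samples[s]["AF"] = (vafs.get(s, 0.0),)
            out.write(rec)


def read_variant_table(path: str | Path, format: str = "tsv") -> list[VariantRecord]:
    """Read an annotated variant table; one record per sample-variant pair.

    Parameters
    ----------
    path
        Input file.
    format
        ``"tsv"`` for the tab-separated dialect or ``"vcf"`` for VCF 4.x
        with per-sample AF/AD; VAF is derived as alt/(ref+alt) from AD when
        AF is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'vcf')")


# ---------------------------------------------------------------------------
# Filtering


def keep_record(
    record: VariantRecord,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    keep_consequences: frozenset[str] | set[str] = DEFAULT_KEEP_CONSEQUENCES,
) -> bool:
    """Filter predicate for one record.

    A record is retained when its population MAF is absent or does not exceed
    the threshold (the removal rule is *strictly greater than*, so a MAF equal
    to the threshold is retained) and its consequence is in the keep set.
    """
    maf_ok = record.population_maf is None or record.population_maf <= maf_threshold
    return maf_ok and record.consequence in keep_consequences


def filter_variants(
    records: Sequence[VariantRecord],
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    keep_consequences: frozenset[str] | set[str] = DEFAULT_KEEP_CONSEQUENCES,
) -> list[VariantRecord]:
    """Apply the population-MAF and consequence pre-filters, preserving order."""
    if not 0.0 <= maf_threshold <= 1.0:
        raise ValueError(f"maf_threshold must be in [0, 1], got {maf_threshold}")
    if not keep_consequences:
        raise ValueError("keep_consequences must be non-empty")
    unknown = set(keep_consequences) - CONSEQUENCES
    if unknown:
        raise ValueError(f"unknown consequences in keep set: {sorted(unknown)}")
    return [r for r in records if keep_record(r, maf_threshold, keep_consequences)]


# ---------------------------------------------------------------------------
# Gene sets (GMT)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB genes...``."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ParseError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# Count summaries


def summarize_counts(records: Sequence[VariantRecord]) -> dict:
    """Per-sample SNV/indel counts with cohort totals, medians and ranges.

    Returns a dict with a ``per_sample`` DataFrame (sample_id, n_snv, n_indel)
    and, for each of ``snv`` and ``indel``, the cohort total, median, min and
    max of the per-sample counts. With no input the counts are zero and the
    median is reported as None (flagged undefined).
    """
    per_sample: dict[str, dict[str, int]] = {}
    for r in records:
        entry = per_sample.setdefault(r.sample_id, {"n_snv": 0, "n_indel": 0})
        if r.is_snv():
            entry["n_snv"] += 1
        else:
            entry["n_indel"] += 1
    frame = pd.DataFrame(
        [
            {"sample_id": s, "n_snv": v["n_snv"], "n_indel": v["n_indel"]}
            for s, v in sorted(per_sample.items())
        ],
        columns=["sample_id", "n_snv", "n_indel"],
    )

    def stats(col: str) -> dict:
        if frame.empty:
            return {"total": 0, "median": None, "min": 0, "max": 0}
        values = frame[col]
        return {
            "total": int(values.sum()),
            "median": float(values.median()),
            "min": int(values.min()),
            "max": int(values.max()),
        }

    return {"per_sample": frame, "snv": stats("n_snv"), "indel": stats("n_indel")}
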