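"""Four-channel consensus pathogenicity scoring of mutated genes.

Four interpreter channels (InterVar, ClinVar, SIFT, CADD) each deliver a
verdict per mutation. Verdicts are normalized to a signed scale — positive
pathogenic, negative benign, 0 for variants of uncertain significance (VUS)
or missing annotation — and the *most pathogenic* (maximum) normalized score
wins as the mutation's consensus score. Per gene and sample, positive
mutation scores are summed; a gene-sample with no pathogenic mutation is
scored 0 if any mutation is a VUS, else by its least-benign (maximum,
still negative) mutation.

The gene-sample score *s* is binned as: benign (s < 0), VUS (s = 0),
pathogenic low (0 < s < 10), mid (10 <= s <= 20) or high (s > 20).

The interpreters themselves are upstream inputs; only the raw->signed
mapping lives here, in a user-overridable config whose SHA-256 hash is
recorded in outputs. The shipped default maps the five-tier categorical
verdicts of InterVar/ClinVar to symmetric scores and the SIFT/CADD numeric
scores through their standard damaging thresholds (SIFT < 0.05 damaging;
CADD phred above 15), scaled so single-channel pathogenic scores fall
roughly in (0, 10].
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .variant_io import VariantRecord

__all__ = [
    "CHANNELS",
    "DEFAULT_MAPPING",
    "InterpreterCall",
    "GeneSampleScore",
    "load_mapping",
    "mapping_hash",
    "normalize_call",
    "consensus_mutation_score",
    "gene_sample_score",
    "classify_score",
    "score_pathogenicity",
    "recurrent_pathogenic_genes",
    "recurrent_mutated_genes",
    "read_interpreter_calls",
    "write_interpreter_calls",
]

CHANNELS = ("InterVar", "ClinVar", "SIFT", "CADD")

#: Default raw->signed mapping. Categorical channels use the ACMG five-tier
#: vocabulary; numeric channels are transformed through a damaging threshold.
DEFAULT_MAPPING: dict = {
    "InterVar": {
        "type": "categorical",
        "scores": {
            "pathogenic": 7.8,
            "likely pathogenic": 3.9,
            "uncertain significance": 0.0,
            "likely benign": -3.9,
            "benign": -7.8,
        },
    },
    "ClinVar": {
        "type": "categorical",
        "scores": {
            "pathogenic": 6.2,
            "likely pathogenic": 3.1,
            "uncertain significance": 0.0,
            "likely benign": -3.1,
            "benign": -6.2,
        },
    },
    # SIFT: tolerance probability in [0, 1]; < 0.05 is damaging. Scores are
    # scaled into (0, 6.1] (damaging) / [-6.1, 0] (tolerated).
    "SIFT": {"type": "sift", "damaging_threshold": 0.05, "scale": 6.1},
    # CADD: phred-scaled score; 15 is a common deleteriousness cutoff.
    # (v - 15) / 3.5, clipped to [-10, 10].
    "CADD": {"type": "cadd", "threshold": 15.0, "scale": 3.5, "cap": 10.0},
}


def mapping_hash(mapping: dict) -> str:
    """SHA-256 of the canonical JSON serialization of a mapping config."""
    blob = json.dumps(mapping, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()


def load_mapping(path: str | Path | None) -> dict:
    """Load a mapping config from YAML/JSON, or return the shipped default."""
    if path is None:
        return DEFAULT_MAPPING
    with open(path, encoding="utf-8") as handle:
        mapping = yaml.safe_load(handle)
    if not isinstance(mapping, dict):
        raise ValueError(f"{path}: mapping config must be a mapping at top level")
    return mapping


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() in ("", ".", "NA", "nan"):
        return True
    return False


def normalize_call(channel: str, raw_value, mapping: dict | None = None) -> float:
    """Normalize one channel's raw verdict to the signed pathogenicity scale.

    Unknown categories and missing values map to 0 (the VUS convention).
    A channel absent from the mapping config is an error.
    """
    mapping = DEFAULT_MAPPING if mapping is None else mapping
    if channel not in mapping:
        raise KeyError(f"channel {channel!r} missing from mapping config")
    spec = mapping[channel]
    if _is_missing(raw_value):
        return 0.0
    kind = spec["type"]
    if kind == "categorical":
        key = str(raw_value).strip().lower().replace("_", " ")
        return float(spec["scores"].get(key, 0.0))
    try:
        v = float(raw_value)
    except (TypeError, ValueError):
        return 0.0
    if kind == "sift":
        thr, scale = spec["damaging_threshold"], spec["scale"]
        if v < thr:
            return scale * (thr - v) / thr
        return -scale * (v - thr) / (1.0 - thr)
    if kind == "cadd":
        thr, scale, cap = spec["threshold"], spec["scale"], spec["cap"]
        return float(min(max((v - thr) / scale, -cap), cap))
    raise ValueError(f"channel {channel!r}: unknown mapping type {kind!r}")


@dataclass
class InterpreterCall:
    """One interpreter channel's verdict for one mutation in one sample."""

    gene_symbol: str
    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    channel: str
    raw_value: object
    norm_score: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(
                f"channel must be one of {CHANNELS}, got {self.channel!r}"
            )

    def mutation_key(self) -> tuple[str, str, int, str, str]:
        return (self.gene_symbol, self.chrom, self.pos, self.ref, self.alt)

    @classmethod
    def from_raw(
        cls,
        gene_symbol: str,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        sample_id: str,
        channel: str,
        raw_value,
        mapping: dict | None = None,
    ) -> "InterpreterCall":
        return cls(
            gene_symbol, chrom, pos, ref, alt, sample_id, channel, raw_value,
            norm_score=normalize_call(channel, raw_value, mapping),
        )


BIN_LABELS = ("benign", "VUS", "pathogenic_low", "pathogenic_mid", "pathogenic_high")


def classify_score(s: float) -> str:
    """Bin a gene-sample score: the partition is exhaustive over the reals."""
    if s < 0:
        return "benign"
    if s == 0:
        return "VUS"
    if s < 10:
        return "pathogenic_low"
    if s <= 20:
        return "pathogenic_mid"
    return "pathogenic_high"


@dataclass
class GeneSampleScore:
    """Summed-pathogenic score of one gene in one sample, with its class."""

    gene_symbol: str
    sample_id: str
    s: float
    klass: str


def consensus_mutation_score(calls: Sequence[InterpreterCall]) -> float:
    """Most-pathogenic-wins consensus: the maximum normalized channel score."""
    if not calls:
        raise ValueError("consensus requires at least one interpreter call")
    keys = {c.mutation_key() for c in calls}
    if len(keys) > 1:
        raise ValueError(f"calls span multiple mutations: {sorted(keys)}")
    return max(c.norm_score for c in calls)


def gene_sample_score(
    mutation_scores: Iterable[float], gene_symbol: str = "", sample_id: str = ""
) -> GeneSampleScore:
    """Aggregate one gene's per-mutation consensus scores within one sample.

    Pathogenic (positive) scores are summed. With no pathogenic mutation the
    gene-sample is VUS (0) if any mutation scored 0, otherwise it takes the
    least-benign (maximum, negative) score.
    """
    scores = list(mutation_scores)
    if not scores:
        raise ValueError("gene_sample_score requires at least one mutation score")
    positives = [x for x in scores if x > 0]
    if positives:
        s = float(sum(positives))
    elif any(x == 0 for x in scores):
        s = 0.0
    else:
        s = float(max(scores))
    return GeneSampleScore(gene_symbol, sample_id, s, classify_score(s))


def score_pathogenicity(
    calls: Sequence[InterpreterCall],
    restrict_to: Sequence[VariantRecord] | None = None,
) -> pd.DataFrame:
    """Per gene-per sample consensus pathogenicity scores from interpreter calls.

    ``restrict_to`` limits scoring to the sample-mutation pairs present in a
    (typically filtered) variant table; variants in that table with no
    interpreter call at all are excluded from scoring and reported in the
    companion column ``annotated`` of the result's ``attrs['unannotated']``
    list, rather than being treated as 0-score calls.

    Returns one row per (gene_symbol, sample_id) with columns ``s`` and
    ``klass``.
    """
    allowed: set[tuple] | None = None
    if restrict_to is not None:
        allowed = {(r.key(), r.sample_id) for r in restrict_to}

    per_mutation: dict[tuple, list[InterpreterCall]] = {}
    for c in calls:
        k = (c.mutation_key(), c.sample_id)
        if allowed is not None and k not in allowed:
            continue
        per_mutation.setdefault(k, []).append(c)

    per_gene_sample: dict[tuple[str, str], list[float]] = {}
    for (mkey, sample_id), group in per_mutation.items():
        score = consensus_mutation_score(group)
        per_gene_sample.setdefault((mkey[0], sample_id), []).append(score)

    rows = []
    for (gene, sample_id), scores in sorted(per_gene_sample.items()):
        gss = gene_sample_score(scores, gene, sample_id)
        rows.append(
            {"gene_symbol": gene, "sample_id": sample_id, "s": gss.s,
             "klass": gss.klass}
        )
    frame = pd.DataFrame(rows, columns=["gene_symbol", "sample_id", "s", "klass"])
    if allowed is not None:
        called = set(per_mutation)
        frame.attrs["unannotated"] = sorted(
            ("{}:{}:{}:{}>{}".format(*mkey), sample)
            for (mkey, sample) in allowed - called
        )
    return frame


def recurrent_pathogenic_genes(
    scores: pd.DataFrame,
    min_samples: int = 5,
    other_scores: pd.DataFrame | None = None,
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Genes pathogenic (s > 0) in at least ``min_samples`` samples of a cohort.

    Returns ``(genes, matrix, counts)``: the recurrent gene list, the full
    gene x sample score matrix (NaN where the gene-sample was not scored),
    and per-gene pathogenic-sample counts — with the analogous count in a
    second cohort when ``other_scores`` is supplied.
    """
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    if scores.empty:
        empty = pd.DataFrame(columns=["gene_symbol", "n_pathogenic_samples"])
        return [], pd.DataFrame(), empty

    matrix = scores.pivot_table(
        index="gene_symbol", columns="sample_id", values="s", aggfunc="first"
    )
    pathogenic = scores[scores["s"] > 0]
    counts = (
        pathogenic.groupby("gene_symbol")["sample_id"].nunique()
        .reindex(matrix.index, fill_value=0)
        .rename("n_pathogenic_samples")
        .reset_index()
    )
    if other_scores is not None and not other_scores.empty:
        other = other_scores[other_scores["s"] > 0]
        other_counts = other.groupby("gene_symbol")["sample_id"].nunique()
        counts["n_pathogenic_samples_other"] = (
            counts["gene_symbol"].map(other_counts).fillna(0).astype(int)
        )
    genes = sorted(
        counts.loc[counts["n_pathogenic_samples"] >= min_samples, "gene_symbol"]
    )
    return genes, matrix, counts


def recurrent_mutated_genes(
    records: Sequence[VariantRecord], min_samples: int = 5
) -> tuple[list[str], pd.DataFrame]:
    """Genes carrying SNVs, indels or both in at least ``min_samples`` samples.

    Returns the recurrent gene list and a gene x sample flag matrix with
    values in {"none", "SNV", "indel", "both"}.
    """
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    if not records:
        return [], pd.DataFrame()
    kinds: dict[tuple[str, str], set[str]] = {}
    for r in records:
        kinds.setdefault((r.gene_symbol, r.sample_id), set()).add(
            "SNV" if r.is_snv() else "indel"
        )
    genes = sorted({g for g, _ in kinds})
    samples = sorted({s for _, s in kinds})
    flags = pd.DataFrame("none", index=pd.Index(genes, name="gene_symbol"),
                         columns=pd.Index(samples, name="sample_id"))
    for (gene, sample), kind in kinds.items():
        flags.loc[gene, sample] = "both" if len(kind) == 2 else next(iter(kind))
    counts = (flags != "none").sum(axis=1)
    recurrent = sorted(counts.index[counts >= min_samples])
    return recurrent, flags


# ---------------------------------------------------------------------------
# Interpreter-call table I/O

CALL_COLUMNS = [
    "sample_id", "gene_symbol", "chrom", "pos", "ref", "alt",
    "channel", "raw_value",
]


def read_interpreter_calls(
    path: str | Path, mapping: dict | None = None
) -> list[InterpreterCall]:
    """Read a per-mutation interpreter-verdict TSV and normalize its verdicts."""
    frame = pd.read_csv(path, sep="\t", dtype=str, na_values=["."],
                        keep_default_na=False)
    missing = [c for c in CALL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: call table missing columns {missing}")
    calls = []
    for _, row in frame.iterrows():
        calls.append(
            InterpreterCall.from_raw(
                gene_symbol=row["gene_symbol"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                sample_id=row["sample_id"],
                channel=row["channel"],
                raw_value=row["raw_value"],
                mapping=mapping,
            )
        )
    return calls


def write_interpreter_calls(
    calls: Sequence[InterpreterCall], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "gene_symbol": c.gene_symbol,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "channel": c.channel,
            "raw_value": "." if _is_missing(c.raw_value) else c.raw_value,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)
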