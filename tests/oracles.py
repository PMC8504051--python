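"""Brute-force reference implementations used as independent oracles.

These deliberately avoid the package's pivoting/sorting machinery: distances
are recomputed over all mutation pairs, aggregations are naive loops.
"""

import math


def brute_gene_acc_scores(records, cohort_samples, log=math.log):
    """Per-gene accumulation scores from raw (sample, gene, chrom, pos, ref,
    alt, vaf) tuples, enumerating all pairwise distances.

    Returns {gene: score}.
    """
    n = len(cohort_samples)
    # distinct mutations with per-sample max VAF
    af = {}
    for sample, gene, chrom, pos, ref, alt, vaf in records:
        key = (gene, chrom, pos, ref, alt)
        af.setdefault(key, {})
        af[key][sample] = max(af[key].get(sample, 0.0), vaf)

    genes = {k[0] for k in af}
    scores = {}
    for gene in genes:
        mutations = [k for k in af if k[0] == gene]
        best = None
        for key in mutations:
            mean_af = sum(af[key].values()) / n
            d_min = math.inf
            for other in mutations:
                if other == key:
                    continue
                d_min = min(d_min, abs(key[2] - other[2]))
            term = 0.0 if math.isinf(d_min) else 1.0 / (log(d_min + 1) + 1)
            score = mean_af + term
            if best is None or score > best:
                best = score
        scores[gene] = best
    return scores


def brute_gene_sample_scores(mutation_scores):
    """{(gene, sample): s} from {(gene, sample): [consensus scores]}."""
    out = {}
    for key, scores in mutation_scores.items():
        pos = [x for x in scores if x > 0]
        if pos:
            s = 0.0
            for x in pos:
                s += x
        elif 0 in scores or 0.0 in scores:
            s = 0.0
        else:
            s = max(scores)
        out[key] = s
    return out


def brute_consensus(norm_scores):
    best = None
    for x in norm_scores:
        if best is None or x > best:
            best = x
    return best


def brute_recurrent_counts(gene_sample_s):
    """{gene: #samples with s > 0} from {(gene, sample): s}."""
    counts = {}
    for (gene, sample), s in gene_sample_s.items():
        counts.setdefault(gene, set())
        if s > 0:
            counts[gene].add(sample)
    return {g: len(v) for g, v in counts.items()}


def brute_mutation_flags(records):
    """{(gene, sample): flag} with flag in {SNV, indel, both}."""
    flags = {}
    for r in records:
        kind = "SNV" if r.variant_class == "SNV" else "indel"
        prev = flags.get((r.gene_symbol, r.sample_id))
        if prev is None:
            flags[(r.gene_symbol, r.sample_id)] = kind
        elif prev != kind:
            flags[(r.gene_symbol, r.sample_id)] = "both"
    return flags
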