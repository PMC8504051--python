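# Methods

## Problem and scope

Given two cohorts of annotated somatic variant calls (per sample: gene,
position, ref/alt, consequence, tumor VAF, optional population MAF), the
package identifies genes that are preferentially altered in one cohort via
two complementary per-gene statistics — a mutation accumulation score and a
consensus pathogenicity score — and reports recurrently altered genes,
optionally grouped by pathway. Alignment, variant calling and functional
annotation are upstream of this package; interpreter verdicts are inputs,
not reimplementations.

## Mutation accumulation score

For a cohort of `n` samples, every distinct mutation `i` of a gene (keyed by
gene, chromosome, position, ref, alt) gets an AF vector of length `n`:
entry `j` is sample `j`'s tumor VAF, or 0 when the sample lacks the call
(a sample called twice for one mutation keeps the maximum VAF). The score is

    Acc(i) = mean(AF vector) + 1 / (log(d_min(i) + 1) + 1)

with `d_min(i)` the minimum base-pair distance from `i` to the previous/next
distinct mutation of the same gene in position order. The gene score is the
maximum over its mutations.

Assumptions and conventions:

* **Pooled distances.** `d_min` is computed over all of the cohort's
  distinct mutations of a gene, not per sample: closely spaced mutations in
  *different* samples are treated as evidence of a shared functional
  hotspot (the regional-mutation-density / kataegis rationale). Because
  positions are sorted, the nearest neighbor is always adjacent, so the
  two-neighbor minimum equals the global nearest-neighbor distance (the
  test oracle recomputes it over all pairs).
* **Isolated mutations.** A gene's only mutation has no neighbor; its
  distance term is defined as the `d_min → ∞` limit, i.e. 0, so it is
  scored by allele frequency alone. The term rewards clustering, and an
  isolated mutation has none.
* **Co-located distinct alleles** (same position, different alt) are
  distance 0 apart and receive the maximal distance term 1 — hotspot logic.
* **Log base.** Natural log by default; base 10 and 2 are selectable and the
  choice is recorded in every output table, because score *values* (and in
  edge cases rankings) depend on it. With VAF ∈ [0,1] the score lies in
  (0, 2] for any base: each term is bounded by 1.
* **Cohort-size normalization** is by each cohort's own `n`, so cohorts of
  different sizes (9 vs 22) are compared on per-sample-mean VAF terms.
  Duplicating every sample leaves scores unchanged; relabeling samples is a
  no-op (both are tested invariants).
* **Tie-break** for a gene's arg-max mutation: smallest position, then
  lexicographically smallest alt — deterministic outputs.

Gene-set aggregation emits each member gene's score per cohort (0 for genes
unmutated in that cohort) plus mean/median/quartiles per set and cohort —
the numbers behind one boxplot pair. Per-gene scores grouped by set are
emitted rather than per-set means, the most literal reading of a
gene-in-pathway boxplot; genes scoring 0 in both cohorts can optionally be
dropped (useful when scoring an arbitrary supplied gene list). No
between-cohort significance test is claimed for these distributions; a
Mann–Whitney U can be run by the user on the emitted long-format table but
is deliberately not part of the report.

## Consensus pathogenicity score

Each mutation carries up to four interpreter verdicts (InterVar, ClinVar,
SIFT, CADD). Verdicts are normalized to a signed scale — positive
pathogenic, negative benign, 0 VUS/unknown — and the per-mutation consensus
is the **maximum** (most pathogenic wins). Per gene and sample:

* if any mutation consensus is > 0: `s` = sum of the positive scores;
* else if any is exactly 0: `s` = 0 (VUS);
* else: `s` = maximum (least benign) of the all-negative scores, mirroring
  the per-mutation most-pathogenic-wins logic so `s` stays < 0.

Classes: benign `s < 0`, VUS `s = 0`, pathogenic low `0 < s < 10`, mid
`10 ≤ s ≤ 20`, high `s > 20`. "Pathogenic in a sample" means `s > 0`
(strict). Scoring is per sample (matching the per-sample structure of a
gene × sample matrix), not pooled across samples.

The raw→signed mapping is not canonical — interpreters emit categorical
tiers (InterVar, ClinVar) or numbers on unrelated scales (SIFT tolerance
probability, CADD phred). The shipped default is an explicit, overridable
config whose SHA-256 is recorded in the run manifest:

| channel | mapping | default |
|---|---|---|
| InterVar | 5-tier categorical | ±7.8, ±3.9, 0 |
| ClinVar | 5-tier categorical | ±6.2, ±3.1, 0 |
| SIFT | signed linear around damaging threshold 0.05 | `6.1·(0.05−v)/0.05` if v < 0.05, else `−6.1·(v−0.05)/0.95` |
| CADD | `(phred − 15)/3.5`, capped at ±10 | phred 32.5 ↦ 5 |

Magnitudes are chosen so each channel's pathogenic range is roughly (0, 10]
and the documented worked example's values (−7.8, −6.2, 6.1, 5) are
reachable: the categorical extremes and the SIFT scale reuse those printed
magnitudes, and CADD's slope makes a phred of 32.5 map to 5. Unknown
categories and missing values normalize to 0 (VUS convention). A channel
entirely absent for a mutation is simply not consulted; a mutation with *no*
calls at all is excluded from pathogenicity scoring and reported as
unannotated rather than silently scored 0.

## Pre-filters

Applied to each cohort before any scoring:

* **Population MAF:** records with MAF **strictly greater than** 1% are
  removed (likely germline polymorphisms); a record at exactly 0.01 is
  retained, and records with no MAF annotation are retained — a novel
  variant cannot fail a frequency filter it has no data for.
* **Consequence:** only exonic protein-changing and splice consequences are
  kept (missense, stop gain/loss, splice, frameshift, in-frame indel);
  synonymous and non-exonic ("other") calls are removed.

The filter is idempotent and order-preserving. Coordinates are 1-based (VCF
convention) throughout, including distances. Multi-allelic VCF sites are
split into one record per alt allele before scoring; a variant annotated to
several overlapping genes is assigned to each listed gene.

## Synthetic cohorts

The generator emulates the target study design: cohort A of 9 samples,
cohort B of 22, a 30-gene universe with 4 planted hot genes. Per hot gene,
cohort A receives 2–4 distinct mutations confined to a 10 bp cluster,
carried by round(7/9 · 9) = 7 samples (recurrence 7/9, comfortably above
the 5-sample reporting threshold while leaving non-carriers), with VAFs
from Beta(9, 11) (mean 0.45, clonal-ish); roughly 60% of carriers share one
anchor mutation so recurrence concentrates. In cohort B the same genes are
sparse (0–2 isolated low-VAF carriers). Background genes are generated by
one symmetric process per cohort: 0–4 carriers with distinct positions at
least 10 kb apart and VAFs from Beta(3, 17) (mean 0.15, subclonal). Planted
hot calls get pathogenic interpreter verdicts on all four channels with
probability 0.8 (`interpreter_concordance`), otherwise 1–3 channels are
flipped to benign while at least one stays pathogenic; background calls are
benign (70%), VUS (20%) or carry a lone pathogenic channel (5%, off-target
noise).

Two removable contaminations exercise the pre-filter, with exact
bookkeeping of the affected rows: 10% of background SNVs are made
synonymous, and 10% of the remaining background records get a population
MAF drawn from (0.011, 0.2). Both are confined to background genes so
filtering never erodes the planted signal — the filter's correctness is
audited record-for-record against the truth labels, not against the hot
genes. A further 20% of background records get a sub-threshold MAF in
[0, 0.01] to exercise the retention boundary.

Two constructions make the recovery checks structural rather than
statistical: background genes are capped at 4 carriers per cohort, so no
background gene can reach the 5-sample recurrence threshold; and every
planted hot record keeps at least one pathogenic channel, so its consensus
is always positive. The accumulation-score separation (hot-gene
cohort-difference above every background gene's) is statistical but has a
wide designed margin: a hot gene scores ≈ 0.5–0.8 in cohort A
(anchor-mutation mean VAF ≈ 0.2–0.3 plus a distance term ≥ 0.29 for a
≤ 10 bp cluster under natural log) versus ≤ ≈ 0.11 in cohort B, while a
background gene's score stays ≈ ≤ 0.25 (distance term ≈ 0.098 at 10 kb
spacing plus a small mean-VAF term).

What the generator does *not* emulate: realistic per-sample mutation counts
(hundreds of SNVs per exome), trinucleotide signature structure, gene
length/replication-timing covariates of background mutation rate, purity or
depth-driven VAF noise, and interpreter errors correlated across channels.
Passing recovery tests therefore demonstrates that the pipeline's
machinery is correct and well-separated under its own model, not that the
scores are powerful on real tumor cohorts.

Determinism: all draws flow from `numpy.random.default_rng` seeded with
(seed, gene index[, cohort]), so outputs are byte-identical across runs and
stable per gene under unrelated spec edits.

## Pipeline and numerical choices

`run_pipeline` executes filter → accumulation scoring per cohort → gene-set
aggregation → pathogenicity matrix and recurrence lists → count summaries,
writing every table as TSV plus a JSON manifest (config hash, mapping hash,
seed, package version, output inventory, partial-failure flag). Reruns with
the same config and inputs are byte-identical. Stage failures carry the
stage name and input path.

Default problem sizes used by the test and acceptance suites — micro-cohorts
of ≤ 6 samples, ≤ 5 genes and ≤ 12 mutations for oracle equivalence (200
replicates, tolerance 1e−12), the default 9 vs 22 synthetic design across
seeds 1–5 for recovery — keep every check well inside a minute on one CPU
while covering each code path; scores are exact arithmetic, so larger
simulations would add running time, not resolution.

## Known limitations

* The accumulation score has no null model: it is a descriptive statistic,
  not a calibrated test, and its mixing of a [0,1] VAF term with a (0,1]
  distance term weights clustering against frequency by fiat.
* The distance term uses only the nearest neighbor; a dense cluster of ten
  mutations scores the same distance term as a single close pair.
* Signed interpreter magnitudes are conventions, not probabilities; the
  gene-sample sum depends on them, so the mapping hash should accompany any
  reported score.
* Comparing cohorts of very different sizes leaves the max-over-mutations
  statistic more variable in the smaller cohort; no correction is applied
  beyond the per-cohort mean normalization.
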