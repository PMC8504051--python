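import pytest

from mutacc.pathogenicity import (
    DEFAULT_MAPPING,
    InterpreterCall,
    classify_score,
    consensus_mutation_score,
    gene_sample_score,
    mapping_hash,
    normalize_call,
    read_interpreter_calls,
    recurrent_mutated_genes,
    recurrent_pathogenic_genes,
    score_pathogenicity,
    write_interpreter_calls,
)

from conftest import make_record
from oracles import brute_consensus, brute_gene_sample_scores


def call(channel="InterVar", norm=0.0, gene="G1", sample="S1", pos=100, alt="T"):
    return InterpreterCall(gene, "chr1", pos, "A", alt, sample, channel,
                           raw_value=None, norm_score=norm)


WORKED_EXAMPLE = [-7.8, -6.2, 6.1, 5.0]  # InterVar, ClinVar, SIFT, CADD


class TestNormalize:
    def test_clinvar_benign_maps_to_shipped_default(self):
        assert normalize_call("ClinVar", "benign") == -6.2
        assert normalize_call("ClinVar", "Likely_pathogenic") == 3.1

    def test_unknown_or_missing_is_vus(self):
        assert normalize_call("InterVar", "weird category") == 0.0
        assert normalize_call("SIFT", None) == 0.0
        assert normalize_call("CADD", ".") == 0.0

    def test_sift_sign_flips_at_damaging_threshold(self):
        thr = DEFAULT_MAPPING["SIFT"]["damaging_threshold"]
        assert normalize_call("SIFT", thr - 0.01) > 0
        assert normalize_call("SIFT", thr) == 0.0
        assert normalize_call("SIFT", thr + 0.1) < 0
        assert normalize_call("SIFT", 0.0) == DEFAULT_MAPPING["SIFT"]["scale"]

    def test_cadd_linear_through_threshold_and_capped(self):
        assert normalize_call("CADD", 32.5) == pytest.approx(5.0)
        assert normalize_call("CADD", 15.0) == 0.0
        assert normalize_call("CADD", 10.0) < 0
        assert normalize_call("CADD", 1000.0) == DEFAULT_MAPPING["CADD"]["cap"]

    def test_channel_missing_from_config_is_error(self):
        with pytest.raises(KeyError, match="PolyPhen"):
            normalize_call("PolyPhen", 0.5, {"SIFT": DEFAULT_MAPPING["SIFT"]})

    def test_mapping_hash_is_stable_and_sensitive(self):
        h = mapping_hash(DEFAULT_MAPPING)
        assert h == mapping_hash(DEFAULT_MAPPING)
        tweaked = {**DEFAULT_MAPPING, "CADD": {**DEFAULT_MAPPING["CADD"], "cap": 9.0}}
        assert h != mapping_hash(tweaked)


class TestConsensus:
    def test_most_pathogenic_channel_wins(self):
        calls = [call(ch, v) for ch, v in
                 zip(("InterVar", "ClinVar", "SIFT", "CADD"), WORKED_EXAMPLE)]
        assert consensus_mutation_score(calls) == 6.1
        assert consensus_mutation_score(calls) == brute_consensus(WORKED_EXAMPLE)

    def test_all_benign_takes_least_benign(self):
        assert consensus_mutation_score(
            [call("InterVar", -3), call("ClinVar", -1)]) == -1

    def test_single_vus_call(self):
        assert consensus_mutation_score([call(norm=0.0)]) == 0.0

    def test_channel_order_irrelevant_and_duplicates_idempotent(self):
        calls = [call(ch, v) for ch, v in
                 zip(("InterVar", "ClinVar", "SIFT", "CADD"), WORKED_EXAMPLE)]
        assert consensus_mutation_score(calls[::-1]) == 6.1
        assert consensus_mutation_score(calls + calls) == 6.1

    def test_empty_or_mixed_mutations_rejected(self):
        with pytest.raises(ValueError):
            consensus_mutation_score([])
        with pytest.raises(ValueError, match="multiple mutations"):
            consensus_mutation_score([call(pos=100), call(pos=101)])


class TestGeneSampleScore:
    def test_positive_scores_summed(self):
        gss = gene_sample_score([6.1, 5.0, -2.0])
        assert gss.s == pytest.approx(11.1)
        assert gss.klass == "pathogenic_mid"

    def test_all_benign_takes_maximum(self):
        gss = gene_sample_score([-7.8, -6.2])
        assert gss.s == -6.2
        assert gss.klass == "benign"

    def test_vus_outranks_benign_when_nothing_pathogenic(self):
        gss = gene_sample_score([-1.0, 0.0])
        assert gss.s == 0.0
        assert gss.klass == "VUS"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_sample_score([])

    def test_matches_brute_force_on_small_grid(self):
        cases = {
            ("G", "S1"): [6.1, 5.0, -2.0],
            ("G", "S2"): [-7.8, -6.2],
            ("G", "S3"): [-1.0, 0.0],
            ("H", "S1"): [0.5],
            ("H", "S2"): [-0.5, 12.0, 11.0],
        }
        expected = brute_gene_sample_scores(cases)
        for (gene, sample), scores in cases.items():
            assert gene_sample_score(scores).s == pytest.approx(
                expected[(gene, sample)], abs=1e-12)


class TestClassBins:
    @pytest.mark.parametrize(
        "s,klass",
        [
            (-0.001, "benign"),
            (0.0, "VUS"),
            (0.001, "pathogenic_low"),
            (9.999, "pathogenic_low"),
            (10.0, "pathogenic_mid"),
            (20.0, "pathogenic_mid"),
            (20.001, "pathogenic_high"),
        ],
    )
    def test_bin_boundaries(self, s, klass):
        assert classify_score(s) == klass


class TestRecurrence:
    def _scores(self, gene_counts, n_samples=9):
        calls = []
        for gene, k in gene_counts.items():
            for j in range(k):
                calls.append(call("InterVar", 5.0, gene=gene, sample=f"S{j}"))
            for j in range(k, n_samples):
                calls.append(call("InterVar", -5.0, gene=gene, sample=f"S{j}"))
        return score_pathogenicity(calls)

    def test_threshold_is_inclusive(self):
        scores = self._scores({"IN5": 5, "OUT4": 4, "IN9": 9})
        genes, matrix, counts = recurrent_pathogenic_genes(scores, min_samples=5)
        assert genes == ["IN5", "IN9"]
        lookup = dict(zip(counts["gene_symbol"], counts["n_pathogenic_samples"]))
        assert lookup == {"IN5": 5, "OUT4": 4, "IN9": 9}
        assert matrix.shape == (3, 9)

    def test_min_samples_one_includes_any_pathogenic(self):
        scores = self._scores({"A": 1, "B": 0})
        genes, _, _ = recurrent_pathogenic_genes(scores, min_samples=1)
        assert genes == ["A"]

    def test_other_cohort_counts_reported(self):
        scores = self._scores({"A": 6})
        other = self._scores({"A": 2}, n_samples=22)
        _, _, counts = recurrent_pathogenic_genes(scores, 5, other)
        assert counts.loc[0, "n_pathogenic_samples_other"] == 2

    def test_empty_cohort(self):
        import pandas as pd
        genes, matrix, _ = recurrent_pathogenic_genes(
            pd.DataFrame(columns=["gene_symbol", "sample_id", "s", "klass"]))
        assert genes == [] and matrix.empty


class TestRecurrentMutated:
    def test_snv_and_indel_samples_pool(self, rec):
        records = [rec(sample_id=f"S{j}", pos=100 + j) for j in range(3)]
        records += [
            rec(sample_id=f"S{j}", pos=200 + j, ref="A", alt="AT",
                consequence="frameshift")
            for j in range(3, 5)
        ]
        genes, flags = recurrent_mutated_genes(records, min_samples=5)
        assert genes == ["GENE1"]
        assert (flags.loc["GENE1"] != "none").sum() == 5

    def test_both_flag_when_sample_has_snv_and_indel(self, rec):
        records = [
            rec(pos=100),
            rec(pos=200, ref="AT", alt="A", consequence="frameshift"),
        ]
        _, flags = recurrent_mutated_genes(records, min_samples=1)
        assert flags.loc["GENE1", "S1"] == "both"

    def test_empty_cohort_gives_empty_list(self):
        genes, flags = recurrent_mutated_genes([], min_samples=5)
        assert genes == [] and flags.empty


class TestScorePathogenicity:
    def test_restriction_and_unannotated_reporting(self, rec):
        records = [rec(sample_id="S1", pos=100), rec(sample_id="S1", pos=200)]
        calls = [call("SIFT", 3.0, gene="GENE1", sample="S1", pos=100)]
        frame = score_pathogenicity(calls, restrict_to=records)
        assert frame.loc[0, "s"] == 3.0
        # the pos-200 variant has no interpreter call: reported, not scored 0
        assert len(frame.attrs["unannotated"]) == 1

    def test_calls_outside_filtered_set_ignored(self, rec):
        records = [rec(sample_id="S1", pos=100)]
        calls = [
            call("SIFT", 3.0, sample="S1", gene="GENE1", pos=100),
            call("CADD", 9.0, sample="S1", gene="GENE1", pos=999),
        ]
        frame = score_pathogenicity(calls, restrict_to=records)
        assert frame["s"].tolist() == [3.0]


class TestCallTableIO:
    def test_roundtrip_preserves_verdicts(self, tmp_path):
        calls = [
            InterpreterCall.from_raw("G1", "chr1", 100, "A", "T", "S1",
                                     "ClinVar", "Benign"),
            InterpreterCall.from_raw("G1", "chr1", 100, "A", "T", "S1",
                                     "SIFT", 0.01),
        ]
        path = tmp_path / "calls.tsv"
        write_interpreter_calls(calls, path)
        loaded = read_interpreter_calls(path)
        assert [c.norm_score for c in loaded] == pytest.approx(
            [c.norm_score for c in calls])

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            call(channel="PolyPhen")
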