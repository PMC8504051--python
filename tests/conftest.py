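import pytest
from hypothesis import settings

from mutacc.variant_io import VariantRecord, infer_variant_class

settings.register_profile("default", derandomize=True, max_examples=60)
settings.load_profile("default")


def make_record(
    sample_id="S1",
    gene_symbol="GENE1",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    consequence="missense",
    tumor_af=0.5,
    population_maf=None,
    variant_class=None,
):
    """VariantRecord factory with sensible defaults; class inferred if omitted."""
    return VariantRecord(
        sample_id=sample_id,
        gene_symbol=gene_symbol,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        variant_class=variant_class or infer_variant_class(ref, alt),
        consequence=consequence,
        tumor_af=tumor_af,
        population_maf=population_maf,
    )


@pytest.fixture
def rec():
    return make_record
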