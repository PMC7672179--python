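import pytest

from truneo.config import RunConfig
from truneo.models import Genotype, HlaCallSet, VariantRecord
from truneo.synthetic import generate_synthetic_bundle


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def small_bundle():
    bundle, truth = generate_synthetic_bundle(30, 5, seed=7)
    return bundle, truth


def make_snv(
    variant_id="V1",
    pos=100,
    depth_tumor=50,
    vaf_tumor=0.2,
    vaf_normal=0.0,
    mq_mut=None,
    mq_ref=None,
    bq_mut=None,
    bq_ref=None,
    dend_mut=None,
    dend_ref=None,
    **kw,
):
    base = [60.0] * 10
    return VariantRecord(
        variant_id=variant_id,
        chrom=kw.pop("chrom", "chr1"),
        pos=pos,
        ref="A",
        alt="T",
        vtype="SNV",
        depth_tumor=depth_tumor,
        depth_normal=60,
        vaf_tumor=vaf_tumor,
        vaf_normal=vaf_normal,
        mq_mut=mq_mut if mq_mut is not None else list(base),
        mq_ref=mq_ref if mq_ref is not None else list(base),
        bq_mut=bq_mut if bq_mut is not None else [35.0] * 10,
        bq_ref=bq_ref if bq_ref is not None else [35.0] * 10,
        dend_mut=dend_mut if dend_mut is not None else [25.0, 30.0, 20.0, 15.0, 35.0],
        dend_ref=dend_ref if dend_ref is not None else [25.0, 30.0, 20.0, 15.0, 35.0],
        gene=kw.pop("gene", "G1"),
        protein_change=kw.pop("protein_change", "p.A21T"),
        consequence=kw.pop("consequence", "missense"),
        **kw,
    ).validate()


@pytest.fixture
def genotype():
    return Genotype(
        (
            "HLA-A*02:01",
            "HLA-A*11:01",
            "HLA-B*07:02",
            "HLA-B*40:01",
            "HLA-C*07:02",
            "HLA-C*08:01",
        )
    )


@pytest.fixture
def identical_callset(genotype):
    return HlaCallSet(genotype, genotype, genotype, genotype)
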