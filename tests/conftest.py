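import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from poleclass.datasets import synthetic_signature_bank
from poleclass.io_formats import VariantCall

settings.register_profile(
    "repro", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def sig_bank():
    """Synthetic 96 x 6 signature bank with sparse, distinct columns."""
    return synthetic_signature_bank(k=6, seed=12345)


@pytest.fixture(scope="session")
def sig_bank4():
    return synthetic_signature_bank(k=4, seed=12345)


@pytest.fixture
def make_variant():
    """Factory for a variant with QC metrics that pass every criterion."""

    def factory(**overrides):
        kwargs = dict(
            tumor_id="T0001", chrom="chr1", pos=100, ref="C", alt="A",
            quality=120.0, depth=80, var_reads_fwd=10, var_reads_rev=12,
            avg_clipped_length=150.0, avg_pos_as_fraction=0.5,
            consequence="nonsynonymous_SNV",
        )
        kwargs.update(overrides)
        return VariantCall(**kwargs)

    return factory


@pytest.fixture
def tiny_genome():
    # chr1: positions 1..12 = A C G T A C G T G G T G
    return {"chr1": "ACGTACGTGGTG", "chr2": "TTTTCCCCAAAA"}
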