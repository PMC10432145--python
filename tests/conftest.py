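import numpy as np
import pytest

from comogen.simulate import make_ld, make_variants
from comogen.sumstats import RegionStats, TraitType, Variant


def make_region_stats(
    beta,
    se,
    trait_name="trait",
    trait_type=TraitType.case_control,
    n=100_000,
    chrom="1",
    case_fraction=0.2,
    variants=None,
):
    """Small RegionStats factory for unit tests."""
    beta = np.asarray(beta, dtype=float)
    se = np.broadcast_to(np.asarray(se, dtype=float), beta.shape)
    if variants is None:
        variants = make_variants(len(beta), chrom=chrom)
    tt = TraitType(trait_type)
    return RegionStats(
        trait_name=trait_name,
        trait_type=tt,
        variants=list(variants),
        beta=beta,
        se=np.array(se),
        n=np.full(len(beta), n),
        case_fraction=case_fraction if tt is TraitType.case_control else None,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230710)


@pytest.fixture
def small_ld():
    return make_ld(10, 0.6)
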