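import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitovar as mv

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def mt_ref():
    """Seeded random 16,569-bp circular genome with the placeholder 'N'."""
    return mv.CircularReference.random_mt(seed=4242)


@pytest.fixture(scope="session")
def shallow_dataset(mt_ref):
    """One simulated dataset at modest depth for fast end-to-end tests."""
    cfg = mv.VariantSimConfig(vaf=0.1, depth=200)
    block, ledger = mv.simulate_dataset(mt_ref, cfg, seed=11)
    return cfg, block, ledger


def make_read(pos, seq, qual=35, qname="r", contig="chrM", cigar=None,
              is_reverse=False, mapq=60, **kw):
    """Small helper for hand-built alignment records (1-based pos)."""
    qual_arr = np.full(len(seq), qual, dtype=np.uint8) \
        if np.isscalar(qual) else np.asarray(qual, dtype=np.uint8)
    return mv.AlignedRead(
        qname=qname, contig=contig, pos=pos, mapq=mapq,
        cigar=cigar or f"{len(seq)}M", seq=seq, qual=qual_arr,
        is_reverse=is_reverse, **kw)


@pytest.fixture
def read_factory():
    return make_read
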