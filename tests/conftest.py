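import warnings

import numpy as np
import pytest

import kinsketch as ks
from kinsketch.params import Params


@pytest.fixture(scope="session")
def p5() -> Params:
    """Small-k parameter set for hand-checkable examples."""
    return Params(k=5, min_sketch_sites=0)


@pytest.fixture(scope="session")
def small_world():
    """A 200 kb diploid individual with 1% isolated heterozygosity."""
    return ks.simulate_diploid(200_000, 0.01, seed=3)


@pytest.fixture(scope="session")
def small_reads(small_world):
    """Clean 10x 150 bp reads from the small individual."""
    return ks.simulate_reads(small_world, 10, 150, 0.0, seed=5)


@pytest.fixture(scope="session")
def small_stage1(small_reads):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ks.run_stage1(small_reads, ks.DEFAULT_PARAMS, high_het=False)


_RC = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def context_pair_key(a: str, b: str):
    """Orientation-independent identity of a ref/alt context pair."""
    fwd = tuple(sorted((a, b)))
    rev = tuple(sorted((revcomp(a), revcomp(b))))
    return min(fwd, rev)


@pytest.fixture(scope="session")
def pair_key():
    return context_pair_key
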