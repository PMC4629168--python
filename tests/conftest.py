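import numpy as np
import pytest
from hypothesis import settings

from adnauth import simulate
from adnauth.sam_io import FORWARD, AlignedRead, AlignmentSet

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def make_read(query: str, ref: str, strand: str = FORWARD, read_id: str = "r",
              start: int = 0, mapq: int = 60,
              rname: str = "chr") -> AlignedRead:
    """Handcrafted ungapped aligned read."""
    return AlignedRead(read_id=read_id, query_sequence=query, strand=strand,
                       reference_name=rname, reference_start=start,
                       reference_end=start + len(query), mapq=mapq,
                       query_aligned=query, ref_aligned=ref)


def make_set(reads, label="toy") -> AlignmentSet:
    return AlignmentSet(reads=list(reads), source_label=label)


@pytest.fixture(scope="session")
def library_pair():
    """Mid-sized ancient-like / modern-like pair for behavioural tests."""
    anc = simulate.simulate_library(
        simulate.ancient_config(seed=11, n_reads=8000),
        source_label="ancient-like")
    mod = simulate.simulate_library(
        simulate.modern_config(seed=12, n_reads=8000),
        source_label="modern-like")
    return anc, mod


@pytest.fixture(scope="session")
def library_pair_large():
    """Full-scale pair (50,000 reads each) shared by the heavier checks."""
    return simulate.simulate_library_pair(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
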