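import numpy as np
import pytest

from strdenovo.config import SimulationConfig
from strdenovo.panel import STRLocus
from strdenovo.reads import ReadRecord


@pytest.fixture
def locus_at():
    """A clean AT dinucleotide locus with motif-free flanks."""
    return STRLocus(
        locus_id="L0", chrom="chr1", start=1000, period=2, motif="AT",
        ref_repeat_count=10, flank_left="GGCCGGCCGG", flank_right="CCGGCCGGCC",
    )


@pytest.fixture
def small_config():
    return SimulationConfig(seed=7, n_families=20, n_loci=100)


def make_read(locus, allele_ru, sample="S", mapq=60, primary=True,
              softclip_left=0, softclip_right=0, pad=0, seq=None, read_id="r"):
    """Construct a spanning read for a locus supporting a given allele."""
    if seq is None:
        seq = locus.flank_left + locus.motif * allele_ru + locus.flank_right \
            + "G" * pad
    return ReadRecord(
        read_id=read_id, sample=sample, locus_id=locus.locus_id,
        pos=locus.start - 10, seq=seq, mapq=mapq, is_primary=primary,
        softclip_left=softclip_left, softclip_right=softclip_right,
    )


@pytest.fixture
def read_factory():
    return make_read


def support_of(counts: dict, sample="S", locus_id="L0"):
    from strdenovo.validation import SampleAlleleSupport
    return SampleAlleleSupport(sample_id=sample, locus_id=locus_id,
                               support=dict(counts))


@pytest.fixture
def support_factory():
    return support_of


@pytest.fixture
def rng(request):
    # per-test deterministic stream, independent of execution order
    import zlib
    return np.random.default_rng(zlib.adler32(request.node.nodeid.encode()))
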