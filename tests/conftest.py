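import numpy as np
import pytest

from strmosaic.simulate import SimConfig


@pytest.fixture
def clean_config():
    """Locus config with sequencing error, stutter and mosaicism switched off."""
    return SimConfig(error_rate=0.0, stutter_prob=0.0, somatic_rate_per_year=0.0)


@pytest.fixture
def entry(clean_config):
    return clean_config.catalog_entry()


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_917)


def make_read(seq, sample="S1", read_id="r1/1", fragment="r1", mate=1,
              chrom="chrSYN", pos=0, quals=None, **kw):
    from strmosaic.reads import ReadRecord

    return ReadRecord(
        read_id=read_id,
        fragment_id=fragment,
        mate_index=mate,
        seq=seq,
        quals=quals if quals is not None else [37] * len(seq),
        chrom=chrom,
        pos=pos,
        mapped=True,
        mate_chrom=kw.get("mate_chrom", chrom),
        mate_pos=kw.get("mate_pos", 0),
        mate_mapped=kw.get("mate_mapped", True),
        sample_id=sample,
    )
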