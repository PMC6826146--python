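import numpy as np
import pytest

from mitopid.align import ProjectedRead, ReferenceAligner
from mitopid.consensus import PidGroup
from mitopid.io_demux import MidTable, TaggedRead
from mitopid.reference import RegionSpec, encode_bases
from mitopid.simulate import DEFAULT_MIDS, synthetic_reference


@pytest.fixture(scope="session")
def genome():
    return synthetic_reference()


@pytest.fixture(scope="session")
def region():
    return RegionSpec()


@pytest.fixture(scope="session")
def aligner(genome, region):
    return ReferenceAligner(genome, region)


@pytest.fixture(scope="session")
def mid_table():
    return MidTable(DEFAULT_MIDS)


def make_projected(calls, pid="ACGTACGTACGTACGTACG", read_id="r0"):
    """Wrap a raw calls vector in a ProjectedRead for consensus tests."""
    calls = np.asarray(calls, dtype=np.uint8)
    return ProjectedRead(
        read=TaggedRead(read_id=read_id, mid_id="MID01", pid=pid, payload=""),
        calls=calls,
        covered_start=0,
        covered_end=len(calls) - 1,
        identity=1.0,
    )


def column_group(aligner, column_bases, col_idx=0, pid="P" * 19):
    """A PID group whose reads match the reference except at one column."""
    ref = aligner.region_codes
    reads = []
    for i, base in enumerate(column_bases):
        calls = ref.copy()
        calls[col_idx] = encode_bases(base)[0]
        reads.append(make_projected(calls, pid=pid, read_id=f"r{i}"))
    return PidGroup(pid=pid, reads=reads)
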