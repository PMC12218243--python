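import pytest

import ssumix
from ssumix.domain_splitter import Pool, build_split_index
from ssumix.mockgen import load_mock_references, mock_reference_pools


@pytest.fixture(scope="session")
def primers():
    return ssumix.DEFAULT_PRIMERS


@pytest.fixture(scope="session")
def mock_refs():
    return load_mock_references()


@pytest.fixture(scope="session")
def ref_fastas(tmp_path_factory, mock_refs):
    """Mock references written out as two pool FASTA files."""
    d = tmp_path_factory.mktemp("refs")
    pools = mock_reference_pools()
    p16 = d / "ref16.fasta"
    p18 = d / "ref18.fasta"
    with open(p16, "w") as f16, open(p18, "w") as f18:
        for rid, seq in mock_refs.items():
            fh = f16 if pools[rid] is Pool.SSU16S else f18
            fh.write(f">{rid}\n{seq}\n")
    return p16, p18


@pytest.fixture(scope="session")
def split_index(ref_fastas):
    return build_split_index(*ref_fastas, k=31)


def make_pair(fwd, rev, fq=None, rq=None, read_id="r1", sample_id="s1"):
    from ssumix.amplicon_io import ReadPair

    if fq is None:
        fq = (30,) * len(fwd)
    if rq is None:
        rq = (30,) * len(rev)
    return ReadPair(read_id, fwd, rev, tuple(fq), tuple(rq), sample_id)
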