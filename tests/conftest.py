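import numpy as np
import pytest

from ctuscope.model import Alignment, SequenceRecord


def make_record(rid, seq, **kw):
    defaults = dict(
        organism_name=f"uncultured organism clone {rid}",
        strain="",
        isolation_source="surface seawater",
        pintail=95.0,
        seq_quality=95.0,
        align_quality=95.0,
        domain="Archaea",
    )
    defaults.update(kw)
    return SequenceRecord(id=rid, aligned_seq=seq, **defaults)


def make_alignment(seqs: dict[str, str], **kw) -> Alignment:
    return Alignment([make_record(rid, seq, **kw) for rid, seq in seqs.items()])


@pytest.fixture
def toy_alignment():
    return make_alignment(
        {
            "A": "ACGTACGTAC",
            "B": "ACGTACGTAC",
            "C": "ACGTACGTTT",
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_distance_matrix(rng, n, discrete=True):
    """Random symmetric percent-distance matrix; discrete values force ties."""
    if discrete:
        vals = rng.integers(1, 11, size=(n, n)).astype(float) * 5.0
    else:
        vals = rng.uniform(0.5, 60.0, size=(n, n))
    d = np.triu(vals, 1)
    d = d + d.T
    return d
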