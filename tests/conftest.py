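import numpy as np
import pytest

from splicedelta.genome import TranscriptModel, reverse_complement
from splicedelta.pwm import PWMatrix, default_library


def make_two_exon_gene(intron_core=("GT", "AG"), strand="+", exon_len=30, intron_len=40, flank=25):
    """A toy one-intron gene with deterministic filler and chosen intron cores.

    Returns (ref mapping, TranscriptModel) with the transcript on the
    requested strand; for '-', the chromosome stores the reverse complement.
    """
    rng = np.random.default_rng(7)
    bases = "ACGT"
    seq = [bases[i] for i in rng.integers(0, 4, flank * 2 + exon_len * 2 + intron_len)]
    e1 = (flank, flank + exon_len)
    intron = (e1[1], e1[1] + intron_len)
    e2 = (intron[1], intron[1] + exon_len)
    seq[intron[0]] = intron_core[0][0]
    seq[intron[0] + 1] = intron_core[0][1]
    seq[intron[1] - 2] = intron_core[1][0]
    seq[intron[1] - 1] = intron_core[1][1]
    tx_seq = "".join(seq)
    total = len(tx_seq)
    if strand == "+":
        ref = {"chrT": tx_seq}
        exons = (e1, e2)
    else:
        ref = {"chrT": reverse_complement(tx_seq)}
        exons = tuple((total - e, total - s) for s, e in (e1, e2))
    return ref, TranscriptModel(id="tx", chrom="chrT", strand=strand, exons=exons)


@pytest.fixture(scope="session")
def bundled_library():
    return default_library()


@pytest.fixture(scope="session")
def donor_matrix(bundled_library):
    return bundled_library["donor_GT"]


@pytest.fixture(scope="session")
def acceptor_matrix(bundled_library):
    return bundled_library["acceptor_AG"]


@pytest.fixture
def tiny_matrix():
    """A 4-position donor-side matrix small enough for exhaustive oracles."""
    freqs = np.array(
        [
            [0.70, 0.10, 0.15, 0.05],
            [0.25, 0.25, 0.25, 0.25],
            [0.05, 0.05, 0.85, 0.05],
            [0.10, 0.40, 0.20, 0.30],
        ]
    )
    return PWMatrix(name="tiny", site_kind="donor", window_spec=(-2, -1, 1, 2), freqs=freqs,
                    core_positions=(1,))
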