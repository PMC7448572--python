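import numpy as np
import pytest

from karyoscan.assembly_io import SequenceRecord
from karyoscan.simulate import SimConfig, simulate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def default_genome():
    """One default synthetic genome shared by read-only tests."""
    cfg = SimConfig(seed=11)
    records, layout, truth = simulate_genome(cfg)
    return cfg, records, layout, truth


def write_sam(path, references, reads):
    """Write a minimal coordinate-sorted SAM.

    ``references``: list of (name, length); ``reads``: list of
    (qname, flag, rname, pos0, cigar, tlen).
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in references:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for qname, flag, rname, pos0, cigar, tlen in reads:
            fh.write(
                f"{qname}\t{flag}\t{rname}\t{pos0 + 1}\t60\t{cigar}\t=\t"
                f"{pos0 + 1}\t{tlen}\t*\t*\n"
            )
    return path


def make_record(seq_id, sequence):
    return SequenceRecord(seq_id, sequence)
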