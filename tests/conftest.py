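import random

import pytest

from anchorpipe.io import LocusAlignment


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def small_alignment():
    """4 taxa x 30 columns, probe span [10, 20)."""
    rows = [
        "ACGTACGTAC" + "ATGAAATTTC" + "GGGGCCCCTT",
        "ACGTACGTAC" + "ATGAAATTTC" + "GGGGCCCCTT",
        "ACGTTCGTAC" + "ATGAAATTTC" + "GGGTCCCCTT",
        "ACGTTCGAAC" + "ATGAAATTTC" + "GGGTCCGCTT",
    ]
    return LocusAlignment("locA", ["t1", "t2", "t3", "t4"], rows, (10, 20), "dna")


def make_alignment(rows, span=(0, 0), locus="locX", alphabet="dna"):
    taxa = [f"t{i + 1}" for i in range(len(rows))]
    return LocusAlignment(locus, taxa, rows, span, alphabet)
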