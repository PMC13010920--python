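import numpy as np
import pandas as pd
import pytest

from perilesion.genome_io import GenomeSequence


@pytest.fixture
def toy_genome() -> GenomeSequence:
    # c1: ACGTA used by the trinucleotide examples; c2 is G-rich
    return GenomeSequence({"c1": "ACGTA", "c2": "GGGGGGGGGG"})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def events_frame(rows):
    """rows: (chrom, pos, strand) triples -> event table."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
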