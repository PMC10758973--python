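import random

import pytest

from offscan.core import GenomeWindow, GuideQuery

#: the 20-nt SpCas9 guide used throughout the examples
GUIDE = "ATTGAGATAGTGTGGGGAAG"


def bare_query(seq: str, strand: str = "+", name: str = "q") -> GuideQuery:
    """A PAM-less query: every position is a guide position."""
    return GuideQuery(
        guide=seq,
        pam_pattern="",
        strand=strand,
        search_seq=seq,
        pam_mask=(False,) * len(seq),
        name=name,
    )


def window(seq: str, chrom: str = "chr1", offset: int = 0) -> GenomeWindow:
    return GenomeWindow(chrom=chrom, offset=offset, seq=seq)


def random_dna(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
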