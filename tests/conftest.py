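import numpy as np
import pytest

from srnaseg.encode import EncodedAlignment
from srnaseg.simulate import Transcript, TranscriptomeSimSpec, simulate_reads


def make_encoded(text: str, ref_id: str = "toy") -> EncodedAlignment:
    """Build an EncodedAlignment from a literal symbol string ('#' allowed)."""
    blocks = []
    bi = 0
    for ch in text:
        if ch == "#":
            bi += 1
        else:
            blocks.append(bi)
    n = len(blocks)
    return EncodedAlignment(
        ref_id=ref_id,
        symbols=text,
        coords=np.arange(1, n + 1, dtype=np.int64),
        block_index=np.asarray(blocks, dtype=np.int64),
    )


@pytest.fixture
def encoded_factory():
    return make_encoded


def three_archetype_spec(seed: int = 0, n_pairs: int = 600) -> TranscriptomeSimSpec:
    """Toy genome with one intergenic-specific transcript, one polycistron
    spanning two genes across a gap, and one UTR read-through transcript."""
    return TranscriptomeSimSpec(
        genome_length=5000,
        genes=[(1, 1000), (1501, 2500), (2701, 3700), (4201, 5000)],
        transcripts=[
            Transcript(1050, 1450, "intergenic_specific"),
            Transcript(1501, 3700, "polycistronic"),
            Transcript(4000, 4600, "utr_readthrough"),
        ],
        n_pairs=n_pairs,
        seed=seed,
    )


@pytest.fixture
def simulated_reads():
    return simulate_reads(three_archetype_spec(seed=7))
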