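import numpy as np
import pytest

from lincpipe import simulate as sim
from lincpipe.models import GenomicInterval, TranscriptModel


@pytest.fixture(scope="session")
def bundle():
    """One shared synthetic fixture bundle (deterministic)."""
    return sim.build(sim.SimulationConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_transcripts(rng, n, chroms=("chr1", "chr2"), strands=("+", "-")):
    """Random valid transcripts for round-trip / locus tests."""
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        strand = strands[rng.integers(len(strands))]
        n_exons = int(rng.integers(1, 5))
        pos = int(rng.integers(0, 50_000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(50, 800))
            exons.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length + int(rng.integers(100, 2_000))
        out.append(
            TranscriptModel(
                f"T{i:04d}", f"G{i % max(n // 2, 1):04d}", exons,
                class_code=str(rng.choice(["u", "j", "=", "."])),
            )
        )
    return out
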