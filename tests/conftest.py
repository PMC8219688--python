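import numpy as np
import pytest

from peakcoloc import GenomeModel, Peak, PeakSet


@pytest.fixture
def toy_genome() -> GenomeModel:
    return GenomeModel([("chrA", 10_000), ("chrB", 20_000)])


@pytest.fixture
def sparse_genome() -> GenomeModel:
    """Single 50 Mb chromosome: random overlap between ~200 bp peaks is rare."""
    return GenomeModel([("chr1", 50_000_000)])


def random_peakset(
    genome: GenomeModel,
    n: int,
    rng: np.random.Generator,
    label: str = "rand",
    max_width: int = 500,
) -> PeakSet:
    """Uniform random peaks for brute-force comparisons."""
    peaks = []
    names = genome.names
    for _ in range(n):
        chrom = names[rng.integers(len(names))]
        L = genome.length_of(chrom)
        w = int(rng.integers(1, min(max_width, L) + 1))
        s = int(rng.integers(0, L - w + 1))
        peaks.append(Peak(chrom, s, s + w))
    return PeakSet(label, genome, peaks)
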