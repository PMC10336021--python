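import numpy as np
import pytest

from taumark.matrix import DistanceMatrix
from taumark.seqio import Alignment


@pytest.fixture
def toy_loci():
    """Three tiny loci over genomes G1..G4; locusC lacks G4."""
    return [
        Alignment("locusA", ["G1", "G2", "G3", "G4"],
                  ["ACGTACGT", "ACGTACGA", "ACGTACCA", "TCGTACCA"]),
        Alignment("locusB", ["G1", "G2", "G3", "G4"],
                  ["GGGGCCCC", "GGGGCCCT", "GGGACCCT", "GGTACCCT"]),
        Alignment("locusC", ["G1", "G2", "G3"],
                  ["AAAATTTT", "AAAATTTC", "AAAGTTTC"]),
    ]


@pytest.fixture
def random_matrix():
    """Factory for random symmetric distance matrices."""

    def make(n: int, seed: int = 0, masked: int = 0) -> DistanceMatrix:
        rng = np.random.default_rng(seed)
        vals = rng.random((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        mask = np.zeros((n, n), dtype=bool)
        while masked > 0:
            i, j = rng.integers(0, n, size=2)
            if i != j and not mask[i, j]:
                mask[i, j] = mask[j, i] = True
                masked -= 1
        labels = [f"G{i + 1}" for i in range(n)]
        return DistanceMatrix(labels=labels, values=vals, mask=mask)

    return make
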