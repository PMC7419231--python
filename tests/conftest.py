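import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dcjkit.genome_model import Chromosome, Genome, Marker


def make_genome(label: str, *chromosomes: list[int], circular: bool = False) -> Genome:
    """Compact genome builder: signed ints per chromosome."""
    g = Genome(label)
    topo = "circular" if circular else "linear"
    for i, ms in enumerate(chromosomes, 1):
        markers = tuple(Marker(abs(x), 1 if x > 0 else -1) for x in ms)
        g.chromosomes.append(Chromosome(f"c{i}", markers, topo))
    return g


def random_genome(n: int, rng: np.random.Generator, label: str = "g", max_chroms: int = 3) -> Genome:
    perm = list(rng.permutation(n) + 1)
    signs = rng.choice([1, -1], n)
    k = int(rng.integers(1, min(max_chroms, n) + 1))
    cuts = sorted(rng.choice(np.arange(1, n), size=k - 1, replace=False)) if k > 1 else []
    bounds = [0] + list(cuts) + [n]
    g = Genome(label)
    for i in range(k):
        ms = tuple(
            Marker(int(perm[j]), int(signs[j])) for j in range(bounds[i], bounds[i + 1])
        )
        g.chromosomes.append(Chromosome(f"c{i+1}", ms))
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
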