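import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from puffalign import ReferenceRecord, build_index, simulate_genome


@pytest.fixture(scope="session")
def toy_refs():
    """Two small references with a shared 40 bp block (unitig sharing)."""
    import numpy as np

    rng = np.random.default_rng(11)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def rand(n):
        return rng.choice(bases, size=n).tobytes().decode()

    shared = rand(40)
    return [
        ReferenceRecord("refA", rand(120) + shared + rand(120)),
        ReferenceRecord("refB", rand(80) + shared + rand(160)),
    ]


@pytest.fixture(scope="session")
def toy_index(toy_refs):
    return build_index(toy_refs, 15)


@pytest.fixture(scope="session")
def small_genome():
    return simulate_genome(5000, seed=42)


@pytest.fixture(scope="session")
def small_genome_index(small_genome):
    return build_index(small_genome, 31)
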