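import numpy as np
import pytest

from sagkit.synthdata import (
    GenomeAssembly,
    _codes_to_str,
    _gen_markov_sequence,
)


@pytest.fixture(scope="session")
def markov_assembly_factory():
    """Factory for assemblies of equal-length scaffolds from one Markov source."""

    def make(profile: str, seed: int, n_scaffolds: int = 50, length: int = 12000):
        rng = np.random.default_rng(seed)
        contigs = {
            f"s{k:03d}": _codes_to_str(_gen_markov_sequence(length, profile, rng))
            for k in range(n_scaffolds)
        }
        return GenomeAssembly(genome_id=f"{profile}_{seed}", contigs=contigs)

    return make


@pytest.fixture(scope="session")
def random_sequence_factory():
    """Factory for iid random ACGT strings."""

    def make(length: int, seed: int) -> str:
        rng = np.random.default_rng(seed)
        return _codes_to_str(rng.integers(0, 4, size=length).astype(np.uint8))

    return make
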