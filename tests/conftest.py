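import numpy as np
import pytest

from plastoflux._seq import random_dna
from plastoflux.genome import AnnotatedGenome
from plastoflux.simulate import FluxScenario, simulate_flux_scenario


SNP_FLIP = {"A": "G", "C": "T", "G": "A", "T": "C"}


def mutate(seq: str, positions, rng) -> str:
    """Substitute a random different base at each given position."""
    chars = list(seq)
    for p in positions:
        chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
    return "".join(chars)


@pytest.fixture(scope="session")
def small_pair():
    """A small simulated species pair shared by read-only tests."""
    scen = FluxScenario(plastid_length=24_000, n_genes=12, gene_codons=150,
                        mito_background_factor=1.5, seed=11)
    return simulate_flux_scenario(scen)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def random_genome_pair():
    """Unrelated mito/plastid random genomes plus a planting helper."""
    rng = np.random.default_rng(42)
    plastid = random_dna(rng, 10_000)
    background = random_dna(rng, 20_000)

    def plant(src_start, src_end, insert_at, identity=1.0, revcomp_block=False):
        from plastoflux._seq import revcomp

        block = plastid[src_start:src_end]
        n_mut = round(len(block) * (1 - identity))
        if n_mut:
            pos = rng.choice(len(block), size=n_mut, replace=False)
            block = mutate(block, pos, rng)
        if revcomp_block:
            block = revcomp(block)
        mito_seq = background[:insert_at] + block + background[insert_at:]
        return (AnnotatedGenome("mito", mito_seq),
                AnnotatedGenome("plastid", plastid),
                (insert_at, insert_at + len(block), src_start, src_end))

    return plant
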