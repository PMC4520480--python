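import pytest

from mitoprofile.model import AlignmentBlock
from mitoprofile.simulate import SimulationParams, simulate_genome
from mitoprofile.vocab import PCG_TOKENS, RRNA_TOKENS, TRNA_TOKENS


@pytest.fixture(scope="session")
def default_sim():
    """One default (complete, circular) simulated genome + manifest."""
    return simulate_genome(SimulationParams(seed=20150730))


@pytest.fixture(scope="session")
def sim_record(default_sim):
    return default_sim[0]


@pytest.fixture(scope="session")
def sim_manifest(default_sim):
    return default_sim[1]


def toy_blocks(pcg_len: int = 9, rna_len: int = 5, taxa=("tax_a", "tax_b")):
    """Deterministic per-gene alignment blocks for all 37 genes."""
    blocks = []
    bases = "ACGT"
    for gi, gene in enumerate(PCG_TOKENS):
        rows = ["".join(bases[(gi + ti + k) % 4] for k in range(pcg_len))
                for ti in range(len(taxa))]
        blocks.append(AlignmentBlock(gene, list(taxa), rows))
    for gi, gene in enumerate(TRNA_TOKENS + RRNA_TOKENS):
        rows = ["".join(bases[(gi + 2 * ti + k) % 4] for k in range(rna_len))
                for ti in range(len(taxa))]
        blocks.append(AlignmentBlock(gene, list(taxa), rows))
    return blocks


@pytest.fixture()
def alignment_blocks():
    return toy_blocks()
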