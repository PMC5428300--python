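import numpy as np
import pytest

from superbarcode import Msa, SimulationConfig, simulate_genomes


def random_msa(rng, n_taxa=5, length=200, p_sub=0.02, p_gap=0.01, p_n=0.005) -> Msa:
    """A random alignment: shared ancestor plus iid substitutions/gaps/Ns."""
    bases = np.array(list("ACGT"))
    root = rng.choice(bases, size=length)
    rows = []
    for _ in range(n_taxa):
        row = root.copy()
        sub = rng.random(length) < p_sub
        row[sub] = rng.choice(bases, size=int(sub.sum()))
        row[rng.random(length) < p_n] = "N"
        row[rng.random(length) < p_gap] = "-"
        rows.append("".join(row))
    return Msa([f"t{i}" for i in range(n_taxa)], rows)


@pytest.fixture(scope="session")
def small_sim():
    """One compact simulated study (9 taxa, 40 kb genome) reused across tests."""
    config = SimulationConfig(
        seed=11, genome_length=40_000, ir_length=8_000, ssc_length=4_000
    )
    return config, simulate_genomes(config)


@pytest.fixture(scope="session")
def full_sim():
    """A full-size simulated study (9 taxa, 152 kb) for end-to-end checks."""
    config = SimulationConfig(seed=1)
    return config, simulate_genomes(config)
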