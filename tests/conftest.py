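import numpy as np
import pytest

from germdiv import Accession, GenotypeMatrix, SimulationSpec, simulate_genotypes


@pytest.fixture
def tiny_gm():
    """Four accessions, two loci: genotypes {AA, AB, BB, AB} at L1 (A=155,
    B=161) and a monomorphic second locus with one missing call."""
    calls = np.array(
        [
            [[155, 155], [150, 150]],
            [[155, 161], [150, 150]],
            [[161, 161], [150, 150]],
            [[161, 155], [-9, -9]],
        ]
    )
    accs = [Accession(f"a{i}", population="P1") for i in range(1, 5)]
    return GenotypeMatrix(accs, ["L1", "L2"], calls)


@pytest.fixture
def two_pop_panel():
    """Strongly diverged two-population panel (the standard test conditions:
    F = 0.3, 2 x 50 individuals, 20 loci)."""
    spec = SimulationSpec(
        pops=("P1", "P2"), n_per_pop=(50, 50), n_loci=20, fst=0.3, seed=42
    )
    gm, source, q_true = simulate_genotypes(spec)
    return gm, source, q_true
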