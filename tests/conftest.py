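import numpy as np
import pytest

from hacsurf.synthetic import (
    make_beta_hairpin,
    make_ideal_helix,
    make_sphere_cluster,
)


@pytest.fixture(scope="session")
def helix15():
    """15-residue poly-Ala ideal alpha-helix."""
    return make_ideal_helix(15, structure_id="helix15")


@pytest.fixture(scope="session")
def helix_mixed():
    """30-residue helix with a charged/hydrophobic sequence mix and varied pLDDT."""
    rng = np.random.default_rng(7)
    seq = list(
        rng.choice(
            ["ALA", "LEU", "LYS", "GLU", "ASP", "ARG", "SER", "VAL", "GLY", "ILE"],
            size=30,
        )
    )
    plddt = list(rng.uniform(55.0, 98.0, 30))
    return make_ideal_helix(30, sequence=seq, plddt=plddt, structure_id="helix-mixed")


@pytest.fixture(scope="session")
def hairpin():
    return make_beta_hairpin(6)


@pytest.fixture(scope="session")
def single_sphere():
    return make_sphere_cluster([[0.0, 0.0, 0.0]], 1.7)


@pytest.fixture(scope="session")
def fused_pair():
    return make_sphere_cluster([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]], 1.7)
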