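import numpy as np
import pandas as pd
import pytest

from famrv.kinship import Pedigree, kinship_matrix


def make_pedigree(rows):
    """rows: (family, id, father, mother, sex) with None for missing parents."""
    t = pd.DataFrame(rows, columns=["family", "id", "father", "mother", "sex"])
    return Pedigree(t)


@pytest.fixture
def trio():
    return make_pedigree(
        [("1", "dad", None, None, 1),
         ("1", "mom", None, None, 2),
         ("1", "kid", "dad", "mom", 1)]
    )


@pytest.fixture
def sib_pedigree():
    """Two founder parents with two full-sib children."""
    return make_pedigree(
        [("1", "p1", None, None, 1),
         ("1", "p2", None, None, 2),
         ("1", "s1", "p1", "p2", 1),
         ("1", "s2", "p1", "p2", 2)]
    )


@pytest.fixture
def inbred_pedigree():
    """Full-sib mating: child of two sibs is inbred with F = 1/4."""
    return make_pedigree(
        [("1", "gp1", None, None, 1),
         ("1", "gp2", None, None, 2),
         ("1", "s1", "gp1", "gp2", 1),
         ("1", "s2", "gp1", "gp2", 2),
         ("1", "inb", "s1", "s2", 1)]
    )


def sib_pair_phi(n_pairs):
    """Block-diagonal Phi for independent full-sib pairs."""
    block = np.array([[1.0, 0.5], [0.5, 1.0]])
    phi = np.zeros((2 * n_pairs, 2 * n_pairs))
    for k in range(n_pairs):
        phi[2 * k: 2 * k + 2, 2 * k: 2 * k + 2] = block
    return phi


@pytest.fixture
def small_study():
    """A compact family sample with genotypes for end-to-end test use."""
    import famrv as f

    cfg = f.SimulationConfig(seed=123, n_families=40)
    rng = np.random.default_rng(9)
    ped = f.simulate_pedigree(cfg, rng)
    phi = kinship_matrix(ped).phi
    panel, genes = f.null_panel(n_genes=12, n_intergenic=12, seed=5)
    dm = f.gene_drop(ped, panel, rng)
    pheno = f.simulate_traits(ped, dm, panel, cfg, rng, phi=phi)
    return {"config": cfg, "ped": ped, "phi": phi, "panel": panel,
            "genes": genes, "dm": dm, "pheno": pheno}
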