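import numpy as np
import pytest

from glycobind.featurize import AtomNode, MolecularGraph, parse_molecule

BETA_D_GLUCOPYRANOSE = "OC[C@H]1O[C@@H](O)[C@H](O)[C@@H](O)[C@@H]1O"


@pytest.fixture(scope="session")
def glucose():
    return parse_molecule(BETA_D_GLUCOPYRANOSE)


@pytest.fixture(scope="session")
def ethanol():
    return parse_molecule("CCO")


def random_labeled_graph(rng: np.random.Generator, max_atoms: int = 8) -> MolecularGraph:
    """Random connected labeled graph used as an AQG enumeration fixture.

    Built directly (no RDKit molecule): a random spanning tree plus extra
    edges, with node labels drawn from small feature alphabets.
    """
    n = int(rng.integers(1, max_atoms + 1))
    atoms = [
        AtomNode(
            index=i,
            element=str(rng.choice(["C", "N", "O"])),
            hybridization=str(rng.choice(["sp2", "sp3"])),
            h_count=int(rng.integers(0, 3)),
            chirality=str(rng.choice(["R", "S", "none"])),
        )
        for i in range(n)
    ]
    edges = set()
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.add((j, i))
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            edges.add((min(i, j), max(i, j)))
    bonds = [(i, j, 1.0) for i, j in sorted(edges)]
    return MolecularGraph(atoms=atoms, bonds=bonds, source_text="<synthetic>")
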