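"""Stereoisomer generation: enantiomers and single-center epimers.

Glycan recognition by lectins is dominated by the configuration of ring
stereocenters, so the key extrapolation test for any atom-level binding
model is whether it distinguishes a molecule from its mirror image.  This
module generates those probes: the enantiomer (all tetrahedral parities
inverted) and the epimers (exactly one parity inverted), leaving the
constitution — elements, bonds, double-bond geometry — untouched.

Only tetrahedral stereocenters are handled; axial and planar chirality do
not occur in the glycoconjugate structures this package targets.  Atoms
with undefined configuration are left undefined in every variant.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from glycobind.featurize import MolecularGraph, parse_molecule


@dataclass
class StereoVariant:
    """A stereoisomer of a parent molecule.

    ``relation`` is "enantiomer" when every tetrahedral stereocenter was
    inverted, "epimer" when exactly one was.
    """

    parent_id: str
    variant_graph: MolecularGraph
    inverted_centers: list[int]
    relation: str  # "enantiomer" | "epimer"


def _defined_tetrahedral_atoms(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetChiralTag()
        in (Chem.ChiralType.CHI_TETRAHEDRAL_CW, Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
    ]


def _invert_and_reparse(graph: MolecularGraph, atom_indices: list[int]) -> MolecularGraph:
    """Invert the parity at the given atoms and reparse from canonical SMILES.

    The round-trip through SMILES re-perceives CIP descriptors, which are
    relational and may not simply swap letter-for-letter at the touched atom.
    Double-bond stereo tags are untouched: a reflection preserves cis/trans.
    """
    mol = Chem.RWMol(graph._mol)
    for idx in atom_indices:
        mol.GetAtomWithIdx(idx).InvertChirality()
    smiles = Chem.MolToSmiles(mol)
    return parse_molecule(smiles)


def count_stereocenters(graph: MolecularGraph) -> int:
    """Number of atoms carrying a defined tetrahedral R/S descriptor."""
    return sum(1 for a in graph.atoms if a.chirality in ("R", "S"))


def enantiomer(graph: MolecularGraph, parent_id: str = "") -> StereoVariant:
    """Mirror image: every tetrahedral parity inverted (R↔S).

    Molecular formula and constitution are unchanged; an achiral input is a
    fixed point (its canonical form equals the parent's), and applying the
    operation twice returns the original canonical form.
    """
    centers = _defined_tetrahedral_atoms(graph._mol)
    variant = _invert_and_reparse(graph, centers)
    return StereoVariant(
        parent_id=parent_id,
        variant_graph=variant,
        inverted_centers=sorted(centers),
        relation="enantiomer",
    )


def epimers(graph: MolecularGraph, parent_id: str = "") -> list[StereoVariant]:
    """All single-center inversions, ordered by atom index.

    One variant per defined tetrahedral stereocenter; a molecule with no
    stereocenters yields an empty list.
    """
    variants = []
    for idx in sorted(_defined_tetrahedral_atoms(graph._mol)):
        variants.append(
            StereoVariant(
                parent_id=parent_id,
                variant_graph=_invert_and_reparse(graph, [idx]),
                inverted_centers=[idx],
                relation="epimer",
            )
        )
    return variants


def variant_id(variant: StereoVariant) -> str:
    """Identifier convention: parent_id + "_ent" or "_epi<atom index>"."""
    if variant.relation == "enantiomer":
        return f"{variant.parent_id}_ent"
    return f"{variant.parent_id}_epi{variant.inverted_centers[0]}"
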