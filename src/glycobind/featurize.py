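"""Atom-level featurization of glycoconjugates.

Two count-based encodings are provided for a parsed molecule:

* **Atom q-grams (AQG)** — counts of all connected *induced* subgraphs of the
  heavy-atom graph with up to ``q_max`` atoms.  Nodes carry a configurable
  label built from element, hybridization, attached-hydrogen count and
  tetrahedral chirality (R/S); bond orders are not encoded directly, node
  hybridization serves as their proxy.  Subgraphs are keyed by a canonical
  code so that isomorphic labeled subgraphs always collapse to one count.

* **Circular (Morgan-type) fingerprints** — counts of hashed atom-centered
  environments at radii ``0..r_max``, optionally folding tetrahedral
  chirality into the atom invariants.  Identifiers are kept unfolded
  (full-width, collision-free dictionary) rather than hashed to a fixed bit
  width, so vocabulary dimensionality is reproducible.

Feature vectors are aligned to an explicit :class:`Vocabulary` built from a
training set; codes unseen at vocabulary-build time are dropped (the cold
start behaviour of any fixed-dimension encoder).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

_HYBRIDIZATION_NAMES = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


class ParseError(ValueError):
    """Raised when a structure record cannot be parsed into a molecular graph."""


@dataclass(frozen=True)
class AtomNode:
    """One heavy atom: element, hybridization class, H count and chirality.

    ``chirality`` is the CIP descriptor ("R"/"S") for tetrahedral
    stereocenters with defined configuration, and "none" otherwise.
    """

    index: int
    element: str
    hybridization: str  # one of {"sp", "sp2", "sp3", "other"}
    h_count: int
    chirality: str  # one of {"R", "S", "none"}


@dataclass
class MolecularGraph:
    """Heavy-atom graph of a single glycoconjugate record.

    Hydrogens are not nodes; each atom carries an attached-H count.  The
    underlying RDKit molecule is retained so that downstream operations
    (fingerprints, stereocenter inversion) do not need to re-perceive
    aromaticity or stereochemistry.
    """

    atoms: list[AtomNode]
    bonds: list[tuple[int, int, float]]  # (i, j, bond order), i < j
    source_text: str
    _mol: Chem.Mol = field(repr=False, compare=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.atoms]
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def canonical_smiles(self) -> str:
        if self._mol is None:
            raise ValueError("graph has no backing molecule")
        return Chem.MolToSmiles(self._mol)


@dataclass(frozen=True)
class FeatureFlags:
    """Which node features enter AQG codes.  All off → shape-only graphs."""

    use_element: bool = True
    use_hybridization: bool = True
    use_h_count: bool = True
    use_chirality: bool = True

    def label(self, atom: AtomNode) -> tuple:
        parts = []
        if self.use_element:
            parts.append(atom.element)
        if self.use_hybridization:
            parts.append(atom.hybridization)
        if self.use_h_count:
            parts.append(str(atom.h_count))
        if self.use_chirality:
            parts.append(atom.chirality)
        return tuple(parts)


@dataclass
class SubstructureCounts:
    """Counts of canonical substructure codes for one molecule."""

    counts: dict[str, int]
    scheme: str  # "AQG" or "circular"
    q_or_r: int


@dataclass
class Vocabulary:
    """Ordered (lexicographic), duplicate-free list of substructure codes."""

    codes: list[str]
    scheme: str
    q_or_r: int

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("vocabulary codes must be unique")
        self._index = {c: i for i, c in enumerate(self.codes)}

    def __len__(self) -> int:
        return len(self.codes)

    def index_of(self, code: str) -> int | None:
        return self._index.get(code)


@dataclass
class FeatureVector:
    """Count vector aligned to a vocabulary (the model's M input)."""

    values: np.ndarray
    vocabulary: Vocabulary


def parse_molecule(smiles: str) -> MolecularGraph:
    """Parse a SMILES record into a labeled heavy-atom graph.

    Stereochemistry is perceived once at parse time: tetrahedral CIP
    descriptors (R/S) are assigned and stored on the nodes; atoms at a
    potential stereocenter with undefined configuration are labeled "none".

    Raises
    ------
    ParseError
        For unparseable input or multi-fragment (disconnected) records —
        glycoconjugate records are single molecules.
    """
    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES record")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ParseError(f"disconnected multi-fragment record: {smiles!r}")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)

    atoms = []
    for atom in mol.GetAtoms():
        hyb = _HYBRIDIZATION_NAMES.get(atom.GetHybridization(), "other")
        cip = atom.GetPropsAsDict().get("_CIPCode", "none")
        atoms.append(
            AtomNode(
                index=atom.GetIdx(),
                element=atom.GetSymbol(),
                hybridization=hyb,
                h_count=atom.GetTotalNumHs(),
                chirality=cip if cip in ("R", "S") else "none",
            )
        )
    bonds = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        bonds.append((i, j, bond.GetBondTypeAsDouble()))
    return MolecularGraph(atoms=atoms, bonds=sorted(bonds), source_text=smiles, _mol=mol)


# ---------------------------------------------------------------------------
# Atom q-gram enumeration
# ---------------------------------------------------------------------------


def _connected_induced_subsets(adj: Sequence[set[int]], q_max: int) -> Iterable[frozenset[int]]:
    """Enumerate every connected induced vertex subset of size 1..q_max once.

    ESU-style enumeration: each subset is generated from its minimum vertex,
    extending only with exclusive neighbors above that root.
    """
    n = len(adj)

    def extend(sub: set[int], ext: set[int], root: int):
        yield frozenset(sub)
        if len(sub) == q_max:
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            new_ext = ext | {
                u
                for u in adj[w]
                if u > root and u not in sub and not any(u in adj[s] for s in sub)
            }
            yield from extend(sub | {w}, new_ext, root)

    for v in range(n):
        yield from extend({v}, {u for u in adj[v] if u > v}, v)


def _canonical_code(vertices: Sequence[int], labels: dict[int, tuple], adj: Sequence[set[int]]) -> str:
    """Canonical string for one labeled induced subgraph.

    Exhaustive minimal-form search: among all vertex orderings whose label
    sequence equals the sorted label sequence, take the lexicographically
    smallest upper-triangle adjacency bitstring.  Feasible because q-gram
    sizes are small (≤ 8 atoms).
    """
    verts = list(vertices)
    k = len(verts)
    sorted_labels = sorted(labels[v] for v in verts)
    best_bits: str | None = None
    for perm in permutations(verts):
        if [labels[v] for v in perm] != sorted_labels:
            continue
        bits = "".join(
            "1" if perm[j] in adj[perm[i]] else "0"
            for i in range(k)
            for j in range(i + 1, k)
        )
        if best_bits is None or bits < best_bits:
            best_bits = bits
    label_part = ";".join(",".join(lab) if lab else "*" for lab in sorted_labels)
    return f"{k}|{label_part}|{best_bits}"


def enumerate_aqg(graph: MolecularGraph, q_max: int, flags: FeatureFlags | None = None) -> SubstructureCounts:
    """Count all connected induced subgraphs on 1..q_max atoms.

    Each subgraph is keyed by a canonical code built from its topology plus
    the node features enabled in ``flags``; disabled features are excluded
    from the code, so e.g. an all-off flag set counts pure shapes.
    """
    if not 1 <= q_max <= 8:
        raise ValueError(f"q_max must be in [1, 8], got {q_max}")
    if flags is None:
        flags = FeatureFlags()
    adj = graph.adjacency()
    labels = {a.index: flags.label(a) for a in graph.atoms}
    counts: dict[str, int] = {}
    for subset in _connected_induced_subsets(adj, q_max):
        code = _canonical_code(sorted(subset), labels, adj)
        counts[code] = counts.get(code, 0) + 1
    return SubstructureCounts(counts=counts, scheme="AQG", q_or_r=q_max)


# ---------------------------------------------------------------------------
# Circular (Morgan-type) fingerprints
# ---------------------------------------------------------------------------


def circular_fingerprint(graph: MolecularGraph, r_max: int, use_chirality: bool = True) -> SubstructureCounts:
    """Count circular atom environments at radii 0..r_max.

    Uses iteratively hashed neighborhoods (Morgan algorithm, RDKit
    implementation) with the standard connectivity invariants; tetrahedral
    chirality is folded into the invariants when ``use_chirality`` is on.
    Identifiers are kept in their full unfolded space (no fixed-width
    folding), so distinct environments never collide.
    """
    if not 0 <= r_max <= 6:
        raise ValueError(f"r_max must be in [0, 6], got {r_max}")
    if graph._mol is None:
        raise ValueError("graph has no backing molecule")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=r_max, includeChirality=use_chirality)
    raw = gen.GetSparseCountFingerprint(graph._mol).GetNonzeroElements()
    counts = {str(k): int(v) for k, v in raw.items()}
    return SubstructureCounts(counts=counts, scheme="circular", q_or_r=r_max)


# ---------------------------------------------------------------------------
# Vocabulary and vectorization
# ---------------------------------------------------------------------------


def build_vocabulary(count_maps: Sequence[SubstructureCounts]) -> Vocabulary:
    """Lexicographically sorted union of codes across count maps.

    Deterministic for a fixed input set regardless of list order.  All maps
    must share scheme and size/radius bound.
    """
    if not count_maps:
        logger.warning("building vocabulary from an empty input list")
        return Vocabulary(codes=[], scheme="AQG", q_or_r=0)
    schemes = {c.scheme for c in count_maps}
    qs = {c.q_or_r for c in count_maps}
    if len(schemes) > 1 or len(qs) > 1:
        raise ValueError(f"mixed schemes/sizes in vocabulary input: {schemes}, {qs}")
    codes = sorted(set().union(*(c.counts.keys() for c in count_maps)))
    return Vocabulary(codes=codes, scheme=schemes.pop(), q_or_r=qs.pop())


def vectorize(counts: SubstructureCounts, vocab: Vocabulary) -> FeatureVector:
    """Align a count map to a vocabulary; unseen codes are dropped.

    Dropped-code totals are reported through logging — they measure how far
    a molecule sits outside the vocabulary's training domain.
    """
    if counts.scheme != vocab.scheme or counts.q_or_r != vocab.q_or_r:
        raise ValueError(
            f"scheme mismatch: counts are {counts.scheme}/{counts.q_or_r}, "
            f"vocabulary is {vocab.scheme}/{vocab.q_or_r}"
        )
    values = np.zeros(len(vocab), dtype=np.int64)
    dropped = 0
    for code, count in counts.counts.items():
        idx = vocab.index_of(code)
        if idx is None:
            dropped += count
        else:
            values[idx] = count
    if dropped:
        logger.info("vectorize: dropped %d substructure counts not in vocabulary", dropped)
    return FeatureVector(values=values, vocabulary=vocab)
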