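"""Featurization: parsing, atom q-grams, circular fingerprints, vocabularies."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from glycobind.featurize import (
    FeatureFlags,
    ParseError,
    SubstructureCounts,
    build_vocabulary,
    circular_fingerprint,
    enumerate_aqg,
    parse_molecule,
    vectorize,
)
from glycobind.stereo import count_stereocenters, enantiomer

from conftest import random_labeled_graph

ELEMENT_ONLY = FeatureFlags(use_element=True, use_hybridization=False, use_h_count=False, use_chirality=False)


def brute_force_aqg(graph, q_max, flags):
    """Independent oracle: all vertex subsets, connectivity filter, exhaustive
    isomorphism grouping (networkx VF2 with label matching)."""
    g = nx.Graph()
    labels = {a.index: flags.label(a) for a in graph.atoms}
    for a in graph.atoms:
        g.add_node(a.index, label=labels[a.index])
    for i, j, _ in graph.bonds:
        g.add_edge(i, j)
    match = lambda a, b: a["label"] == b["label"]  # noqa: E731
    groups: list[list] = []  # [representative subgraph, count]
    for k in range(1, q_max + 1):
        for subset in combinations(g.nodes, k):
            sub = g.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            for entry in groups:
                if entry[0].number_of_nodes() == k and nx.is_isomorphic(entry[0], sub, node_match=match):
                    entry[1] += 1
                    break
            else:
                groups.append([nx.Graph(sub), 1])
    return sorted(c for _, c in groups)


class TestParse:
    def test_small_achiral_molecule(self, ethanol):
        assert ethanol.n_atoms == 3
        assert count_stereocenters(ethanol) == 0

    def test_glucopyranose_stereocenters(self, glucose):
        # β-D-glucopyranose: 12 heavy atoms, 5 ring stereocenters (C1-C5)
        assert glucose.n_atoms == 12
        assert count_stereocenters(glucose) == 5

    @pytest.mark.parametrize("bad", ["not-a-smiles", "", "   ", "C1CC"])
    def test_unparseable_input(self, bad):
        with pytest.raises(ParseError):
            parse_molecule(bad)

    def test_disconnected_record_rejected(self):
        with pytest.raises(ParseError, match="disconnected"):
            parse_molecule("CCO.CCN")

    def test_reparse_is_idempotent(self, glucose):
        again = parse_molecule(glucose.canonical_smiles())
        assert again.canonical_smiles() == glucose.canonical_smiles()
        assert again.n_atoms == glucose.n_atoms
        assert count_stereocenters(again) == count_stereocenters(glucose)

    def test_every_bond_references_existing_atoms(self, glucose):
        indices = {a.index for a in glucose.atoms}
        assert len(indices) == glucose.n_atoms
        for i, j, _ in glucose.bonds:
            assert i in indices and j in indices


class TestAQG:
    def test_single_atom(self):
        counts = enumerate_aqg(parse_molecule("C"), 6, ELEMENT_ONLY)
        assert list(counts.counts.values()) == [1]

    def test_linear_three_atom_path(self, ethanol):
        # O–C–C element-only: O, 2×C, O–C, C–C, O–C–C
        counts = enumerate_aqg(ethanol, 3, ELEMENT_ONLY)
        assert len(counts.counts) == 5
        assert sorted(counts.counts.values()) == [1, 1, 1, 1, 2]

    def test_q_max_out_of_range(self, ethanol):
        with pytest.raises(ValueError):
            enumerate_aqg(ethanol, 0)
        with pytest.raises(ValueError):
            enumerate_aqg(ethanol, 9)

    def test_size1_counts_conserve_heavy_atoms(self, glucose):
        counts = enumerate_aqg(glucose, 3, ELEMENT_ONLY)
        size1 = sum(v for k, v in counts.counts.items() if k.startswith("1|"))
        assert size1 == glucose.n_atoms

    def test_mirror_symmetry_of_featurization(self, glucose):
        ent = enantiomer(glucose).variant_graph
        achiral = FeatureFlags(use_chirality=False)
        chiral = FeatureFlags(use_chirality=True)
        assert enumerate_aqg(glucose, 4, achiral).counts == enumerate_aqg(ent, 4, achiral).counts
        assert enumerate_aqg(glucose, 4, chiral).counts != enumerate_aqg(ent, 4, chiral).counts

    def test_codes_invariant_under_atom_renumbering(self, glucose):
        from rdkit import Chem

        mol = glucose._mol
        order = list(range(mol.GetNumAtoms()))[::-1]
        renumbered = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
        counts_a = enumerate_aqg(glucose, 4)
        counts_b = enumerate_aqg(parse_molecule(renumbered), 4)
        assert counts_a.counts == counts_b.counts

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        flags = FeatureFlags()
        for _ in range(20):
            graph = random_labeled_graph(rng)
            counts = enumerate_aqg(graph, 4, flags)
            assert sorted(counts.counts.values()) == brute_force_aqg(graph, 4, flags)


class TestCircularFingerprint:
    def test_single_atom_radius_zero(self):
        counts = circular_fingerprint(parse_molecule("C"), 0)
        assert list(counts.counts.values()) == [1]

    def test_ethanol_radius_one_environments(self, ethanol):
        # 3 radius-0 atom environments + 3 distinct radius-1 environments
        counts = circular_fingerprint(ethanol, 1, use_chirality=False)
        assert len(counts.counts) == 6
        assert set(counts.counts.values()) == {1}

    def test_enantiomer_pair_symmetry(self, glucose):
        ent = enantiomer(glucose).variant_graph
        achiral_a = circular_fingerprint(glucose, 3, use_chirality=False)
        achiral_b = circular_fingerprint(ent, 3, use_chirality=False)
        assert achiral_a.counts == achiral_b.counts
        chiral_a = circular_fingerprint(glucose, 3, use_chirality=True)
        chiral_b = circular_fingerprint(ent, 3, use_chirality=True)
        assert chiral_a.counts != chiral_b.counts

    def test_radius_out_of_range(self, ethanol):
        with pytest.raises(ValueError):
            circular_fingerprint(ethanol, 7)


class TestVocabulary:
    def test_sorted_union_and_order_independence(self):
        a = SubstructureCounts({"a": 2}, "AQG", 3)
        b = SubstructureCounts({"b": 1}, "AQG", 3)
        assert build_vocabulary([a, b]).codes == ["a", "b"]
        assert build_vocabulary([b, a]).codes == ["a", "b"]

    def test_mixed_schemes_rejected(self):
        a = SubstructureCounts({"a": 2}, "AQG", 3)
        b = SubstructureCounts({"b": 1}, "circular", 3)
        with pytest.raises(ValueError):
            build_vocabulary([a, b])

    def test_empty_input_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            vocab = build_vocabulary([])
        assert len(vocab) == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_vectorize_alignment_and_dropping(self):
        vocab = build_vocabulary([SubstructureCounts({"a": 1, "b": 1}, "AQG", 3)])
        vec = vectorize(SubstructureCounts({"a": 2, "c": 5}, "AQG", 3), vocab)
        assert vec.values.tolist() == [2, 0]
        assert vectorize(SubstructureCounts({"b": 1}, "AQG", 3), vocab).values.tolist() == [0, 1]
        assert vectorize(SubstructureCounts({}, "AQG", 3), vocab).values.tolist() == [0, 0]

    def test_vectorize_scheme_mismatch(self):
        vocab = build_vocabulary([SubstructureCounts({"a": 1}, "AQG", 3)])
        with pytest.raises(ValueError):
            vectorize(SubstructureCounts({"a": 1}, "circular", 3), vocab)
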