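"""Phylogeny model: parsing, cumulative profiles, divergence queries."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mtqc import (
    PhylogenyError,
    Variant,
    format_phylogeny,
    load_phylogeny,
    parse_variant,
)
from conftest import random_tree


def test_minimal_two_line_tree():
    t = load_phylogeny("ROOT\n  L1b: C6548T")
    assert set(t.index) == {"ROOT", "L1b"}
    assert t.expected_profile("L1b") == frozenset({parse_variant("C6548T")})
    assert t.expected_profile("ROOT") == frozenset()


@pytest.mark.parametrize(
    "source, message",
    [
        ("ROOT\n  L2: A7146G\n  L2: C8468T", "duplicate"),
        ("ROOT\n  A: C6548T\n    B: !A7146G", "back mutation"),
        ("ROOT\n  A: C6548T, T6548C", "repeats a position"),
        ("ROOT\n      A: C6548T", "more than one level"),
        ("ROOT: A7146G\n  A: C6548T", "root"),
        ("ROOT\n  A: ZZT", "parse"),
        ("ROOT\n  A: C6548T\nROOT2", "second root"),
    ],
)
def test_load_phylogeny_rejects(source, message):
    with pytest.raises(PhylogenyError, match=message):
        load_phylogeny(source)


def test_fixture_tree_contains_named_haplogroups(tree):
    expected = {
        "L1b1a3a", "L2a", "L2c", "L3e2b1a", "L3d1", "L3e3b", "K1a4a1a",
        "K1a4a1", "J2a1a1", "J1c5", "H", "H1", "H1c3", "HV", "HV0a", "V1a",
        "U4b", "U5a", "R", "C1", "F1c",
    }
    assert expected <= set(tree.index)
    assert len(tree) >= 20


def test_fixture_l1b_cumulative_profile(tree):
    printed = {
        "C6548T", "T6827C", "A6989G", "A7055G", "T7389C", "C7915T",
        "A8248G", "C16270T",
    }
    tokens = {str(v) for v in tree.expected_profile("L1b")}
    assert printed <= tokens


def test_back_mutation_removes_ancestral_entry(tree):
    # the HV branch reverts position 14766 acquired on the N branch
    assert 14766 in {v.position for v in tree.expected_profile("N")}
    assert 14766 not in {v.position for v in tree.expected_profile("HV")}
    assert 14766 not in {v.position for v in tree.expected_profile("H1c3")}


def test_expected_profile_root_is_empty(tree):
    assert tree.expected_profile(tree.root.name) == frozenset()


def test_unknown_names_raise(tree):
    with pytest.raises(KeyError):
        tree.expected_profile("NOPE")
    with pytest.raises(KeyError):
        tree.lineage_divergence("L1b", "NOPE")


def _oracle_profile(tree, name):
    """Independent accumulation: walk to root collecting per-position state."""
    chain = []
    node = tree.node(name)
    while node is not None:
        chain.append(node)
        node = node.parent
    state = {}
    for n in reversed(chain):
        for entry in n.branch_motif:
            if entry.is_back_mutation:
                state.pop(entry.variant.position, None)
            else:
                state[entry.variant.position] = entry.variant
    return set(state.values())


def test_lineage_divergence_matches_bruteforce_on_random_tree():
    t = random_tree(np.random.default_rng(99), n_nodes=30)
    names = list(t.index)
    for a, b in itertools.combinations(names, 2):
        count, path = t.lineage_divergence(a, b)
        expected = _oracle_profile(t, a) ^ _oracle_profile(t, b)
        assert path == frozenset(expected)
        assert count == len(expected)
        assert t.lineage_divergence(b, a) == (count, path)


def test_divergence_identity_and_single_edge(tree):
    assert tree.lineage_divergence("L2a", "L2a") == (0, frozenset())
    count, path = tree.lineage_divergence("L2", "L2a")
    motif = {e.variant for e in tree.node("L2a").branch_motif}
    assert count == len(motif) == 8
    assert path == frozenset(motif)


def test_divergence_equals_path_edge_entries_without_back_mutations(tree):
    """On back-mutation-free paths, divergence counts path motif entries."""

    def path_edges(a, b):
        m = tree.mrca(a, b)
        edges = []
        for name in (a, b):
            node = tree.node(name)
            while node is not m:
                edges.append(node)
                node = node.parent
        return edges

    names = list(tree.index)
    for a, b in itertools.combinations(names, 2):
        edges = path_edges(a, b)
        if any(e.is_back_mutation for n in edges for e in n.branch_motif):
            continue
        count, _ = tree.lineage_divergence(a, b)
        assert count == sum(len(n.branch_motif) for n in edges)


def test_format_load_roundtrip(tree, small_random_tree):
    for t in (tree, small_random_tree):
        text = format_phylogeny(t)
        t2 = load_phylogeny(text)
        assert set(t2.index) == set(t.index)
        for name in t.index:
            assert t2.expected_profile(name) == t.expected_profile(name)
            assert t2.node(name).branch_motif == t.node(name).branch_motif
        assert format_phylogeny(t2) == text


def test_newick_export_topology(tree):
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    for leaf in tree.leaves():
        assert leaf.name in nwk
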