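"""Iteration domain, accesses, dependence extraction and closed form."""

import numpy as np
import pytest

from nusstile.iterspace import (
    Dependence,
    DomainCapError,
    EmptyDomainError,
    S1,
    S2,
    accesses_of,
    dependence_pairs,
    deps_to_tsv,
    distance_vectors,
    domain_arrays,
    domain_size,
    enumerate_domain,
    extract_deps,
    in_dependence_relation,
    instance_indices,
    stamp_key,
)

from _oracles import brute_force_dependences


def test_domain_smallest_cases():
    assert enumerate_domain(2) == [S1(0, 1, 0), S2(0, 1)]
    d3 = enumerate_domain(3)
    assert len(d3) == 7
    assert d3[:2] == [S1(1, 2, 0), S2(1, 2)]  # i descends: row 1 first
    assert domain_size(4) == 16 == len(enumerate_domain(4))


def test_domain_errors():
    with pytest.raises(EmptyDomainError):
        enumerate_domain(1)
    with pytest.raises(DomainCapError):
        extract_deps(200)


@pytest.mark.parametrize("n", [2, 3, 5, 9])
def test_domain_is_in_execution_order(n):
    insts = enumerate_domain(n)
    keys = [stamp_key(x) for x in insts]
    assert keys == sorted(keys)
    assert len(set(keys)) == len(keys)


@pytest.mark.parametrize("n", [2, 4, 7])
def test_domain_arrays_and_indices_agree_with_enumeration(n):
    insts = enumerate_domain(n)
    s, i, j, k = domain_arrays(n)
    assert np.array_equal(s, [int(x.stmt) for x in insts])
    assert np.array_equal(i, [x.i for x in insts])
    assert np.array_equal(j, [x.j for x in insts])
    assert np.array_equal(k, [x.k if x.k is not None else 0 for x in insts])
    assert np.array_equal(instance_indices(s, i, j, k, n), np.arange(len(insts)))


def test_accesses_examples():
    assert accesses_of(S1(0, 2, 0)) == ((0, 2), ((0, 2), (0, 0), (1, 2)))
    assert accesses_of(S2(1, 2)) == ((1, 2), ((1, 2), (2, 1)))
    _, reads = accesses_of(S1(0, 3, 2))
    assert (0, 2) in reads and (3, 3) in reads


@pytest.mark.parametrize("n", [2, 3, 4, 5, 6, 7])
def test_extract_deps_equals_literal_pair_scan(n):
    """The per-cell extractor matches a literal scan of all ordered
    instance pairs, categories and cells included."""
    got = {(d.src, d.dst, d.category, d.cell) for d in extract_deps(n)}
    assert got == brute_force_dependences(n)
    # and the index-pair fast path carries exactly the distinct pairs
    insts = enumerate_domain(n)
    si, di = dependence_pairs(n)
    got_pairs = {(insts[a], insts[b]) for a, b in zip(si, di)}
    assert got_pairs == {(s, d) for s, d, _, _ in brute_force_dependences(n)}
    assert len(si) == len(got_pairs)  # no duplicate pairs emitted


def test_specific_dependences_present():
    deps3 = {(d.src, d.dst, d.category, d.cell) for d in extract_deps(3)}
    assert (S2(1, 2), S1(0, 2, 0), "flow", (1, 2)) in deps3
    deps4 = {(d.src, d.dst, d.category, d.cell) for d in extract_deps(4)}
    assert (S2(1, 2), S2(0, 3), "flow", (1, 2)) in deps4


def test_n2_has_only_same_cell_chain():
    deps = extract_deps(2)
    assert {(d.src, d.dst, d.cell) for d in deps} == {(S1(0, 1, 0), S2(0, 1), (0, 1))}
    assert {d.category for d in deps} == {"flow", "anti", "output"}


def test_relation_membership_examples():
    assert in_dependence_relation(S1(0, 2, 1), S1(0, 3, 2), 4)
    assert in_dependence_relation(S2(1, 2), S2(0, 3), 4)
    assert not in_dependence_relation(S2(0, 3), S2(1, 2), 4)


@pytest.mark.parametrize("n", range(3, 11))
def test_relation_members_are_genuine_dependences(n):
    """Soundness: every instance pair admitted by the closed-form relation
    is an actual dependence found by brute force."""
    insts = enumerate_domain(n)
    si, di = dependence_pairs(n)
    genuine = {(insts[a], insts[b]) for a, b in zip(si, di)}
    admitted = 0
    for a in insts:
        for b in insts:
            if in_dependence_relation(a, b, n):
                admitted += 1
                assert (a, b) in genuine, (a, b)
    assert admitted > 0


@pytest.mark.parametrize("n", range(3, 9))
def test_value_flows_are_admitted_or_transitively_implied(n):
    """Every value-carrying flow dependence (the last write of a cell
    feeding a read) is admitted by the closed-form relation, directly or
    through a composition of admitted pairs."""
    import networkx as nx

    insts = enumerate_domain(n)
    order = {inst: pos for pos, inst in enumerate(insts)}
    graph = nx.DiGraph()
    graph.add_nodes_from(insts)
    for a in insts:
        for b in insts:
            if in_dependence_relation(a, b, n):
                graph.add_edge(a, b)
    flows = [d for d in extract_deps(n) if d.category == "flow"]
    # last writer of each cell before each reading instance
    by_cell_readers = {}
    for d in flows:
        by_cell_readers.setdefault((d.cell, d.dst), []).append(d.src)
    checked = 0
    for (cell, dst), writers in by_cell_readers.items():
        last_writer = max(writers, key=lambda w: order[w])
        checked += 1
        assert in_dependence_relation(last_writer, dst, n) or nx.has_path(
            graph, last_writer, dst
        ), (last_writer, dst, cell)
    assert checked > 0


def test_distance_vector_examples():
    vecs = distance_vectors(4)
    assert (-1, 1, 0, 0) in vecs
    assert any(v[0] == 0 and v[1] >= 1 and v[2] == -1 and v[3] > 0 for v in vecs)


@pytest.mark.parametrize("n", [3, 5, 8])
def test_distance_vectors_forward_in_decremented_order(n):
    """First component never positive: the outer loop decrements, so a
    forward dependence steps to an equal or smaller i."""
    for v in distance_vectors(n):
        assert v[0] <= 0


def test_deps_tsv_shape():
    deps = extract_deps(3)
    text = deps_to_tsv(deps)
    lines = text.strip().split("\n")
    assert lines[0] == "src\tdst\tcategory\tcell"
    assert len(lines) == len(deps) + 1
    assert all(len(line.split("\t")) == 4 for line in lines[1:])
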