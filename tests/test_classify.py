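"""Peptide/protein classification: worked examples, oracle, invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protinfer import (
    PeptideCategory,
    PeptideRecord,
    ProteinCategory,
    ValidationError,
    build_graph,
    classify,
    classify_peptides,
    classify_proteins,
    infer,
    oracle_classify,
)
from protinfer.fixtures import random_graph

U = PeptideCategory.UNIQUE
D = PeptideCategory.DISCRIMINATING
N = PeptideCategory.NON_DISCRIMINATING


def _categories(graph):
    return {s: p.category for s, p in graph.peptides.items()}


def _graph(mapping, n_runs=1):
    records = [PeptideRecord(seq, set(accs)) for seq, accs in mapping.items()]
    return build_graph(records, n_runs=n_runs)


def test_single_protein_single_peptide_is_unique_and_conclusive():
    graph = _graph({"PEPTIDEK": {"A"}})
    result = classify(graph)
    assert _categories(graph) == {"PEPTIDEK": U}
    assert [(g.category, g.members) for g in result.groups] == [
        (ProteinCategory.CONCLUSIVE, ("A",))
    ]


def test_f1_peptide_categories(f1_graph):
    classify_peptides(f1_graph)
    assert _categories(f1_graph) == {
        "AIDEGLK": U,   # only in A
        "CHEWGR": N,    # contains conclusive A
        "DELTAK": D,
        "FGHIKK": D,
        "MNPQRK": D,
        "STVWYK": N,    # strict superset of DELTAK's {C,D}
    }


def test_f1_protein_groups(f1_result):
    by_cat = {}
    for g in f1_result.groups:
        by_cat.setdefault(g.category, []).append(g.members)
    assert by_cat[ProteinCategory.CONCLUSIVE] == [("A",)]
    assert sorted(by_cat[ProteinCategory.NON_CONCLUSIVE]) == [("B",), ("H",), ("I",)]
    assert by_cat[ProteinCategory.INDISTINGUISHABLE] == [("C", "D")]
    assert by_cat[ProteinCategory.AMBIGUOUS_GROUP] == [("E", "F", "G")]
    assert f1_result.stats[ProteinCategory.CONCLUSIVE] == (1, 1)
    assert f1_result.stats[ProteinCategory.NON_CONCLUSIVE] == (3, 3)
    assert f1_result.stats[ProteinCategory.INDISTINGUISHABLE] == (2, 1)
    assert f1_result.stats[ProteinCategory.AMBIGUOUS_GROUP] == (3, 1)
    # canonical numbering by smallest member accession
    assert [g.group_id for g in f1_result.groups] == [1, 2, 3, 4, 5, 6]
    assert [g.members[0] for g in f1_result.groups] == ["A", "B", "C", "E", "H", "I"]


def test_shared_only_peptide_stays_discriminating():
    """Two proteins whose single peptide is shared: no strict superset exists."""
    graph = _graph({"PEPTIDEK": {"A", "B"}})
    result = classify(graph)
    assert _categories(graph) == {"PEPTIDEK": D}
    assert [(g.category, g.members) for g in result.groups] == [
        (ProteinCategory.INDISTINGUISHABLE, ("A", "B"))
    ]


def test_strict_subset_chain():
    graph = _graph({"AAK": {"A"}, "CCK": {"A", "B"}, "DDK": {"A", "B", "C"}})
    classify_peptides(graph)
    assert _categories(graph) == {"AAK": U, "CCK": N, "DDK": N}


def test_disjoint_unique_peptides_are_all_unique():
    graph = _graph({"AAK": {"A"}, "CCK": {"B"}, "DDK": {"C"}})
    assert set(oracle_classify(graph).values()) == {U}
    classify_peptides(graph)
    assert set(_categories(graph).values()) == {U}


def test_mixed_component_is_ambiguous_not_indistinguishable():
    """Identical peptide sets -> indistinguishable; mixed components -> ambiguous."""
    graph = _graph({"AAK": {"A", "B"}, "CCK": {"B", "C"}})
    result = classify(graph)
    assert [(g.category, g.members) for g in result.groups] == [
        (ProteinCategory.AMBIGUOUS_GROUP, ("A", "B", "C"))
    ]


def test_transitive_ambiguous_merging(f1_result):
    """E and G never share a peptide but are merged through F."""
    ambiguous = [
        g for g in f1_result.groups if g.category is ProteinCategory.AMBIGUOUS_GROUP
    ]
    assert ambiguous[0].members == ("E", "F", "G")


def test_classify_requires_peptide_categories(f1_graph):
    with pytest.raises(ValidationError):
        classify_proteins(f1_graph)


def test_empty_graph_is_rejected():
    from protinfer import EvidenceGraph

    with pytest.raises(ValidationError):
        classify_peptides(EvidenceGraph({}, {}, 1))


def test_group_annotations_cover_member_peptides(f1_result):
    for g in f1_result.groups:
        expected = set()
        for acc in g.members:
            expected |= f1_result.graph.proteins[acc].peptides
        assert set(g.peptide_annotations) == expected


@settings(deadline=None, derandomize=True, max_examples=200)
@given(seed=st.integers(0, 10**6))
def test_iterative_classifier_matches_oracle(seed):
    """The iterative procedure equals the closed-form strict-subset oracle."""
    records = random_graph(
        n_proteins=1 + seed % 12,
        n_peptides=1 + (seed // 7) % 20,
        mean_degree=1.0 + (seed % 30) / 10.0,
        seed=seed,
    )
    graph = build_graph(records)
    classify_peptides(graph)
    assert _categories(graph) == oracle_classify(graph)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(seed=st.integers(0, 10**6))
def test_partition_and_structural_invariants(seed):
    records = random_graph(
        n_proteins=2 + seed % 11, n_peptides=2 + seed % 19,
        mean_degree=2.0, n_runs=1 + seed % 4, dropout=0.2, seed=seed,
    )
    result = infer(records, runs_threshold=1 + seed % 3)
    graph = result.graph
    # partition: every non-filtered protein in exactly one group
    seen = [acc for g in result.groups for acc in g.members]
    assert len(seen) == len(set(seen))
    assert set(seen) | set(result.filtered_accessions) == (
        set(graph.proteins) | set(result.filtered_accessions)
    )
    assert sum(n for n, _ in result.stats.values()) == len(seen) + len(
        result.filtered_accessions
    )
    for g in result.groups:
        if g.category in (ProteinCategory.CONCLUSIVE, ProteinCategory.NON_CONCLUSIVE):
            assert len(g.members) == 1
        else:
            assert len(g.members) >= 2
    # conclusive proteins never hold a discriminating peptide
    for acc, prot in graph.proteins.items():
        if prot.category is ProteinCategory.CONCLUSIVE:
            assert all(
                graph.peptides[s].category is not D for s in prot.peptides
            )
    # every discriminating peptide's protein set lies inside one group
    membership = {acc: g.group_id for g in result.groups for acc in g.members}
    for pep in graph.peptides.values():
        if pep.category is D:
            assert len({membership[a] for a in pep.proteins}) == 1


@settings(deadline=None, derandomize=True, max_examples=50)
@given(seed=st.integers(0, 10**6))
def test_record_order_never_changes_the_result(seed):
    import random as _random

    records = random_graph(
        n_proteins=9, n_peptides=14, mean_degree=2.2, n_runs=2, dropout=0.2, seed=seed
    )
    base = classify(build_graph(records, 2))
    shuffled = list(records)
    _random.Random(seed).shuffle(shuffled)
    other = classify(build_graph(shuffled, 2))
    assert [(g.category, g.members) for g in base.groups] == [
        (g.category, g.members) for g in other.groups
    ]
    assert {s: p.category for s, p in base.graph.peptides.items()} == {
        s: p.category for s, p in other.graph.peptides.items()
    }
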