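"""Evidence-graph construction: merging, canonical order, invariants."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protinfer import PeptideRecord, ValidationError, build_graph
from protinfer.fixtures import random_graph


def test_single_record_builds_minimal_graph():
    graph = build_graph([PeptideRecord("PEPTIDEK", {"A"}, run_index=1)], n_runs=1)
    assert set(graph.peptides) == {"PEPTIDEK"}
    assert set(graph.proteins) == {"A"}
    assert graph.peptides["PEPTIDEK"].runs == {1}
    assert graph.proteins["A"].peptides == {"PEPTIDEK"}


def test_records_with_same_sequence_are_merged():
    records = [
        PeptideRecord("PEPTIDEK", {"A"}, run_index=1),
        PeptideRecord("PEPTIDEK", {"B"}, run_index=2),
    ]
    graph = build_graph(records, n_runs=2)
    pep = graph.peptides["PEPTIDEK"]
    assert pep.proteins == {"A", "B"}
    assert pep.runs == {1, 2}
    assert len(graph.peptides) == 1


def test_f1_fixture_graph_dimensions(f1_graph):
    assert len(f1_graph.peptides) == 6
    assert len(f1_graph.proteins) == 9


def test_modification_variants_are_collected_and_deduplicated():
    records = [
        PeptideRecord("PEPTIDEK", {"A"}, modifications=[(3, "Oxidation")]),
        PeptideRecord("PEPTIDEK", {"A"}, modifications=[(3, "Oxidation")]),
        PeptideRecord("PEPTIDEK", {"A"}, modifications=[]),
    ]
    graph = build_graph(records, n_runs=1)
    assert graph.peptides["PEPTIDEK"].variants == [(), ((3, "Oxidation"),)]


@pytest.mark.parametrize(
    "records, match",
    [
        ([], "no identifications"),
        ([PeptideRecord("PEPTIDEK", set())], "PEPTIDEK"),
        ([PeptideRecord("PEPTIDEK", {"A"}, run_index=0)], "run_index"),
    ],
)
def test_invalid_inputs_are_rejected(records, match):
    with pytest.raises(ValidationError, match=match):
        build_graph(records, n_runs=1)


def test_run_index_above_n_runs_is_rejected():
    with pytest.raises(ValidationError, match="run_index 3"):
        build_graph([PeptideRecord("PEPTIDEK", {"A"}, run_index=3)], n_runs=2)


def _graph_fingerprint(graph):
    return (
        [(s, sorted(p.proteins), sorted(p.runs), p.variants)
         for s, p in graph.peptides.items()],
        [(a, sorted(p.peptides)) for a, p in graph.proteins.items()],
    )


@settings(deadline=None, derandomize=True, max_examples=50)
@given(seed=st.integers(0, 10_000))
def test_symmetry_duplication_and_order_invariance(seed):
    """Random graphs are symmetric, and canonical under shuffle/duplication."""
    records = random_graph(
        n_proteins=8, n_peptides=12, mean_degree=2.5, n_runs=3, dropout=0.3, seed=seed
    )
    graph = build_graph(records, n_runs=3)
    graph.check_symmetry()

    rng = random.Random(seed)
    shuffled = list(records)
    rng.shuffle(shuffled)
    duplicated = shuffled + [rng.choice(records)]
    assert _graph_fingerprint(build_graph(shuffled, 3)) == _graph_fingerprint(graph)
    assert _graph_fingerprint(build_graph(duplicated, 3)) == _graph_fingerprint(graph)
    # canonical iteration order, not just set equality
    assert list(graph.peptides) == sorted(graph.peptides)
    assert list(graph.proteins) == sorted(graph.proteins)
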