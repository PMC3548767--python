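"""Replicate-run integration: voting threshold, filtering, monotonicity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protinfer import (
    PeptideRecord,
    ProteinCategory,
    RunsThreshold,
    ValidationError,
    filter_by_runs,
    infer,
    voting_threshold,
)
from protinfer.fixtures import random_graph


@pytest.mark.parametrize("n_runs, expected", [(1, 1), (2, 2), (3, 2), (4, 3), (5, 3), (6, 4)])
def test_voting_threshold_is_strict_majority(n_runs, expected):
    assert voting_threshold(n_runs) == expected


def test_voting_threshold_rejects_nonpositive_runs():
    with pytest.raises(ValidationError):
        voting_threshold(0)


def test_runs_threshold_must_be_positive():
    with pytest.raises(ValidationError):
        RunsThreshold(0)


def _category(result, acc):
    return result.graph.proteins[acc].category


def test_mr1_merging_keeps_every_peptide_and_all_proteins_conclusive(mr1_records):
    kept, filtered = filter_by_runs(mr1_records, 1)
    assert kept == list(mr1_records)
    assert filtered == frozenset()
    result = infer(mr1_records, n_runs=3, runs_threshold=1)
    for acc in "ABCD":
        assert _category(result, acc) is ProteinCategory.CONCLUSIVE


def test_mr1_voting_filters_single_run_peptide_and_demotes_protein(mr1_records):
    kept, filtered = filter_by_runs(mr1_records, voting_threshold(3))
    assert "EEHMTK" not in {r.sequence for r in kept}  # seen in one run only
    assert filtered == frozenset()  # C keeps its shared peptide
    result = infer(mr1_records, n_runs=3, runs_threshold=2)
    assert _category(result, "C") is ProteinCategory.NON_CONCLUSIVE
    assert _category(result, "A") is ProteinCategory.CONCLUSIVE


def test_threshold_above_n_runs_filters_everything(mr1_records):
    kept, filtered = filter_by_runs(mr1_records, 4)
    assert kept == []
    assert filtered == {a for r in mr1_records for a in r.proteins}
    result = infer(mr1_records, n_runs=3, runs_threshold=4)
    assert result.groups == []
    assert result.stats[ProteinCategory.FILTERED] == (4, 0)


def test_kept_and_filtered_accessions_partition_the_input(mr1_records):
    for threshold in (1, 2, 3, 4):
        kept, filtered = filter_by_runs(mr1_records, threshold)
        kept_accs = {a for r in kept for a in r.proteins}
        all_accs = {a for r in mr1_records for a in r.proteins}
        assert kept_accs | set(filtered) == all_accs
        assert kept_accs & set(filtered) == set()


@settings(deadline=None, derandomize=True, max_examples=60)
@given(seed=st.integers(0, 10**6))
def test_kept_peptides_shrink_as_threshold_rises(seed):
    n_runs = 2 + seed % 4
    records = random_graph(
        n_proteins=8, n_peptides=15, mean_degree=2.0,
        n_runs=n_runs, dropout=0.35, seed=seed,
    )
    previous = None
    for threshold in range(1, n_runs + 2):
        kept, _ = filter_by_runs(records, threshold)
        kept_seqs = {r.sequence for r in kept}
        if previous is not None:
            assert kept_seqs <= previous
        previous = kept_seqs
    # threshold 1 is a no-op filter
    kept1, filtered1 = filter_by_runs(records, 1)
    assert kept1 == list(records) and filtered1 == frozenset()
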