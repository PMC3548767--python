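"""CSV and HTML reports: markers, row counts, determinism, anchors."""

import csv
import re

import pytest

from protinfer import (
    PeptideCategory,
    PeptideRecord,
    ProteinCategory,
    infer,
    peptide_marker,
    write_csv,
    write_html,
)
from protinfer.fixtures import fixture_MR1


@pytest.mark.parametrize(
    "category, marker",
    [
        (PeptideCategory.UNIQUE, ""),
        (PeptideCategory.DISCRIMINATING, "*"),
        (PeptideCategory.NON_DISCRIMINATING, "**"),
    ],
)
def test_peptide_marker_convention(category, marker):
    assert peptide_marker(category) == marker


def _read_rows(path):
    with open(path, newline="", encoding="utf-8") as handle:
        lines = [line for line in handle if not line.startswith("#")]
    return list(csv.reader(lines))


def test_f1_csv_has_one_row_per_protein_across_six_groups(f1_result, tmp_path):
    path = tmp_path / "f1.csv"
    write_csv(f1_result, path)
    header, *rows = _read_rows(path)
    assert len(rows) == 9  # one per protein
    assert len({r[0] for r in rows}) == 6  # six groups
    assert sum(len(g.members) for g in f1_result.groups) == len(rows)
    a_row = next(r for r in rows if r[2] == "A")
    assert a_row[1] == "conclusive"
    assert "AIDEGLK" in a_row[4] and "CHEWGR**" in a_row[4]


def test_csv_stats_block_matches_result(f1_result, tmp_path):
    path = tmp_path / "f1.csv"
    write_csv(f1_result, path)
    stats_lines = [
        line for line in path.read_text().splitlines() if line.startswith("# ")
    ]
    assert "# conclusive,1,1" in stats_lines
    assert "# indistinguishable,2,1" in stats_lines
    assert "# ambiguous group,3,1" in stats_lines
    assert "# non-conclusive,3,3" in stats_lines
    assert "# filtered,0,0" in stats_lines


def test_description_with_comma_is_quoted(tmp_path):
    records = [
        PeptideRecord(
            "ELVISK",
            {"P1"},
            protein_descriptions=(("P1", "kinase, putative"),),
        )
    ]
    result = infer(records)
    path = tmp_path / "comma.csv"
    write_csv(result, path)
    header, row = _read_rows(path)
    assert row[3] == "kinase, putative"
    assert '"kinase, putative"' in path.read_text()


def test_empty_result_writes_header_and_stats_only(tmp_path):
    records = [PeptideRecord("ELVISK", {"P1"}, run_index=1)]
    result = infer(records, n_runs=2, runs_threshold=2)  # filters everything
    assert result.groups == []
    path = tmp_path / "empty.csv"
    write_csv(result, path)
    header, *rows = _read_rows(path)
    assert rows == []
    assert "# filtered,1,0" in path.read_text()


def test_reports_are_byte_identical_across_reruns(f1_result, tmp_path):
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    write_csv(f1_result, a)
    write_csv(f1_result, b)
    assert a.read_bytes() == b.read_bytes()
    ha, hb = tmp_path / "a.html", tmp_path / "b.html"
    write_html(f1_result, ha)
    write_html(f1_result, hb)
    assert ha.read_bytes() == hb.read_bytes()


def test_html_stats_table_lists_all_categories(f1_result, tmp_path):
    path = tmp_path / "f1.html"
    write_html(f1_result, path)
    text = path.read_text()
    for cat in ProteinCategory:
        assert f"<td>{cat.label}</td>" in text
    assert "<td>3 (1)</td>" in text  # ambiguous group: proteins (groups)
    assert "<td>2 (1)</td>" in text  # indistinguishable


def test_html_summary_links_resolve_to_detail_anchors(f1_result, tmp_path):
    path = tmp_path / "f1.html"
    write_html(f1_result, path)
    text = path.read_text()
    hrefs = set(re.findall(r'href="#(prot-[^"]+)"', text))
    anchors = set(re.findall(r'id="(prot-[^"]+)"', text))
    assert hrefs and hrefs <= anchors


def test_html_details_show_run_occupancy(tmp_path):
    result = infer(fixture_MR1(), n_runs=3, runs_threshold=2)
    path = tmp_path / "mr1.html"
    write_html(result, path)
    text = path.read_text()
    assert "runs: 1,2,3" in text
    assert "runs: 1,2" in text  # protein A's unique peptide
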