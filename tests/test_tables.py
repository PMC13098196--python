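import pytest

from umbrannot import tables
from umbrannot.tables import (
    FixtureError,
    fixture_duplex_audit,
    fixture_slippery_offsets,
    load_tables,
    tally,
    tally_report,
)


@pytest.fixture(scope="module")
def rows():
    return load_tables()


def test_row_counts(rows):
    groups = {}
    for r in rows:
        groups[r.group] = groups.get(r.group, 0) + 1
    assert groups == {"UV": 17, "Group1": 8, "Group2": 1}


def test_rows_preserve_printed_values(rows):
    by = {r.virus: r for r in rows}
    assert by["PEMV2"].pk1_pair == ("CCAAA", "UUUGG")
    assert by["AgULV"].pk1_pair is None
    assert by["IxYMoV2"].psi1 == "?"  # unknown is a distinct state
    assert by["IxYMoV2"].tss == "?"
    assert by["ETBTV"].slippery_raw == "*AAAUUUU* UAG"  # printed space kept
    assert by["GULV4"].ca_placement_uncertain is True
    assert by["GULV4"].ca_placement == "HC_base"
    assert by["CY1"].cite_type == "ISS-like"


def test_all_expected_tallies_pass(rows):
    report = tally_report(rows)
    assert (report["status"] == "PASS").all()
    # tallies are auditable: contributing rows are listed and consistent
    for _, rec in report.iterrows():
        assert rec["count"] == len([v for v in rec["viruses"].split(",") if v])


def test_tally_returns_contributing_rows(rows):
    count, viruses = tally(rows, "UV", lambda r: r.pk1_pair is not None)
    assert count == 15 and len(viruses) == 15 and "PEMV2" in viruses
    count, viruses = tally(rows, "UV", lambda r: False)
    assert count == 0 and viruses == []
    # "-like" classes are counted apart from their namesakes
    assert tally(rows, "UV", lambda r: r.cite_type == "UTE")[0] == 5
    assert tally(rows, "UV", lambda r: r.cite_type == "UTE-like")[0] == 1


def test_slippery_offsets(rows):
    offsets = fixture_slippery_offsets(rows)
    assert offsets["PEMV2"] == 3
    assert offsets["CY1"] == 12
    assert offsets["GULV2"] == 0


def test_duplex_audit(rows):
    audit = fixture_duplex_audit(rows)
    anomalous = set(map(tuple, audit[audit.anomalous][["virus", "kind"]].values))
    # the two printed pairs that do not read as antiparallel duplexes
    assert anomalous == {("PMMoV", "PK2"), ("OPMV", "PK1")}
    pm = audit[(audit.virus == "PMMoV") & (audit.kind == "PK2")].iloc[0]
    assert pm.same_direction_only  # valid only as a parallel complement
    key = audit.set_index(["virus", "kind"])
    for virus, kind in (("PEMV2", "PK1"), ("WSVA", "PK1"), ("PEMV2", "LDI"), ("AgULV", "LDI")):
        row = key.loc[(virus, kind)]
        assert bool(row["antiparallel_wc"]) and row["gu_pairs"] == 0


def test_checksum_guard(monkeypatch):
    monkeypatch.setitem(tables.CHECKSUMS, "translation_elements.tsv", "0" * 64)
    with pytest.raises(FixtureError, match="checksum"):
        load_tables()
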