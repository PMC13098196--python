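import pytest

from umbrannot.fold import Hairpin
from umbrannot.motifs import MotifHit
from umbrannot.recoding import classify_ca_placement
from umbrannot.synth import GenomeDesign, generate_genome
from umbrannot.annotate import annotate_genome
from umbrannot.tables import fixture_slippery_offsets, load_tables


def test_full_recoding_site_recovered(uv_genome, uv_report):
    record, manifest = uv_genome
    rec = uv_report.recoding
    assert rec.slippery is not None
    assert (rec.slippery.start, rec.slippery.end) == manifest.get("slippery_site").interval
    assert rec.slippery_offset == 3
    assert (rec.ca.start, rec.ca.end) == manifest.get("CA").interval
    assert rec.ca_placement == "HC_base"
    for kind, hp in (("HA", rec.ha), ("FSE", rec.fse), ("HB", rec.hb), ("HC", rec.hc)):
        planted = manifest.get(kind)
        inter = min(hp.end, planted.end) - max(hp.start, planted.start)
        assert inter >= planted.end - planted.start - 3, kind
    assert rec.pk1 is not None and rec.pk2 is not None
    assert rec.fse_ldi is not None and rec.fse_ldi_source == "internal_loop"
    assert all(rec.conformance.values())


def test_element_order_invariant(uv_report):
    rec = uv_report.recoding
    marks = [
        rec.ha.start,
        rec.fse.start,
        rec.hb.start,
        rec.pk1.partner_interval[0],
        rec.ca.start,
    ]
    assert marks == sorted(marks)
    assert rec.ca.start <= rec.hc.start
    assert rec.hc.start < rec.pk2.partner_interval[0]
    assert not rec.notes  # no order violations recorded


def test_absent_ca_reported_absent():
    record, _ = generate_genome(GenomeDesign(plant_ca=False, plant_pk2=False), seed=5)
    report = annotate_genome(record)
    rec = report.recoding
    assert rec.ca is None
    assert rec.conformance["CA"] is False
    assert rec.ca_placement == "none"
    # the rest of the site is still assembled
    assert rec.conformance["slippery"] and rec.conformance["FSE"]


def _hairpin_from_arms(start, arm, loop):
    n = len(arm)
    pairs = [(start + k, start + 2 * n + len(loop) - 1 - k) for k in range(n)]
    return Hairpin(
        start=start,
        end=start + 2 * n + len(loop),
        stem_pairs=pairs,
        apical_loop=(start + n, start + n + len(loop)),
        score=n,
    )


def test_classify_ca_placement_cases():
    # CA's final 4 nt open HC's stem
    ca = MotifHit("CA", 100, 112, "CACAACAACUCC")
    hc = _hairpin_from_arms(108, "CUCCGGCAGC", "AAUUC")
    assert classify_ca_placement(ca, hc) == "HC_base"
    # CA inside HC's apical loop
    hc2 = _hairpin_from_arms(90, "GGCAGC", "X" * 30)
    hc2.apical_loop = (96, 126)
    assert classify_ca_placement(ca, hc2) == "in_HC"
    # CA far from HC
    hc3 = _hairpin_from_arms(300, "GGCAGC", "AAUUC")
    assert classify_ca_placement(ca, hc3) == "none"
    assert classify_ca_placement(None, hc3) == "none"
    assert classify_ca_placement(ca, None) == "none"


def test_fixture_offsets_follow_the_printed_pattern():
    """Detector offsets on the printed strings: umbravirus offsets are 0
    or 3 nt, the Group 2 representative sits 12 nt upstream; the one
    outlier string is surfaced, not silently reconciled."""
    rows = load_tables()
    offsets = fixture_slippery_offsets(rows)
    assert offsets["PEMV2"] == 3
    assert offsets["CY1"] == 12
    for r in rows:
        if r.group == "UV" and r.virus != "PicUV":
            assert offsets[r.virus] in (0, 3), r.virus
        if r.group == "Group1":
            assert offsets[r.virus] in (0, 3), r.virus
    # the PicUV string as printed implies a 4-nt gap — flagged by value
    assert offsets["PicUV"] == 4
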