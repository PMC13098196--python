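import pytest

from umbrannot.annotate import annotate_genome
from umbrannot.cite import classify_cite, find_cas, find_cite_ldi
from umbrannot.config import RunConfig
from umbrannot.motifs import duplex_check, revcomp
from umbrannot.synth import (
    AUX_ARM,
    CITE_LDI_LOOP,
    GenomeDesign,
    TSS_H1_ARM,
    TSS_H1_LOOP,
    TSS_H2_ARM,
    TSS_H2_LOOP,
    TSS_H3_ARM,
    generate_genome,
)
from umbrannot.termini import validate_3prime, validate_5prime


def test_validate_5prime_gate():
    assert validate_5prime("GGAUUUU" + "A" * 60).truncated_call is False
    # single leading G: non-canonical, truncated
    assert validate_5prime("GAUUUU" + "A" * 60).truncated_call is True
    # consensus starting beyond the gate does not rescue the call
    assert validate_5prime("A" * 12 + "GGAUUUU" + "A" * 40, gate_n=10).truncated_call is True


def test_validate_3prime_planted_and_truncation_flip(uv_genome, config):
    record, manifest = uv_genome
    seq = record.sequence
    report = validate_3prime(seq, config)
    assert report.truncated_call is False
    assert report.terminal_motif == "GCCC"
    assert report.psi1_pairs >= 4
    h5_planted = manifest.get("H5")
    assert report.h5 is not None and report.h5.start <= h5_planted.start + 3
    assert report.pr is not None
    # deleting terminal cytidylates flips the truncation call ...
    assert validate_3prime(seq[:-1], config).truncated_call is True
    assert validate_3prime(seq[:-2], config).truncated_call is True
    # ... and restoring the canonical three cytidylates flips it back
    assert validate_3prime(seq[:-2] + "CC", config).truncated_call is False


@pytest.mark.parametrize("conf", ["UV_apical", "tombus_internal", "GULV_asymmetric"])
def test_h5_conformations(conf):
    record, _ = generate_genome(GenomeDesign(h5_conformation=conf), seed=31)
    report = validate_3prime(record.sequence)
    assert report.h5_conformation == conf
    assert report.truncated_call is False


def test_find_cas_and_kl(uv_genome, uv_report, config):
    record, manifest = uv_genome
    call = uv_report.cas
    assert call.cas is not None
    planted = manifest.get("CAS")
    assert call.cas.start <= planted.start + 2 and call.cas.end >= planted.end - 2
    assert call.kl_pair is not None
    h1, h2, duplex = call.kl_pair
    assert duplex.length >= 4
    assert duplex_check(duplex.duplex_a, duplex.duplex_b)[0]


@pytest.mark.parametrize("archetype", ["TSS", "ISS", "ISS_branched", "UTE"])
def test_classify_cite_archetypes(archetype):
    record, manifest = generate_genome(GenomeDesign(cite_archetype=archetype), seed=41)
    report = annotate_genome(record)
    assert report.cite.cite_type == archetype
    if archetype == "ISS_branched":
        assert report.cite.branched and report.cite.gnra_capped
    if archetype == "ISS":
        assert not report.cite.branched
    # the CITE<->5' interaction resolves to the planted 6-pair duplex
    assert report.cite_ldi is not None and report.cite_ldi.length >= 6
    ok, _, gu = duplex_check(report.cite_ldi.duplex_a, report.cite_ldi.duplex_b)
    assert ok and gu == 0


def test_tss_tolerates_one_nt_spacer():
    """The adenylate-separated variant: one extra residue between the
    two 5' hairpins still classifies as a T-shaped structure."""
    config = RunConfig()
    h1 = TSS_H1_ARM + TSS_H1_LOOP + revcomp(TSS_H1_ARM)
    h2 = TSS_H2_ARM + TSS_H2_LOOP + revcomp(TSS_H2_ARM)
    h3 = TSS_H3_ARM + CITE_LDI_LOOP + revcomp(TSS_H3_ARM)
    accs = revcomp(TSS_H1_LOOP) + revcomp(TSS_H2_LOOP)
    for spacer in ("", "A"):
        seq = "GCAAUC" + h1 + spacer + h2 + "GCG" + h3 + accs + "CAAUCG"
        call = classify_cite(seq, (0, len(seq)), config)
        assert call.cite_type == "TSS", f"spacer={spacer!r}"
    # a clearly separated pair is no longer juxtaposed
    seq = "GCAAUC" + h1 + "AACAAACA" + h2 + "GCG" + h3 + accs + "CAAUCG"
    assert classify_cite(seq, (0, len(seq)), config).cite_type != "TSS"


def test_classify_cite_unknown_on_plain_sequence():
    call = classify_cite("AACC" * 30, (0, 120), RunConfig())
    assert call.cite_type == "unknown"


def test_bte_motif_classification():
    config = RunConfig()
    seq = "AACU" * 8 + config.signatures.bte_a_motif + "UCAA" * 8
    call = classify_cite(seq, (0, len(seq)), config)
    assert call.cite_type == "BTE_A"


def test_cite_ldi_uses_printed_interaction_chemistry():
    """The common GCCA/UGGC interaction chemistry: the planted CITE loop
    UUGGCC pairs the 5'-proximal hairpin loop GGCCAA in full."""
    record, _ = generate_genome(GenomeDesign(cite_archetype="ISS"), seed=43)
    report = annotate_genome(record)
    ldi = report.cite_ldi
    assert ldi is not None
    assert {ldi.duplex_a, ldi.duplex_b} == {"UUGGCC", "GGCCAA"}
    assert report.cite_ldi_context == "gRNA_5p"


def test_psi1_partner_pairs_terminal_motif(uv_report, uv_genome):
    record, _ = uv_genome
    t3 = uv_report.three_prime
    lo, hi = t3.psi1_partner
    partner = record.sequence[lo:hi]
    assert duplex_check(partner, t3.terminal_motif)[0]
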