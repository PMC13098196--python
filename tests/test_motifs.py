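import random
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umbrannot.motifs import (
    CCS_PATTERN,
    duplex_check,
    find_degenerate,
    find_longest_duplex,
    find_slippery,
    hamming,
    match_ccs,
    revcomp,
)

rna = st.text(alphabet="ACGU", min_size=1, max_size=60)


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("CCAAA", "UUUGG"),  # a pseudoknot duplex pair as printed for PEMV2
        ("GGCCAA", "UUGGCC"),  # the AgULV CITE<->5' interaction pair
        ("", ""),
    ],
)
def test_revcomp_examples(seq, expected):
    assert revcomp(seq) == expected


@given(rna)
@settings(max_examples=200, derandomize=True)
def test_revcomp_involution_and_duplex(seq):
    assert revcomp(revcomp(seq)) == seq
    ok, paired, gu = duplex_check(seq, revcomp(seq))
    assert ok and paired == len(seq) and gu == 0


@pytest.mark.parametrize(
    "a, b, expect_ok, expect_paired",
    [
        ("CCAAA", "UUUGG", True, 5),  # PEMV2 PK1
        ("GACGC", "GCGUC", True, 5),  # WSVA PK1
        ("AACA", "UUGU", False, 2),  # PMMoV PK2 as printed: antiparallel fails
        ("AUCG", "GCAU", False, 2),  # OPMV PK1 as printed: antiparallel fails
    ],
)
def test_duplex_check_printed_pairs(a, b, expect_ok, expect_paired):
    ok, paired, _ = duplex_check(a, b)
    assert ok is expect_ok
    assert paired == expect_paired


def test_duplex_check_gu_and_lengths():
    ok, paired, gu = duplex_check("GGG", "UCC", allow_gu=True)
    assert ok and gu == 1 and paired == 3
    assert duplex_check("GGG", "UCC")[0] is False
    assert duplex_check("AAA", "UU")[0] is False
    with pytest.raises(ValueError):
        duplex_check("", "A")


def test_match_ccs_examples():
    hits = match_ccs("GGAUUUU")
    assert hits and hits[0].start == 0 and hits[0].matched == "GGAUUUU"
    # a single leading G does not satisfy the consensus
    assert all(h.start != 0 for h in match_ccs("GAUUUU"))
    hits = match_ccs("CCGGGCUUUA")
    assert hits[0].start == 2 and hits[0].matched == "GGGCUUUA"  # greedy-longest


@given(st.text(alphabet="ACGU", min_size=5, max_size=200))
@settings(max_examples=150, derandomize=True)
def test_match_ccs_agrees_with_regex_scan(seq):
    expected = set()
    for start in range(len(seq)):
        m = CCS_PATTERN.match(seq, start)
        if m and m.start() == start:
            expected.add((m.start(), m.end()))
    got = {(h.start, h.end) for h in match_ccs(seq)}
    assert got == expected
    for h in match_ccs(seq):
        assert h.matched == seq[h.start : h.end]


def test_find_degenerate_examples():
    seq = "AAA" + "CACAACAACUCC" + "GGG"
    hits = find_degenerate(seq, "CACAACAACUCC", max_mismatch=2)
    assert hits[0].start == 3 and hits[0].mismatches == 0
    assert find_degenerate("CACAACAACUCG", "CACAACAACUCC", max_mismatch=0) == []
    with pytest.raises(ValueError):
        find_degenerate("ACGU", "ACG", max_mismatch=3)


@given(st.text(alphabet="ACGU", min_size=12, max_size=60), st.integers(0, 2))
@settings(max_examples=100, derandomize=True)
def test_find_degenerate_agrees_with_hamming_scan(seq, mm):
    consensus = "CACAACAACUCC"
    got = {(h.start, h.mismatches) for h in find_degenerate(seq, consensus, mm)}
    expected = set()
    for i in range(len(seq) - len(consensus) + 1):
        d = hamming(seq[i : i + len(consensus)], consensus)
        if d <= mm:
            expected.add((i, d))
    assert got == expected


@pytest.mark.parametrize(
    "printed, heptamer, offset",
    [
        ("GGAUUUUUGGUAG", "GGAUUUU", 3),  # PEMV2
        ("GGGUUUUCGCGAUUUGCAGUGA", "GGGUUUU", 12),  # CY1
        ("AAAUUUUUAG", "AAAUUUU", 0),  # ETBTV, printed space removed
        ("GGGAAACUAA", "GGGAAAC", 0),  # GULV2
    ],
)
def test_find_slippery_on_printed_strings(printed, heptamer, offset):
    hit = find_slippery(printed, len(printed) - 3)
    assert hit is not None
    found, got_offset = hit
    assert found.matched == heptamer
    assert got_offset == offset


def test_find_slippery_contract():
    with pytest.raises(ValueError, match="stop codon"):
        find_slippery("GGAUUUUUGGAAA", 10)
    # outside the gate: heptamer 25 nt upstream of the stop is not reported
    seq = "GGAUUUU" + "C" * 25 + "UAG"
    assert find_slippery(seq, len(seq) - 3, max_upstream=20) is None


def test_find_longest_duplex_prefers_longest_then_most_5prime():
    #            0123456789...
    seq = "CCAAAGGGGGUUUGGAAAUUUGG"
    call = find_longest_duplex(seq, (0, 5), (5, len(seq)), min_len=4)
    assert call.length == 5
    assert call.duplex_a == "CCAAA"
    assert call.region_b[0] == 10  # first (most-5') full-length partner
    assert find_longest_duplex("AAAA" + "CCCC", (0, 4), (4, 8), min_len=4) is None


@given(st.text(alphabet="ACGU", min_size=6, max_size=12), st.text(alphabet="ACGU", min_size=30, max_size=60))
@settings(max_examples=100, derandomize=True)
def test_find_longest_duplex_agrees_with_brute_force(loop, window):
    seq = loop + window
    call = find_longest_duplex(seq, (0, len(loop)), (len(loop), len(seq)), min_len=3, max_len=8)
    # brute force over all substring pairs
    best = None
    for L in range(min(8, len(loop)), 2, -1):
        for j in range(len(window) - L + 1):
            for i in range(len(loop) - L + 1):
                if duplex_check(loop[i : i + L], window[j : j + L])[0]:
                    cand = (L, -j, -i)
                    if best is None or cand > best:
                        best = cand
        if best:
            break
    if best is None:
        assert call is None
    else:
        assert call.length == best[0]
        assert call.region_b[0] == len(loop) - best[1]
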