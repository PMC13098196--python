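import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umbrannot.fold import (
    FoldParams,
    best_hairpin_pair_count,
    dot_bracket,
    find_hairpins,
    find_pseudoknot,
    max_nested_pairs,
)
from umbrannot.motifs import duplex_check, revcomp
from umbrannot.reference import (
    exhaustive_best_hairpin_pairs,
    exhaustive_max_nested_pairs,
    validate_hairpin,
)


def test_designed_hairpin_recovered_rank_one():
    arm = "GGCAGCGC"
    seq = "AAUA" + arm + "CUAG" + revcomp(arm) + "AUAA"
    hits = find_hairpins(seq)
    assert hits
    top = hits[0]
    assert top.pair_count == len(arm) == top.score
    assert seq[top.apical_loop[0] : top.apical_loop[1]] == "CUAG"


def test_no_hairpin_in_unpairable_sequence():
    assert find_hairpins("AAAAAAAAAAAAAAAAA") == []
    assert find_hairpins("ACGU") == []  # region too short


def test_hairpins_respect_constraints():
    rng = random.Random(3)
    params = FoldParams()
    for _ in range(20):
        seq = "".join(rng.choice("ACGU") for _ in range(120))
        for hp in find_hairpins(seq, params=params):
            assert validate_hairpin(seq, hp, params)


@pytest.mark.parametrize("trial", range(30))
def test_best_pair_count_matches_exhaustive_enumeration(trial):
    """On short windows the constrained hairpin DP reaches exactly the
    pair count found by enumerating every admissible stem chain."""
    rng = random.Random(trial)
    n = rng.randint(10, 30)
    seq = "".join(rng.choice("ACGU") for _ in range(n))
    assert best_hairpin_pair_count(seq) == exhaustive_best_hairpin_pairs(seq)


@pytest.mark.parametrize("trial", range(30))
def test_nussinov_matches_exhaustive_enumeration(trial):
    rng = random.Random(1000 + trial)
    n = rng.randint(8, 30)
    seq = "".join(rng.choice("ACGU") for _ in range(n))
    assert max_nested_pairs(seq) == exhaustive_max_nested_pairs(seq)


def test_find_pseudoknot_planted_pair():
    loop = "CCAAA"
    seq = "GGGG" + loop + "CCCCAGAG" + "UUUGG" + "AAAA"
    pk = find_pseudoknot(seq, (4, 9), search_from=9, search_window=50, min_len=4, max_len=8)
    assert pk is not None
    assert pk.duplex.duplex_a == "CCAAA"
    assert pk.partner_interval == (17, 22)
    assert duplex_check(pk.duplex.duplex_a, pk.duplex.duplex_b)[0]


def test_find_pseudoknot_absent():
    seq = "GGGG" + "AAAA" + "CCCC"
    assert find_pseudoknot(seq, (4, 8), search_from=8, min_len=4) is None


@given(st.text(alphabet="ACGU", min_size=40, max_size=100))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_pseudoknot_call_passes_duplex_check(seq):
    pk = find_pseudoknot(seq, (0, 10), search_from=10, search_window=50, min_len=4, max_len=8)
    if pk is not None:
        ok, paired, gu = duplex_check(pk.duplex.duplex_a, pk.duplex.duplex_b)
        assert ok and gu == 0 and 4 <= paired <= 8


def test_deterministic_output():
    rng = random.Random(9)
    seq = "".join(rng.choice("ACGU") for _ in range(200))
    a = find_hairpins(seq)
    b = find_hairpins(seq)
    assert [(h.interval, tuple(h.stem_pairs)) for h in a] == [
        (h.interval, tuple(h.stem_pairs)) for h in b
    ]


def test_dot_bracket_layers():
    arm = "GGGG"
    seq = arm + "CCAAA" + revcomp(arm) + "AGAG" + "UUUGG"
    hps = find_hairpins(seq, params=FoldParams(min_stem=3))
    hp = hps[0]
    pk = find_pseudoknot(seq, hp.apical_loop, search_from=hp.end, min_len=4)
    db = dot_bracket(len(seq), [hp], [pk] if pk else [])
    assert db.count("(") == db.count(")") == hp.pair_count
    if pk:
        assert "[" in db and "]" in db
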