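import random

import pytest

from umbrannot.sequence_io import (
    Annotation,
    FEATURE_TYPES,
    GenomeRecord,
    SequenceError,
    normalize_rna,
    read_fasta,
    read_gff3,
    write_fasta,
    write_gff3,
)


@pytest.mark.parametrize(
    "raw, expected",
    [("acgt", "ACGU"), ("GCCC", "GCCC"), ("AcGuT", "ACGUU")],
)
def test_normalize_rna(raw, expected):
    assert normalize_rna(raw) == expected


def test_normalize_rna_rejects_with_offset():
    with pytest.raises(SequenceError, match="offset 2"):
        normalize_rna("GC-C")
    with pytest.raises(SequenceError):
        normalize_rna("")
    with pytest.raises(SequenceError, match="N"):
        normalize_rna("ACN")


def test_read_fasta_normalizes_and_preserves_order(tmp_path):
    path = tmp_path / "in.fa"
    path.write_text(">x\nACGT\n>y second\nggau\n")
    records = read_fasta(path)
    assert [r.id for r in records] == ["x", "y"]
    assert records[0].sequence == "ACGU"
    assert records[0].length == 4
    assert records[1].sequence == "GGAU"


def test_read_fasta_errors(tmp_path):
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(SequenceError, match="no records"):
        read_fasta(empty)
    bad = tmp_path / "bad.fa"
    bad.write_text(">x\nACN\n")
    with pytest.raises(SequenceError, match="x"):
        read_fasta(bad)


def test_fasta_round_trip(tmp_path):
    records = [
        GenomeRecord("a", "ACGU" * 30),
        GenomeRecord("b", "GGCCAAUU"),
    ]
    path = tmp_path / "out.fa"
    write_fasta(records, path)
    back = read_fasta(path)
    assert [(r.id, r.sequence) for r in back] == [(r.id, r.sequence) for r in records]


def test_gff3_round_trip_random_annotations(tmp_path):
    rng = random.Random(0)
    genome = GenomeRecord("g1", "".join(rng.choice("ACGU") for _ in range(500)))
    types = sorted(FEATURE_TYPES)
    annotations = []
    for _ in range(50):
        start = rng.randrange(0, 490)
        end = rng.randrange(start + 1, min(start + 40, 500))
        annotations.append(
            Annotation(
                "g1",
                rng.choice(types),
                start,
                end,
                {"note": "a;b=c, d%", "rank": str(rng.randrange(10))},
            )
        )
    path = tmp_path / "x.gff3"
    write_gff3(annotations, genome, path)
    assert path.read_text().startswith("##gff-version 3")
    back = read_gff3(path)
    key = lambda a: (a.start, a.end, a.feature_type, tuple(sorted(a.attributes.items())))
    assert sorted(map(key, back)) == sorted(map(key, annotations))
    # 1-based inclusive externally: length is preserved through the conversion
    for a in back:
        assert a.end - a.start == a.length


def test_gff3_empty_and_out_of_range(tmp_path):
    genome = GenomeRecord("g1", "ACGUACGUAC")
    path = tmp_path / "x.gff3"
    write_gff3([], genome, path)
    lines = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
    assert lines == []
    bad = Annotation("g1", "CCS", 5, 20)
    with pytest.raises(SequenceError, match="CCS"):
        write_gff3([bad], genome, path)
    other = Annotation("g2", "CCS", 0, 4)
    with pytest.raises(SequenceError, match="g2"):
        write_gff3([other], genome, path)


def test_annotation_invariants():
    with pytest.raises(SequenceError):
        Annotation("g", "not_a_type", 0, 5)
    with pytest.raises(SequenceError):
        Annotation("g", "CCS", 5, 5)
    with pytest.raises(SequenceError):
        GenomeRecord("g", "ACGT")  # T must be normalized before construction
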