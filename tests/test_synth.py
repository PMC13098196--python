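import collections

import pytest

from umbrannot.annotate import annotate_genome, report_annotations
from umbrannot.sequence_io import Annotation
from umbrannot.synth import (
    GenomeDesign,
    dinucleotide_shuffle,
    generate_genome,
    recovery_score,
)


def test_determinism_byte_identical():
    a, ma = generate_genome(GenomeDesign(), seed=1)
    b, mb = generate_genome(GenomeDesign(), seed=1)
    assert a.sequence == b.sequence
    assert [e.interval for e in ma.planted] == [e.interval for e in mb.planted]
    c, _ = generate_genome(GenomeDesign(), seed=2)
    assert c.sequence != a.sequence


def test_planted_sequences_occur_verbatim(uv_genome):
    record, manifest = uv_genome
    for el in manifest.planted:
        if el.seq:
            assert record.sequence[el.start : el.end] == el.seq, el.kind


def test_manifest_roundtrips_to_json(uv_genome):
    import json

    _, manifest = uv_genome
    payload = json.loads(manifest.to_json())
    assert payload["genome_id"] == manifest.genome_id
    assert len(payload["planted"]) == len(manifest.planted)


def test_recovery_score_arithmetic(uv_genome):
    _, manifest = uv_genome
    gid = manifest.genome_id
    planted_ha = manifest.get("HA")
    anns = [Annotation(gid, "HA", planted_ha.start, planted_ha.end)]
    score = recovery_score(manifest, anns, tolerance=0)
    assert score["HA"]["recall"] == 1.0 and score["HA"]["precision"] == 1.0
    # removing the single annotation of a kind drops recall to 0 for it
    score2 = recovery_score(manifest, [], tolerance=0)
    assert score2["HA"]["recall"] == 0.0
    assert score2["HA"]["misses"] == [planted_ha.interval]


def test_dinucleotide_shuffle_preserves_composition(uv_genome):
    record, _ = uv_genome
    seq = record.sequence

    def dinucs(s):
        return collections.Counter(s[i : i + 2] for i in range(len(s) - 1))

    shuffled = dinucleotide_shuffle(seq, seed=3)
    assert len(shuffled) == len(seq)
    assert shuffled != seq
    assert dinucs(shuffled) == dinucs(seq)
    assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]


def test_shuffled_control_destroys_structure_recovery(uv_genome):
    """Negative control: after a dinucleotide shuffle the planted
    structural elements are gone, so structure-dependent recalls drop
    to zero."""
    record, manifest = uv_genome
    shuffled = record.__class__(id=record.id, sequence=dinucleotide_shuffle(record.sequence, 5))
    report = annotate_genome(shuffled)
    anns = report_annotations(report)
    score = recovery_score(manifest, anns, tolerance=3)
    for kind in ("FSE", "HB", "HC", "CAS", "H5", "Pr"):
        assert score[kind]["recall"] == 0.0, kind


def test_generator_logs_attempts(uv_genome):
    _, manifest = uv_genome
    assert manifest.attempts >= 1
    assert len(manifest.notes) == manifest.attempts - 1
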