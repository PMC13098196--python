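"""Reading, writing and normalising viral genome sequences and annotations.

Umbravirus and umbra-like virus genomes are single-component, plus-sense
RNA molecules.  Everything downstream of this module works on an
RNA-alphabet string (A/C/G/U) with 0-based half-open coordinates
internally; all *external* reporting (GFF3, JSON, TSV) uses 1-based
inclusive coordinates, converted in exactly one place (:func:`write_gff3`
and the report writers).  Only the "+" strand is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

#: Controlled vocabulary for annotation feature types.
FEATURE_TYPES = frozenset(
    {
        "CCS",
        "ORF",
        "slippery_site",
        "HA",
        "FSE",
        "HB",
        "HC",
        "PK1",
        "PK2",
        "CA",
        "H5",
        "Pr",
        "PSI1",
        "CAS",
        "KL_hairpin",
        "CITE",
        "LDI",
    }
)


class SequenceError(ValueError):
    """Raised for malformed sequences or annotation coordinates."""


@dataclass(frozen=True)
class GenomeRecord:
    """A single viral genome: id, normalised RNA sequence, description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise SequenceError(
                f"genome {self.id!r}: non-RNA residues {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Annotation:
    """A located feature on a genome.

    ``start``/``end`` are 0-based half-open internally.  ``attributes``
    holds free-form key/value evidence.
    """

    genome_id: str
    feature_type: str
    start: int
    end: int
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise SequenceError(
                f"feature_type {self.feature_type!r} not in controlled vocabulary"
            )
        if not (0 <= self.start < self.end):
            raise SequenceError(
                f"bad interval [{self.start}, {self.end}) for {self.feature_type}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_rna(raw: str) -> str:
    """Uppercase, convert T->U, and reject anything outside A/C/G/U/T.

    IUPAC ambiguity codes are rejected rather than expanded: the genomes
    this package targets are unambiguous single-molecule sequences.
    """
    if not raw:
        raise SequenceError("empty sequence")
    up = raw.upper().replace("T", "U")
    for offset, ch in enumerate(up):
        if ch not in RNA_ALPHABET:
            raise SequenceError(f"disallowed character {ch!r} at offset {offset}")
    return up


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into normalised :class:`GenomeRecord` objects.

    Order is preserved.  An empty file raises ``SequenceError("no
    records")``; a non-ACGUT residue raises an error naming the residue,
    its offset and the record.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = normalize_rna(str(rec.seq))
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
        records.append(GenomeRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise SequenceError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _escape_gff3(value: str) -> str:
    return (
        value.replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace("&", "%26")
        .replace(",", "%2C")
    )


def write_gff3(annotations: Iterable[Annotation], genome: GenomeRecord, path: str | Path) -> None:
    """Write annotations as GFF3 (1-based inclusive, strand "+").

    Refuses to write any feature whose coordinates fall outside the
    genome or that references a different genome id.
    """
    annotations = list(annotations)
    for ann in annotations:
        if ann.genome_id != genome.id:
            raise SequenceError(
                f"feature {ann.feature_type} references genome {ann.genome_id!r}, "
                f"not {genome.id!r}"
            )
        if ann.end > genome.length:
            raise SequenceError(
                f"feature {ann.feature_type} [{ann.start}, {ann.end}) outside "
                f"genome of length {genome.length}"
            )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for ann in sorted(annotations, key=lambda a: (a.start, a.end, a.feature_type)):
            attrs = ";".join(
                f"{_escape_gff3(str(k))}={_escape_gff3(str(v))}"
                for k, v in ann.attributes.items()
            )
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "umbrannot",
                        ann.feature_type,
                        str(ann.start + 1),  # 0-based half-open -> 1-based inclusive
                        str(ann.end),
                        ".",
                        "+",
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Annotation]:
    """Read a GFF3 file back into annotations (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    annotations: list[Annotation] = []
    for feat in db.all_features(order_by=("start", "end", "featuretype")):
        attributes = {k: v[0] if len(v) == 1 else ",".join(v) for k, v in feat.attributes.items()}
        annotations.append(
            Annotation(
                genome_id=feat.seqid,
                feature_type=feat.featuretype,
                start=feat.start - 1,
                end=feat.end,
                attributes=attributes,
            )
        )
    return annotations
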