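"""Curated per-virus element tables and the tallies derived from them.

The package ships two literature-derived tables covering the 17
umbraviruses, 8 Group 1 umbra-like viruses, and the Group 2
representative CY1:

* ``translation_elements.tsv`` — psi1 presence, 3'-terminal TSS
  presence, 3'CITE class, the CITE<->5' LDI pair, and CAS / CAS+KL
  presence, plus whether the database entry is described as full length
  (FL) or partial (PS);
* ``recoding_elements.tsv`` — the slippery-site string as printed
  (slippery heptamer marked ``*...*``, the ORF1 stop codon at the end,
  a space preserving heptamer/stop adjacency), the PK1 and PK2 duplex
  pairs, and the CA-consensus placement relative to hairpin HC.

Printed strings are preserved verbatim — no orientation "fixes" — and
"?" is a distinct unknown state, never coerced to "no".  Loading is
checksummed; tallies return the contributing rows so every count is
auditable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import pandas as pd

from .motifs import DEFAULT_SLIPPERY_MOTIFS, duplex_check, find_slippery

DATA_DIR = Path(__file__).parent / "data"

CHECKSUMS = {
    "translation_elements.tsv": "3660d6f78be2b39af3360fa23c134d96bde90d28de58c19ea0cdbaa60ec356c2",
    "recoding_elements.tsv": "9b8a9ba87f96d15595dbabc32a0190c2df0f1e7f8f8b4a78c8d6fb9148de7e85",
}


class FixtureError(RuntimeError):
    pass


@dataclass
class ElementTableRow:
    """One virus's curated element annotations (both tables merged)."""

    virus: str
    group: str  # UV | Group1 | Group2
    psi1: str  # yes | no | ?
    tss: str  # yes | no | ?
    cite_type: str
    ldi_pair: tuple[str, str] | None
    cas: str
    cas_kl: str
    entry_status: str  # FL | PS
    slippery_raw: str
    slippery_parsed: str  # markup and spaces stripped
    pk1_pair: tuple[str, str] | None
    pk2_pair: tuple[str, str] | None
    ca_placement_raw: str  # HC base | In HC | HC base? | None
    ca_placement: str  # HC_base | in_HC | none
    ca_placement_uncertain: bool


def _read_checked(name: str) -> pd.DataFrame:
    path = DATA_DIR / name
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != CHECKSUMS[name]:
        raise FixtureError(f"checksum mismatch for {name}: {digest}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _pair(cell: str) -> tuple[str, str] | None:
    if cell in ("None", "?", ""):
        return None
    a, _, b = cell.partition("-")
    return (a, b)


def load_tables() -> list[ElementTableRow]:
    """Load and merge both tables: 17 UV + 8 Group 1 + 1 Group 2 rows."""
    t1 = _read_checked("translation_elements.tsv")
    t2 = _read_checked("recoding_elements.tsv").set_index("virus")
    rows: list[ElementTableRow] = []
    for _, r in t1.iterrows():
        r2 = t2.loc[r["virus"]]
        raw = r2["slippery_raw"]
        placement_raw = r2["ca_placement"]
        placement = {
            "HC base": "HC_base",
            "HC base?": "HC_base",
            "In HC": "in_HC",
            "None": "none",
        }[placement_raw]
        rows.append(
            ElementTableRow(
                virus=r["virus"],
                group=r["group"],
                psi1=r["psi1"],
                tss=r["tss"],
                cite_type=r["cite_type"],
                ldi_pair=_pair(r["ldi_pair"]),
                cas=r["cas"],
                cas_kl=r["cas_kl"],
                entry_status=r["entry_status"],
                slippery_raw=raw,
                slippery_parsed=raw.replace("*", "").replace(" ", ""),
                pk1_pair=_pair(r2["pk1_pair"]),
                pk2_pair=_pair(r2["pk2_pair"]),
                ca_placement_raw=placement_raw,
                ca_placement=placement,
                ca_placement_uncertain=placement_raw.endswith("?"),
            )
        )
    counts = {g: sum(1 for x in rows if x.group == g) for g in ("UV", "Group1", "Group2")}
    if counts != {"UV": 17, "Group1": 8, "Group2": 1}:
        raise FixtureError(f"unexpected row counts {counts}")
    return rows


def tally(
    rows: list[ElementTableRow],
    group: str | None,
    predicate: Callable[[ElementTableRow], bool],
) -> tuple[int, list[str]]:
    """Count rows in a group satisfying a predicate; returns the count
    and the contributing virus names (auditable)."""
    hits = [r.virus for r in rows if (group is None or r.group == group) and predicate(r)]
    return len(hits), hits


def fixture_slippery_offsets(rows: list[ElementTableRow]) -> dict[str, int | None]:
    """Slippery offset per virus, computed by running the slippery-site
    detector on the printed string (stop codon = final three residues).

    Rows whose string cannot be resolved by the detector come back as
    ``None`` rather than being dropped.
    """
    offsets: dict[str, int | None] = {}
    for r in rows:
        s = r.slippery_parsed
        hit = find_slippery(
            s, len(s) - 3, motif_set=DEFAULT_SLIPPERY_MOTIFS, max_upstream=20
        )
        offsets[r.virus] = hit[1] if hit else None
    return offsets


def fixture_duplex_audit(rows: list[ElementTableRow]) -> pd.DataFrame:
    """Audit every printed duplex pair (PK1, PK2, CITE LDI).

    For each pair, records whether the two printed strings (both read
    5'->3') form an antiparallel Watson-Crick duplex, an antiparallel
    duplex once G:U wobble is allowed, or only a same-direction
    (parallel) complement — printed orientations are not always
    consistent, so anomalies are flagged rather than silently fixed.
    """
    records = []
    for r in rows:
        for kind, pair in (("PK1", r.pk1_pair), ("PK2", r.pk2_pair), ("LDI", r.ldi_pair)):
            if pair is None:
                continue
            a, b = pair
            wc, _, _ = duplex_check(a, b) if len(a) == len(b) else (False, 0, 0)
            gu, _, n_gu = duplex_check(a, b, allow_gu=True) if len(a) == len(b) else (False, 0, 0)
            same_dir = len(a) == len(b) and duplex_check(a, b[::-1])[0]
            records.append(
                {
                    "virus": r.virus,
                    "group": r.group,
                    "kind": kind,
                    "pair": f"{a}-{b}",
                    "length": len(a),
                    "antiparallel_wc": wc,
                    "antiparallel_gu": gu and not wc,
                    "gu_pairs": n_gu if gu else 0,
                    "same_direction_only": (not gu) and same_dir,
                    "anomalous": not wc,
                }
            )
    return pd.DataFrame.from_records(records)


#: The printed counts the tables reproduce, as (name, group, predicate,
#: expected) — used by the tally report and the acceptance checks.
EXPECTED_TALLIES: list[tuple[str, str, Callable[[ElementTableRow], bool], int]] = [
    ("uv_pk1", "UV", lambda r: r.pk1_pair is not None, 15),
    ("uv_ca_hc_base", "UV", lambda r: r.ca_placement == "HC_base", 14),
    (
        "uv_hc_base_ca_with_pk2",
        "UV",
        lambda r: r.ca_placement == "HC_base" and r.pk2_pair is not None,
        10,
    ),
    ("group1_pk1", "Group1", lambda r: r.pk1_pair is not None, 7),
    ("group1_pk2", "Group1", lambda r: r.pk2_pair is not None, 2),
    ("uv_tss", "UV", lambda r: r.tss == "yes", 13),
    ("uv_cas_kl", "UV", lambda r: r.cas_kl == "yes", 13),
    ("uv_bte", "UV", lambda r: r.cite_type in ("BTE-A", "BTE-B"), 9),
    ("uv_ute", "UV", lambda r: r.cite_type == "UTE", 5),
    ("group1_iss", "Group1", lambda r: r.cite_type == "ISS", 7),
]


def tally_report(rows: list[ElementTableRow] | None = None) -> pd.DataFrame:
    """Every expected tally with its computed count, contributing rows,
    and PASS/FAIL status."""
    if rows is None:
        rows = load_tables()
    records = []
    for name, group, predicate, expected in EXPECTED_TALLIES:
        count, viruses = tally(rows, group, predicate)
        records.append(
            {
                "tally": name,
                "group": group,
                "count": count,
                "expected": expected,
                "status": "PASS" if count == expected else "FAIL",
                "viruses": ",".join(viruses),
            }
        )
    return pd.DataFrame.from_records(records)
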