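"""Degenerate consensus motif search and antiparallel duplex testing.

Houses the sequence-level primitives the annotators are built on:

* the carmovirus consensus sequence (CCS), ``G{2,3}(A|U|C)(A|U){3,8}``,
  which marks genomic and subgenomic RNA 5' starts;
* the CA consensus ``CACAACAACUCC`` found near -1 frameshift recoding
  sites, matched with a configurable Hamming-mismatch allowance;
* ribosome slippery heptamers (e.g. ``GGAUUUU``) located a small number
  of nucleotides upstream of the ORF1 termination codon;
* antiparallel Watson-Crick duplex checking used for pseudoknots,
  kissing loops and long-distance RNA:RNA interactions (LDIs).

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: Watson-Crick pairs (canonical).
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
#: Wobble pairs, counted only when explicitly enabled.
GU_PAIRS = frozenset({("G", "U"), ("U", "G")})

#: CCS consensus: two or three G, one A/U/C, then a run of 3-8 A/U.
CCS_PATTERN = re.compile(r"G{2,3}[AUC][AU]{3,8}")

#: CA consensus near the recoding site.
CA_CONSENSUS = "CACAACAACUCC"

#: Slippery heptamers observed across umbraviruses and umbra-like
#: viruses.  The literature gives instances rather than a closed
#: formula, so the set is extensible via configuration.
DEFAULT_SLIPPERY_MOTIFS = ("GGAUUUU", "GGGUUUU", "AAAUUUU", "GGGAAAC", "GGGUUUC")

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})


@dataclass(frozen=True)
class MotifHit:
    """A located motif match.  ``matched`` is the genome substring."""

    motif_name: str
    start: int
    end: int
    matched: str
    mismatches: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LdiCall:
    """An antiparallel duplex between two genome intervals.

    ``duplex_a``/``duplex_b`` are both given 5'->3'.  When ``gu_pairs``
    is zero, ``duplex_b`` is exactly the reverse complement of
    ``duplex_a``.
    """

    region_a: tuple[int, int]
    region_b: tuple[int, int]
    duplex_a: str
    duplex_b: str
    length: int
    gu_pairs: int = 0


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (A<->U, G<->C)."""
    return seq.translate(COMPLEMENT)[::-1]


def duplex_check(a: str, b: str, allow_gu: bool = False) -> tuple[bool, int, int]:
    """Test whether two 5'->3' strings form a full antiparallel duplex.

    Returns ``(is_duplex, paired, gu_pairs)``.  ``is_duplex`` is true iff
    the strings have equal length and every position ``a[i] : b[n-1-i]``
    is a Watson-Crick pair (G:U counted as paired only with
    ``allow_gu``).  ``paired`` is the number of positions paired under
    the setting; for a failing duplex it counts the positions that do
    pair.
    """
    if not a or not b:
        raise ValueError("duplex_check requires two non-empty strings")
    if len(a) != len(b):
        return False, 0, 0
    n = len(a)
    paired = 0
    gu = 0
    ok = True
    for i in range(n):
        pair = (a[i], b[n - 1 - i])
        if pair in WC_PAIRS:
            paired += 1
        elif allow_gu and pair in GU_PAIRS:
            paired += 1
            gu += 1
        else:
            ok = False
    return ok, paired, gu


def pairs_wc(x: str, y: str, allow_gu: bool = False) -> bool:
    """Whether two single residues form an allowed pair."""
    p = (x, y)
    return p in WC_PAIRS or (allow_gu and p in GU_PAIRS)


def match_ccs(
    sequence: str, window: tuple[int, int] | None = None, motif_name: str = "CCS"
) -> list[MotifHit]:
    """Find carmovirus consensus sequences within a window.

    Matching is greedy-longest at each start position; overlapping hits
    at distinct starts are all reported, left to right.  The caller
    disambiguates (e.g. the 5'-terminal gate keeps the first hit).
    """
    lo, hi = window if window is not None else (0, len(sequence))
    region = sequence[lo:hi]
    hits: list[MotifHit] = []
    for start in range(len(region)):
        m = CCS_PATTERN.match(region, start)
        if m and m.start() == start:
            hits.append(
                MotifHit(
                    motif_name=motif_name,
                    start=lo + m.start(),
                    end=lo + m.end(),
                    matched=m.group(0),
                )
            )
    return hits


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_degenerate(
    sequence: str,
    consensus: str,
    max_mismatch: int = 0,
    window: tuple[int, int] | None = None,
    motif_name: str | None = None,
) -> list[MotifHit]:
    """All windows of ``len(consensus)`` within Hamming distance
    ``max_mismatch`` of the consensus, sorted by (mismatches, position)."""
    if not consensus:
        raise ValueError("empty consensus")
    if max_mismatch >= len(consensus):
        raise ValueError("max_mismatch must be smaller than the consensus length")
    lo, hi = window if window is not None else (0, len(sequence))
    k = len(consensus)
    name = motif_name or ("CA" if consensus == CA_CONSENSUS else "custom")
    hits = []
    for start in range(lo, min(hi, len(sequence)) - k + 1):
        sub = sequence[start : start + k]
        mm = hamming(sub, consensus)
        if mm <= max_mismatch:
            hits.append(
                MotifHit(motif_name=name, start=start, end=start + k, matched=sub, mismatches=mm)
            )
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


def find_slippery(
    sequence: str,
    orf1_stop_start: int,
    motif_set: tuple[str, ...] = DEFAULT_SLIPPERY_MOTIFS,
    max_upstream: int = 20,
) -> tuple[MotifHit, int] | None:
    """Locate the slippery heptamer upstream of the ORF1 stop codon.

    Returns the nearest-upstream heptamer from ``motif_set`` whose 3'
    end lies within ``max_upstream`` nt of the stop-codon start,
    together with the offset (nt between heptamer end and stop start:
    0 means the heptamer abuts the stop codon).  ``None`` if no motif
    from the set is found in the gate.
    """
    stop = sequence[orf1_stop_start : orf1_stop_start + 3]
    if stop not in STOP_CODONS:
        raise ValueError(
            f"position {orf1_stop_start} does not start a stop codon (found {stop!r})"
        )
    best: tuple[MotifHit, int] | None = None
    for motif in motif_set:
        k = len(motif)
        # heptamer end must lie within the gate and not extend past the stop
        lo = max(0, orf1_stop_start - max_upstream - k)
        for start in range(lo, orf1_stop_start - k + 1):
            if sequence[start : start + k] == motif:
                offset = orf1_stop_start - (start + k)
                if offset <= max_upstream and (best is None or offset < best[1]):
                    best = (
                        MotifHit("slippery", start, start + k, motif),
                        offset,
                    )
    return best


def find_longest_duplex(
    sequence: str,
    region_a: tuple[int, int],
    region_b: tuple[int, int],
    min_len: int = 4,
    max_len: int | None = None,
    allow_gu: bool = False,
) -> LdiCall | None:
    """Longest antiparallel duplex between substrings of two regions.

    Exhaustive scan over all substring pairs (the regions involved —
    loops and terminal windows — are tens of nt, so this is cheap and
    transparently correct).  Ties are broken in favour of the most-5'
    partner in ``region_b``, then the most-5' substring of ``region_a``.
    """
    a_lo, a_hi = region_a
    b_lo, b_hi = region_b
    a_seq = sequence[a_lo:a_hi]
    b_seq = sequence[b_lo:b_hi]
    cap = min(len(a_seq), len(b_seq))
    if max_len is not None:
        cap = min(cap, max_len)
    if not allow_gu:
        # pure Watson-Crick: partner must literally be the reverse
        # complement, so search by string matching
        for L in range(cap, min_len - 1, -1):
            patterns: dict[str, int] = {}
            for i in range(len(a_seq) - L + 1):
                rc = revcomp(a_seq[i : i + L])
                if rc not in patterns:
                    patterns[rc] = i
            best_j = None
            best_i = None
            for rc, i in patterns.items():
                j = b_seq.find(rc)
                if j != -1 and (best_j is None or j < best_j or (j == best_j and i < best_i)):
                    best_j, best_i = j, i
            if best_j is not None:
                return LdiCall(
                    region_a=(a_lo + best_i, a_lo + best_i + L),
                    region_b=(b_lo + best_j, b_lo + best_j + L),
                    duplex_a=a_seq[best_i : best_i + L],
                    duplex_b=b_seq[best_j : best_j + L],
                    length=L,
                    gu_pairs=0,
                )
        return None
    for L in range(cap, min_len - 1, -1):
        for j in range(len(b_seq) - L + 1):
            b_sub = b_seq[j : j + L]
            for i in range(len(a_seq) - L + 1):
                a_sub = a_seq[i : i + L]
                ok, _paired, gu = duplex_check(a_sub, b_sub, allow_gu=allow_gu)
                if ok:
                    return LdiCall(
                        region_a=(a_lo + i, a_lo + i + L),
                        region_b=(b_lo + j, b_lo + j + L),
                        duplex_a=a_sub,
                        duplex_b=b_sub,
                        length=L,
                        gu_pairs=gu,
                    )
    return None
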