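"""Assembly of the -1 frameshift recoding-site model.

The recoding site of umbraviruses and Group 1 umbra-like viruses is a
chain of elements around the ORF1 stop codon: a slippery heptamer 0-12
nt upstream of the stop; hairpin HA upstream of the frameshift
stimulatory element (FSE); the FSE itself just downstream of the stop,
with a lower asymmetric internal loop carrying the sequence that pairs
with the 3' end (the FSE<->3' long-distance interaction); hairpin HB
downstream of the FSE whose apical loop can form pseudoknot PK1 with
nearby downstream sequence; the CA consensus (CACAACAACUCC) downstream
of PK1, whose final residues usually form the lower stem of hairpin HC;
and a second pseudoknot PK2 from HC's apical loop.

HA and HB are positional roles (upstream / downstream of the FSE), not
sequence families.  Every element that cannot be located is reported as
absent — absence is a result, never fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import RunConfig
from .fold import Hairpin, Pseudoknot, find_hairpins, find_pseudoknot
from .layout import OrfAnnotation
from .motifs import (
    CA_CONSENSUS,
    LdiCall,
    MotifHit,
    find_degenerate,
    find_longest_duplex,
    find_slippery,
)

RECODING_ELEMENT_ORDER = ("HA", "FSE", "HB", "PK1", "CA", "HC", "PK2")


@dataclass
class RecodingSite:
    slippery: MotifHit | None
    slippery_offset: int | None
    ha: Hairpin | None
    fse: Hairpin | None
    hb: Hairpin | None
    hc: Hairpin | None
    pk1: Pseudoknot | None
    pk2: Pseudoknot | None
    ca: MotifHit | None
    ca_placement: str  # HC_base | in_HC | none
    fse_ldi: LdiCall | None
    fse_ldi_source: str | None  # internal_loop | apical_loop
    conformance: dict[str, bool] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _pick_role_hairpin(
    hairpins: list[Hairpin],
    anchor: int,
    start_range: tuple[int, int] | None = None,
    end_range: tuple[int, int] | None = None,
    min_score: int = 7,
) -> Hairpin | None:
    """Choose the hairpin filling a positional role.

    The recoding-site roles are positional ("just downstream of the
    stop", "upstream of the FSE"), so selection is proximity-first:
    among candidates whose 5' arm starts (or 3' arm ends) in the given
    range and whose score clears ``min_score``, the one closest to the
    expected anchor wins; ties go to the higher score, then the most-5'.
    When nothing clears the score bar the best-scoring candidate in the
    range is returned, so weak elements are still reported rather than
    silently dropped.
    """
    cands = []
    for hp in hairpins:
        if start_range is not None and not (start_range[0] <= hp.start <= start_range[1]):
            continue
        if end_range is not None and not (end_range[0] <= hp.end <= end_range[1]):
            continue
        cands.append(hp)
    if not cands:
        return None
    strong = [h for h in cands if h.score >= min_score]
    if strong:
        return min(
            strong,
            key=lambda h: (
                abs((h.start if start_range else h.end) - anchor),
                -h.score,
                h.start,
            ),
        )
    return min(cands, key=lambda h: (-h.score, -h.pair_count, h.start))


def classify_ca_placement(ca: MotifHit | None, hc: Hairpin | None) -> str:
    """Where the CA consensus sits relative to hairpin HC.

    ``HC_base`` when at least 3 of CA's final 6 nt are paired within
    HC's lowest (outermost contiguous) stem segment — the usual
    arrangement in which the end of CA forms HC's lower stem.
    ``in_HC`` when CA overlaps HC's apical loop.  ``none`` otherwise.
    """
    if ca is None or hc is None:
        return "none"
    loop_lo, loop_hi = hc.apical_loop
    if ca.start < loop_hi and loop_lo < ca.end:
        return "in_HC"
    # HC_base: the end of CA is built into HC's stem (5' side).  Chance
    # pairing may extend the stem below the designed base, so any paired
    # 5'-side position counts, not just the outermost run.
    paired_5p = {i for i, _ in hc.stem_pairs}
    final6 = set(range(max(ca.start, ca.end - 6), ca.end))
    if len(final6 & paired_5p) >= 3:
        return "HC_base"
    return "none"


def find_fse_ldi(
    sequence: str,
    fse: Hairpin,
    three_prime_region: tuple[int, int],
    config: RunConfig = RunConfig(),
    partners: list[Hairpin] | None = None,
) -> tuple[LdiCall | None, str | None]:
    """Long-distance interaction between FSE loop residues and the
    loops of the two 3'-terminal hairpins (Pr or the penultimate one).

    Returns ``(call, source)`` where source records which FSE loop
    donated the interacting residues: the lower internal loop for the
    UV / Group 1 arrangement, the apical loop for the Group 2
    arrangement.
    """
    if partners is None:
        hairpins = find_hairpins(sequence, three_prime_region, config.fold)
        partners = sorted(hairpins, key=lambda h: h.end)[-2:]
    if not partners:
        return None, None
    partner_loops = [h.apical_loop_padded(1) for h in partners]

    sources: list[tuple[tuple[int, int], str]] = []
    for side5, side3 in fse.internal_loops:
        if side5[1] > side5[0]:
            sources.append((side5, "internal_loop"))
        if side3[1] > side3[0]:
            sources.append((side3, "internal_loop"))
    sources.append((fse.apical_loop_padded(1), "apical_loop"))

    best: tuple[LdiCall, str] | None = None
    for loop, label in sources:
        for partner in partner_loops:
            call = find_longest_duplex(
                sequence, loop, partner, min_len=config.ldi_min_len,
                allow_gu=config.fold.allow_gu,
            )
            if call and (best is None or call.length > best[0].length):
                best = (call, label)
    if best is None:
        return None, None
    return best


def annotate_recoding_site(
    sequence: str,
    orf1: OrfAnnotation,
    config: RunConfig = RunConfig(),
    three_prime_hairpins: list[Hairpin] | None = None,
) -> RecodingSite:
    """Locate slippery site, HA/FSE/HB/HC, PK1/PK2, CA and the FSE LDI.

    ``W = config.element_window`` is the proximity window between
    consecutive elements.  Selection among competing hairpins is by
    pair count, then anchor proximity — deterministic throughout.
    """
    if orf1.end - orf1.start < 6:
        raise ValueError("ORF1 annotation required")
    n = len(sequence)
    W = config.element_window
    fold = config.fold
    notes: list[str] = []

    slip = find_slippery(
        sequence,
        orf1.stop_start,
        motif_set=config.slippery_motifs,
        max_upstream=config.slippery_max_upstream,
    )
    slippery, offset = slip if slip else (None, None)

    stop_end = orf1.end
    search_hi = min(n, stop_end + W + fold.max_span)
    down_hairpins = find_hairpins(sequence, (stop_end, search_hi), fold)
    fse = _pick_role_hairpin(
        down_hairpins, stop_end, start_range=(stop_end, stop_end + W),
        min_score=config.role_min_score,
    )

    ha = hb = hc = None
    pk1 = pk2 = None
    ca = None
    if fse is not None:
        up_lo = max(0, fse.start - W - fold.max_span)
        up_hairpins = find_hairpins(sequence, (up_lo, fse.start), fold)
        ha = _pick_role_hairpin(
            up_hairpins, fse.start, end_range=(max(0, fse.start - W), fse.start),
            min_score=config.role_min_score,
        )
        hb_hairpins = find_hairpins(sequence, (fse.end, min(n, fse.end + W + fold.max_span)), fold)
        hb = _pick_role_hairpin(
            hb_hairpins, fse.end, start_range=(fse.end, fse.end + W),
            min_score=config.role_min_score,
        )

    if hb is not None:
        pk1 = find_pseudoknot(
            sequence,
            hb.apical_loop_padded(1),
            search_from=hb.end,
            search_window=config.pk_search_window,
            min_len=config.pk_min_len,
            max_len=config.pk_max_len,
            allow_gu=fold.allow_gu,
            kind="PK1",
        )

    # CA sits downstream of PK1's partner; anchoring the search on HB's
    # 3' end covers the same stretch without inheriting a mis-resolved
    # pseudoknot partner
    ca_anchor = None
    if hb is not None:
        ca_anchor = hb.end
    elif pk1 is not None:
        ca_anchor = pk1.partner_interval[1]
    if ca_anchor is not None:
        ca_hits = find_degenerate(
            sequence,
            CA_CONSENSUS,
            max_mismatch=config.ca_max_mismatch,
            window=(ca_anchor, min(n, ca_anchor + W + len(CA_CONSENSUS))),
        )
        ca = ca_hits[0] if ca_hits else None

    hc_anchor = ca.start if ca is not None else ca_anchor
    if hc_anchor is not None:
        hc_hi = (ca.end + W) if ca is not None else (hc_anchor + W)
        hc_hairpins = find_hairpins(
            sequence, (hc_anchor, min(n, hc_hi + fold.max_span)), fold
        )
        hc = _pick_role_hairpin(
            hc_hairpins, hc_anchor, start_range=(hc_anchor, hc_hi),
            min_score=config.role_min_score,
        )

    if hc is not None:
        pk2 = find_pseudoknot(
            sequence,
            hc.apical_loop_padded(1),
            search_from=hc.end,
            search_window=config.pk_search_window,
            min_len=config.pk_min_len,
            max_len=config.pk_max_len,
            allow_gu=fold.allow_gu,
            kind="PK2",
        )

    placement = classify_ca_placement(ca, hc)

    fse_ldi, ldi_source = (None, None)
    if fse is not None:
        region = (max(0, n - config.fse_ldi_region), n)
        fse_ldi, ldi_source = find_fse_ldi(
            sequence, fse, region, config, partners=three_prime_hairpins
        )

    site = RecodingSite(
        slippery=slippery,
        slippery_offset=offset,
        ha=ha,
        fse=fse,
        hb=hb,
        hc=hc,
        pk1=pk1,
        pk2=pk2,
        ca=ca,
        ca_placement=placement,
        fse_ldi=fse_ldi,
        fse_ldi_source=ldi_source,
        conformance={
            "slippery": slippery is not None,
            "HA": ha is not None,
            "FSE": fse is not None,
            "HB": hb is not None,
            "PK1": pk1 is not None,
            "CA": ca is not None,
            "HC": hc is not None,
            "PK2": pk2 is not None,
            "FSE_LDI": fse_ldi is not None,
        },
        notes=notes,
    )
    _check_element_order(site)
    return site


def _check_element_order(site: RecodingSite) -> None:
    """Verify the along-genome ordering HA < FSE < HB < PK1 partner <
    CA <= HC < PK2 partner for the elements that are present; violations
    are recorded as notes (they indicate an unusual architecture)."""
    marks = []
    if site.ha:
        marks.append(("HA", site.ha.start))
    if site.fse:
        marks.append(("FSE", site.fse.start))
    if site.hb:
        marks.append(("HB", site.hb.start))
    if site.pk1:
        marks.append(("PK1_partner", site.pk1.partner_interval[0]))
    if site.ca:
        marks.append(("CA", site.ca.start))
    if site.hc:
        marks.append(("HC", site.hc.start))
    if site.pk2:
        marks.append(("PK2_partner", site.pk2.partner_interval[0]))
    for (name_a, pos_a), (name_b, pos_b) in zip(marks, marks[1:]):
        ok = pos_a <= pos_b if (name_a, name_b) == ("CA", "HC") else pos_a < pos_b
        if not ok:
            site.notes.append(f"element order violation: {name_a} at {pos_a} !< {name_b} at {pos_b}")
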