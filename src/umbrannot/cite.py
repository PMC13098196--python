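"""3' cap-independent translation enhancer (3'CITE) classification.

Members of this virus family enhance translation through structured 3'
UTR elements that contact the genomic (or subgenomic) 5' end via a
long-distance RNA:RNA interaction (LDI).  Classes handled here:

* TSS — T-shaped, ribosome-binding structure of three hairpins and two
  pseudoknots; the two 5' hairpins are juxtaposed (at most a 1-nt
  spacer, accommodating the adenylate-separated variant).
* ISS — I-shaped structure: one extended stem interrupted by two
  opposing bulged loops carrying conserved eIF4F-binding motifs;
  a *branched* variant carries the LDI sequence in a separate hairpin
  while the primary stem is capped by a highly stable GNRA (or UNCG)
  tetraloop.
* UTE — three hairpins atop an extended scaffold stem.
* BTE — recognised by a configurable conserved motif only.

Classification precedence is TSS -> ISS -> UTE -> BTE -> unknown; a
genome may legitimately carry two CITEs (e.g. one next to the
CITE-associated structure, CAS, and one at the 3' end), so the
classifier is run per region.  PTE and other classes whose geometry is
not encoded here come out as ``unknown``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .config import RunConfig
from .fold import Hairpin, Pseudoknot, find_hairpins, find_pseudoknot
from .motifs import LdiCall, MotifHit, find_degenerate, find_longest_duplex

GNRA_RE = re.compile(r"^G[ACGU][AG]A$")
UNCG_RE = re.compile(r"^U[ACGU]CG$")


@dataclass
class CiteCall:
    cite_type: str  # TSS | ISS | ISS_branched | UTE | BTE_A | BTE_B | unknown
    location: tuple[int, int] | None
    hairpins: list[Hairpin] = field(default_factory=list)
    pseudoknots: list[Pseudoknot] = field(default_factory=list)
    motif: MotifHit | None = None
    branched: bool = False
    gnra_capped: bool = False
    scaffold_duplex: LdiCall | None = None

    def loop_intervals(self) -> list[tuple[int, int]]:
        loops = []
        for hp in self.hairpins:
            loops.extend(hp.loop_intervals(pad=1))
        return loops


@dataclass
class CasCall:
    cas: Hairpin | None
    kl_pair: tuple[Hairpin, Hairpin, LdiCall] | None


def find_cas(
    sequence: str,
    region: tuple[int, int],
    config: RunConfig = RunConfig(),
    hairpins: list[Hairpin] | None = None,
) -> CasCall:
    """Locate the CITE-associated structure (CAS) and its upstream
    kissing-loop (KL) hairpin pair.

    CAS is the best-ranked hairpin in the region that has an internal
    loop, the configured apical-loop motif, and the configured motif at
    the base of its 5' arm.  The KL pair is the pair of hairpins
    upstream of CAS whose apical loops form the longest duplex of at
    least 4 nt (most-5' pair on ties).
    """
    sig = config.signatures
    if hairpins is None:
        hairpins = find_hairpins(sequence, region, config.fold)
    cas = None
    for hp in hairpins:  # ranked best-first
        if not hp.internal_loops:
            continue
        lo, hi = hp.apical_loop
        if sig.cas_apical_motif not in sequence[lo:hi]:
            continue
        # the stem-base motif sits at (or within a few nt of) the 5' arm
        # base — the stem may be extended outward by chance pairing
        base_window = sequence[hp.start : hp.start + len(sig.cas_stem_base_motif) + 8]
        if sig.cas_stem_base_motif not in base_window:
            continue
        cas = hp
        break
    kl = None
    if cas is not None:
        # the CAS stem may extend a few nt over the gap toward KL2, so
        # candidates may reach slightly past its reported 5' boundary as
        # long as their apical loops lie upstream of the CAS apical
        upstream = sorted(
            (
                h
                for h in hairpins
                if h.end <= cas.start + 8
                and h.apical_loop[1] <= cas.apical_loop[0]
                and h.pair_count >= 4
            ),
            key=lambda h: (-h.score, h.start),
        )[:30]
        upstream.sort(key=lambda h: h.start)
        best = None
        for a_idx in range(len(upstream)):
            for b_idx in range(a_idx + 1, len(upstream)):
                h1, h2 = upstream[a_idx], upstream[b_idx]
                duplex = find_longest_duplex(
                    sequence, h1.apical_loop_padded(1), h2.apical_loop_padded(1),
                    min_len=config.ldi_min_len, allow_gu=config.fold.allow_gu,
                )
                if duplex and (best is None or duplex.length > best[2].length):
                    best = (h1, h2, duplex)
        kl = best
    return CasCall(cas=cas, kl_pair=kl)


def _tss_call(
    sequence: str, region: tuple[int, int], hairpins: list[Hairpin], config: RunConfig
) -> CiteCall | None:
    """Three solid hairpins, the 5' two juxtaposed, plus two pseudoknot
    duplexes with tRNA-mimic geometry: the loops of both 5' hairpins
    reach over the third hairpin to pair with the sequence beyond it.

    Geometry is anchored on apical loops (stem boundaries wander with
    chance flank pairing, apical loops do not): juxtaposed hairpins of
    4-8-pair arms put their apicals 8-18 nt apart.
    """
    ordered = sorted(
        (h for h in hairpins if h.pair_count >= 4 and h.score >= 5),
        key=lambda h: h.apical_loop[0],
    )
    uniq = []
    seen: set = set()
    for h in ordered:  # one representative per apical loop (best-ranked kept)
        if h.apical_loop not in seen:
            seen.add(h.apical_loop)
            uniq.append(h)
    for i in range(len(uniq)):
        h1 = uniq[i]
        a1 = h1.apical_loop
        for j in range(i + 1, len(uniq)):
            h2 = uniq[j]
            a2 = h2.apical_loop
            if not (8 <= a2[0] - a1[1] <= 18):
                continue
            for k in range(j + 1, len(uniq)):
                h3 = uniq[k]
                a3 = h3.apical_loop
                if not (8 <= a3[0] - a2[1] <= 40):
                    continue
                pk_a = find_pseudoknot(
                    sequence, h1.apical_loop_padded(1), search_from=a3[1],
                    search_window=config.pk_search_window,
                    min_len=config.tss_pk_min_len, max_len=config.pk_max_len,
                    allow_gu=config.fold.allow_gu, kind="TSS_PK",
                )
                pk_b = find_pseudoknot(
                    sequence, h2.apical_loop_padded(1), search_from=a3[1],
                    search_window=config.pk_search_window,
                    min_len=config.tss_pk_min_len, max_len=config.pk_max_len,
                    allow_gu=config.fold.allow_gu, kind="TSS_PK",
                )
                if pk_a and pk_b:
                    return CiteCall(
                        cite_type="TSS",
                        location=(h1.start, max(h3.end, pk_a.partner_interval[1],
                                                pk_b.partner_interval[1])),
                        hairpins=[h1, h2, h3],
                        pseudoknots=[pk_a, pk_b],
                    )
    return None


def _iss_call(
    sequence: str, region: tuple[int, int], hairpins: list[Hairpin], config: RunConfig
) -> CiteCall | None:
    """One stem with two opposing bulged loops carrying the conserved
    motifs; branched when an auxiliary hairpin flanks the scaffold."""
    sig = config.signatures
    for hp in hairpins:  # ranked best-first
        for side5, side3 in hp.internal_loops:
            s5 = sequence[side5[0] : side5[1]]
            s3 = sequence[side3[0] : side3[1]]
            if sig.iss_bulge5_motif in s5 and sig.iss_bulge3_motif in s3:
                # a branch must be a solid stem emanating just 3' of the
                # scaffold — not a chance 4-pair run, and not the
                # unrelated CAS/KL structures upstream
                aux = [
                    h
                    for h in hairpins
                    if h is not hp
                    and h.pair_count >= 5
                    and h.score >= 5
                    and h.apical_loop[0] >= hp.apical_loop[1]
                    and hp.end - 8 <= h.start <= hp.end + 25
                ]
                loop_seq = sequence[hp.apical_loop[0] : hp.apical_loop[1]]
                gnra = bool(GNRA_RE.match(loop_seq) or UNCG_RE.match(loop_seq))
                branched = bool(aux)
                call_hairpins = [hp] + sorted(aux, key=lambda h: h.start)[:1]
                lo = min(h.start for h in call_hairpins)
                hi = max(h.end for h in call_hairpins)
                return CiteCall(
                    cite_type="ISS_branched" if branched else "ISS",
                    location=(lo, hi),
                    hairpins=call_hairpins,
                    branched=branched,
                    gnra_capped=gnra,
                )
    return None


def _ute_call(
    sequence: str, region: tuple[int, int], hairpins: list[Hairpin], config: RunConfig
) -> CiteCall | None:
    """Three hairpins in close succession flanked by a scaffold stem:
    the region just upstream of the first hairpin pairs with the region
    just downstream of the third.  Geometry is anchored on the apical
    loops (stem boundaries wander with chance pairing, apical loops do
    not); among qualifying triples the one with the longest scaffold
    duplex wins."""
    ordered = sorted(
        (h for h in hairpins if h.pair_count >= 4 and h.score >= 5),
        key=lambda h: h.apical_loop[0],
    )
    best_call: CiteCall | None = None
    seen_apicals: set = set()
    uniq = []
    for h in ordered:  # one representative per apical loop (best-ranked kept)
        if h.apical_loop not in seen_apicals:
            seen_apicals.add(h.apical_loop)
            uniq.append(h)
    for i in range(len(uniq)):
        h1 = uniq[i]
        a1 = h1.apical_loop
        for j in range(i + 1, len(uniq)):
            h2 = uniq[j]
            a2 = h2.apical_loop
            if not (4 <= a2[0] - a1[1] <= 24):
                continue
            for k in range(j + 1, len(uniq)):
                h3 = uniq[k]
                a3 = h3.apical_loop
                if not (4 <= a3[0] - a2[1] <= 24):
                    continue
                up = (max(region[0], a1[0] - 20), max(region[0], a1[0] - 4))
                down = (min(region[1], a3[1] + 4), min(region[1], a3[1] + 20))
                if up[1] <= up[0] or down[1] <= down[0]:
                    continue
                duplex = find_longest_duplex(
                    sequence, up, down, min_len=max(config.ldi_min_len, 5),
                    allow_gu=config.fold.allow_gu,
                )
                if duplex and (
                    best_call is None or duplex.length > best_call.scaffold_duplex.length
                ):
                    best_call = CiteCall(
                        cite_type="UTE",
                        location=(duplex.region_a[0], duplex.region_b[1]),
                        hairpins=[h1, h2, h3],
                        scaffold_duplex=duplex,
                    )
    return best_call


def classify_cite(
    sequence: str,
    region: tuple[int, int],
    config: RunConfig = RunConfig(),
    after_apical: int | None = None,
    hairpins: list[Hairpin] | None = None,
) -> CiteCall:
    """Classify the 3'CITE in a region.  First matching rule wins, in
    the order TSS -> ISS -> UTE -> BTE; ``unknown`` (never an
    exception) when nothing matches.

    ``after_apical`` keeps only hairpins whose apical loop begins at or
    beyond the given position — the CITE sits just downstream of the
    CAS, so evidence upstream of the CAS apical (including the CAS
    itself) is excluded while the fold is still taken over the whole
    region (clipping the region instead would change which chains the
    fold reports).
    """
    if hairpins is None:
        hairpins = find_hairpins(sequence, region, config.fold)
    if after_apical is not None:
        hairpins = [h for h in hairpins if h.apical_loop[0] >= after_apical]
    for caller in (_tss_call, _iss_call, _ute_call):
        call = caller(sequence, region, hairpins, config)
        if call is not None:
            return call
    sig = config.signatures
    for name, motif in (("BTE_A", sig.bte_a_motif), ("BTE_B", sig.bte_b_motif)):
        hits = find_degenerate(sequence, motif, max_mismatch=1, window=region, motif_name=name)
        if hits:
            hit = hits[0]
            return CiteCall(cite_type=name, location=(hit.start, hit.end), motif=hit)
    return CiteCall(cite_type="unknown", location=None)


def find_cite_ldi(
    sequence: str,
    cite: CiteCall,
    sg_starts: list[int] | None = None,
    config: RunConfig = RunConfig(),
) -> tuple[LdiCall | None, str | None]:
    """LDI between any CITE loop and the apical loops of hairpins near
    the genomic 5' end or any supplied sgRNA start.

    Returns ``(call, context)`` where context names the matched 5'
    region ("gRNA_5p" or "sgRNA@<pos>").  Longest duplex wins; the
    gRNA 5' end is tried before sgRNA starts.
    """
    contexts: list[tuple[str, tuple[int, int]]] = [
        ("gRNA_5p", (0, min(len(sequence), config.cite_ldi_5p_window)))
    ]
    for pos in sg_starts or []:
        contexts.append(
            (f"sgRNA@{pos}", (pos, min(len(sequence), pos + config.cite_ldi_5p_window)))
        )
    cite_loops = cite.loop_intervals()
    best: tuple[LdiCall, str] | None = None
    for label, window in contexts:
        hairpins = [h for h in find_hairpins(sequence, window, config.fold) if h.pair_count >= 4]
        for hp in hairpins:
            for loop in cite_loops:
                call = find_longest_duplex(
                    sequence, loop, hp.apical_loop_padded(1),
                    min_len=config.ldi_min_len, allow_gu=config.fold.allow_gu,
                )
                if call and (best is None or call.length > best[0].length):
                    best = (call, label)
    if best is None:
        return None, None
    return best
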