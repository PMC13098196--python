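"""Synthetic genome generator with planted, ground-truthed elements.

Generates random viral-genome backbones (default 3,000 nt, GC 0.45 —
within the family's genome-size range, scaled for test throughput)
carrying a designed complement of cis-elements: a 5' CCS, ORF1 with an
in-frame stop and a slippery heptamer at a chosen offset, the HA / FSE /
HB / HC hairpin set with PK1/PK2 partners and the CA consensus, a -1
frame ORF2 continuation, a UV / Group 1 / Group 2 ORF architecture, a
CAS hairpin with an upstream kissing-loop pair, one 3'CITE archetype
(TSS / ISS / branched ISS / UTE), and an H5 - Pr - psi1 terminus ending
GCCC-OH, with the FSE<->3' and CITE<->5' long-distance interactions.

Coding-region fillers are sampled codon-aware so no reading frame that
must stay open acquires a stop codon; backbones that would create
accidental slippery heptamers near the ORF1 stop, spurious ORFs beyond
ORF2, stray GGGC motifs in the psi1 window, or decoy pseudoknot
partners upstream of the planted ones are rejected and resampled (the
attempt count and reasons are logged in the manifest).  Every random
draw comes from the seeded generator: identical design + seed give
byte-identical genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .config import RunConfig
from .motifs import (
    CA_CONSENSUS,
    STOP_CODONS,
    DEFAULT_SLIPPERY_MOTIFS,
    find_longest_duplex,
    match_ccs,
    revcomp,
)
from .fold import find_hairpins
from .layout import find_orfs
from .sequence_io import GenomeRecord

CCS_SEQ = "GGCAAAA"

# Designed element sequences.  The arm set was chosen so that elements
# that can fall within one folding window share no cross-complementary
# run longer than 4 nt beyond the intended interactions (otherwise the
# pair-maximizing fold would chain one planted element's arm onto its
# neighbour's); sequences placed inside coding regions contain no stop
# triplet at any offset.
HP5_ARM = "GGCCGUUU"
HP5_LOOP = "GGCCAA"  # pairs the CITE LDI loop UUGGCC
HA_ARM = "ACCGAGACGC"
HA_LOOP = "GCGC"
FSE_ARM_LOWER = "GGCGGAU"
FSE_IL5 = "UGGCGA"  # FSE<->3' LDI donor (lower asymmetric internal loop)
FSE_ARM_UPPER = "CUUGGC"
FSE_LOOP = "GCAC"
FSE_IL3 = "CC"
HB_ARM = "CGAUGCUGCA"
HB_LOOP = "CCGUA"  # PK1 donor
HC_ARM_TAIL = "CCCCGC"  # HC 5' arm = CA[-4:] + this
HC_LOOP = "AAUUC"  # PK2 donor
KL1_ARM = "UACCUGCA"
KL1_LOOP = "GCUCC"
KL2_ARM = "ACAGCUCC"  # KL2 loop is revcomp(KL1_LOOP)
H5_ARM = "CCCCGGUG"
H5_LOOP = "GGGCAA"  # GGGC psi1 partner on the loop's 5' side
PR_ARM = "GAGCGGAA"
PR_LOOP = "UCGCCA"  # FSE LDI acceptor
CITE_LDI_LOOP = "UUGGCC"  # pairs HP5_LOOP at the 5' end
# TSS sub-elements
TSS_H1_ARM, TSS_H1_LOOP = "GCCUAA", "UUUCG"
TSS_H2_ARM, TSS_H2_LOOP = "AUUCCA", "GAGUU"
TSS_H3_ARM = "GCUCUC"
# ISS / branched-ISS sub-elements
ISS_ARM_LOWER, ISS_ARM_UPPER = "AUCUCGU", "AGAC"
AUX_ARM = "AUCACA"
# UTE sub-elements
UTE_SCAFFOLD = "GCCUCG"
UTE_H1_ARM, UTE_H1_LOOP = "AAUGG", "ACCCG"
UTE_H2_ARM, UTE_H2_LOOP = "CGAGG", "AACUC"
UTE_H3_ARM = "CCGGG"


@dataclass
class PlantedElement:
    kind: str
    start: int
    end: int
    seq: str
    attrs: dict = field(default_factory=dict)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GenomeDesign:
    """The study conditions a synthetic genome emulates."""

    length: int = 3000
    gc: float = 0.45
    layout: str = "UV"  # UV | group1 | group2
    slippery_motif: str = "GGAUUUU"
    slippery_offset: int = 3  # nt between heptamer end and ORF1 stop
    cite_archetype: str | None = "TSS"  # TSS | ISS | ISS_branched | UTE | None
    h5_conformation: str = "UV_apical"  # UV_apical | tombus_internal | GULV_asymmetric
    terminal: str = "GCCC"
    plant_ca: bool = True
    plant_pk1: bool = True
    plant_pk2: bool = True
    plant_ha: bool = True


@dataclass
class SyntheticManifest:
    genome_id: str
    seed: int
    length: int
    gc: float
    design: GenomeDesign
    attempts: int
    planted: list[PlantedElement]
    notes: list[str] = field(default_factory=list)

    def get(self, kind: str, **attrs) -> PlantedElement | None:
        for el in self.planted:
            if el.kind == kind and all(el.attrs.get(k) == v for k, v in attrs.items()):
                return el
        return None

    def get_all(self, kind: str) -> list[PlantedElement]:
        return [el for el in self.planted if el.kind == kind]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


class InfeasibleDesign(RuntimeError):
    pass


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(("A", "C", "G", "U"), size=n, p=p))


def _codon_fill(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Random stop-free codons (frame-aligned coding filler)."""
    out = []
    while len(out) < n_codons:
        codon = _rand_seq(rng, 3, gc)
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _constrained_fill(
    rng: np.random.Generator,
    n: int,
    gc: float,
    abs_pos: int,
    forbidden_frames: frozenset[int],
    left: str = "",
    right: str = "",
    last_char: str | None = None,
    avoid: tuple[str, ...] = (),
) -> str:
    """Random filler that introduces no stop codon in the forbidden
    genome reading frames (including windows crossing into the 2-nt
    flanking contexts) and none of the ``avoid`` substrings.  Built in
    12-nt chunks by rejection sampling."""

    def clean(chunk: str, chunk_abs: int, lctx: str, rctx: str) -> bool:
        lctx = lctx[-2:]
        ctx = lctx + chunk + rctx[:2]
        base = chunk_abs - len(lctx)
        for i in range(len(ctx) - 2):
            if (base + i) % 3 in forbidden_frames and ctx[i : i + 3] in STOP_CODONS:
                return False
        for sub in avoid:
            if sub in ctx:
                return False
        return True

    if not forbidden_frames and not last_char and not avoid:
        return _rand_seq(rng, n, gc)
    out = ""
    while len(out) < n:
        size = min(12, n - len(out))
        is_last = len(out) + size == n
        rctx = right if is_last else ""
        for _ in range(500):
            chunk = _rand_seq(rng, size, gc)
            if is_last and last_char:
                chunk = chunk[:-1] + last_char
            if clean(chunk, abs_pos + len(out), left + out, rctx):
                out += chunk
                break
        else:
            raise InfeasibleDesign("constrained filler sampling failed")
    return out


class _Builder:
    def __init__(self, rng: np.random.Generator, gc: float):
        self.rng = rng
        self.gc = gc
        self.seq = ""
        self.planted: list[PlantedElement] = []

    @property
    def pos(self) -> int:
        return len(self.seq)

    def fixed(self, s: str, kind: str | None = None, **attrs) -> PlantedElement | None:
        el = None
        if kind is not None:
            el = PlantedElement(kind, self.pos, self.pos + len(s), s, attrs)
            self.planted.append(el)
        self.seq += s
        return el

    def hairpin(self, arm: str, loop: str, kind: str | None = None, **attrs):
        s0 = self.pos
        return self.fixed(
            arm + loop + revcomp(arm),
            kind=kind,
            apical=[s0 + len(arm), s0 + len(arm) + len(loop)],
            pairs=len(arm),
            **attrs,
        )

    def plant(self, kind: str, start: int, end: int, **attrs) -> None:
        self.planted.append(PlantedElement(kind, start, end, self.seq[start:end], attrs))

    def fill(
        self,
        n: int,
        forbidden: frozenset[int] | set[int] = frozenset(),
        right: str = "",
        last_char: str | None = None,
        avoid: tuple[str, ...] = (),
    ) -> None:
        if n <= 0:
            return
        self.seq += _constrained_fill(
            self.rng, n, self.gc, self.pos, frozenset(forbidden),
            left=self.seq[-2:], right=right, last_char=last_char, avoid=avoid,
        )

    def codons(self, n_codons: int) -> None:
        self.seq += _codon_fill(self.rng, n_codons, self.gc)


def _hairpin(arm: str, loop: str) -> str:
    return arm + loop + revcomp(arm)


def _cite_block(b: _Builder, archetype: str, config: RunConfig) -> None:
    sig = config.signatures
    start = b.pos
    subs: list[dict] = []

    def sub(role: str, s0: int, arm_len: int, loop_len: int) -> None:
        subs.append(
            {
                "role": role,
                "start": s0,
                "end": b.pos,
                "apical": [s0 + arm_len, s0 + arm_len + loop_len],
            }
        )

    if archetype == "TSS":
        # both pseudoknot acceptors sit 3' of the third hairpin, as in
        # the tRNA-mimic geometry (loops reach over the downstream stem)
        s0 = b.pos
        b.fixed(_hairpin(TSS_H1_ARM, TSS_H1_LOOP))
        sub("H1", s0, len(TSS_H1_ARM), len(TSS_H1_LOOP))
        s0 = b.pos
        b.fixed(_hairpin(TSS_H2_ARM, TSS_H2_LOOP))
        sub("H2", s0, len(TSS_H2_ARM), len(TSS_H2_LOOP))
        b.fixed("GCG")
        s0 = b.pos
        b.fixed(_hairpin(TSS_H3_ARM, CITE_LDI_LOOP))
        sub("H3_LDI", s0, len(TSS_H3_ARM), len(CITE_LDI_LOOP))
        b.fixed(revcomp(TSS_H1_LOOP))  # pseudoknot A acceptor
        b.fixed(revcomp(TSS_H2_LOOP))  # pseudoknot B acceptor
    elif archetype in ("ISS", "ISS_branched"):
        gnra = archetype == "ISS_branched"
        apical = "GCGA" if gnra else CITE_LDI_LOOP
        s0 = b.pos
        b.fixed(
            ISS_ARM_LOWER + sig.iss_bulge5_motif + ISS_ARM_UPPER + apical
            + revcomp(ISS_ARM_UPPER) + sig.iss_bulge3_motif + revcomp(ISS_ARM_LOWER)
        )
        sub("ISS_stem", s0, 0, 0)
        if gnra:
            b.fill(4, right=AUX_ARM)
            s0 = b.pos
            b.fixed(_hairpin(AUX_ARM, CITE_LDI_LOOP))
            sub("LDI_hairpin", s0, len(AUX_ARM), len(CITE_LDI_LOOP))
    elif archetype == "UTE":
        h2 = _hairpin(UTE_H2_ARM, UTE_H2_LOOP)
        h3 = _hairpin(UTE_H3_ARM, CITE_LDI_LOOP)
        b.fixed(UTE_SCAFFOLD)  # scaffold 5' arm
        s0 = b.pos
        b.fixed(_hairpin(UTE_H1_ARM, UTE_H1_LOOP))
        sub("H1", s0, len(UTE_H1_ARM), len(UTE_H1_LOOP))
        b.fixed("CAA")
        s0 = b.pos
        b.fixed(h2)
        sub("H2", s0, len(UTE_H2_ARM), len(UTE_H2_LOOP))
        b.fixed("CAA")
        s0 = b.pos
        b.fixed(h3)
        sub("H3_LDI", s0, len(UTE_H3_ARM), len(CITE_LDI_LOOP))
        b.fixed(revcomp(UTE_SCAFFOLD))  # scaffold 3' arm
    else:
        raise ValueError(f"unknown CITE archetype {archetype!r}")
    b.planted.append(
        PlantedElement("CITE", start, b.pos, b.seq[start:], {"archetype": archetype, "subs": subs})
    )


def _h5_block(b: _Builder, conformation: str) -> None:
    """H5 with its GGGC psi1 partner in the chosen conformation; the
    residue preceding GGGC is never G, so the partner's position is
    unambiguous."""
    start = b.pos
    if conformation == "UV_apical":
        s = _hairpin(H5_ARM, H5_LOOP)
        ggg = start + s.index("GGGC")
        apical = [start + len(H5_ARM), start + len(H5_ARM) + len(H5_LOOP)]
    elif conformation == "tombus_internal":
        s = "GCAGG" + "CA" + "GUGC" + "ACAA" + "GCAC" + "GGGCA" + "CCUGC"
        ggg = start + 19
        apical = [start + 11, start + 15]
    elif conformation == "GULV_asymmetric":
        s = "GCAGGGUGC" + "ACAA" + "GCAC" + "GGGCA" + "CCUGC"
        ggg = start + 17
        apical = [start + 9, start + 13]
    else:
        raise ValueError(f"unknown H5 conformation {conformation!r}")
    b.fixed(s, kind="H5", conformation=conformation, apical=apical)
    b.plant("PSI1_partner", ggg, ggg + 4)


def _assemble(design: GenomeDesign, rng: np.random.Generator, config: RunConfig) -> _Builder:
    b = _Builder(rng, design.gc)

    # ---- 5' end: CCS gate, ORF1 start, 5'-proximal LDI hairpin -------
    b.fixed(CCS_SEQ, kind="CCS", context="gRNA")
    b.fixed("CC")
    orf1_start = b.pos
    f1 = orf1_start % 3
    f2 = (f1 + 2) % 3  # the -1 frame read after the frameshift
    b.fixed("AUG")
    b.fixed("GCC")
    s0 = b.pos
    b.fixed(_hairpin(HP5_ARM, HP5_LOOP))
    b.plant("five_prime_hairpin", s0, b.pos, loop=HP5_LOOP)
    b.fixed("GC")

    # ---- size budget: slack goes 55% to ORF1, 30% to the ORF2
    # continuation, the rest to the 3' UTR ----------------------------
    downstream_designed = 620 if design.layout != "group2" else 430
    slack = max(design.length - b.pos - 55 - downstream_designed, 180)
    n1 = (int(slack * 0.55) // 3) * 3
    orf2_extra = int(slack * 0.30)
    utr_extra = max(slack - n1 - orf2_extra, 12)

    # ---- ORF1 body, HA, slippery site, stop --------------------------
    b.codons(n1 // 3)
    if design.plant_ha:
        b.fixed(_hairpin(HA_ARM, HA_LOOP), kind="HA", pairs=len(HA_ARM))
    else:
        b.fill(24, forbidden={f1})
    b.codons(5)  # 15 nt between HA and the slippery region
    b.fixed("GC")
    b.fixed(design.slippery_motif, kind="slippery_site", offset=design.slippery_offset)
    if design.slippery_offset:
        b.fill(design.slippery_offset, forbidden={f1, f2}, right="UAG")
    b.fixed("UAG")
    orf1_end = b.pos
    if (orf1_end - orf1_start) % 3:
        raise InfeasibleDesign("ORF1 frame misaligned (offset must be a multiple of 3)")
    b.plant("ORF", orf1_start, orf1_end, orf_id="ORF1", frame=f1)

    # ---- recoding site, read in the -1 frame -------------------------
    fb = frozenset({f2})
    b.fill(6, forbidden=fb, right=FSE_ARM_LOWER)
    s0 = b.pos
    b.fixed(
        FSE_ARM_LOWER + FSE_IL5 + FSE_ARM_UPPER + FSE_LOOP
        + revcomp(FSE_ARM_UPPER) + FSE_IL3 + revcomp(FSE_ARM_LOWER),
        kind="FSE", pairs=13,
    )
    b.plant("FSE_LDI_donor", s0 + len(FSE_ARM_LOWER), s0 + len(FSE_ARM_LOWER) + len(FSE_IL5))
    b.fill(8, forbidden=fb, right=HB_ARM)
    hb = b.fixed(_hairpin(HB_ARM, HB_LOOP), kind="HB", pairs=len(HB_ARM))
    hb_loop = (hb.start + len(HB_ARM), hb.start + len(HB_ARM) + len(HB_LOOP))
    ca_right = CA_CONSENSUS if design.plant_ca else ("CUCC" + HC_ARM_TAIL)
    if design.plant_pk1:
        b.fill(10, forbidden=fb, right=revcomp(HB_LOOP))
        b.fixed(revcomp(HB_LOOP), kind="PK1", loop=list(hb_loop), hairpin_end=hb.end)
        b.fill(6, forbidden=fb, right=ca_right)
    else:
        b.fill(16, forbidden=fb, right=ca_right)
    if design.plant_ca:
        ca = b.fixed(CA_CONSENSUS, kind="CA")
        hc_start = ca.end - 4
        hc_arm5 = CA_CONSENSUS[-4:] + HC_ARM_TAIL
        b.fixed(HC_ARM_TAIL + HC_LOOP + revcomp(hc_arm5))
    else:
        hc_start = b.pos
        hc_arm5 = "CUCC" + HC_ARM_TAIL
        b.fixed(hc_arm5 + HC_LOOP + revcomp(hc_arm5))
    hc_end = b.pos
    b.plant("HC", hc_start, hc_end, pairs=len(hc_arm5))
    hc_loop = (hc_start + len(hc_arm5), hc_start + len(hc_arm5) + len(HC_LOOP))
    if design.plant_pk2:
        b.fill(8, forbidden=fb, right=revcomp(HC_LOOP))
        b.fixed(revcomp(HC_LOOP), kind="PK2", loop=list(hc_loop), hairpin_end=hc_end)

    # ---- ORF2 continuation, stop, and the ORF3/4 architecture --------
    # the continuation tail is AUG-free so chance ORFs straddling the
    # ORF2 stop do not shadow the planted downstream ORFs
    b.fill(max(orf2_extra - 120, 0), forbidden=fb)
    b.fill(min(orf2_extra, 120), forbidden=fb, avoid=("AUG",))
    if design.layout == "group1":
        # ORF3 starts inside ORF2's 3' end (out of frame), CCS-supported.
        # A stop codon planted in ORF3's frame just upstream guarantees
        # the planted AUG opens its stop-to-stop segment.
        f3 = (f2 + 1) % 3
        b.fill((f3 - b.pos) % 3, forbidden=fb, right="UAA")
        b.fixed("UAA")  # stop in ORF3's frame; not a stop in ORF2's frame
        b.fixed(CCS_SEQ, kind="CCS", context="sgRNA")
        b.fixed("CC")
        orf3_start = b.pos
        b.fixed("AUG")
        b.fill(12, forbidden={f2, f3}, avoid=("AUG",))
        b.fill((f2 - b.pos) % 3, forbidden={f2, f3}, right="UAA", avoid=("AUG",))
        b.fixed("UAA")  # ORF2 stop, inside ORF3
        orf2_stop_end = b.pos
        b.fill(orf3_start + 150 - b.pos, forbidden={f3}, right="UAG")
        b.fixed("UAG")
        b.plant("ORF", orf3_start, b.pos, orf_id="ORF3", frame=f3)
        b.fixed("UAACUAACUAA")  # stops in all three frames before the ORF4 sgRNA start
        b.fill(4, right=CCS_SEQ, avoid=("AUG",))
        b.fixed(CCS_SEQ, kind="CCS", context="sgRNA")
        b.fixed("CC")
        orf4_start = b.pos
        f4 = orf4_start % 3
        b.fixed("AUG")
        b.fill(120, forbidden={f4}, right="UAA")
        b.fixed("UAA")
        b.plant("ORF", orf4_start, b.pos, orf_id="ORF4", frame=f4)
    else:
        b.fill((f2 - b.pos) % 3, forbidden=fb, right="UAA")
        b.fixed("UAA")
        orf2_stop_end = b.pos
        if design.layout == "UV":
            b.fill(10, avoid=("AUG",))  # intergenic region
            b.fixed("UAACUAACUAA")  # stops in all three frames before the sgRNA start
            b.fixed(CCS_SEQ, kind="CCS", context="sgRNA")
            b.fixed("CC")
            orf3_start = b.pos
            f3 = orf3_start % 3
            b.fixed("AUG")
            b.fill(10, forbidden={f3}, right="AUG", avoid=("AUG",))
            orf4_start = b.pos  # ORF4 start 13 nt downstream of ORF3 start
            f4 = orf4_start % 3
            b.fixed("AUG")
            b.fill(134, forbidden={f3, f4}, right="UAG")
            b.fixed("UAG")  # ORF3 stop
            b.plant("ORF", orf3_start, b.pos, orf_id="ORF3", frame=f3)
            b.fill(40, forbidden={f4}, right="UAA")
            b.fixed("UAA")  # ORF4 stop
            b.plant("ORF", orf4_start, b.pos, orf_id="ORF4", frame=f4)
    b.plant("ORF2_stop", orf2_stop_end - 3, orf2_stop_end, frame=f2)

    # ---- 3' UTR: KL pair, CAS, CITE, H5, Pr, terminus ----------------
    b.fill(utr_extra, right=KL1_ARM, avoid=("AUG",))
    b.hairpin(KL1_ARM, KL1_LOOP, kind="KL_hairpin")
    b.fill(5, right=KL2_ARM, avoid=("AUG",))
    b.hairpin(KL2_ARM, revcomp(KL1_LOOP), kind="KL_hairpin")
    sig = config.signatures
    cas_arm5a = sig.cas_stem_base_motif + "C"
    b.fill(6, right=cas_arm5a, avoid=("AUG",))
    b.fixed(
        cas_arm5a + "CA" + "GCGC" + sig.cas_apical_motif + revcomp("GCGC")
        + "A" + revcomp(cas_arm5a),
        kind="CAS",
    )
    if design.cite_archetype:
        b.fill(8, avoid=("AUG",))
        _cite_block(b, design.cite_archetype, config)
    # a gap wider than the folding span separates the CITE/CAS region
    # from the 3'-terminal H5-Pr-psi1 module
    b.fill(85, avoid=("AUG",))
    _h5_block(b, design.h5_conformation)
    b.fill(6, right=PR_ARM, avoid=("AUG",))
    b.hairpin(PR_ARM, PR_LOOP, kind="Pr")
    b.fill(4, last_char="A", avoid=("AUG",))
    b.fixed(design.terminal, kind="PSI1_terminus")
    return b


def _verify(seq: str, b: _Builder, design: GenomeDesign, config: RunConfig) -> list[str]:
    """Reject backbones whose random content interferes with the
    planted ground truth."""
    problems: list[str] = []
    planted_orfs = {el.attrs["orf_id"]: el for el in b.planted if el.kind == "ORF"}
    orf2_stop = next(el for el in b.planted if el.kind == "ORF2_stop")
    found = find_orfs(seq, min_protein_aa=40)
    found_by_start = {o.start: o for o in found}
    for orf_id, el in planted_orfs.items():
        hit = found_by_start.get(el.start)
        if hit is None or hit.end != el.end:
            problems.append(f"{orf_id} not recovered as planted")
    orf1 = planted_orfs["ORF1"]
    planted_starts = {el.start for el in planted_orfs.values()}
    for o in found:
        if o.start < orf1.start:
            problems.append("spurious ORF upstream of ORF1")
        elif o.start > orf1.end and o.end > orf2_stop.end and o.start not in planted_starts:
            problems.append(f"spurious ORF beyond ORF2 at {o.start}")

    # slippery-site uniqueness within the detector's gate
    slip = next(el for el in b.planted if el.kind == "slippery_site")
    stop_start = orf1.end - 3
    gate_lo = max(0, stop_start - 20 - 7)
    for motif in set(DEFAULT_SLIPPERY_MOTIFS) | {design.slippery_motif}:
        idx = seq.find(motif, gate_lo, stop_start)
        while idx != -1:
            if idx != slip.start:
                problems.append(f"decoy slippery heptamer at {idx}")
            idx = seq.find(motif, idx + 1, stop_start)

    # pseudoknot partners must be the first maximal duplex in their windows
    for el in b.planted:
        if el.kind in ("PK1", "PK2"):
            lo, hi = el.attrs["loop"]
            loop = (lo - 1, hi + 1)  # matches the padded loop the annotator searches
            hp_end = el.attrs["hairpin_end"]
            # the found hairpin may be extended a few nt, shifting the
            # annotator's search window; cover the shifted windows too
            window = (max(0, hp_end - 10), min(len(seq), hp_end + config.pk_search_window + 10))
            call = find_longest_duplex(
                seq, loop, window,
                min_len=config.pk_min_len, max_len=config.pk_max_len,
            )
            if call is None or call.region_b != el.interval:
                problems.append(f"decoy {el.kind} partner precedes the planted one")

    # the psi1 window must contain exactly the planted GGGC
    partner = next(el for el in b.planted if el.kind == "PSI1_partner")
    idx = seq.find("GGGC", len(seq) - config.three_prime_window)
    while idx != -1:
        if idx != partner.start:
            problems.append(f"stray GGGC at {idx} in the psi1 window")
        idx = seq.find("GGGC", idx + 1)

    # fold-based checks are an order of magnitude more expensive than
    # the motif scans above; skip them when the backbone already failed
    if problems:
        return problems

    cite_el = next((el for el in b.planted if el.kind == "CITE"), None)

    # a plain (unbranched) ISS must not have an accidental hairpin
    # beside it, which would mimic the branched configuration
    if cite_el is not None and cite_el.attrs.get("archetype") == "ISS":
        cas_el2 = next(el for el in b.planted if el.kind == "CAS")
        lo = max(cas_el2.end, cite_el.start - 35)
        hi = min(len(seq), cite_el.end + 75)
        for hp in find_hairpins(seq, (lo, hi), config.fold):
            if (
                hp.pair_count >= 5
                and hp.score >= 5
                and (hp.end <= cite_el.start or hp.start >= cite_el.end)
                and (hp.start - cite_el.end <= 31 and cite_el.start - hp.end <= 31)
            ):
                problems.append("accidental hairpin beside a plain ISS")
                break

    if problems:
        return problems

    # every planted structural hairpin must fold back as a reported
    # maximal hairpin that keeps its designed apical loop and does not
    # stray far beyond its designed boundaries: chance pairing between
    # flanking backbone and designed arms can otherwise wrap
    # neighbouring stems into one chain and hide them
    def folds_cleanly(hps, start, end, apical) -> bool:
        # a loop whose end residues happen to pair closes by one extra
        # pair, so accept the designed apical or its one-shrunk form
        ok_apicals = {tuple(apical), (apical[0] + 1, apical[1] - 1)}
        return any(
            h.apical_loop in ok_apicals and start - 6 <= h.start and h.end <= end + 6
            for h in hps
        )

    tail_hps = find_hairpins(
        seq, (max(0, len(seq) - config.three_prime_window), len(seq)), config.fold
    )
    for kind in ("H5", "Pr"):
        el = next(e for e in b.planted if e.kind == kind)
        if not folds_cleanly(tail_hps, el.start, el.end, el.attrs["apical"]):
            problems.append(f"{kind} not recovered as a separate hairpin")

    if problems:
        return problems

    # the terminus validator must resolve the module to the planted
    # hairpins and conformation (alternative GGGC-presenting parses of
    # the same region would otherwise win the selection by chance)
    from .termini import validate_3prime

    t3 = validate_3prime(seq, config)
    h5_pl = next(e for e in b.planted if e.kind == "H5")
    pr_pl = next(e for e in b.planted if e.kind == "Pr")

    def covers(hp, el) -> bool:
        return (
            hp is not None
            and min(hp.end, el.end) - max(hp.start, el.start) >= (el.end - el.start) - 3
        )

    if not covers(t3.h5, h5_pl) or not covers(t3.pr, pr_pl):
        problems.append("terminus validator resolves to a different H5/Pr parse")
    elif t3.h5_conformation != design.h5_conformation:
        problems.append("H5 conformation misread from the realized fold")

    # the annotator folds the whole 3' UTR (last-ORF end to H5) as one
    # window; verify against exactly that window so the guarantees
    # transfer (region boundaries shift which chains the fold reports)
    kls = [e for e in b.planted if e.kind == "KL_hairpin"]
    cas_el = next((e for e in b.planted if e.kind == "CAS"), None)
    h5_el = next(e for e in b.planted if e.kind == "H5")
    utr_lo = max(el.end for el in b.planted if el.kind in ("ORF", "ORF2_stop"))
    utr_hps = find_hairpins(seq, (utr_lo, h5_el.start), config.fold)
    for el in kls:
        if not folds_cleanly(utr_hps, el.start, el.end, el.attrs["apical"]):
            problems.append("KL hairpin not recovered as planted")
            break

    if cite_el is not None and cas_el is not None:
        for s in cite_el.attrs.get("subs", []):
            if s["role"] == "ISS_stem":
                # the ISS stem is identified by its internal-loop motifs,
                # not by exact boundaries: require a reported hairpin
                # carrying both conserved motifs in one internal loop
                sig = config.signatures
                ok = False
                for hp in utr_hps:
                    for s5, s3 in hp.internal_loops:
                        if (
                            sig.iss_bulge5_motif in seq[s5[0] : s5[1]]
                            and sig.iss_bulge3_motif in seq[s3[0] : s3[1]]
                        ):
                            ok = True
                if not ok:
                    problems.append("ISS stem motifs not presented in one internal loop")
                    break
                continue
            if not folds_cleanly(utr_hps, s["start"], s["end"], s["apical"]):
                problems.append(f"CITE sub-hairpin {s['role']} not recovered")
                break

    # no decoy CCS in the 5' gate
    for hit in match_ccs(seq, (0, config.ccs_gate_n + 13)):
        if hit.start != 0 and hit.start < config.ccs_gate_n:
            problems.append(f"decoy CCS at {hit.start}")
    return problems


def generate_genome(
    design: GenomeDesign = GenomeDesign(),
    seed: int = 0,
    genome_id: str | None = None,
    config: RunConfig = RunConfig(),
    max_attempts: int = 150,
) -> tuple[GenomeRecord, SyntheticManifest]:
    """Generate one genome and its ground-truth manifest.

    Deterministic for fixed (design, seed).  Raises
    :class:`InfeasibleDesign` when no clean backbone is found within
    ``max_attempts`` full resamplings.
    """
    rng = np.random.default_rng(seed)
    notes: list[str] = []
    for attempt in range(1, max_attempts + 1):
        try:
            b = _assemble(design, rng, config)
        except InfeasibleDesign as exc:
            notes.append(f"attempt {attempt}: {exc}")
            continue
        problems = _verify(b.seq, b, design, config)
        if not problems:
            gid = genome_id or f"synth_{design.layout}_{seed}"
            record = GenomeRecord(id=gid, sequence=b.seq, description=gid)
            return record, SyntheticManifest(
                genome_id=gid,
                seed=seed,
                length=len(b.seq),
                gc=design.gc,
                design=design,
                attempts=attempt,
                planted=b.planted,
                notes=notes,
            )
        notes.append(f"attempt {attempt}: " + "; ".join(problems[:4]))
    raise InfeasibleDesign(f"no clean backbone in {max_attempts} attempts; last: {notes[-1]}")


def dinucleotide_shuffle(sequence: str, seed: int = 0) -> str:
    """Dinucleotide-preserving shuffle (Altschul-Erickson style): keep
    the dinucleotide transition multiset, emit a random Eulerian walk.
    The negative control: composition preserved, planted structure
    destroyed."""
    rng = np.random.default_rng(seed)
    if len(sequence) < 3:
        return sequence
    edges: dict[str, list[str]] = {}
    for a, nxt in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(nxt)
    last = sequence[-1]
    # choose, for every vertex except the final one, a reserved last
    # out-edge forming a tree oriented toward the final vertex
    last_edge: dict[str, str] = {}
    connected = {last}
    pending = [v for v in edges if v != last]
    while pending:
        progress = []
        for v in pending:
            targets = [t for t in edges[v] if t in connected]
            if targets:
                last_edge[v] = targets[int(rng.integers(len(targets)))]
                connected.add(v)
                progress.append(v)
        if not progress:
            v = pending[0]
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
            connected.add(v)
            progress.append(v)
        pending = [v for v in pending if v not in progress]
    shuffled: dict[str, list[str]] = {}
    for v, outs in edges.items():
        outs = list(outs)
        if v in last_edge:
            outs.remove(last_edge[v])
        perm = rng.permutation(len(outs)) if outs else []
        shuffled[v] = [outs[i] for i in perm]
        if v in last_edge:
            shuffled[v].append(last_edge[v])
    walk = [sequence[0]]
    cursor = {v: 0 for v in edges}
    for _ in range(len(sequence) - 1):
        v = walk[-1]
        walk.append(shuffled[v][cursor[v]])
        cursor[v] += 1
    return "".join(walk)


def recovery_score(
    manifest: SyntheticManifest, annotations: list, tolerance: int = 0
) -> dict[str, dict]:
    """Per-kind precision/recall of annotations against the planted
    ground truth.

    An annotation matches a planted element iff it has the same feature
    kind and covers it to within ``tolerance`` nt (intersection at
    least the planted length minus the tolerance): annotations may
    extend a planted stem outward without penalty.
    """
    by_kind: dict[str, list[PlantedElement]] = {}
    for el in manifest.planted:
        by_kind.setdefault(el.kind, []).append(el)
    ann_by_kind: dict[str, list] = {}
    for ann in annotations:
        ann_by_kind.setdefault(ann.feature_type, []).append(ann)

    def covered(el: PlantedElement, ann) -> bool:
        inter = min(el.end, ann.end) - max(el.start, ann.start)
        return inter >= (el.end - el.start) - tolerance

    report: dict[str, dict] = {}
    for kind, els in by_kind.items():
        anns = ann_by_kind.get(kind, [])
        hits = [el for el in els if any(covered(el, a) for a in anns)]
        matched_anns = [a for a in anns if any(covered(el, a) for el in els)]
        report[kind] = {
            "n_planted": len(els),
            "recall": len(hits) / len(els),
            "precision": (len(matched_anns) / len(anns)) if anns else None,
            "misses": [el.interval for el in els if el not in hits],
        }
    return report
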