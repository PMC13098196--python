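"""ORF finding, CCS-gated start annotation, -1 frameshift fusion, and
genome-architecture classification.

Umbraviruses (UVs) carry four ORFs: replication ORFs 1/2 joined by -1
programmed ribosomal frameshifting, an intergenic region, then
overlapping movement-protein ORFs 3/4 whose shared subgenomic RNA start
is marked by an upstream carmovirus consensus sequence (CCS).
Umbra-like viruses (ULVs) lack the intergenic region: their third ORF,
when present, overlaps the 3' end of ORF2.  These architectural
differences drive :func:`classify_layout`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .motifs import STOP_CODONS, MotifHit


@dataclass
class OrfAnnotation:
    """An AUG-initiated ORF.  ``end`` is one past the stop codon
    (0-based half-open), so ``end - start`` is divisible by 3."""

    orf_id: str
    start: int
    end: int
    frame: int
    ccs_support: MotifHit | None = None

    @property
    def protein_length(self) -> int:
        return (self.end - self.start) // 3 - 1

    @property
    def stop_start(self) -> int:
        return self.end - 3


@dataclass
class StartSuggestion:
    """A re-annotation suggestion: move an ORF start downstream to the
    nearest in-frame AUG that has CCS support."""

    orf_id: str
    old_start: int
    new_start: int
    ccs: MotifHit
    note: str = "downstream in-frame AUG with upstream CCS"


@dataclass
class FusedOrf:
    """ORF1 extended through the -1 frameshift into the ORF2 frame."""

    start: int
    end: int  # one past the ORF2-frame stop codon
    fusion_point: int  # 3' end of the slippery heptamer
    orf1_segment: int  # nt translated in the ORF1 frame
    continuation_segment: int  # nt translated in the -1 frame
    protein_length: int


@dataclass
class GenomeLayout:
    orfs: list[OrfAnnotation]
    fused: FusedOrf | None
    intergenic_after_orf2: bool
    intergenic_length: int
    orf3_overlaps_orf2: bool
    orf3_orf4_relation: str  # embedded | partial_overlap | non_overlapping | absent
    group_call: str  # UV_like | Group1_like | Group2_like | unknown
    rule_trace: list[str] = field(default_factory=list)
    suggestions: list[StartSuggestion] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def find_orfs(sequence: str, min_protein_aa: int = 40) -> list[OrfAnnotation]:
    """All AUG-initiated, stop-terminated ORFs in the three "+" frames.

    Uses the first-AUG-per-stop-segment convention: within each
    stop-to-stop stretch of a frame, only the 5'-most AUG opens an ORF
    (alternative starts are surfaced separately via CCS gating).
    Sorted by start position.  ``orf_id`` is left as "other"; labels
    are assigned by genomic order during layout assembly.
    """
    if min_protein_aa < 1:
        raise ValueError("min_protein_aa must be >= 1")
    n = len(sequence)
    orfs: list[OrfAnnotation] = []
    for frame in range(3):
        pending_aug: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = sequence[pos : pos + 3]
            if codon == "AUG" and pending_aug is None:
                pending_aug = pos
            elif codon in STOP_CODONS:
                if pending_aug is not None:
                    orf = OrfAnnotation("other", pending_aug, pos + 3, frame)
                    if orf.protein_length >= min_protein_aa:
                        orfs.append(orf)
                pending_aug = None
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def gate_starts_on_ccs(
    orfs: list[OrfAnnotation],
    ccs_hits: list[MotifHit],
    sequence: str,
    max_gap: int = 20,
) -> tuple[list[OrfAnnotation], list[StartSuggestion]]:
    """Attach sgRNA-start support (an upstream CCS) to each ORF.

    For each ORF the nearest CCS whose 3' end lies at most ``max_gap``
    nt upstream of the AUG is attached.  When none exists but a
    downstream in-frame AUG does have such support, a re-annotation
    suggestion is emitted (starts are only ever moved downstream).
    """

    def support_for(start: int) -> MotifHit | None:
        best = None
        for hit in ccs_hits:
            if hit.end <= start and start - hit.end <= max_gap:
                if best is None or hit.end > best.end:
                    best = hit
        return best

    suggestions: list[StartSuggestion] = []
    for orf in orfs:
        orf.ccs_support = support_for(orf.start)
        if orf.ccs_support is None:
            for pos in range(orf.start + 3, orf.stop_start, 3):
                if sequence[pos : pos + 3] == "AUG":
                    ccs = support_for(pos)
                    if ccs is not None:
                        suggestions.append(
                            StartSuggestion(orf.orf_id, orf.start, pos, ccs)
                        )
                        break
    return orfs, suggestions


def fuse_orf1_orf2(
    sequence: str, orf1: OrfAnnotation, slippery: MotifHit
) -> FusedOrf | None:
    """Fuse ORF1 into the -1 frame across the slippery site.

    After a -1 slip the ribosome reads the frame one nt behind ORF1's,
    i.e. frame ``(orf1.frame + 2) % 3``.  The fusion exists when the
    -1-frame stop-to-stop segment containing the slippery site extends
    past ORF1's stop codon; returns ``None`` (no continuation) when the
    -1 frame closes before ORF1 does.
    """
    if not (orf1.start <= slippery.start and slippery.end <= orf1.end):
        raise ValueError("slippery site lies outside ORF1")
    n = len(sequence)
    frame2 = (orf1.frame + 2) % 3
    # walk -1-frame codons from the first full codon at/after the
    # slippery site to the next stop
    first = slippery.start + ((frame2 - slippery.start) % 3)
    stop_end = None
    for pos in range(first, n - 2, 3):
        if sequence[pos : pos + 3] in STOP_CODONS:
            stop_end = pos + 3
            break
    if stop_end is None or stop_end <= orf1.end:
        return None
    orf1_segment = slippery.end - orf1.start
    continuation = stop_end - 3 - (slippery.end - 1)
    return FusedOrf(
        start=orf1.start,
        end=stop_end,
        fusion_point=slippery.end,
        orf1_segment=orf1_segment,
        continuation_segment=continuation,
        protein_length=(orf1_segment + continuation) // 3,
    )


def _overlaps(a: OrfAnnotation, b: OrfAnnotation) -> bool:
    return a.start < b.end and b.start < a.end


def classify_layout(
    orf2_end: int,
    downstream: list[OrfAnnotation],
    orf34_spacing: int = 13,
    orf34_spacing_tol: int = 6,
) -> tuple[str, str, bool, list[str], list[str]]:
    """Classify genome architecture from the ORFs downstream of ORF2.

    Returns ``(group_call, orf3_orf4_relation, orf3_overlaps_orf2,
    trace, warnings)``.  The call is a pure function of the listed
    features and the trace reproduces it step by step.
    """
    trace: list[str] = []
    warnings: list[str] = []
    orf3 = downstream[0] if downstream else None
    orf4 = downstream[1] if len(downstream) > 1 else None
    n_down = len(downstream)
    trace.append(f"{n_down} ORF(s) beyond ORF2")

    orf3_overlaps_orf2 = bool(orf3 and orf3.start < orf2_end)
    trace.append(f"ORF3 overlaps ORF2 3' end: {orf3_overlaps_orf2}")
    intergenic = bool(orf3) and orf3.start > orf2_end
    trace.append(f"intergenic region after ORF2: {intergenic}")

    if orf3 is None:
        relation = "absent"
    elif orf4 is None:
        relation = "absent"
    elif orf4.start >= orf3.start and orf4.end <= orf3.end:
        relation = "embedded"
    elif _overlaps(orf3, orf4):
        relation = "partial_overlap"
    else:
        relation = "non_overlapping"
    trace.append(f"ORF3/ORF4 relation: {relation}")

    if intergenic and orf4 is not None and relation in ("embedded", "partial_overlap"):
        spacing = orf4.start - orf3.start
        trace.append(f"ORF4 start {spacing} nt downstream of ORF3 start")
        if abs(spacing - orf34_spacing) <= orf34_spacing_tol:
            trace.append("-> UV_like (intergenic + overlapping ORFs 3/4)")
            return "UV_like", relation, orf3_overlaps_orf2, trace, warnings
        warnings.append(
            f"ORF3/ORF4 start spacing {spacing} outside "
            f"{orf34_spacing}+/-{orf34_spacing_tol}; not called UV_like"
        )
    if relation == "embedded" and orf3_overlaps_orf2:
        trace.append("-> Group2_like (embedded ORF4 within ORF2-overlapping ORF3)")
        return "Group2_like", relation, orf3_overlaps_orf2, trace, warnings
    if orf3_overlaps_orf2 and 1 <= n_down <= 2:
        trace.append("-> Group1_like (ORF3 overlaps ORF2, 1-2 downstream ORFs)")
        return "Group1_like", relation, orf3_overlaps_orf2, trace, warnings
    if n_down <= 1 and (orf3 is None or orf3_overlaps_orf2):
        trace.append("-> Group2_like (<=1 ORF beyond ORF2, overlapping or absent)")
        return "Group2_like", relation, orf3_overlaps_orf2, trace, warnings
    trace.append("-> unknown (no architecture rule matched)")
    return "unknown", relation, orf3_overlaps_orf2, trace, warnings


def build_layout(
    sequence: str,
    orfs: list[OrfAnnotation],
    fused: FusedOrf | None,
    orf1: OrfAnnotation | None,
    orf34_spacing: int = 13,
    orf34_spacing_tol: int = 6,
) -> GenomeLayout:
    """Label ORFs by genomic order after fusion and classify the
    architecture.  ORF1 is the 5'-most qualifying ORF; ORF2 is the
    fused -1-frame extension; ORFs beyond the ORF2 stop are ORF3,
    ORF4, ... in start order."""
    if orf1 is None:
        return GenomeLayout(
            orfs=orfs,
            fused=None,
            intergenic_after_orf2=False,
            intergenic_length=0,
            orf3_overlaps_orf2=False,
            orf3_orf4_relation="absent",
            group_call="unknown",
            rule_trace=["no ORF1 identified"],
        )
    orf1.orf_id = "ORF1"
    orf2_end = fused.end if fused else orf1.end
    downstream = [o for o in orfs if o is not orf1 and o.end > orf2_end and o.start > orf1.end]
    downstream.sort(key=lambda o: o.start)
    for idx, orf in enumerate(downstream, start=3):
        orf.orf_id = f"ORF{idx}" if idx <= 4 else "other"
    group, relation, overlaps2, trace, warnings = classify_layout(
        orf2_end, downstream, orf34_spacing, orf34_spacing_tol
    )
    orf3 = downstream[0] if downstream else None
    gap = (orf3.start - orf2_end) if orf3 else 0
    return GenomeLayout(
        orfs=orfs,
        fused=fused,
        intergenic_after_orf2=gap > 0,
        intergenic_length=max(gap, 0),
        orf3_overlaps_orf2=overlaps2,
        orf3_orf4_relation=relation,
        group_call=group,
        rule_trace=trace,
        suggestions=[],
        warnings=warnings,
    )
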