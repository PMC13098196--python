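"""Composite annotation pipeline: one genome in, one evidence bundle out.

Order of operations: terminus validation (5' CCS gate; 3' H5-Pr-psi1),
ORF finding with CCS gating and -1 frameshift fusion, architecture
classification, recoding-site assembly, CAS/KL location, 3'CITE
classification in the CAS-adjacent region, and the two long-distance
interactions (FSE <-> 3' end; CITE <-> 5' end / sgRNA starts).  Absent
elements are reported as absent — absence is a result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cite import CasCall, CiteCall, classify_cite, find_cas, find_cite_ldi
from .config import RunConfig
from .fold import Hairpin
from .layout import GenomeLayout, build_layout, find_orfs, fuse_orf1_orf2, gate_starts_on_ccs
from .motifs import LdiCall, match_ccs
from .recoding import RecodingSite, annotate_recoding_site
from .sequence_io import Annotation, GenomeRecord
from .termini import FivePrimeReport, ThreePrimeReport, validate_3prime, validate_5prime


@dataclass
class GenomeReport:
    genome: GenomeRecord
    five_prime: FivePrimeReport
    three_prime: ThreePrimeReport
    layout: GenomeLayout
    recoding: RecodingSite | None
    cas: CasCall | None
    cite: CiteCall | None
    cite_ldi: LdiCall | None
    cite_ldi_context: str | None
    sg_starts: list[int] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def annotate_genome(record: GenomeRecord, config: RunConfig = RunConfig()) -> GenomeReport:
    seq = record.sequence
    n = len(seq)
    notes: list[str] = []

    five = validate_5prime(seq, config.ccs_gate_n)
    three = validate_3prime(seq, config)

    orfs = find_orfs(seq, config.min_protein_aa)
    ccs_hits = match_ccs(seq)
    orfs, suggestions = gate_starts_on_ccs(orfs, ccs_hits, seq, config.ccs_max_gap)

    orf1 = orfs[0] if orfs else None
    recoding = None
    fused = None
    if orf1 is not None:
        terminal_hairpins = [h for h in (three.pr, three.h5) if h is not None]
        recoding = annotate_recoding_site(
            seq, orf1, config, three_prime_hairpins=terminal_hairpins or None
        )
        if recoding.slippery is not None:
            fused = fuse_orf1_orf2(seq, orf1, recoding.slippery)
            if fused is None:
                notes.append("no -1-frame continuation past the ORF1 stop")
        else:
            notes.append("no slippery heptamer within the gate upstream of the ORF1 stop")
    layout = build_layout(
        seq, orfs, fused, orf1, config.orf34_spacing, config.orf34_spacing_tol
    )
    layout.suggestions = suggestions

    sg_starts = [
        o.start for o in orfs
        if o.ccs_support is not None and o.orf_id in ("ORF3", "ORF4")
    ]

    cas = None
    cite = None
    cite_ldi = None
    cite_context = None
    utr_start = max((o.end for o in orfs), default=0)
    if fused is not None:
        utr_start = max(utr_start, fused.end)
    utr_end = three.h5.start if three.h5 is not None else max(utr_start, n - 30)
    if utr_end - utr_start > 2 * config.fold.min_stem + 3:
        from .fold import find_hairpins

        utr_hairpins = find_hairpins(seq, (utr_start, utr_end), config.fold)
        cas = find_cas(seq, (utr_start, utr_end), config, hairpins=utr_hairpins)
        # classify over the same full 3' UTR window the CAS search used
        # (region boundaries shift which chains the fold reports, so the
        # CITE evidence must come from one consistent parse); the CAS
        # hairpin itself is masked out by its apical loop
        cite = classify_cite(
            seq,
            (utr_start, utr_end),
            config,
            after_apical=cas.cas.apical_loop[1] if cas.cas is not None else None,
            hairpins=utr_hairpins,
        )
        if cite.cite_type != "unknown":
            cite_ldi, cite_context = find_cite_ldi(seq, cite, sg_starts, config)
    else:
        notes.append("3' UTR too short for CAS/CITE search")

    return GenomeReport(
        genome=record,
        five_prime=five,
        three_prime=three,
        layout=layout,
        recoding=recoding,
        cas=cas,
        cite=cite,
        cite_ldi=cite_ldi,
        cite_ldi_context=cite_context,
        sg_starts=sg_starts,
        notes=notes,
    )


def _hp_ann(gid: str, hp: Hairpin, ftype: str, **attrs) -> Annotation:
    attrs.setdefault("pairs", hp.pair_count)
    return Annotation(gid, ftype, hp.start, hp.end, attrs)


def report_annotations(report: GenomeReport) -> list[Annotation]:
    """Flatten a report into controlled-vocabulary features (0-based
    internally; GFF3 emission converts to 1-based inclusive)."""
    gid = report.genome.id
    anns: list[Annotation] = []
    if report.five_prime.ccs is not None:
        c = report.five_prime.ccs
        anns.append(Annotation(gid, "CCS", c.start, c.end, {"context": "gRNA"}))
    for orf in report.layout.orfs:
        attrs = {"orf_id": orf.orf_id, "frame": orf.frame}
        if orf.ccs_support is not None:
            attrs["ccs_support"] = f"{orf.ccs_support.start + 1}-{orf.ccs_support.end}"
            if orf.orf_id in ("ORF3", "ORF4"):
                c = orf.ccs_support
                anns.append(Annotation(gid, "CCS", c.start, c.end, {"context": "sgRNA"}))
        anns.append(Annotation(gid, "ORF", orf.start, orf.end, attrs))
    rec = report.recoding
    if rec is not None:
        if rec.slippery is not None:
            anns.append(
                Annotation(
                    gid, "slippery_site", rec.slippery.start, rec.slippery.end,
                    {"offset": rec.slippery_offset, "motif": rec.slippery.matched},
                )
            )
        for hp, ftype in ((rec.ha, "HA"), (rec.fse, "FSE"), (rec.hb, "HB"), (rec.hc, "HC")):
            if hp is not None:
                anns.append(_hp_ann(gid, hp, ftype))
        for pk, ftype in ((rec.pk1, "PK1"), (rec.pk2, "PK2")):
            if pk is not None:
                lo, hi = pk.partner_interval
                anns.append(
                    Annotation(
                        gid, ftype, lo, hi,
                        {"loop": f"{pk.loop_interval[0] + 1}-{pk.loop_interval[1]}"},
                    )
                )
        if rec.ca is not None:
            anns.append(
                Annotation(
                    gid, "CA", rec.ca.start, rec.ca.end,
                    {"placement": rec.ca_placement, "mismatches": rec.ca.mismatches},
                )
            )
        if rec.fse_ldi is not None:
            lo, hi = rec.fse_ldi.region_b
            anns.append(
                Annotation(
                    gid, "LDI", lo, hi,
                    {
                        "role": "FSE_3p",
                        "source": rec.fse_ldi_source or "",
                        "donor": f"{rec.fse_ldi.region_a[0] + 1}-{rec.fse_ldi.region_a[1]}",
                    },
                )
            )
    if report.three_prime.h5 is not None:
        anns.append(
            _hp_ann(
                gid, report.three_prime.h5, "H5",
                conformation=report.three_prime.h5_conformation,
            )
        )
    if report.three_prime.pr is not None:
        anns.append(_hp_ann(gid, report.three_prime.pr, "Pr"))
    if report.three_prime.psi1_partner is not None and report.three_prime.terminal_motif:
        n = report.genome.length
        anns.append(
            Annotation(
                gid, "PSI1", n - len(report.three_prime.terminal_motif), n,
                {
                    "pairs": report.three_prime.psi1_pairs,
                    "partner": f"{report.three_prime.psi1_partner[0] + 1}-"
                    f"{report.three_prime.psi1_partner[1]}",
                },
            )
        )
    if report.cas is not None and report.cas.cas is not None:
        anns.append(_hp_ann(gid, report.cas.cas, "CAS"))
        if report.cas.kl_pair is not None:
            h1, h2, duplex = report.cas.kl_pair
            anns.append(_hp_ann(gid, h1, "KL_hairpin", duplex=duplex.length))
            anns.append(_hp_ann(gid, h2, "KL_hairpin", duplex=duplex.length))
    if report.cite is not None and report.cite.cite_type != "unknown" and report.cite.location:
        lo, hi = report.cite.location
        anns.append(
            Annotation(
                gid, "CITE", lo, hi,
                {
                    "cite_type": report.cite.cite_type,
                    "branched": report.cite.branched,
                    "gnra_capped": report.cite.gnra_capped,
                },
            )
        )
    if report.cite_ldi is not None:
        lo, hi = report.cite_ldi.region_a
        anns.append(
            Annotation(
                gid, "LDI", lo, hi,
                {
                    "role": "CITE_5p",
                    "context": report.cite_ldi_context or "",
                    "acceptor": f"{report.cite_ldi.region_b[0] + 1}-{report.cite_ldi.region_b[1]}",
                },
            )
        )
    return anns


def report_to_dict(report: GenomeReport) -> dict:
    """JSON-ready evidence bundle (1-based inclusive coordinates)."""

    def iv(pair) -> list[int] | None:
        if pair is None:
            return None
        return [pair[0] + 1, pair[1]]

    rec = report.recoding
    t3 = report.three_prime
    return {
        "genome": {"id": report.genome.id, "length": report.genome.length},
        "five_prime": {
            "ccs": iv((report.five_prime.ccs.start, report.five_prime.ccs.end))
            if report.five_prime.ccs
            else None,
            "truncated": report.five_prime.truncated_call,
        },
        "three_prime": {
            "terminal_motif": t3.terminal_motif,
            "h5": iv(t3.h5.interval) if t3.h5 else None,
            "h5_conformation": t3.h5_conformation,
            "pr": iv(t3.pr.interval) if t3.pr else None,
            "psi1_pairs": t3.psi1_pairs,
            "truncated": t3.truncated_call,
            "warnings": t3.warnings,
        },
        "layout": {
            "orfs": [
                {
                    "orf_id": o.orf_id,
                    "interval": iv((o.start, o.end)),
                    "frame": o.frame,
                    "protein_length": o.protein_length,
                    "ccs_support": iv((o.ccs_support.start, o.ccs_support.end))
                    if o.ccs_support
                    else None,
                }
                for o in report.layout.orfs
            ],
            "fused_orf12": iv((report.layout.fused.start, report.layout.fused.end))
            if report.layout.fused
            else None,
            "intergenic_after_orf2": report.layout.intergenic_after_orf2,
            "orf3_orf4_relation": report.layout.orf3_orf4_relation,
            "group_call": report.layout.group_call,
            "rule_trace": report.layout.rule_trace,
            "suggestions": [
                {"orf": s.orf_id, "old_start": s.old_start + 1, "new_start": s.new_start + 1}
                for s in report.layout.suggestions
            ],
        },
        "recoding": None
        if rec is None
        else {
            "slippery": {
                "interval": iv((rec.slippery.start, rec.slippery.end)),
                "motif": rec.slippery.matched,
                "offset": rec.slippery_offset,
            }
            if rec.slippery
            else None,
            "elements": {
                name: iv(hp.interval) if hp else None
                for name, hp in (("HA", rec.ha), ("FSE", rec.fse), ("HB", rec.hb), ("HC", rec.hc))
            },
            "pk1": iv(rec.pk1.partner_interval) if rec.pk1 else None,
            "pk2": iv(rec.pk2.partner_interval) if rec.pk2 else None,
            "ca": iv((rec.ca.start, rec.ca.end)) if rec.ca else None,
            "ca_placement": rec.ca_placement,
            "fse_ldi": {
                "donor": iv(rec.fse_ldi.region_a),
                "acceptor": iv(rec.fse_ldi.region_b),
                "length": rec.fse_ldi.length,
                "source": rec.fse_ldi_source,
            }
            if rec.fse_ldi
            else None,
            "conformance": rec.conformance,
        },
        "cas": iv(report.cas.cas.interval) if report.cas and report.cas.cas else None,
        "kl_pair": (
            [iv(report.cas.kl_pair[0].interval), iv(report.cas.kl_pair[1].interval)]
            if report.cas and report.cas.kl_pair
            else None
        ),
        "cite": None
        if report.cite is None
        else {
            "cite_type": report.cite.cite_type,
            "location": iv(report.cite.location) if report.cite.location else None,
            "branched": report.cite.branched,
            "gnra_capped": report.cite.gnra_capped,
        },
        "cite_ldi": {
            "cite_loop": iv(report.cite_ldi.region_a),
            "five_prime": iv(report.cite_ldi.region_b),
            "length": report.cite_ldi.length,
            "context": report.cite_ldi_context,
        }
        if report.cite_ldi
        else None,
        "notes": report.notes,
    }


ELEMENT_TABLE_COLUMNS = [
    "genome",
    "group_call",
    "psi1",
    "slippery",
    "offset",
    "pk1",
    "pk2",
    "ca_placement",
    "cite_type",
    "ldi_pair",
    "cas",
    "cas_kl",
    "truncated_5p",
    "truncated_3p",
]


def report_table_row(report: GenomeReport) -> dict:
    """One TSV row per genome, mirroring the published element tables."""
    rec = report.recoding
    ldi = report.cite_ldi
    return {
        "genome": report.genome.id,
        "group_call": report.layout.group_call,
        "psi1": "yes" if report.three_prime.psi1_partner else "no",
        "slippery": rec.slippery.matched if rec and rec.slippery else "",
        "offset": rec.slippery_offset if rec and rec.slippery else "",
        "pk1": f"{rec.pk1.duplex.duplex_a}-{rec.pk1.duplex.duplex_b}" if rec and rec.pk1 else "None",
        "pk2": f"{rec.pk2.duplex.duplex_a}-{rec.pk2.duplex.duplex_b}" if rec and rec.pk2 else "None",
        "ca_placement": rec.ca_placement if rec else "none",
        "cite_type": report.cite.cite_type if report.cite else "unknown",
        "ldi_pair": f"{ldi.duplex_a}-{ldi.duplex_b}" if ldi else "",
        "cas": "yes" if report.cas and report.cas.cas else "no",
        "cas_kl": "yes" if report.cas and report.cas.kl_pair else "no",
        "truncated_5p": report.five_prime.truncated_call,
        "truncated_3p": report.three_prime.truncated_call,
    }
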