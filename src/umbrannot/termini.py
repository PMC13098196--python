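"""5'/3' genome-completeness validation.

A complete genome 5' end begins with a carmovirus consensus sequence
(CCS) within the first few nt.  A complete 3' end carries, in order, a
hairpin H5 containing the 5'-GGGC psi1 partner, an intervening terminal
hairpin Pr, and 3'-terminal residues (usually GCCC-OH) that pair with
the GGGC segment to form the psi1 pseudoknot.  Sequences missing the
CCS, the terminal cytidylates, or psi1 are flagged as likely truncated
— reported database entries frequently lack one or two terminal
residues that are present in planta.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .config import RunConfig
from .fold import Hairpin, find_hairpins
from .motifs import MotifHit, match_ccs, revcomp

TERMINAL_MOTIF_RE = re.compile(r"G?C{2,3}$")


@dataclass
class FivePrimeReport:
    ccs: MotifHit | None
    truncated_call: bool


@dataclass
class ThreePrimeReport:
    terminal_motif: str
    h5: Hairpin | None
    h5_conformation: str  # UV_apical | tombus_internal | GULV_asymmetric | other | none
    pr: Hairpin | None
    psi1_partner: tuple[int, int] | None  # location of the GGGC segment in H5
    psi1_pairs: int
    truncated_call: bool
    warnings: list[str] = field(default_factory=list)


def validate_5prime(sequence: str, gate_n: int = 10) -> FivePrimeReport:
    """Truncation call for the 5' end: a CCS must *begin* within the
    first ``gate_n`` nt."""
    hits = [h for h in match_ccs(sequence, (0, min(len(sequence), gate_n + 13))) if h.start < gate_n]
    return FivePrimeReport(ccs=hits[0] if hits else None, truncated_call=not hits)


def classify_h5(h5: Hairpin, partner: tuple[int, int]) -> str:
    """Conformation of H5 from where its GGGC psi1 partner sits.

    ``UV_apical``: GGGC on the 5' side of the apical loop (the
    UV / Group 2 arrangement, unique within the family).
    ``tombus_internal``: GGGC on the 3' side of an internal loop with
    residues opposing it (the tombusvirus-like arrangement).
    ``GULV_asymmetric``: GGGC in an internal loop with an empty
    opposing side (the grapevine-isolate variant).  ``other``
    otherwise (e.g. GGGC paired within the stem).
    """
    lo, hi = partner
    a_lo, a_hi = h5.apical_loop
    if a_lo <= lo and hi <= a_hi:
        midpoint = (a_lo + a_hi) / 2
        if lo - a_lo <= a_hi - hi or lo < midpoint:
            return "UV_apical"
        return "other"
    for side5, side3 in h5.internal_loops:
        if side3[0] <= lo and hi <= side3[1]:
            return "tombus_internal" if side5[1] > side5[0] else "GULV_asymmetric"
        if side5[0] <= lo and hi <= side5[1]:
            return "other"
    return "other"


def validate_3prime(sequence: str, config: RunConfig = RunConfig()) -> ThreePrimeReport:
    """Completeness of the 3' terminus: terminal motif, H5, Pr, psi1.

    The terminal motif is the longest 3'-terminal match of G?C{2,3}.
    H5 is the 3'-most GGGC-containing hairpin in the terminal window
    that still leaves room for an intervening Pr hairpin; psi1 is the
    duplex between the terminal motif and the GGGC segment (minimum
    ``psi1_min_pairs`` pairs, warned below 4).  The truncation call is
    raised when fewer than three terminal cytidylates remain or psi1
    cannot form.
    """
    n = len(sequence)
    warnings: list[str] = []
    m = TERMINAL_MOTIF_RE.search(sequence)
    terminal = m.group(0) if m else ""
    c_run = len(sequence) - len(sequence.rstrip("C"))

    window = (max(0, n - config.three_prime_window), n)
    hairpins = find_hairpins(sequence, window, config.fold)

    def ggg_in_loop(hp) -> int | None:
        # GGGC must be presentable for pairing, i.e. in a loop
        for lo, hi in hp.loop_intervals():
            idx = sequence.find("GGGC", max(lo - 0, hp.start), hi)
            if idx >= 0 and idx + 4 <= hi:
                return idx
        return None

    ggg_hairpins = []
    for hp in hairpins:
        idx = ggg_in_loop(hp)
        if idx is not None:
            ggg_hairpins.append((hp, idx))
    ggg_hairpins.sort(key=lambda t: t[0].end)

    # Joint H5/Pr selection: among GGGC-loop hairpins, prefer the one
    # followed by the best intervening terminal (Pr) hairpin — a merged
    # chain that swallows Pr leaves only junk behind it and loses.  The
    # terminal residues themselves may be touched by chance stem
    # extension, so only Pr's 5' boundary is enforced strictly.
    h5 = None
    partner_idx = None
    pr = None
    best_key = None
    for hp, idx in ggg_hairpins:
        following = [h for h in hairpins if h.start >= hp.end]
        if not following:
            continue
        cand_pr = max(following, key=lambda h: (h.score, h.pair_count, h.end))
        key = (cand_pr.score, hp.score, hp.end)
        if best_key is None or key > best_key:
            best_key = key
            h5, partner_idx, pr = hp, idx, cand_pr
    if h5 is None and ggg_hairpins:
        h5, partner_idx = ggg_hairpins[-1]

    psi1_pairs = 0
    partner = None
    if h5 is not None and terminal:
        partner = (partner_idx, partner_idx + 4)
        # the terminal motif pairs with the matching stretch of GGGC
        want = revcomp(terminal)
        region = sequence[max(h5.start, partner_idx - 1) : partner_idx + 5]
        if want in region:
            psi1_pairs = len(terminal)
        elif len(terminal) > 3 and revcomp(terminal[-3:]) in region:
            psi1_pairs = 3
    psi1_ok = psi1_pairs >= config.psi1_min_pairs
    if 0 < psi1_pairs < 4 and psi1_ok:
        warnings.append(f"psi1 duplex of only {psi1_pairs} pairs")

    conformation = "none"
    if h5 is not None and partner is not None:
        conformation = classify_h5(h5, partner)

    truncated = c_run < 3 or not psi1_ok
    if c_run < 3:
        warnings.append(
            f"only {c_run} terminal cytidylate(s); a complete terminus ends ...CCC-OH"
        )
    return ThreePrimeReport(
        terminal_motif=terminal,
        h5=h5,
        h5_conformation=conformation,
        pr=pr,
        psi1_partner=partner if psi1_ok else None,
        psi1_pairs=psi1_pairs,
        truncated_call=truncated,
        warnings=warnings,
    )
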