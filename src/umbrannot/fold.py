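"""Hairpin and pseudoknot calling by constrained base-pair maximization.

The curated RNA elements this package annotates (HA/FSE/HB/HC at the
frameshift site, H5/Pr at the 3' terminus, CAS, kissing-loop and CITE
hairpins) are compact stem-loops.  They are recovered here with a
deterministic, oracle-checkable combinatorial criterion — Nussinov-style
base-pair maximization under explicit structural caps — rather than
free-energy minimization: every decision (minimum apical loop of 3 nt,
bulge/internal-loop caps, span cap, lexicographic tie-breaks) is stated
and reproducible, and small instances can be verified by exhaustive
enumeration.

A *hairpin* is a single inward-nested chain of Watson-Crick (optionally
G:U) pairs with at most ``max_bulge`` unpaired nt per side between
consecutive pairs, closed by an apical loop of 3..``max_loop`` nt.  A
*pseudoknot* is a duplex between a hairpin's loop and a nearby
downstream window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .motifs import LdiCall, find_longest_duplex, pairs_wc


@dataclass(frozen=True)
class FoldParams:
    """Structural caps and scoring for hairpin search.

    Defaults: stems of at least 3 pairs, apical loops of 3-12 nt, at
    most 6 unpaired nt per internal-loop side, hairpins spanning at most
    80 nt, canonical pairs only.

    A hairpin's score is its pair count minus, for every internal loop
    or bulge event, ``loop_penalty`` plus one per six unpaired loop
    nucleotides; ranking is by this score, not by raw pair count.
    Under the bulge caps above, raw pair maximization lets sparse
    chains of one-or-two-pair runs strung together by internal loops
    dominate any random sequence, which no curator would draw as a
    hairpin; a size-aware per-loop cost keeps the criterion
    combinatorial and exactly checkable while favouring the compact
    stems the annotated elements actually are.  ``loop_penalty = 0``
    disables all loop costs (pure constrained pair maximization).
    """

    min_stem: int = 3
    max_loop: int = 12
    max_bulge: int = 6
    max_span: int = 80
    allow_gu: bool = False
    loop_penalty: int = 2
    #: at most this many internal-loop/bulge events per hairpin; curated
    #: stem-loops have one or two, whereas chance chains in random
    #: sequence need many
    max_internal_loops: int = 2


@dataclass
class Hairpin:
    """A stem-loop: outer interval, pair chain, loops, pair count."""

    start: int  # 5' arm start (0-based)
    end: int  # one past the 3' arm end (half-open)
    stem_pairs: list[tuple[int, int]]  # outermost first
    apical_loop: tuple[int, int]
    internal_loops: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)
    score: int = 0  # pair count minus loop penalties

    @property
    def pair_count(self) -> int:
        return len(self.stem_pairs)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def apical_loop_padded(self, pad: int = 1) -> tuple[int, int]:
        """Apical loop widened by ``pad`` nt into the closing stem.

        Loop-closing pairs breathe; duplex searches that read the loop
        therefore include one stem residue on each side so that a
        partner overlapping the loop boundary is not missed.
        """
        lo, hi = self.apical_loop
        return (max(self.start, lo - pad), min(self.end, hi + pad))

    def loop_intervals(self, pad: int = 0) -> list[tuple[int, int]]:
        """Apical loop (optionally padded) plus the non-empty
        internal-loop sides."""
        loops = [self.apical_loop_padded(pad) if pad else self.apical_loop]
        for side5, side3 in self.internal_loops:
            if side5[1] > side5[0]:
                loops.append(side5)
            if side3[1] > side3[0]:
                loops.append(side3)
        return loops


@dataclass
class Pseudoknot:
    """A loop <-> downstream duplex emanating from a hairpin loop."""

    loop_interval: tuple[int, int]
    partner_interval: tuple[int, int]
    duplex: LdiCall
    kind: str = "PK"


def _stem_chain_dp(
    sequence: str, region: tuple[int, int], params: FoldParams
) -> tuple[dict, dict]:
    """Best inward stem chain anchored at each pairable (i, j).

    ``best[(i, j)][e]`` is a ``(score, pairs)`` tuple for the best
    hairpin whose outermost pair is (i, j) using at most ``e`` internal
    loop/bulge events — score is pairs minus the per-event cost, and
    ties on score are broken toward more pairs; ``nxt[(i, j)][e]`` is
    the chosen inward step ``(i2, j2, e2)`` (None when the chain closes
    with the apical loop).  Remaining ties prefer the smallest inward
    step (stacked pairs first), which makes the traced structure
    deterministic.
    """
    lo, hi = region
    step = params.max_bulge + 1
    penalty = params.loop_penalty
    cap = params.max_internal_loops
    max_span = params.max_span
    best: dict[tuple[int, int], list] = {}
    nxt: dict[tuple[int, int], list] = {}
    # states keyed by packed integer for speed; the per-(di, dj) loop
    # cost is precomputed once
    width = hi - lo
    packed: dict[int, list] = {}
    cost_of = {
        (di, dj): _step_cost(di, dj, penalty)
        for di in range(1, step + 1)
        for dj in range(1, step + 1)
    }
    steps = sorted(cost_of, key=lambda dd: (dd[0], dd[1]))  # di asc, dj asc

    # iterate by increasing inner width so inner states are ready
    pairable = [
        (i, j)
        for i in range(lo, hi)
        for j in range(i + 4, min(hi, i + max_span))
        if pairs_wc(sequence[i], sequence[j], params.allow_gu)
    ]
    pairable.sort(key=lambda ij: ij[1] - ij[0])
    get = packed.get
    for i, j in pairable:
        loop_len = j - i - 1
        base = (1, 1) if 3 <= loop_len <= params.max_loop else None
        # probe the inward steps once, preserving (di asc, dj asc) order
        found = []
        for di, dj in steps:
            i2 = i + di
            j2 = j - dj
            if j2 - i2 < 4:
                continue
            sub_list = get((i2 - lo) * width + (j2 - lo))
            if sub_list is not None:
                found.append((i2, j2, di == 1 and dj == 1, cost_of[(di, dj)], sub_list))
        if base is None and not found:
            continue
        vals: list = [None] * (cap + 1)
        chs: list = [None] * (cap + 1)
        for e in range(cap + 1):
            value = base
            choice = None
            for i2, j2, stacked, cost, sub_list in found:
                if stacked:
                    sub, e2, c = sub_list[e], e, 0
                elif e > 0:
                    sub, e2, c = sub_list[e - 1], e - 1, cost
                else:
                    continue
                if sub is not None:
                    cand = (sub[0] + 1 - c, sub[1] + 1)
                    if value is None or cand > value:
                        value = cand
                        choice = (i2, j2, e2)
            vals[e] = value
            chs[e] = choice
        if any(v is not None for v in vals):
            key = (i, j)
            best[key] = vals
            nxt[key] = chs
            packed[(i - lo) * width + (j - lo)] = vals
    return best, nxt


def _step_cost(di: int, dj: int, penalty: int) -> int:
    """Cost of one non-stacked step: the loop penalty plus a mild size
    term (one per six unpaired nucleotides, rounded up) — zero when
    penalties are off.  The size term is deliberately gentle so that one
    large designed internal loop is cheaper than two small ones plus an
    isolated bridging pair."""
    if penalty == 0:
        return 0
    unpaired = (di - 1) + (dj - 1)
    return penalty + (unpaired + 5) // 6


def _trace_chain(nxt: dict, head: tuple[int, int], e: int) -> list[tuple[int, int]]:
    chain = [head]
    cur = nxt[head][e]
    while cur is not None:
        i2, j2, e2 = cur
        chain.append((i2, j2))
        cur = nxt[(i2, j2)][e2]
    return chain


def _hairpin_from_chain(chain: list[tuple[int, int]], loop_penalty: int) -> Hairpin:
    i0, j0 = chain[0]
    ik, jk = chain[-1]
    internal = []
    cost = 0
    for (a, b), (c, d) in zip(chain, chain[1:]):
        if c - a > 1 or b - d > 1:
            internal.append(((a + 1, c), (d + 1, b)))
            cost += _step_cost(c - a, b - d, loop_penalty)
    return Hairpin(
        start=i0,
        end=j0 + 1,
        stem_pairs=chain,
        apical_loop=(ik + 1, jk),
        internal_loops=internal,
        score=len(chain) - cost,
    )


def find_hairpins(
    sequence: str, region: tuple[int, int] | None = None, params: FoldParams = FoldParams()
) -> list[Hairpin]:
    """All maximal hairpins in a region, best first.

    For every pairable anchor the single best (highest-scoring) stem
    chain is traced; anchors whose chain is a sub-stem of another
    reported chain are dropped (maximality).  Ranking is by score
    (descending), then pair count (descending), then span (ascending),
    then 5' position — fully deterministic, no randomness anywhere in
    folding.

    A region shorter than ``2*min_stem + 3`` cannot hold a qualifying
    hairpin and yields an empty list.
    """
    if region is None:
        region = (0, len(sequence))
    lo, hi = region
    if hi - lo < 2 * params.min_stem + 3:
        return []
    best, nxt = _stem_chain_dp(sequence, region, params)
    cap = params.max_internal_loops
    heads = [
        ij for ij, v in best.items() if v[cap] is not None and v[cap][1] >= params.min_stem
    ]
    # maximality with a score guard: a sub-stem is hidden by a chain
    # that extends it only if that chain scores at least as well —
    # otherwise the compact stem is reported in its own right
    absorbed_score: dict[tuple[int, int], int] = {}
    chains = {}
    for head in heads:
        chain = _trace_chain(nxt, head, cap)
        chains[head] = chain
        head_score = best[head][cap][0]
        for p in chain[1:]:
            if absorbed_score.get(p, -(10 ** 9)) < head_score:
                absorbed_score[p] = head_score
    hairpins = [
        _hairpin_from_chain(chains[head], params.loop_penalty)
        for head in heads
        if head not in absorbed_score or best[head][cap][0] > absorbed_score[head]
    ]
    hairpins.sort(key=lambda h: (-h.score, -h.pair_count, h.span, h.start))
    return hairpins


def best_hairpin_pair_count(
    sequence: str, region: tuple[int, int] | None = None, params: FoldParams = FoldParams()
) -> int:
    """Maximum raw pair count over all hairpins in the region (0 if
    none); computed with the loop penalty disabled so it is a pure
    constrained pair maximization (the event cap still applies),
    checkable by exhaustive enumeration."""
    if region is None:
        region = (0, len(sequence))
    from dataclasses import replace

    best, _ = _stem_chain_dp(sequence, region, replace(params, loop_penalty=0))
    cap = params.max_internal_loops
    return max(
        (v[cap][1] for v in best.values() if v[cap] is not None), default=0
    )


def max_nested_pairs(sequence: str, min_loop: int = 3, allow_gu: bool = False) -> int:
    """Maximum number of non-crossing pairs (Nussinov pair maximization).

    Bottom-up interval DP with a minimum apical loop of ``min_loop`` nt.
    Used as the general pair-maximization criterion; on small sequences
    it is checked against exhaustive enumeration of nested pairings.
    """
    n = len(sequence)
    if n == 0:
        return 0
    dp = [[0] * n for _ in range(n)]
    for width in range(min_loop + 1, n):
        for i in range(n - width):
            j = i + width
            best = dp[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if pairs_wc(sequence[i], sequence[k], allow_gu):
                    inner = dp[i + 1][k - 1] if k - 1 > i + 1 else 0
                    right = dp[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            dp[i][j] = best
    return dp[0][n - 1]


def find_pseudoknot(
    sequence: str,
    loop: tuple[int, int],
    search_from: int | None = None,
    search_window: int = 50,
    min_len: int = 4,
    max_len: int = 8,
    allow_gu: bool = False,
    kind: str = "PK",
) -> Pseudoknot | None:
    """Call a pseudoknot: the longest duplex between a hairpin-loop
    substring and a window downstream of the hairpin.

    ``search_from`` anchors the downstream window (typically the 3' end
    of the hairpin that carries the loop; defaults to the loop end).
    Ties are broken in favour of the most-5' partner.  Returns ``None``
    when no duplex of at least ``min_len`` pairs exists.
    """
    if search_from is None:
        search_from = loop[1]
    window = (search_from, min(len(sequence), search_from + search_window))
    if window[1] <= window[0]:
        return None
    duplex = find_longest_duplex(
        sequence, loop, window, min_len=min_len, max_len=max_len, allow_gu=allow_gu
    )
    if duplex is None:
        return None
    return Pseudoknot(
        loop_interval=duplex.region_a,
        partner_interval=duplex.region_b,
        duplex=duplex,
        kind=kind,
    )


def dot_bracket(
    length: int,
    hairpins: list[Hairpin],
    pseudoknots: list[Pseudoknot] | None = None,
    offset: int = 0,
) -> str:
    """Render hairpin pairs as ``()`` and pseudoknot duplexes as a
    ``[]`` layer over a region of ``length`` nt starting at ``offset``."""
    chars = ["."] * length
    for hp in hairpins:
        for i, j in hp.stem_pairs:
            if 0 <= i - offset < length and 0 <= j - offset < length:
                chars[i - offset] = "("
                chars[j - offset] = ")"
    for pk in pseudoknots or []:
        (a_lo, a_hi), (b_lo, b_hi) = pk.loop_interval, pk.partner_interval
        for i in range(a_lo, a_hi):
            if 0 <= i - offset < length:
                chars[i - offset] = "["
        for j in range(b_lo, b_hi):
            if 0 <= j - offset < length:
                chars[j - offset] = "]"
    return "".join(chars)
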