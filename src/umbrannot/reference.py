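"""Naive reference implementations used only for validation.

These are deliberately simple, exhaustive procedures against which the
production algorithms in :mod:`umbrannot.fold` are checked on small
inputs.  Nothing in the annotation pipeline calls this module.
"""

from __future__ import annotations

from .fold import FoldParams, Hairpin
from .motifs import pairs_wc


def exhaustive_max_nested_pairs(
    sequence: str, min_loop: int = 3, allow_gu: bool = False
) -> int:
    """Maximum nested (non-crossing) pair count by explicit enumeration.

    Depth-first search over per-position decisions (leave position i
    unpaired, or pair it with each admissible k), carrying the list of
    remaining independent segments.  An admissible upper bound — per
    segment, the smaller of the packing bound (m - min_loop) // 2 and
    the composition bound min(#A, #U) + min(#G, #C) — prunes branches
    that cannot beat the incumbent.  The search is exact: a branch is
    cut only when the bound proves it cannot improve on the best
    structure already enumerated.
    """
    n = len(sequence)
    if n == 0:
        return 0

    def upper(i: int, j: int) -> int:
        m = j - i + 1
        if m < min_loop + 2:
            return 0
        pack = (m - min_loop) // 2
        a = u = g = c = 0
        for ch in sequence[i : j + 1]:
            if ch == "A":
                a += 1
            elif ch == "U":
                u += 1
            elif ch == "G":
                g += 1
            else:
                c += 1
        if allow_gu:
            comp = min(a + g, u + c)  # loose but valid with wobble
        else:
            comp = min(a, u) + min(g, c)
        return min(pack, comp)

    best = 0
    # stack items: (segments, count) where segments is a tuple of (i, j)
    stack = [(((0, n - 1),), 0)]
    while stack:
        segments, count = stack.pop()
        if count > best:
            best = count
        bound = count + sum(upper(i, j) for i, j in segments)
        if bound <= best:
            continue
        # expand the first segment still capable of holding a pair
        rest = list(segments)
        head = None
        while rest:
            i, j = rest.pop(0)
            if j - i >= min_loop + 1:
                head = (i, j)
                break
        if head is None:
            continue
        i, j = head
        remainder = tuple(rest)
        # decision: i unpaired
        stack.append((((i + 1, j),) + remainder, count))
        # decision: i paired with k
        for k in range(i + min_loop + 1, j + 1):
            if pairs_wc(sequence[i], sequence[k], allow_gu):
                new_segments = []
                if k - 1 - (i + 1) >= min_loop + 1 - 1:
                    new_segments.append((i + 1, k - 1))
                if j - (k + 1) >= 0:
                    new_segments.append((k + 1, j))
                stack.append((tuple(new_segments) + remainder, count + 1))
    return best


def exhaustive_best_hairpin_pairs(
    sequence: str, region: tuple[int, int] | None = None, params: FoldParams = FoldParams()
) -> int:
    """Best hairpin pair count by enumerating every admissible stem chain.

    Recursively extends each anchor pair inward through all bulge /
    internal-loop steps of at most ``max_bulge`` nt per side (at most
    ``max_internal_loops`` non-stacked steps in total), closing only on
    an apical loop of 3..``max_loop`` nt.  No memoisation, no ranking
    shortcuts — pure enumeration for use on short windows.
    """
    if region is None:
        region = (0, len(sequence))
    lo, hi = region

    def extend(i: int, j: int, events: int) -> int | None:
        best_here = None
        if 3 <= j - i - 1 <= params.max_loop:
            best_here = 1
        for di in range(1, params.max_bulge + 2):
            for dj in range(1, params.max_bulge + 2):
                i2, j2 = i + di, j - dj
                if j2 - i2 < 4:
                    continue
                stacked = di == 1 and dj == 1
                if not stacked and events == 0:
                    continue
                if not pairs_wc(sequence[i2], sequence[j2], params.allow_gu):
                    continue
                sub = extend(i2, j2, events if stacked else events - 1)
                if sub is not None and (best_here is None or 1 + sub > best_here):
                    best_here = 1 + sub
        return best_here

    best = 0
    for i in range(lo, hi):
        for j in range(i + 4, min(hi, i + params.max_span)):
            if pairs_wc(sequence[i], sequence[j], params.allow_gu):
                value = extend(i, j, params.max_internal_loops)
                if value is not None and value > best:
                    best = value
    return best


def validate_hairpin(sequence: str, hairpin: Hairpin, params: FoldParams) -> bool:
    """Independently check that a reported hairpin satisfies every
    structural constraint: complementary nested pairs, step caps, loop
    size, span, and minimum stem."""
    chain = hairpin.stem_pairs
    if len(chain) < params.min_stem:
        return False
    if hairpin.span > params.max_span:
        return False
    for i, j in chain:
        if not pairs_wc(sequence[i], sequence[j], params.allow_gu):
            return False
    events = 0
    for (a, b), (c, d) in zip(chain, chain[1:]):
        if not (a < c <= a + params.max_bulge + 1):
            return False
        if not (d < b and b - d <= params.max_bulge + 1):
            return False
        if c - a > 1 or b - d > 1:
            events += 1
    if events > params.max_internal_loops:
        return False
    ik, jk = chain[-1]
    loop = jk - ik - 1
    return 3 <= loop <= params.max_loop
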