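"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: direct scans
and enumerations against which the implementation is checked.
"""

import itertools

from scaffcheck.pairs import ContactSet


def naive_spanning_count(contacts: ContactSet, scaffold: str, position: int, window: int) -> int:
    """O(n) scan over every pair, both endpoint orders."""
    length = contacts.references[scaffold]
    lo, hi = max(0, position - window), min(length, position + window)
    n = 0
    for p in contacts:
        ends = [(p.ref1, p.pos1), (p.ref2, p.pos2)]
        for (ra, pa), (rb, pb) in (tuple(ends), tuple(reversed(ends))):
            if ra == scaffold and rb == scaffold and lo <= pa < position <= pb < hi:
                n += 1
                break
    return n


def _oriented_errors(d: tuple[int, ...]) -> tuple[int, int]:
    """Switch/mismatch counts for one orientation, by direct run grouping.

    Isolated disagreeing site: one mismatch. Disagreeing run of >=2: one
    switch per change-point with an agreeing neighbor (interior run: two,
    edge-touching run: one, whole-block run: zero).
    """
    n = len(d)
    sw = mm = 0
    pos = 0
    for val, grp in itertools.groupby(d):
        ln = len(list(grp))
        if val == 1:
            if ln == 1:
                mm += 1
            else:
                sw += (1 if pos > 0 else 0) + (1 if pos + ln < n else 0)
        pos += ln
    return sw, mm


def oracle_block_errors(d: tuple[int, ...]) -> tuple[int, int]:
    """Best-orientation switch/mismatch counts for a disagreement pattern.

    Enumerates both global orientations; ties go to the orientation that
    agrees at the first site.
    """
    c0 = _oriented_errors(d)
    c1 = _oriented_errors(tuple(1 - x for x in d))
    if sum(c0) < sum(c1):
        return c0
    if sum(c1) < sum(c0):
        return c1
    return c0 if d and d[0] == 0 else c1
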