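"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a result from first principles with code that
shares nothing with the library implementation, so agreement is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import math


def pic_double_loop(freqs: list[float]) -> float:
    """Botstein PIC via the literal double sum over ordered pairs."""
    total = 1.0
    for p in freqs:
        total -= p * p
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            total -= 2.0 * freqs[i] ** 2 * freqs[j] ** 2
    return total


def nei_distance_single_locus(px: dict, py: dict) -> float:
    """Nei standard distance for one locus, straight from the formula."""
    jx = sum(v * v for v in px.values())
    jy = sum(v * v for v in py.values())
    jxy = sum(px[a] * py.get(a, 0.0) for a in px)
    if jxy == 0.0:
        return math.inf
    return -math.log(jxy / math.sqrt(jx * jy))


def _primitive(motif: str) -> bool:
    for d in range(1, len(motif)):
        if len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d):
            return False
    return True


def brute_force_ssrs(seq: str, min_repeats) -> list[tuple]:
    """Every qualifying maximal perfect repeat, by exhaustive enumeration.

    For each (start, unit) pair: take the motif at that position, count
    how many complete copies follow, and keep the run iff the count
    meets the unit's threshold, the motif is primitive (not itself a
    repeat of a shorter unit), and the run cannot be extended one base
    to the left with the same period.  Returns tuples
    ``(start_1based, end_1based, unit, motif, count)`` sorted by
    (start, unit).
    """
    s = seq.upper()
    n = len(s)
    found = []
    for u in range(1, 7):
        thr = min_repeats[u - 1]
        for a in range(n - 2 * u + 1):
            if s[a] != s[a + u]:
                continue
            motif = s[a : a + u]
            if any(c not in "ACGT" for c in motif) or not _primitive(motif):
                continue
            count = 1
            while s[a + u * count : a + u * (count + 1)] == motif:
                count += 1
            if count < thr:
                continue
            if a >= 1 and s[a - 1] in "ACGT" and s[a - 1] == s[a - 1 + u]:
                continue  # run actually starts further left
            found.append((a + 1, a + u * count, u, motif, count))
    return sorted(found)
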