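"""Independent brute-force oracles used only by the test suite.

These are deliberately naive (character-by-character loops, direct
double sums) and share no code with the package implementation.
"""

from __future__ import annotations

import math

VALID = set("ACGT")


def _primitive(motif: str) -> bool:
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def brute_force_ssrs(seq: str,
                     min_repeats: dict[int, int] | None = None
                     ) -> list[tuple[int, int, str, int]]:
    """Exhaustively enumerate maximal perfect SSR tracts.

    For every (start, motif size) the k-periodic character run is grown
    one character at a time; a candidate is kept when its start cannot
    be extended left, the motif is primitive and pure ACGT, and the
    whole-unit repeat count meets the threshold.  Returns sorted
    (start, end, motif, repeat_count) tuples with 1-based inclusive
    coordinates trimmed to whole motif units.
    """
    min_repeats = min_repeats or {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    n = len(seq)
    out = []
    for k, min_rep in min_repeats.items():
        for a in range(n - k + 1):
            motif = seq[a : a + k]
            if any(c not in VALID for c in motif):
                continue
            # left char-maximality: position a-1 must not extend the run
            if a >= 1 and seq[a - 1] in VALID and seq[a - 1] == seq[a - 1 + k]:
                continue
            if not _primitive(motif):
                continue
            # grow the periodic character run to the right
            m = k
            j = a + k
            while j < n and seq[j] in VALID and seq[j] == seq[j - k]:
                m += 1
                j += 1
            repeat_count = m // k
            if repeat_count < min_rep:
                continue
            out.append((a + 1, a + repeat_count * k, motif, repeat_count))
    return sorted(out)


def brute_pic(freqs: list[float]) -> float:
    """PIC by direct evaluation of the double sum."""
    total = 1.0
    for p in freqs:
        total -= p * p
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            total -= 2.0 * freqs[i] ** 2 * freqs[j] ** 2
    return total


def brute_nei(calls_x: list, calls_y: list) -> float:
    """Nei distance between two single-allele profiles (None = missing)."""
    shared = comparable = 0
    for x, y in zip(calls_x, calls_y):
        if x is None or y is None:
            continue
        comparable += 1
        if x == y:
            shared += 1
    if comparable == 0:
        raise ValueError("no comparable loci")
    if shared == 0:
        return math.inf
    return -math.log(shared / comparable)


def compound_groups(intervals: list[tuple[int, int]],
                    max_gap: int) -> list[list[int]]:
    """Transitive closure of the <= max_gap adjacency over sorted tracts."""
    groups: list[list[int]] = []
    for idx, (start, end) in enumerate(intervals):
        if groups:
            _, prev_end = intervals[groups[-1][-1]]
            if start - prev_end - 1 <= max_gap:
                groups[-1].append(idx)
                continue
        groups.append([idx])
    return [g for g in groups if len(g) >= 2]
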