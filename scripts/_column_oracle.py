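"""Naive per-column recomputations used by the acceptance script.

Deliberately independent of the package implementation: plain Python
loops over characters, base-2 logs from the standard library.
"""

import math

DNA = set("ACGT")


def density(column: str) -> float:
    return sum(1 for c in column if c in DNA) / len(column)


def entropy(column: str) -> float:
    counts: dict[str, int] = {}
    for c in column:
        if c in DNA:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return -sum((n / total) * math.log2(n / total) for n in counts.values())


def brute_seg(rows) -> int:
    n = 0
    for col in zip(*rows):
        if len({c for c in col if c in DNA}) >= 2:
            n += 1
    return n


def brute_pic(rows) -> int:
    n = 0
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            if c in DNA:
                counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            n += 1
    return n
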