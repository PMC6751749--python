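"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (per-column scans, explicit
bipartition enumeration, closed forms) and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import itertools
import math

DNA = set("ACGT")
PROTEIN = set("ACDEFGHIKLMNPQRSTVWY")


def column_density(column: str, determinate=DNA) -> float:
    return sum(1 for c in column if c in determinate) / len(column)


def column_entropy(column: str, determinate=DNA) -> float:
    counts: dict[str, int] = {}
    for c in column:
        if c in determinate:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 0.0
    h = 0.0
    for n in counts.values():
        p = n / total
        h -= p * math.log2(p)
    return h


def brute_segregating_sites(rows: list[str], determinate=DNA) -> int:
    n = 0
    for col in zip(*rows):
        states = {c for c in col if c in determinate}
        if len(states) >= 2:
            n += 1
    return n


def brute_parsimony_informative(rows: list[str], determinate=DNA) -> int:
    n = 0
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            if c in determinate:
                counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            n += 1
    return n


def shared_kmer(a: str, b: str, k: int) -> bool:
    ka = {a[i: i + k] for i in range(len(a) - k + 1)}
    return any(b[i: i + k] in ka for i in range(len(b) - k + 1))


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def jc_expected_p(distance: float) -> float:
    """Expected proportion of differing sites under Jukes-Cantor."""
    return 0.75 * (1.0 - math.exp(-4.0 * distance / 3.0))


def newick_bipartitions(newick: str) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, by explicit recursion.

    Each bipartition is represented as the smaller (or lexicographically
    first, on ties) side's frozen leaf set.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    bips = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue  # trivial
        key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        bips.add(key)
    return bips


def brute_rf(newick_a: str, newick_b: str) -> int:
    a = newick_bipartitions(newick_a)
    b = newick_bipartitions(newick_b)
    return len(a ^ b)


def random_alignment(rng, n_taxa: int, length: int, missing_rate=0.15,
                     alphabet="ACGT-N?R") -> list[str]:
    rows = []
    for _ in range(n_taxa):
        rows.append("".join(rng.choice(list(alphabet)) for _ in range(length)))
    return rows


STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def hand_translate(seq: str, frame: int = 0) -> str:
    out = []
    usable = seq[frame:]
    for i in range(len(usable) // 3):
        codon = usable[3 * i: 3 * i + 3]
        if any(c not in DNA for c in codon):
            out.append("X")
        else:
            out.append(STANDARD_CODE[codon])
    return "".join(out)
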