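"""Probe-baited iterative assembly with orthology and contamination screening.

Each locus is assembled per sample by recruiting reads that share an exact
k-mer with the bait (or its reverse complement), placing them on the
growing consensus by k-mer offset voting, and taking a per-column
majority-rule consensus wherever read depth reaches ``min_depth``. The
consensus extends beyond the probe region as recruitment re-runs against
the updated consensus each iteration, until a fixpoint or the iteration
cap.

Orthology: recruited reads are partitioned by identity to the final
consensus at the paralog-divergence threshold; if a second cluster exists,
the cluster closest to the reference is kept and ``paralog_detected`` is
flagged. Cross-sample contamination (barcode leakage) is screened per
locus: consensus pairs from different taxa at near-identity mark the
lower-depth member ``contamination_suspect``.

All assembly steps are deterministic given the configuration and input
order; ties break toward the lexicographically smaller alternative.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

# uint8 residue codes: A=0 C=1 G=2 T=3, anything else 4 (missing).
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[ord(chr(_b).lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed integer codes for every valid (ACGT-only) k-mer.

    Returns (positions, packed codes); k must be <= 31 to fit int64.
    """
    if k > 31:
        raise ParameterError("k-mer size above 31 is not supported")
    if len(codes) < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows < 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    packed = windows.astype(np.int64) @ powers
    pos = np.flatnonzero(valid)
    return pos, packed[pos]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Read:
    read_id: str
    sequence: str
    quality: str | None = None


@dataclass
class ReadSet:
    """All reads demultiplexed to one sample."""

    sample_id: str
    reads: list[Read]
    barcode: str = ""

    def __post_init__(self) -> None:
        ids = [r.read_id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ParameterError(f"{self.sample_id}: duplicate read ids")
        if any(not r.sequence for r in self.reads):
            raise ParameterError(f"{self.sample_id}: empty read sequence")


@dataclass
class AssemblyConfig:
    """Assembly and screening parameters.

    k
        Exact k-mer size for recruitment and placement (odd, 11..31).
    min_depth
        Minimum read depth for a consensus call; undercovered columns are
        trimmed at the ends and masked ``N`` in the interior.
    paralog_divergence
        Fractional divergence separating within-sample haplotype clusters:
        reads below ``1 - paralog_divergence`` identity to the consensus
        form a second cluster.
    contamination_identity
        Cross-sample consensus identity at or above which the lower-depth
        member is flagged as a barcode-leakage suspect.
    min_consensus_length
        Minimum number of called (determinate) consensus columns for a
        result to be reported; shorter fragments come back ``absent``.
    paralog_min_fraction
        A second identity cluster is treated as a paralog only if it holds
        at least this fraction of the on-target cluster's reads (and at
        least 3 reads). Set well above barcode-leakage noise (a few
        percent of reads) and well below the weakest expected paralog
        signal (a co-captured copy contributes reads at a rate comparable
        to the target).
    """

    k: int = 31
    max_iterations: int = 10
    min_depth: int = 2
    paralog_divergence: float = 0.05
    contamination_identity: float = 0.99
    min_consensus_length: int = 60
    paralog_min_fraction: float = 0.1
    paralog_scan_k: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (11 <= self.k <= 63 and self.k % 2 == 1):
            raise ParameterError("k must be odd and in [11, 63]")
        if self.k > 31:
            raise ParameterError("k above 31 is not supported by this implementation")
        if not 0 < self.paralog_divergence < 1:
            raise ParameterError("paralog_divergence must be in (0, 1)")
        if not 0 < self.contamination_identity <= 1:
            raise ParameterError("contamination_identity must be in (0, 1]")
        if self.min_depth < 1 or self.max_iterations < 1:
            raise ParameterError("min_depth and max_iterations must be >= 1")
        if not 0 <= self.paralog_min_fraction < 1:
            raise ParameterError("paralog_min_fraction must be in [0, 1)")
        if not 7 <= self.paralog_scan_k <= 31:
            raise ParameterError("paralog_scan_k must be in [7, 31]")


@dataclass
class AssemblyResult:
    sample_id: str
    locus_id: str
    consensus: str | None = None
    support: np.ndarray | None = None
    flags: set = field(default_factory=set)
    read_ids: list[str] = field(default_factory=list)  # reads behind the consensus

    def __post_init__(self) -> None:
        if self.consensus is None and "absent" not in self.flags:
            self.flags.add("absent")
        if self.consensus is not None and self.support is not None:
            if len(self.support) != len(self.consensus):
                raise ParameterError("support length != consensus length")

    @property
    def mean_depth(self) -> float:
        if self.support is None or len(self.support) == 0:
            return 0.0
        return float(np.mean(self.support))


# ---------------------------------------------------------------------------
# Recruitment
# ---------------------------------------------------------------------------

def recruit_reads(reads: list[Read], bait: str, k: int) -> list[Read]:
    """Reads sharing at least one exact k-mer with the bait or its
    reverse complement."""
    if len(bait) < k:
        raise ParameterError(f"bait length {len(bait)} shorter than k={k}")
    bait_codes = encode(bait)
    _, fwd = kmer_codes(bait_codes, k)
    _, rev = kmer_codes(revcomp_codes(bait_codes), k)
    bait_set = set(fwd.tolist()) | set(rev.tolist())
    recruited = []
    for read in reads:
        _, kc = kmer_codes(encode(read.sequence), k)
        if any(c in bait_set for c in kc.tolist()):
            recruited.append(read)
    return recruited


class ReadIndex:
    """Inverted k-mer index over one sample's reads (forward strand).

    Built once per sample; every locus assembly then recruits and places
    reads by looking up consensus k-mers instead of scanning the read pool.
    """

    def __init__(self, reads: list[Read], k: int):
        self.k = k
        self.reads = reads
        self.codes = [encode(r.sequence) for r in reads]
        self._rc_cache: dict[int, np.ndarray] = {}
        self._rc_kmers: dict[int, tuple[list[int], list[int]]] = {}
        self._kmers: list[tuple[list[int], list[int]]] = []
        owners, positions, packed_all = [], [], []
        for i, codes in enumerate(self.codes):
            pos, packed = kmer_codes(codes, k)
            self._kmers.append((pos.tolist(), packed.tolist()))
            owners.append(np.full(len(pos), i, dtype=np.int32))
            positions.append(pos.astype(np.int32))
            packed_all.append(packed)
        if packed_all:
            packed_cat = np.concatenate(packed_all)
            owner_cat = np.concatenate(owners)
            order = np.argsort(packed_cat, kind="stable")
            packed_sorted = packed_cat[order]
            self._owners = owner_cat[order]
            self._uniq, starts = np.unique(packed_sorted, return_index=True)
            self._bounds = np.append(starts, len(packed_sorted))
        else:
            self._owners = np.empty(0, dtype=np.int32)
            self._uniq = np.empty(0, dtype=np.int64)
            self._bounds = np.zeros(1, dtype=np.int64)

    def candidates(self, cons: np.ndarray, skip) -> dict[int, int]:
        """Reads sharing >= 1 exact k-mer with the consensus, with a strand
        hint: +1 if the read's forward k-mers hit the consensus, -1 if they
        hit its reverse complement. Reads in ``skip`` are excluded."""
        if len(self._uniq) == 0:
            return {}
        found: dict[int, int] = {}
        for strand, strand_cons in ((1, cons), (-1, revcomp_codes(cons))):
            _, packed = kmer_codes(strand_cons, self.k)
            if len(packed) == 0:
                continue
            ii = np.searchsorted(self._uniq, packed)
            ii[ii >= len(self._uniq)] = len(self._uniq) - 1
            sel = ii[self._uniq[ii] == packed]
            if len(sel) == 0:
                continue
            parts = [
                self._owners[a:b]
                for a, b in zip(self._bounds[sel].tolist(), self._bounds[sel + 1].tolist())
            ]
            for r in np.unique(np.concatenate(parts)).tolist():
                if r not in found and r not in skip:
                    found[r] = strand
        return found

    def oriented_codes(self, read_i: int, strand: int) -> np.ndarray:
        codes = self.codes[read_i]
        if strand == 1:
            return codes
        rc = self._rc_cache.get(read_i)
        if rc is None:
            rc = revcomp_codes(codes)
            self._rc_cache[read_i] = rc
        return rc

    def _oriented_kmers(self, read_i: int, strand: int) -> tuple[list[int], list[int]]:
        if strand == 1:
            return self._kmers[read_i]
        cached = self._rc_kmers.get(read_i)
        if cached is None:
            pos, packed = kmer_codes(self.oriented_codes(read_i, -1), self.k)
            cached = (pos.tolist(), packed.tolist())
            self._rc_kmers[read_i] = cached
        return cached

    def place(
        self, read_i: int, kd: dict[int, int], hint: int = 1
    ) -> tuple[int, int] | None:
        """First-shared-k-mer placement of a read against a consensus k-mer
        dict ``{packed k-mer: consensus position}``; the hinted strand is
        tried first. Exact 31-mer collisions are vanishingly rare, so the
        first hit fixes the offset."""
        for strand in (hint, -hint):
            pos, packed = self._oriented_kmers(read_i, strand)
            for q, c in zip(pos, packed):
                p = kd.get(c)
                if p is not None:
                    return (strand, p - q)
        return None


# ---------------------------------------------------------------------------
# Consensus construction
# ---------------------------------------------------------------------------

def _stack_counts(
    placed: list[tuple[np.ndarray, int]],
) -> tuple[np.ndarray, int]:
    """Per-column base counts over all placed reads.

    ``placed`` holds (oriented codes, offset) pairs in a shared coordinate
    frame; returns (counts[4, W], base) where base is the leftmost offset.
    """
    base = min(off for _, off in placed)
    width = max(off + len(codes) for codes, off in placed) - base
    counts = np.zeros((4, width), dtype=np.int32)
    all_codes = np.concatenate([codes for codes, _ in placed])
    all_cols = np.concatenate(
        [np.arange(len(codes)) + (off - base) for codes, off in placed]
    )
    valid = all_codes < 4
    np.add.at(counts, (all_codes[valid].astype(np.intp), all_cols[valid]), 1)
    return counts, base


def _call_consensus(
    counts: np.ndarray, min_depth: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Strict-majority consensus; undercovered ends trimmed, interior masked N.

    A base is called only where depth reaches ``min_depth`` AND one base
    holds a strict majority of the reads (ties yield ``N`` rather than an
    arbitrary pick). Returns (consensus codes, coverage, left trim) —
    empty if no column is callable.
    """
    coverage = counts.sum(axis=0)
    majority = 2 * counts.max(axis=0) > coverage
    called = (coverage >= min_depth) & majority
    if not called.any():
        return np.empty(0, dtype=np.uint8), np.empty(0, dtype=np.int64), 0
    first = int(np.argmax(called))
    last = len(called) - int(np.argmax(called[::-1]))
    cons = counts[:, first:last].argmax(axis=0).astype(np.uint8)
    cons[~called[first:last]] = 4
    return cons, coverage[first:last].astype(np.int64), first


def iterative_assemble(
    reads: list[Read],
    bait: str,
    config: AssemblyConfig,
    *,
    index: ReadIndex | None = None,
    detect_index: ReadIndex | None = None,
    reference: str | None = None,
    sample_id: str = "",
    locus_id: str = "",
) -> AssemblyResult:
    """Assemble one locus for one sample by bait-seeded iteration.

    Loops {recruit against the current consensus; place recruited reads;
    majority-rule consensus at depth >= ``min_depth``} until the consensus
    reaches a fixpoint or ``max_iterations``. The consensus may extend
    beyond the bait on both ends. Degenerate inputs never raise: no
    recruited reads yields an ``absent`` result, thin coverage a
    ``low_coverage`` flag.

    ``detect_index``, if given, is a second index over the same reads
    built at ``paralog_scan_k``: exact k-mers at the assembly k miss reads
    from copies diverged well beyond the paralog threshold, so a
    shorter-seed scan of the leftover reads supplies the divergent-copy
    evidence for the ``paralog_detected`` flag.
    """
    if len(bait) < config.k:
        raise ParameterError(f"bait length {len(bait)} shorter than k={config.k}")
    if index is None:
        index = ReadIndex(reads, config.k)
    reference = reference if reference is not None else bait

    # Placements live in a fixed absolute frame (bait starts at 0); the
    # consensus occupies [cons_start, cons_start + len(cons)) of it. Only
    # reads near the current consensus contribute to the base counts: the
    # first round is bait-seeded (divergent paralogous copies rarely share
    # exact k-mers with the reference, so the seed cluster is the
    # on-target haplotype), and later recruits below the identity
    # threshold accumulate as a second cluster instead of being averaged
    # into a chimeric consensus. Far reads are re-judged every iteration
    # in case a short first overlap misclassified them.
    cons = encode(bait)
    cons_start = 0
    placements: dict[int, tuple[int, int]] = {}
    near: dict[int, tuple[int, int]] = {}
    far: dict[int, tuple[int, int]] = {}
    counts: np.ndarray | None = None
    lo = 0  # absolute coordinate of counts[:, 0]
    # Reads are only admitted to a cluster once they overlap the called
    # consensus by enough columns for the identity verdict to be reliable
    # (at 2*d_p haplotype separation, ~60 columns keeps misassignment in
    # the low percent range); shorter overlaps defer to a later iteration.
    min_judge_overlap = 60
    for iteration in range(config.max_iterations):
        new_reads = index.candidates(cons, skip=placements)
        arrivals: list[int] = []
        if new_reads:
            pos, packed = kmer_codes(cons, config.k)
            kd: dict[int, int] = dict(zip(packed.tolist(), pos.tolist()))
            for read_i in sorted(new_reads):
                hit = index.place(read_i, kd, hint=new_reads[read_i])
                if hit is not None:
                    strand, off = hit
                    placements[read_i] = (strand, off + cons_start)
                    arrivals.append(read_i)
        if not placements:
            return AssemblyResult(sample_id, locus_id, None, None, {"absent"})

        placed_new: list[tuple[np.ndarray, int]] = []
        if iteration == 0:
            for read_i in arrivals:
                strand, off = placements[read_i]
                near[read_i] = (strand, off)
                placed_new.append((index.oriented_codes(read_i, strand), off))
        else:
            for read_i in arrivals + sorted(far):
                strand, off = placements[read_i]
                codes = index.oriented_codes(read_i, strand)
                rel = off - cons_start
                overlap = min(len(codes), len(cons) - rel) - max(0, -rel)
                if overlap < min_judge_overlap:
                    if read_i not in far:
                        far[read_i] = (strand, off)
                    continue
                ident = _read_identity_to(codes, rel, cons)
                if ident >= 1 - config.paralog_divergence:
                    far.pop(read_i, None)
                    near[read_i] = (strand, off)
                    placed_new.append((codes, off))
                elif read_i not in far:
                    far[read_i] = (strand, off)
        if not near:
            return AssemblyResult(sample_id, locus_id, None, None, {"absent"})

        if placed_new:
            new_lo = min(lo if counts is not None else 2**31, *(o for _, o in placed_new))
            new_hi = max(
                lo + counts.shape[1] if counts is not None else -(2**31),
                *(o + len(c) for c, o in placed_new),
            )
            fresh = np.zeros((4, new_hi - new_lo), dtype=np.int32)
            if counts is not None:
                fresh[:, lo - new_lo: lo - new_lo + counts.shape[1]] = counts
            counts, lo = fresh, new_lo
            for codes, off in placed_new:
                valid = codes < 4
                cols = np.arange(len(codes))[valid] + (off - lo)
                np.add.at(counts, (codes[valid].astype(np.intp), cols), 1)
        new_cons, _, first = _call_consensus(counts, config.min_depth)
        if len(new_cons) == 0:
            return AssemblyResult(sample_id, locus_id, None, None, {"absent"})
        converged = (
            not placed_new
            and len(new_cons) == len(cons)
            and (new_cons == cons).all()
        )
        cons = new_cons
        cons_start = lo + first
        if converged:
            break

    flags: set = set()

    # Orthology: a far cluster counts as a paralog only if it carries a
    # substantial share of the recruited reads; stray low-identity reads
    # (sequencing-error tails, trace leakage) are dropped without a flag.
    kept = near
    threshold = max(3, int(np.ceil(config.paralog_min_fraction * len(near))))
    divergent = len(far)
    if detect_index is not None and divergent < threshold:
        divergent += _scan_divergent_reads(
            detect_index, placements, cons, cons_start, config, min_judge_overlap
        )
    if divergent >= threshold:
        flags.add("paralog_detected")
        if len(far) >= threshold:
            kept = _select_ortholog_cluster(index, [near, far], cons, reference, config)

    placed = [
        (index.oriented_codes(i, strand), off)
        for i, (strand, off) in sorted(kept.items())
    ]
    counts, _ = _stack_counts(placed)
    cons, coverage, _ = _call_consensus(counts, config.min_depth)
    if int((cons < 4).sum()) < config.min_consensus_length:
        return AssemblyResult(sample_id, locus_id, None, None, {"absent"} | flags)
    interior_thin = (coverage < config.min_depth).any() or (cons == 4).any()
    if interior_thin:
        flags.add("low_coverage")
    kept_ids = [reads[i].read_id for i in sorted(kept)]
    return AssemblyResult(sample_id, locus_id, decode(cons), coverage, flags, kept_ids)


def _read_identity_to(
    codes: np.ndarray, offset: int, cons: np.ndarray
) -> float:
    lo = max(0, -offset)
    hi = min(len(codes), len(cons) - offset)
    if hi <= lo:
        return 0.0
    seg = codes[lo:hi]
    ref = cons[offset + lo: offset + hi]
    both = (seg < 4) & (ref < 4)
    n = int(both.sum())
    if n == 0:
        return 0.0
    return float((seg[both] == ref[both]).sum() / n)


def _scan_divergent_reads(
    detect_index: ReadIndex,
    placements: dict[int, tuple[int, int]],
    cons: np.ndarray,
    cons_start: int,
    config: AssemblyConfig,
    min_overlap: int,
) -> int:
    """Count reads that align to the consensus at paralog-level divergence.

    Uses the short-seed index to pick up reads too diverged to share any
    assembly-length k-mer; a read counts if it overlaps the consensus by
    ``min_overlap`` columns at identity in [0.60, 1 - paralog_divergence).
    """
    cand = detect_index.candidates(cons, skip=placements)
    if not cand:
        return 0
    pos, packed = kmer_codes(cons, detect_index.k)
    kd: dict[int, int] = dict(zip(packed.tolist(), pos.tolist()))
    n = 0
    for read_i, hint in cand.items():
        hit = detect_index.place(read_i, kd, hint=hint)
        if hit is None:
            continue
        strand, rel = hit
        codes = detect_index.oriented_codes(read_i, strand)
        overlap = min(len(codes), len(cons) - rel) - max(0, -rel)
        if overlap < min_overlap:
            continue
        ident = _read_identity_to(codes, rel, cons)
        if 0.60 <= ident < 1 - config.paralog_divergence:
            n += 1
    return n


def _select_ortholog_cluster(
    index: ReadIndex,
    clusters: list[dict[int, tuple[int, int]]],
    cons: np.ndarray,
    reference: str,
    config: AssemblyConfig,
) -> dict[int, tuple[int, int]]:
    """Keep the cluster whose consensus best matches the reference.

    Ties go to the higher-depth cluster, then to the lexicographically
    smaller consensus string.
    """
    scored = []
    for rank, cluster in enumerate(clusters):
        placed = [
            (index.oriented_codes(i, strand), off)
            for i, (strand, off) in sorted(cluster.items())
        ]
        counts, _ = _stack_counts(placed)
        ccons, coverage, _ = _call_consensus(counts, config.min_depth)
        if len(ccons) == 0:
            continue
        ident, overlap = ungapped_identity(decode(ccons), reference)
        depth = float(coverage.mean())
        scored.append((-round(ident, 6), -round(depth, 6), decode(ccons), rank, cluster))
    if not scored:
        return clusters[0]
    scored.sort(key=lambda t: t[:3])
    return scored[0][4]


# ---------------------------------------------------------------------------
# Pairwise sequence comparison and paralog resolution on contigs
# ---------------------------------------------------------------------------

def ungapped_identity(
    a: str, b: str, k: int = 15
) -> tuple[float, int]:
    """Best-offset ungapped identity between two sequences.

    The relative offset (either strand) is chosen by exact k-mer vote;
    returns ``(identity, overlap_length)`` over positions where both are
    determinate, or ``(0.0, 0)`` when no k-mer is shared.
    """
    ca, cb = encode(a), encode(b)
    pos_a, packed_a = kmer_codes(ca, k)
    amap: dict[int, int] = {}
    for p, c in zip(pos_a.tolist(), packed_a.tolist()):
        amap.setdefault(c, p)
    best: tuple[int, int, int] | None = None  # (-votes, strand_key, offset)
    for strand, codes in ((1, cb), (-1, revcomp_codes(cb))):
        votes: dict[int, int] = defaultdict(int)
        pos_b, packed_b = kmer_codes(codes, k)
        for q, c in zip(pos_b.tolist(), packed_b.tolist()):
            if c in amap:
                votes[amap[c] - q] += 1
        for off, n in votes.items():
            cand = (-n, 0 if strand == 1 else 1, off)
            if best is None or cand < best:
                best = cand
    if best is None:
        return 0.0, 0
    _, strand_key, off = best
    codes_b = cb if strand_key == 0 else revcomp_codes(cb)
    lo = max(0, -off)
    hi = min(len(codes_b), len(ca) - off)
    seg_b = codes_b[lo:hi]
    seg_a = ca[off + lo: off + hi]
    both = (seg_a < 4) & (seg_b < 4)
    n = int(both.sum())
    if n == 0:
        return 0.0, 0
    return float((seg_a[both] == seg_b[both]).sum() / n), n


def resolve_paralogs(
    sequences: list[str],
    reference: str,
    d_p: float = 0.05,
    depths: list[float] | None = None,
) -> tuple[str, bool]:
    """Single-linkage cluster contigs at identity >= 1 - d_p; keep the
    reference-closest cluster.

    Returns the kept cluster's consensus and a flag that is True when more
    than one cluster was found. Ties in reference identity go to the
    higher-depth cluster, then to the lexicographically smaller consensus.
    """
    if not sequences:
        raise ParameterError("no sequences to resolve")
    if not 0 < d_p < 1:
        raise ParameterError("d_p must be in (0, 1)")
    n = len(sequences)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ident, overlap = ungapped_identity(sequences[i], sequences[j])
            if overlap and ident >= 1 - d_p:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(i)
    clusters = sorted(groups.values(), key=lambda g: g[0])
    if len(clusters) == 1:
        return _contig_cluster_consensus(sequences, clusters[0]), False

    scored = []
    for members in clusters:
        ccons = _contig_cluster_consensus(sequences, members)
        ident, _ = ungapped_identity(ccons, reference)
        depth = (
            float(np.mean([depths[i] for i in members])) if depths is not None
            else float(len(members))
        )
        scored.append((-round(ident, 6), -round(depth, 6), ccons))
    scored.sort(key=lambda t: t[:3])
    return scored[0][2], True


def _contig_cluster_consensus(sequences: list[str], members: list[int]) -> str:
    """Majority consensus of a contig cluster, anchored on its longest member."""
    ordered = sorted(members, key=lambda i: (-len(sequences[i]), sequences[i]))
    anchor = encode(sequences[ordered[0]])
    if len(ordered) == 1:
        return sequences[ordered[0]]
    k = 15
    pos_a, packed_a = kmer_codes(anchor, k)
    amap: dict[int, int] = {}
    for p, c in zip(pos_a.tolist(), packed_a.tolist()):
        amap.setdefault(c, p)
    placed = [(anchor, 0)]
    for i in ordered[1:]:
        codes = encode(sequences[i])
        best = None
        for strand, oc in ((1, codes), (-1, revcomp_codes(codes))):
            votes: dict[int, int] = defaultdict(int)
            pos_b, packed_b = kmer_codes(oc, k)
            for q, c in zip(pos_b.tolist(), packed_b.tolist()):
                if c in amap:
                    votes[amap[c] - q] += 1
            for off, nv in votes.items():
                cand = (-nv, 0 if strand == 1 else 1, off, oc)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        if best is not None:
            placed.append((best[3], best[2]))
    counts, _ = _stack_counts(placed)
    cons, _, _ = _call_consensus(counts, 1)
    return decode(cons)


# ---------------------------------------------------------------------------
# Cross-sample contamination screen
# ---------------------------------------------------------------------------

def contamination_screen(
    results: list[AssemblyResult],
    c_i: float = 0.99,
    sample_taxon: dict[str, str] | None = None,
    min_overlap: int = 60,
) -> list[AssemblyResult]:
    """Flag barcode-leakage suspects among one locus's assemblies.

    Every cross-sample pair of consensuses from *different* taxa (samples
    map to themselves when no taxon mapping is given, so conspecific
    replicates can be exempted) is compared at best ungapped offset; at
    identity >= ``c_i`` over at least ``min_overlap`` determinate columns
    the lower-mean-depth member is flagged ``contamination_suspect``
    (both, if depths tie). Flags are added in place; the list is returned.
    """
    if not 0 < c_i <= 1:
        raise ParameterError("c_i must be in (0, 1]")
    taxon_of = sample_taxon or {}
    with_cons = [r for r in results if r.consensus is not None]
    for i in range(len(with_cons)):
        for j in range(i + 1, len(with_cons)):
            a, b = with_cons[i], with_cons[j]
            if a.sample_id == b.sample_id:
                continue
            if taxon_of.get(a.sample_id, a.sample_id) == taxon_of.get(
                b.sample_id, b.sample_id
            ):
                continue
            ident, overlap = ungapped_identity(a.consensus, b.consensus)
            if overlap < min_overlap or ident < c_i:
                continue
            if a.mean_depth < b.mean_depth:
                a.flags.add("contamination_suspect")
            elif b.mean_depth < a.mean_depth:
                b.flags.add("contamination_suspect")
            else:
                a.flags.add("contamination_suspect")
                b.flags.add("contamination_suspect")
    return results
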