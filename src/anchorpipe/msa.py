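"""Multiple sequence alignment of assembled consensuses.

Assembled per-sample consensuses for a locus are unaligned (flank indels
and coverage differences make them ragged); before curation they are
aligned with MAFFT, the standard aligner for this kind of data. The probe
span is then located in alignment coordinates by anchoring the bait in
each row.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import defaultdict

import numpy as np

from .assembly import encode, kmer_codes
from .errors import ParameterError
from .io import LocusAlignment, read_fasta_sequences


def mafft_available() -> bool:
    return shutil.which("mafft") is not None


def align_sequences(
    seqs: dict[str, str], locus_id: str = "locus"
) -> LocusAlignment:
    """Align name->sequence with MAFFT (input order preserved)."""
    if not seqs:
        raise ParameterError("no sequences to align")
    if not mafft_available():
        raise RuntimeError("mafft executable not found on PATH")
    if len(seqs) == 1:
        (name, seq), = seqs.items()
        return LocusAlignment(locus_id, [name], [seq.upper()], (0, 0), "dna")
    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
        in_path = fh.name
    try:
        proc = subprocess.run(
            ["mafft", "--quiet", "--retree", "1", "--inputorder", in_path],
            capture_output=True, text=True, check=True,
        )
    finally:
        import os
        os.unlink(in_path)
    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as out:
        out.write(proc.stdout)
        out_path = out.name
    try:
        aligned = read_fasta_sequences(out_path, alphabet="dna")
    finally:
        import os
        os.unlink(out_path)
    taxa = list(aligned)
    rows = [aligned[t] for t in taxa]
    return LocusAlignment(locus_id, taxa, rows, (0, 0), "dna")


def locate_probe_span(
    aln: LocusAlignment, bait: str, k: int = 15
) -> tuple[int, int] | None:
    """Find the bait's column interval in an alignment.

    Each row's ungapped sequence votes for a bait offset via shared
    k-mers; the per-row intervals are mapped to alignment columns and the
    median start/end is returned, or ``None`` if no row anchors the bait.
    """
    bait_codes = encode(bait)
    pos_b, packed_b = kmer_codes(bait_codes, k)
    bmap: dict[int, int] = {}
    for p, c in zip(pos_b.tolist(), packed_b.tolist()):
        bmap.setdefault(c, p)
    starts, ends = [], []
    for row in aln.rows:
        gapless = row.replace("-", "")
        codes = encode(gapless)
        votes: dict[int, int] = defaultdict(int)
        pos_r, packed_r = kmer_codes(codes, k)
        for q, c in zip(pos_r.tolist(), packed_r.tolist()):
            if c in bmap:
                votes[q - bmap[c]] += 1
        if not votes:
            continue
        offset = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        u_start = max(0, offset)
        u_end = min(len(gapless), offset + len(bait))
        if u_end <= u_start:
            continue
        # map ungapped positions to alignment columns
        col_of = np.flatnonzero(np.frombuffer(row.encode(), dtype=np.uint8) != ord("-"))
        starts.append(int(col_of[u_start]))
        ends.append(int(col_of[u_end - 1]) + 1)
    if not starts:
        return None
    start = int(np.median(starts))
    end = int(np.median(ends))
    start = max(0, min(start, aln.length))
    end = max(start, min(end, aln.length))
    return start, end


def with_probe_span(aln: LocusAlignment, span: tuple[int, int]) -> LocusAlignment:
    return LocusAlignment(aln.locus_id, list(aln.taxa), list(aln.rows), span, aln.alphabet)
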