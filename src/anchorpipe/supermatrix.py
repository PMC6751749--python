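"""Concatenated supermatrix construction with explicit partition schemes.

Three dataset constructions are supported, mirroring standard practice
for anchored-enrichment phylogenomics:

``prfl``
    One DNA partition per probe region (loci in lexicographic order)
    followed by a single partition concatenating every flank — the
    flanking data is site-homologous after curation and is treated as one
    SNP-like block.
``aa``
    One protein partition per locus, with amino-acid-invariant loci
    excluded (they carry no signal at that level).
``genewise``
    No concatenation: each curated locus (probe + flank, as aligned) is
    emitted on its own, ready for per-locus gene-tree inference.

Taxa missing from a locus are padded with ``-`` over that locus's
columns; taxon labels are normalized (whitespace to underscore, only word
characters kept) for Newick/partition-file safety.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import DuplicateTaxonError, ParameterError
from .io import LocusAlignment, Partition, PartitionScheme
from .selection import flag_aa_invariant


def normalize_taxon(label: str) -> str:
    label = re.sub(r"\s+", "_", label.strip())
    return re.sub(r"[^0-9A-Za-z_]", "", label)


@dataclass
class Supermatrix:
    """Inference-ready concatenation: taxa x total width, plus its scheme."""

    taxa: list[str]
    rows: list[str]
    scheme: PartitionScheme
    provenance: list[str] = field(default_factory=list)
    alphabet: str = "dna"

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def validate(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ParameterError("ragged supermatrix rows")
        self.scheme.validate(self.width)
        if not self.scheme.covers_exactly(self.width):
            raise ParameterError("partition scheme does not tile the matrix")


def _normalized_taxa(loci: list[LocusAlignment]) -> list[str]:
    mapping: dict[str, str] = {}
    for aln in loci:
        for taxon in aln.taxa:
            norm = normalize_taxon(taxon)
            if norm in mapping and mapping[norm] != taxon:
                raise DuplicateTaxonError(
                    f"taxon labels {mapping[norm]!r} and {taxon!r} collide as {norm!r}"
                )
            mapping[norm] = taxon
    return sorted(mapping)


def _pad_rows(aln: LocusAlignment, taxa: list[str], pad: str) -> dict[str, str]:
    by_norm = {normalize_taxon(t): r for t, r in zip(aln.taxa, aln.rows)}
    return {t: by_norm.get(t, pad * aln.length) for t in taxa}


def concatenate(
    loci: list[LocusAlignment], mode: str = "prfl", pad_char: str = "-"
) -> Supermatrix | dict[str, LocusAlignment]:
    """Build the requested dataset from curated locus alignments.

    Loci are sorted lexicographically by id before concatenation, so the
    result is independent of file-discovery order. ``genewise`` mode
    returns the per-locus alignments keyed by id instead of a matrix.
    """
    if not loci:
        raise ParameterError("empty locus list")
    loci = sorted(loci, key=lambda a: a.locus_id)
    if mode == "genewise":
        return {aln.locus_id: aln for aln in loci}
    if mode not in ("prfl", "aa"):
        raise ParameterError(f"unknown concatenation mode {mode!r}")

    if mode == "aa":
        if any(a.alphabet != "protein" for a in loci):
            raise ParameterError("aa mode requires protein alignments")
        loci = [a for a in loci if not flag_aa_invariant(a)]
        if not loci:
            raise ParameterError("all loci are amino-acid invariant")
        pad = "-" if pad_char == "-" else pad_char
        taxa = _normalized_taxa(loci)
        parts: dict[str, list[str]] = {t: [] for t in taxa}
        scheme = PartitionScheme()
        pos = 1
        for aln in loci:
            padded = _pad_rows(aln, taxa, pad)
            for t in taxa:
                parts[t].append(padded[t])
            scheme.partitions.append(
                Partition(aln.locus_id, "protein", [(pos, pos + aln.length - 1)], "AUTO")
            )
            pos += aln.length
        sm = Supermatrix(
            taxa, ["".join(parts[t]) for t in taxa], scheme,
            [a.locus_id for a in loci], "protein",
        )
        sm.validate()
        return sm

    # prfl: probe partitions in locus order, then one combined flank block
    taxa = _normalized_taxa(loci)
    probe_parts: dict[str, list[str]] = {t: [] for t in taxa}
    flank_parts: dict[str, list[str]] = {t: [] for t in taxa}
    scheme = PartitionScheme()
    pos = 1
    for aln in loci:
        start, end = aln.probe_span
        padded = _pad_rows(aln, taxa, pad_char)
        for t in taxa:
            row = padded[t]
            probe_parts[t].append(row[start:end])
            flank_parts[t].append(row[:start] + row[end:])
        probe_width = end - start
        if probe_width:
            scheme.partitions.append(
                Partition(f"{aln.locus_id}_probe", "dna", [(pos, pos + probe_width - 1)], "GTR")
            )
            pos += probe_width
    flank_width = sum(len(x) for x in flank_parts[taxa[0]]) if taxa else 0
    if flank_width:
        scheme.partitions.append(
            Partition("flanks", "dna", [(pos, pos + flank_width - 1)], "GTR")
        )
    rows = ["".join(probe_parts[t]) + "".join(flank_parts[t]) for t in taxa]
    sm = Supermatrix(taxa, rows, scheme, [a.locus_id for a in loci], "dna")
    sm.validate()
    return sm


MISSING_CHARS = set("-?NX")


def dataset_summary(sm: Supermatrix) -> dict:
    """Locus/partition counts, widths, taxon count, and missingness."""
    sm.validate()
    total = sm.width * len(sm.taxa)
    missing = sum(
        sum(1 for c in row if c in MISSING_CHARS) for row in sm.rows
    )
    return {
        "n_loci": len(sm.provenance),
        "n_partitions": len(sm.scheme.partitions),
        "width": sm.width,
        "partition_widths": {
            p.name: sum(b - a + 1 for a, b in p.ranges) for p in sm.scheme.partitions
        },
        "n_taxa": len(sm.taxa),
        "missingness": missing / total if total else 0.0,
    }


def summary_frame(sm: Supermatrix) -> pd.DataFrame:
    info = dataset_summary(sm)
    rows = [
        {"partition": name, "width": width}
        for name, width in info["partition_widths"].items()
    ]
    return pd.DataFrame(rows, columns=["partition", "width"])


def write_supermatrix_fasta(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(sm.taxa, sm.rows):
            fh.write(f">{taxon}\n{row}\n")


def write_supermatrix_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP: full names, single space, one sequence per line."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.width}\n")
        pad = max((len(t) for t in sm.taxa), default=0) + 2
        for taxon, row in zip(sm.taxa, sm.rows):
            fh.write(taxon.ljust(pad) + row + "\n")


def supermatrix_alignment(sm: Supermatrix) -> LocusAlignment:
    """View the matrix as one alignment (for distance computations)."""
    return LocusAlignment("supermatrix", list(sm.taxa), list(sm.rows), (0, 0), sm.alphabet)
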