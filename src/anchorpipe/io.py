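"""On-disk artifact handling for the capture pipeline.

Reads and writes the plain-text formats the pipeline exchanges with the
outside world: per-locus FASTA alignments, FASTQ read files, Newick trees,
locus manifest tables (TSV or CSV), partition files (RAxML-style or NEXUS
``sets`` blocks), and tabular reports.

Coordinate convention: everything in memory is 0-based half-open; every
emitted file is 1-based inclusive (the RAxML / NEXUS convention).
"""

from __future__ import annotations

import io as _stdio
import logging
import re
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentFormatError,
    DuplicateTaxonError,
    ManifestSchemaError,
    ParameterError,
    PartitionSchemeError,
)

logger = logging.getLogger(__name__)

# Determinate residues; everything else counts as missing for statistics.
DNA_BASES = "ACGT"
DNA_AMBIGUITY = "RYSWKMBDHV"
DNA_ALLOWED = set(DNA_BASES + DNA_AMBIGUITY + "N-?")
PROTEIN_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALLOWED = set(PROTEIN_RESIDUES + "X-?*")


# ---------------------------------------------------------------------------
# Core alignment container
# ---------------------------------------------------------------------------

@dataclass
class LocusAlignment:
    """One multiple-sequence alignment for a captured locus.

    The probe (conserved, typically exonic) region occupies a contiguous
    block of columns given by ``probe_span`` as a 0-based half-open
    interval; everything outside it is flanking sequence.
    """

    locus_id: str
    taxa: list[str]
    rows: list[str]
    probe_span: tuple[int, int] = (0, 0)
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if self.alphabet not in ("dna", "protein"):
            raise ParameterError(f"unknown alphabet {self.alphabet!r}")
        if len(self.taxa) != len(self.rows):
            raise AlignmentFormatError(
                f"{self.locus_id}: {len(self.taxa)} labels vs {len(self.rows)} rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise DuplicateTaxonError(f"{self.locus_id}: duplicate taxon labels {dup}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentFormatError(
                f"{self.locus_id}: ragged row lengths {sorted(lengths)}"
            )
        start, end = self.probe_span
        if not (0 <= start <= end <= self.length):
            raise ParameterError(
                f"{self.locus_id}: probe span {self.probe_span} outside [0, {self.length}]"
            )

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def column(self, i: int) -> str:
        return "".join(r[i] for r in self.rows)

    def take_columns(self, indices: list[int], probe_span: tuple[int, int]) -> "LocusAlignment":
        rows = ["".join(r[i] for i in indices) for r in self.rows]
        return LocusAlignment(self.locus_id, list(self.taxa), rows, probe_span, self.alphabet)


def _normalize_row(seq: str, alphabet: str, label: str) -> str:
    seq = seq.upper()
    allowed = DNA_ALLOWED if alphabet == "dna" else PROTEIN_ALLOWED
    missing = "N" if alphabet == "dna" else "X"
    if set(seq) <= allowed:
        return seq
    bad = sorted(set(seq) - allowed)
    logger.warning("unknown characters %s in %s mapped to %s", bad, label, missing)
    return "".join(c if c in allowed else missing for c in seq)


def read_locus_fasta(
    path, probe_span: tuple[int, int] = (0, 0), locus_id: str | None = None,
    alphabet: str = "dna",
) -> LocusAlignment:
    """Read an aligned FASTA file into a :class:`LocusAlignment`.

    Residues are uppercased; characters outside the alphabet are mapped to
    the missing symbol with a logged warning. Ragged sequence lengths raise
    :class:`AlignmentFormatError`, duplicate labels :class:`DuplicateTaxonError`.
    """
    path = str(path)
    if locus_id is None:
        locus_id = re.sub(r"\.(fa|fasta|fna|faa)$", "", path.rsplit("/", 1)[-1])
    taxa, rows = [], []
    for rec in SeqIO.parse(path, "fasta"):
        taxa.append(rec.id)
        rows.append(_normalize_row(str(rec.seq), alphabet, f"{locus_id}/{rec.id}"))
    return LocusAlignment(locus_id, taxa, rows, probe_span, alphabet)


def write_locus_fasta(aln: LocusAlignment, path) -> None:
    records = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(aln.taxa, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_sequences(path, alphabet: str = "dna") -> dict[str, str]:
    """Read a possibly-unaligned FASTA file as an ordered name->sequence map."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DuplicateTaxonError(f"{path}: duplicate record {rec.id}")
        out[rec.id] = _normalize_row(str(rec.seq), alphabet, rec.id)
    return out


def write_fasta_sequences(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read a FASTQ file as a list of ``(read_id, sequence, quality)``."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(reads: list[tuple[str, str, str | None]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Locus manifest
# ---------------------------------------------------------------------------

ORIGIN_BASE_KIT = "base-kit"
ORIGIN_LEGACY = "legacy"
ORIGIN_VISION = "vision"


@dataclass
class ManifestRecord:
    locus_id: str
    origin: str
    target_length: int
    bait: str | None = None


@dataclass
class LocusManifest:
    """Per-locus design metadata: origin class, target length, optional bait."""

    records: dict[str, ManifestRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def count_origin(self, origin: str) -> int:
        return sum(1 for r in self.records.values() if r.origin == origin)


def classify_origin(text: str) -> str:
    """Classify a free-text origin cell into base-kit / legacy / vision."""
    low = str(text).lower()
    if "vision" in low:
        return ORIGIN_VISION
    if "legacy" in low or "sanger" in low:
        return ORIGIN_LEGACY
    return ORIGIN_BASE_KIT


def _find_column(columns, *keys) -> str | None:
    for key in keys:
        for col in columns:
            if key in col.lower():
                return col
    return None


def read_manifest(path) -> LocusManifest:
    """Parse a locus manifest table (TSV or CSV, sniffed from the header).

    Requires locus-name, origin, and length columns (matched loosely, extra
    columns tolerated); raises :class:`ManifestSchemaError` otherwise.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    locus_col = _find_column(df.columns, "locus", "name")
    origin_col = _find_column(df.columns, "origin", "kit", "source")
    length_col = _find_column(df.columns, "length")
    missing = [
        label
        for label, col in (("locus", locus_col), ("origin", origin_col), ("length", length_col))
        if col is None
    ]
    if missing:
        raise ManifestSchemaError(f"{path}: missing required column(s) {missing}")
    bait_col = _find_column(df.columns, "bait", "probe_seq")

    manifest = LocusManifest()
    for _, row in df.iterrows():
        locus_id = str(row[locus_col]).strip()
        raw_len = str(row[length_col]).strip()
        try:
            length = int(raw_len)
        except ValueError as exc:
            raise ManifestSchemaError(
                f"{path}: non-integer length {raw_len!r} for locus {locus_id}"
            ) from exc
        if length <= 0:
            raise ManifestSchemaError(f"{path}: non-positive length for locus {locus_id}")
        if locus_id in manifest.records:
            raise ManifestSchemaError(f"{path}: duplicate locus id {locus_id}")
        bait = str(row[bait_col]).strip() or None if bait_col else None
        manifest.records[locus_id] = ManifestRecord(
            locus_id, classify_origin(row[origin_col]), length, bait
        )
    return manifest


def write_manifest(manifest: LocusManifest, path) -> None:
    rows = [
        {"locus": r.locus_id, "origin": r.origin, "length": r.target_length}
        for r in manifest.records.values()
    ]
    pd.DataFrame(rows, columns=["locus", "origin", "length"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Partition schemes
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    name: str
    data_type: str  # dna | protein
    ranges: list[tuple[int, int]]  # 1-based inclusive
    model_hint: str = ""


@dataclass
class PartitionScheme:
    """Named, disjoint 1-based inclusive column ranges with model hints."""

    partitions: list[Partition] = field(default_factory=list)

    def validate(self, matrix_width: int | None = None) -> None:
        seen: list[tuple[int, int, str]] = []
        for part in self.partitions:
            for a, b in part.ranges:
                if a < 1 or b < a:
                    raise PartitionSchemeError(f"{part.name}: bad interval {a}-{b}")
                if matrix_width is not None and b > matrix_width:
                    raise PartitionSchemeError(
                        f"{part.name}: interval {a}-{b} beyond width {matrix_width}"
                    )
                for a2, b2, other in seen:
                    if a <= b2 and a2 <= b:
                        raise PartitionSchemeError(
                            f"{part.name} overlaps {other} on {max(a, a2)}-{min(b, b2)}"
                        )
                seen.append((a, b, part.name))

    def total_width(self) -> int:
        return sum(b - a + 1 for p in self.partitions for a, b in p.ranges)

    def covers_exactly(self, matrix_width: int) -> bool:
        covered = sorted(
            (a, b) for p in self.partitions for a, b in p.ranges
        )
        pos = 1
        for a, b in covered:
            if a != pos:
                return False
            pos = b + 1
        return pos == matrix_width + 1


def _raxml_type(part: Partition) -> str:
    if part.data_type == "dna":
        return "DNA"
    return part.model_hint or "AUTO"


def write_partition_file(scheme: PartitionScheme, dialect: str = "raxml") -> str:
    """Render a scheme as RAxML-style lines or a NEXUS ``sets`` block."""
    scheme.validate()
    if not scheme.partitions:
        logger.warning("writing empty partition scheme")
        return ""
    if dialect == "raxml":
        lines = [
            f"{_raxml_type(p)}, {p.name} = "
            + ", ".join(f"{a}-{b}" for a, b in p.ranges)
            for p in scheme.partitions
        ]
        return "\n".join(lines) + "\n"
    if dialect == "nexus":
        lines = ["#NEXUS", "begin sets;"]
        for p in scheme.partitions:
            ivals = " ".join(f"{a}-{b}" for a, b in p.ranges)
            lines.append(f"    charset {p.name} = {ivals};")
        lines.append("end;")
        return "\n".join(lines) + "\n"
    raise ParameterError(f"unknown partition dialect {dialect!r}")


_RAXML_LINE = re.compile(r"^\s*(\S+)\s*,\s*(\S+)\s*=\s*(.+?)\s*$")
_NEXUS_CHARSET = re.compile(r"charset\s+(\S+)\s*=\s*([^;]+);", re.IGNORECASE)


def _parse_ranges(text: str) -> list[tuple[int, int]]:
    ranges = []
    for chunk in re.split(r"[,\s]+", text.strip()):
        if not chunk:
            continue
        if "-" in chunk:
            a, b = chunk.split("-")
            ranges.append((int(a), int(b)))
        else:
            ranges.append((int(chunk), int(chunk)))
    return ranges


def read_partition_file(text: str, dialect: str = "raxml") -> PartitionScheme:
    scheme = PartitionScheme()
    if dialect == "raxml":
        for line in text.splitlines():
            if not line.strip():
                continue
            m = _RAXML_LINE.match(line)
            if not m:
                raise PartitionSchemeError(f"unparseable partition line: {line!r}")
            model, name, ranges = m.groups()
            data_type = "dna" if model.upper() == "DNA" else "protein"
            hint = "" if model.upper() == "DNA" else model
            scheme.partitions.append(Partition(name, data_type, _parse_ranges(ranges), hint))
    elif dialect == "nexus":
        for name, ranges in _NEXUS_CHARSET.findall(text):
            scheme.partitions.append(Partition(name, "dna", _parse_ranges(ranges)))
    else:
        raise ParameterError(f"unknown partition dialect {dialect!r}")
    scheme.validate()
    return scheme


# ---------------------------------------------------------------------------
# Trees and tables
# ---------------------------------------------------------------------------

def read_tree(path_or_text, schema: str = "newick") -> dendropy.Tree:
    text = str(path_or_text)
    if "(" in text and ";" in text:  # looks like literal newick
        return dendropy.Tree.get(data=text, schema=schema)
    return dendropy.Tree.get(path=text, schema=schema)


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_spans_table(path) -> dict[str, tuple[int, int]]:
    """Read a TSV of per-locus probe spans (0-based half-open columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"locus": str})
    for col in ("locus", "probe_start", "probe_end"):
        if col not in df.columns:
            raise ManifestSchemaError(f"{path}: missing column {col}")
    return {
        str(r.locus): (int(r.probe_start), int(r.probe_end)) for r in df.itertuples()
    }


def write_spans_table(spans: dict[str, tuple[int, int]], path) -> None:
    rows = [
        {"locus": k, "probe_start": a, "probe_end": b} for k, (a, b) in spans.items()
    ]
    pd.DataFrame(rows, columns=["locus", "probe_start", "probe_end"]).to_csv(
        path, sep="\t", index=False
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def manifest_to_frame(manifest: LocusManifest) -> pd.DataFrame:
    rows = [
        {"locus": r.locus_id, "origin": r.origin, "length": r.target_length}
        for r in manifest.records.values()
    ]
    return pd.DataFrame(rows, columns=["locus", "origin", "length"])


def frame_to_tsv_text(df: pd.DataFrame) -> str:
    buf = _stdio.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
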