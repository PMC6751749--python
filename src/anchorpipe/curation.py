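"""Per-site statistics and alignment curation.

Flanking (non-probe) columns of each locus alignment are kept only if
enough taxa are represented there (site density >= the density cutoff) and
the column is not substitution-saturated (Shannon entropy <= the entropy
cutoff, in bits). Probe columns are exempt from trimming and are instead
translated to amino acids after a data-driven reading-frame choice, with
internal stop codons reported as putative frame-shift / sequencing-error
sites.

Density counts only determinate residues (A/C/G/T for DNA; the twenty
standard residues for protein): gaps, ``N``/``X``, ``?`` and IUPAC
ambiguity codes all count as missing. Entropy is computed over determinate
residues only, so its range for DNA is [0, 2] bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .errors import DegenerateSpanError, ParameterError
from .io import DNA_BASES, PROTEIN_RESIDUES, LocusAlignment

logger = logging.getLogger(__name__)

_DNA_CODES = np.frombuffer(DNA_BASES.encode(), dtype=np.uint8)
_PROTEIN_CODES = np.frombuffer(PROTEIN_RESIDUES.encode(), dtype=np.uint8)


@dataclass
class CurationConfig:
    """Cutoffs governing trimming, recovery filtering, and translation.

    density_cutoff
        Minimum fraction of taxa with a determinate residue for a flank
        column to be kept (default 0.60).
    entropy_cutoff
        Maximum Shannon entropy, in bits, for a flank column to be kept
        (default 1.5; saturated columns exceed it).
    recovery_cutoff
        Minimum fraction of sampled taxa a locus must be recovered in to
        enter phylogenetic analysis (default 0.40).
    design_capture_cutoff
        Minimum capture fraction for a locus to stay in the probe kit
        (default 0.60).
    genetic_code
        NCBI translation table id (default 1, the standard code).
    density_over_recovered_taxa
        If True, the density denominator is the number of taxa with at
        least one determinate residue in the alignment rather than all
        alignment rows. Default False: a taxon that was sampled but not
        recovered still counts as missing data at every site.
    """

    density_cutoff: float = 0.60
    entropy_cutoff: float = 1.5
    recovery_cutoff: float = 0.40
    design_capture_cutoff: float = 0.60
    genetic_code: int = 1
    density_over_recovered_taxa: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.density_cutoff <= 1:
            raise ParameterError("density_cutoff must be in (0, 1]")
        if not 0 < self.entropy_cutoff <= 2:
            raise ParameterError("entropy_cutoff must be in (0, 2]")
        for name in ("recovery_cutoff", "design_capture_cutoff"):
            if not 0 < getattr(self, name) <= 1:
                raise ParameterError(f"{name} must be in (0, 1]")


@dataclass
class SiteProfile:
    """Per-column trimming evidence: density, entropy, probe membership, fate."""

    density: np.ndarray
    entropy: np.ndarray
    in_probe: np.ndarray
    retained: np.ndarray

    def __len__(self) -> int:
        return len(self.density)


def _matrix(aln: LocusAlignment) -> np.ndarray:
    if not aln.rows:
        return np.empty((0, 0), dtype=np.uint8)
    return np.frombuffer("".join(aln.rows).encode(), dtype=np.uint8).reshape(
        aln.n_taxa, aln.length
    )


def _determinate_codes(alphabet: str) -> np.ndarray:
    return _DNA_CODES if alphabet == "dna" else _PROTEIN_CODES


def _state_counts(mat: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """counts[s, j] = occurrences of determinate state s in column j."""
    return (mat[None, :, :] == codes[:, None, None]).sum(axis=1)


def site_density(column: str, n_taxa: int, alphabet: str = "dna") -> float:
    """Fraction of taxa with a determinate residue at this column."""
    if n_taxa == 0:
        raise ParameterError("n_taxa must be positive")
    if len(column) != n_taxa:
        raise ParameterError("column length must equal n_taxa")
    determinate = set(DNA_BASES if alphabet == "dna" else PROTEIN_RESIDUES)
    return sum(1 for c in column.upper() if c in determinate) / n_taxa


def site_entropy(column: str, alphabet: str = "dna") -> float:
    """Base-2 Shannon entropy over determinate residue frequencies.

    Gaps, missing symbols, and ambiguity codes are excluded from the
    denominator; a column with no determinate residue has entropy 0.
    """
    determinate = set(DNA_BASES if alphabet == "dna" else PROTEIN_RESIDUES)
    states: dict[str, int] = {}
    for c in column.upper():
        if c in determinate:
            states[c] = states.get(c, 0) + 1
    total = sum(states.values())
    if total == 0:
        return 0.0
    freqs = np.array(list(states.values()), dtype=float) / total
    return float(-(freqs * np.log2(freqs)).sum())


def site_profile(aln: LocusAlignment, config: CurationConfig | None = None) -> SiteProfile:
    """Vectorized density/entropy profile with the retention decision applied."""
    config = config or CurationConfig()
    mat = _matrix(aln)
    codes = _determinate_codes(aln.alphabet)
    counts = _state_counts(mat, codes).astype(float)
    totals = counts.sum(axis=0)
    if config.density_over_recovered_taxa:
        recovered = int(np.isin(mat, codes).any(axis=1).sum())
        denominator = max(recovered, 1)
    else:
        denominator = max(aln.n_taxa, 1)
    density = totals / denominator
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 0.0)
        ent_terms = np.where(freqs > 0, -freqs * np.log2(np.where(freqs > 0, freqs, 1)), 0.0)
    entropy = ent_terms.sum(axis=0)
    in_probe = np.zeros(aln.length, dtype=bool)
    start, end = aln.probe_span
    in_probe[start:end] = True
    retained = in_probe | (
        (density >= config.density_cutoff) & (entropy <= config.entropy_cutoff)
    )
    return SiteProfile(density, entropy, in_probe, retained)


def trim_flanks(
    aln: LocusAlignment, config: CurationConfig | None = None,
    profile: SiteProfile | None = None,
) -> tuple[LocusAlignment, SiteProfile]:
    """Delete flank columns failing the density/entropy cutoffs.

    Probe columns are never removed; the probe span is re-indexed to the
    trimmed coordinates. The operation is idempotent: a surviving flank
    column passes both cutoffs by construction, so trimming again is a
    no-op.
    """
    config = config or CurationConfig()
    if profile is None:
        profile = site_profile(aln, config)
    keep = np.flatnonzero(profile.retained)
    start, _ = aln.probe_span
    probe_width = aln.probe_span[1] - aln.probe_span[0]
    new_start = int((keep < start).sum())
    trimmed = aln.take_columns(list(keep), (new_start, new_start + probe_width))
    return trimmed, site_profile(trimmed, config)


def split_probe_flank(aln: LocusAlignment) -> tuple[LocusAlignment, LocusAlignment]:
    """Separate the probe block from the (left + right) flanking columns.

    Widths are conserved: probe width + flank width == input width. The
    flank alignment concatenates the left flank then the right flank, in
    original column order.
    """
    start, end = aln.probe_span
    if end - start == 0:
        raise DegenerateSpanError(f"{aln.locus_id}: empty probe span")
    probe = aln.take_columns(list(range(start, end)), (0, end - start))
    flank_cols = list(range(0, start)) + list(range(end, aln.length))
    if not flank_cols:
        logger.info("%s: probe span covers the whole alignment; empty flank", aln.locus_id)
    flank = aln.take_columns(flank_cols, (0, 0))
    return probe, flank


def interleave_probe_flank(
    probe: LocusAlignment, flank: LocusAlignment, original_span: tuple[int, int]
) -> LocusAlignment:
    """Inverse of :func:`split_probe_flank` given the original span."""
    start, end = original_span
    left = start
    rows = [
        f[:left] + p + f[left:]
        for p, f in zip(probe.rows, flank.rows)
    ]
    return LocusAlignment(probe.locus_id, list(probe.taxa), rows, (start, end), probe.alphabet)


# ---------------------------------------------------------------------------
# Reading-frame choice and translation
# ---------------------------------------------------------------------------

@dataclass
class TranslationReport:
    """QC record from probe translation."""

    locus_id: str
    frame: int
    internal_stops: dict[str, list[int]] = field(default_factory=dict)
    terminal_stop_taxa: list[str] = field(default_factory=list)
    frame_shift_suspect: bool = False


def _codon_strings(row: str, frame: int) -> list[str]:
    usable = row[frame:]
    n = len(usable) // 3
    return [usable[3 * i: 3 * i + 3] for i in range(n)]


def _translate_codon(codon: str, table) -> str:
    if any(c not in DNA_BASES for c in codon):
        return "X"
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def choose_frame_and_translate(
    probe: LocusAlignment, genetic_code: int = 1
) -> tuple[LocusAlignment, TranslationReport]:
    """Pick the reading frame minimizing internal stops, then translate.

    All three frames are scored by the total number of internal stop codons
    across taxa (ties resolved toward the lowest frame index). Codons
    containing gaps or ambiguity translate to ``X``; surviving internal
    stops are replaced by ``X`` and reported per taxon. A trailing codon
    column consisting solely of stops is dropped (a shared terminal stop,
    not an error). If more than half the sequenced taxa still show internal
    stops in the best frame the locus is flagged ``frame_shift_suspect``.
    """
    if probe.length < 3:
        raise ParameterError(f"{probe.locus_id}: probe shorter than one codon")
    table = CodonTable.unambiguous_dna_by_id[genetic_code]

    def frame_translation(frame: int):
        per_taxon = []
        for row in probe.rows:
            aa = [_translate_codon(c, table) for c in _codon_strings(row, frame)]
            per_taxon.append(aa)
        return per_taxon

    best = None
    for frame in range(3):
        per_taxon = frame_translation(frame)
        n_codons = len(per_taxon[0]) if per_taxon else 0
        internal = sum(
            sum(1 for i, aa in enumerate(row[:-1]) if aa == "*") for row in per_taxon
        ) if n_codons else 0
        if best is None or internal < best[1]:
            best = (frame, internal, per_taxon)
    frame, _, per_taxon = best
    n_codons = len(per_taxon[0]) if per_taxon else 0

    report = TranslationReport(probe.locus_id, frame)
    # Terminal codon column: drop it if every determinate entry is a stop.
    if n_codons:
        last = [row[-1] for row in per_taxon]
        stops_last = [aa == "*" for aa in last]
        if any(stops_last) and all(aa in ("*", "X") for aa in last):
            report.terminal_stop_taxa = [
                t for t, s in zip(probe.taxa, stops_last) if s
            ]
            per_taxon = [row[:-1] for row in per_taxon]
            n_codons -= 1

    rows = []
    for taxon, aa_row in zip(probe.taxa, per_taxon):
        stops = [i for i, aa in enumerate(aa_row) if aa == "*"]
        if stops:
            report.internal_stops[taxon] = stops
        rows.append("".join("X" if aa == "*" else aa for aa in aa_row))

    sequenced = [
        t for t, row in zip(probe.taxa, rows) if any(c != "X" for c in row)
    ]
    affected = [t for t in sequenced if t in report.internal_stops]
    if sequenced and len(affected) / len(sequenced) > 0.5:
        report.frame_shift_suspect = True
        logger.warning(
            "%s: internal stops in %d/%d taxa in best frame %d; frame-shift suspect",
            probe.locus_id, len(affected), len(sequenced), frame,
        )

    protein = LocusAlignment(
        probe.locus_id, list(probe.taxa), rows, (0, n_codons), "protein"
    )
    return protein, report
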