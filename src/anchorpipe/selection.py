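"""Per-locus statistics and inclusion/exclusion filters.

Loci enter phylogenetic analysis only if recovered in enough of the
sampled taxa (>= 40% by default) and stay in the probe kit only if they
capture well across the design panel (>= 60% by default). Informativeness
is summarized by the segregating-site count and the parsimony-informative
character count; probe regions whose translations show no amino-acid
variation are flagged so the amino-acid supermatrix can exclude them.

All statistics treat gaps, ``N``/``X``, ``?`` and ambiguity codes as
missing: only determinate states are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import _determinate_codes, _matrix, _state_counts
from .errors import ParameterError
from .io import LocusAlignment


@dataclass
class LocusRecord:
    """Filtering/design ledger entry for one locus."""

    locus_id: str
    n_taxa_present: int
    recovery_fraction: float
    pic: int
    seg_sites: int
    aa_invariant: bool = False
    retained_for: set = field(default_factory=set)


def count_segregating_sites(aln: LocusAlignment) -> int:
    """Columns with at least two distinct determinate states."""
    mat = _matrix(aln)
    counts = _state_counts(mat, _determinate_codes(aln.alphabet))
    return int(((counts > 0).sum(axis=0) >= 2).sum())


def count_parsimony_informative(aln: LocusAlignment) -> int:
    """Columns with >= 2 determinate states each present in >= 2 taxa."""
    mat = _matrix(aln)
    counts = _state_counts(mat, _determinate_codes(aln.alphabet))
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def taxa_present(aln: LocusAlignment) -> list[str]:
    """Taxa with at least one determinate residue in this alignment."""
    mat = _matrix(aln)
    codes = _determinate_codes(aln.alphabet)
    det = np.isin(mat, codes)
    return [t for t, has in zip(aln.taxa, det.any(axis=1)) if has]


def flag_aa_invariant(protein: LocusAlignment) -> bool:
    """True iff no two determinate residues differ at any column.

    Equivalently: every pair of taxa is identical wherever both are
    determinate, so the locus carries no amino-acid signal.
    """
    counts = _state_counts(_matrix(protein), _determinate_codes("protein"))
    return bool(((counts > 0).sum(axis=0) <= 1).all())


def make_record(
    aln: LocusAlignment, total_taxa: int, protein: LocusAlignment | None = None
) -> LocusRecord:
    """Compute the full statistics record for one curated locus."""
    if total_taxa <= 0:
        raise ParameterError("total_taxa must be positive")
    present = taxa_present(aln)
    return LocusRecord(
        locus_id=aln.locus_id,
        n_taxa_present=len(present),
        recovery_fraction=len(present) / total_taxa,
        pic=count_parsimony_informative(aln),
        seg_sites=count_segregating_sites(aln),
        aa_invariant=flag_aa_invariant(protein) if protein is not None else False,
    )


def filter_by_recovery(
    records: list[LocusRecord], cutoff: float | None = None, mode: str = "phylogeny"
) -> list[LocusRecord]:
    """Keep loci recovered in at least ``cutoff`` of the sampled taxa.

    ``phylogeny`` mode defaults the cutoff to 0.40 (analysis inclusion);
    ``design`` mode defaults to 0.60 (kit retention: loci capturing in
    fewer than 60% of the design panel are dropped). Membership only —
    records are not modified.
    """
    if mode not in ("phylogeny", "design"):
        raise ParameterError(f"unknown recovery filter mode {mode!r}")
    if cutoff is None:
        cutoff = 0.40 if mode == "phylogeny" else 0.60
    if not 0 < cutoff <= 1:
        raise ParameterError("recovery cutoff must be in (0, 1]")
    return [r for r in records if r.recovery_fraction >= cutoff]


def uninformative(record: LocusRecord) -> bool:
    """Operational 'phylogenetically uninformative' flag for kit design."""
    return record.pic == 0 or record.aa_invariant


def locus_report(records: list[LocusRecord]) -> pd.DataFrame:
    """Ranked per-locus table: pic desc, seg_sites desc, recovery desc, id asc."""
    rows = [
        {
            "locus": r.locus_id,
            "n_taxa": r.n_taxa_present,
            "recovery": r.recovery_fraction,
            "pic": r.pic,
            "seg_sites": r.seg_sites,
            "aa_invariant": r.aa_invariant,
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows, columns=["locus", "n_taxa", "recovery", "pic", "seg_sites", "aa_invariant"]
    )
    if len(df):
        df = df.sort_values(
            by=["pic", "seg_sites", "recovery", "locus"],
            ascending=[False, False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df
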