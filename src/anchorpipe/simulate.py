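"""Ground-truthed synthetic capture data and desk-scale inference oracles.

The generator emulates the structure anchored-hybrid-enrichment data is
assumed to have: each locus is a conserved, in-frame probe core (no
indels, no internal stop codons, evolving at a reduced rate) flanked on
both sides by faster-evolving non-coding sequence with indels; taxa drop
out per locus with one minus the capture probability; short reads carry
substitution errors, a configurable fraction of barcode leakage into the
neighboring sample, and optional paralogous copies.

Species trees are pure-birth (Yule) with branch lengths in expected
substitutions per site; a minimum branch-length floor keeps simulated taxa
at species-level divergence. Flank indels are modeled as deletions
relative to the ancestral sequence, which keeps the true alignment
bookkeeping exact (a deleted column is a gap in the affected clade).

Everything is reproducible from a single seed: independent generators for
the tree, root sequences, evolution, capture dropout, reads, paralogs,
and leakage are spawned from it in that fixed order.
"""

from __future__ import annotations

import io as _stdio
import itertools
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.calculate import treecompare
from dendropy.simulate import treesim

from .assembly import Read, ReadSet, decode, encode
from .errors import ParameterError
from .io import (
    ORIGIN_BASE_KIT,
    ORIGIN_LEGACY,
    ORIGIN_VISION,
    LocusAlignment,
    LocusManifest,
    ManifestRecord,
)

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in _STOP_CODONS
)
# base i -> its transition partner (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults describe a desk-scale capture experiment: 12 species, 40
    loci of a 210 bp probe core with 200 bp flanks per side, 100 bp reads
    at 20x depth with 1% substitution error, 85% per-locus capture
    probability, and no leakage or paralogy unless switched on.
    """

    n_taxa: int = 12
    n_loci: int = 40
    probe_len: int = 210
    flank_len: int = 200
    birth_rate: float = 8.0
    tree_height: float = 0.12  # root-to-tip depth, expected substitutions/site
    substitution_model: str = "JC69"  # or K2P
    kappa: float = 2.0
    probe_rate_multiplier: float = 0.4
    flank_rate_multiplier: float = 2.0
    flank_indel_rate: float = 0.02  # deletion events per site per unit branch length
    capture_probability: float = 0.85
    read_length: int = 100
    depth: float = 20.0
    error_rate: float = 0.01
    leakage_fraction: float = 0.0
    paralog_probability: float = 0.0
    paralog_divergence: float = 0.10
    min_branch_length: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ParameterError("n_taxa must be >= 3")
        if self.probe_len % 3 != 0 or self.probe_len <= 0:
            raise ParameterError("probe_len must be a positive multiple of 3")
        for name in (
            "capture_probability", "error_rate", "leakage_fraction",
            "paralog_probability", "paralog_divergence",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        for name in ("birth_rate", "tree_height", "probe_rate_multiplier", "flank_rate_multiplier"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.substitution_model not in ("JC69", "K2P"):
            raise ParameterError("substitution_model must be JC69 or K2P")
        if not self.probe_rate_multiplier < 1:
            raise ParameterError("probe_rate_multiplier must be < 1")
        if not self.flank_rate_multiplier > 1:
            raise ParameterError("flank_rate_multiplier must be > 1")


@dataclass
class ProvenanceRecord:
    sample_id: str  # sample the read was demultiplexed to
    locus_id: str
    read_id: str
    origin: str  # own | leaked | paralog
    source_sample: str  # biological source of the molecule


@dataclass
class TruthSet:
    """Simulator ground truth: the oracle for end-to-end validation."""

    tree: dendropy.Tree
    newick: str
    alignments: dict[str, LocusAlignment]
    baits: dict[str, str]
    taxon_sequences: dict[str, dict[str, str]]  # locus -> taxon -> ungapped seq
    present: dict[str, set]
    provenance: list[ProvenanceRecord] = field(default_factory=list)
    # (sample, locus) -> injected paralog sequence, for divergence audits
    paralog_sequences: dict[tuple[str, str], str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def evolve_sequence(
    codes: np.ndarray,
    distance: float,
    rng: np.random.Generator,
    model: str = "JC69",
    kappa: float = 2.0,
) -> np.ndarray:
    """Evolve a coded sequence over ``distance`` expected substitutions/site.

    JC69 substitutes a site with probability (3/4)(1 - e^(-4d/3)), uniform
    over the three alternatives; K2P uses the standard transition /
    transversion closed forms with ratio ``kappa``.
    """
    if distance < 0:
        raise ParameterError("distance must be non-negative")
    out = codes.copy()
    n = len(codes)
    if n == 0 or distance == 0:
        return out
    if model == "JC69":
        p_diff = 0.75 * (1.0 - np.exp(-4.0 * distance / 3.0))
        hit = rng.random(n) < p_diff
        if hit.any():
            shift = rng.integers(1, 4, size=int(hit.sum()))
            out[hit] = (out[hit] + shift) % 4
        return out
    # K2P: d = (alpha + 2 beta) t with kappa = alpha / beta
    bt = distance / (kappa + 2.0)
    at = kappa * bt
    e1 = np.exp(-4.0 * bt)
    e2 = np.exp(-2.0 * (at + bt))
    p_transition = 0.25 + 0.25 * e1 - 0.5 * e2
    p_transversion_each = 0.25 * (1.0 - e1)
    u = rng.random(n)
    ts = u < p_transition
    tv1 = (u >= p_transition) & (u < p_transition + p_transversion_each)
    tv2 = (u >= p_transition + p_transversion_each) & (
        u < p_transition + 2 * p_transversion_each
    )
    out[ts] = _TRANSITION[out[ts]]
    # transversion partners: A/G -> {C,T}, C/T -> {A,G}
    out[tv1] = np.where(out[tv1] % 2 == 0, 1, 0)
    out[tv2] = np.where(out[tv2] % 2 == 0, 3, 2)
    return out


def _fix_stops(child_probe: np.ndarray, parent_probe: np.ndarray) -> np.ndarray:
    """Revert any codon that mutated into a stop back to its parent codon."""
    probe = child_probe.copy()
    for i in range(0, len(probe), 3):
        codon = decode(probe[i: i + 3])
        if codon in _STOP_CODONS:
            probe[i: i + 3] = parent_probe[i: i + 3]
    return probe


def _mutate_uniform(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    hit = rng.random(len(codes)) < rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def _simulate_tree(config: SimConfig, seed: int) -> dendropy.Tree:
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_taxa,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1:02d}"
    # rescale to the configured root-to-tip depth, then floor branch lengths
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    scale = config.tree_height / depth if depth > 0 else 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = max(float(edge.length) * scale, config.min_branch_length)
    tree.is_rooted = False
    return tree


def _evolve_locus(
    tree: dendropy.Tree, config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]], str]:
    """Evolve one locus along the tree.

    Returns per-leaf (probe codes, flank codes, flank deletion mask) where
    the flank arrays cover left+right flanks in alignment coordinates, and
    the bait (root probe) sequence.
    """
    n_codons = config.probe_len // 3
    root_probe = encode(
        "".join(_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons))
    )
    total_flank = 2 * config.flank_len
    root_flank = rng.integers(0, 4, total_flank).astype(np.uint8)
    root_del = np.zeros(total_flank, dtype=bool)

    leaves: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    stack = [(tree.seed_node, root_probe, root_flank, root_del)]
    while stack:
        node, probe, flank, deleted = stack.pop()
        for child in node.child_nodes():
            b = float(child.edge.length or 0.0)
            c_probe = evolve_sequence(
                probe, b * config.probe_rate_multiplier, rng,
                config.substitution_model, config.kappa,
            )
            c_probe = _fix_stops(c_probe, probe)
            c_flank = evolve_sequence(
                flank, b * config.flank_rate_multiplier, rng,
                config.substitution_model, config.kappa,
            )
            c_del = deleted.copy()
            n_events = rng.poisson(config.flank_indel_rate * b * total_flank)
            for _ in range(n_events):
                start = int(rng.integers(0, total_flank))
                length = 1 + int(rng.geometric(0.5))
                c_del[start: start + length] = True
            if child.is_leaf():
                leaves[child.taxon.label] = (c_probe, c_flank, c_del)
            else:
                stack.append((child, c_probe, c_flank, c_del))
    return leaves, decode(root_probe)


def _locus_alignment(
    locus_id: str,
    leaves: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    config: SimConfig,
) -> LocusAlignment:
    taxa = sorted(leaves)
    fl = config.flank_len
    rows = []
    for t in taxa:
        probe, flank, deleted = leaves[t]
        flank_chars = np.frombuffer(decode(flank).encode(), dtype=np.uint8).copy()
        flank_chars[deleted] = ord("-")
        flank_str = flank_chars.tobytes().decode()
        rows.append(flank_str[:fl] + decode(probe) + flank_str[fl:])
    return LocusAlignment(
        locus_id, taxa, rows, (fl, fl + config.probe_len), "dna"
    )


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def _make_reads(
    seq: str, n_reads: int, config: SimConfig, rng: np.random.Generator,
    id_prefix: str,
) -> list[Read]:
    codes = encode(seq)
    length = min(config.read_length, len(codes))
    reads = []
    max_start = len(codes) - length
    starts = rng.integers(0, max_start + 1, n_reads)
    for i, start in enumerate(starts):
        fragment = codes[start: start + length]
        fragment = _mutate_uniform(fragment, config.error_rate, rng)
        if rng.random() < 0.5:
            fragment = (3 - fragment)[::-1]  # reverse complement strand
        reads.append(Read(f"{id_prefix}.{i}", decode(fragment)))
    return reads


def simulate(config: SimConfig) -> tuple[TruthSet, dict[str, ReadSet], dict[str, LocusAlignment]]:
    """Generate a fully ground-truthed capture experiment.

    Returns the truth set (species tree, true per-locus alignments with
    probe spans, baits, read provenance), the per-sample read sets, and
    the true locus alignments keyed by locus id. Byte-identical outputs
    for identical configs.
    """
    streams = np.random.SeedSequence(config.seed).spawn(7)
    tree_seed = int(np.random.default_rng(streams[0]).integers(0, 2**31 - 1))
    rng_evolve = np.random.default_rng(streams[2])
    rng_capture = np.random.default_rng(streams[3])
    rng_reads = np.random.default_rng(streams[4])
    rng_paralog = np.random.default_rng(streams[5])
    rng_leak = np.random.default_rng(streams[6])

    tree = _simulate_tree(config, tree_seed)
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    samples = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())

    alignments: dict[str, LocusAlignment] = {}
    baits: dict[str, str] = {}
    taxon_sequences: dict[str, dict[str, str]] = {}
    present: dict[str, set] = {}
    reads_by_sample: dict[str, list[Read]] = {s: [] for s in samples}
    provenance: list[ProvenanceRecord] = []
    paralog_sequences: dict[tuple[str, str], str] = {}

    for li in range(config.n_loci):
        locus_id = f"L{li + 1:04d}"
        leaves, bait = _evolve_locus(tree, config, rng_evolve)
        baits[locus_id] = bait
        alignments[locus_id] = _locus_alignment(locus_id, leaves, config)
        taxon_sequences[locus_id] = {
            t: alignments[locus_id].row(t).replace("-", "") for t in sorted(leaves)
        }
        present[locus_id] = {
            t for t in samples if rng_capture.random() < config.capture_probability
        }

        for sample in samples:
            if sample not in present[locus_id]:
                continue
            seq = taxon_sequences[locus_id][sample]
            n_reads = int(np.ceil(config.depth * len(seq) / config.read_length))
            own = _make_reads(seq, n_reads, config, rng_reads, f"{sample}|{locus_id}|o")
            batch = [(r, "own") for r in own]
            if rng_paralog.random() < config.paralog_probability:
                para_seq = decode(
                    _mutate_uniform(encode(seq), config.paralog_divergence, rng_paralog)
                )
                paralog_sequences[(sample, locus_id)] = para_seq
                para = _make_reads(
                    para_seq, n_reads, config, rng_reads, f"{sample}|{locus_id}|p"
                )
                batch.extend((r, "paralog") for r in para)
            neighbor = samples[(samples.index(sample) + 1) % len(samples)]
            for read, origin in batch:
                if config.leakage_fraction and rng_leak.random() < config.leakage_fraction:
                    reads_by_sample[neighbor].append(read)
                    provenance.append(
                        ProvenanceRecord(neighbor, locus_id, read.read_id, "leaked", sample)
                    )
                else:
                    reads_by_sample[sample].append(read)
                    provenance.append(
                        ProvenanceRecord(sample, locus_id, read.read_id, origin, sample)
                    )

    readsets = {
        s: ReadSet(s, reads, barcode=f"BC{idx + 1:02d}")
        for idx, (s, reads) in enumerate(sorted(reads_by_sample.items()))
    }
    truth = TruthSet(
        tree, newick, alignments, baits, taxon_sequences, present, provenance,
        paralog_sequences,
    )
    return truth, readsets, alignments


# ---------------------------------------------------------------------------
# Synthetic probe-kit manifest
# ---------------------------------------------------------------------------

def design_kit_manifest(
    n_base_kit: int = 539, n_legacy: int = 24, n_vision: int = 8, seed: int = 0
) -> LocusManifest:
    """Synthetic stand-in for a published bombycoid AHE kit manifest.

    Mirrors the composition of the final kit this package models: loci
    carried over from the base anchor kit, legacy Sanger loci, and
    vision-related genes. Locus names and target lengths are synthetic.
    """
    rng = np.random.default_rng(seed)
    manifest = LocusManifest()
    legacy_names = [
        "CO1", "CAD", "DDC", "period", "wingless", "EF1a", "ArgK", "GAPDH",
        "IDH", "MDH", "RpS5", "RpS2", "ACC", "Wnt1", "Nex9", "HCL", "CPS",
        "PolII", "Ldh", "Enolase", "AlaRS", "TPI", "PGD", "FTZ",
    ][:n_legacy]
    for i in range(n_base_kit):
        name = f"AHE_L{i + 1:04d}"
        manifest.records[name] = ManifestRecord(
            name, ORIGIN_BASE_KIT, int(rng.integers(400, 1400))
        )
    for name in legacy_names:
        manifest.records[name] = ManifestRecord(
            name, ORIGIN_LEGACY, int(rng.integers(600, 2000))
        )
    for i in range(n_vision):
        name = f"vision_{i + 1:02d}"
        manifest.records[name] = ManifestRecord(
            name, ORIGIN_VISION, int(rng.integers(400, 1400))
        )
    return manifest


def manifest_table_text(manifest: LocusManifest) -> str:
    """Render a manifest as the TSV layout a kit supplementary table uses."""
    lines = ["locus_name\torigin\ttarget_length_bp"]
    origin_text = {
        ORIGIN_BASE_KIT: "base AHE kit",
        ORIGIN_LEGACY: "legacy Sanger locus",
        ORIGIN_VISION: "vision-related gene",
    }
    for rec in manifest.records.values():
        lines.append(f"{rec.locus_id}\t{origin_text[rec.origin]}\t{rec.target_length}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Distance, NJ, and RF oracles
# ---------------------------------------------------------------------------

def jc_distance_matrix(
    aln: LocusAlignment, max_distance: float = 5.0
) -> tuple[list[str], np.ndarray]:
    """Pairwise Jukes-Cantor distances with pairwise deletion of missing data.

    Saturated pairs (p >= 3/4) and pairs with no shared determinate
    columns are capped at ``max_distance``.
    """
    mats = np.frombuffer("".join(aln.rows).encode(), dtype=np.uint8).reshape(
        aln.n_taxa, aln.length
    )
    det = np.zeros(mats.shape, dtype=bool)
    for b in b"ACGT":
        det |= mats == b
    n = aln.n_taxa
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = det[i] & det[j]
            compared = int(both.sum())
            if compared == 0:
                d = max_distance
            else:
                p = float((mats[i][both] != mats[j][both]).sum() / compared)
                if p >= 0.7499:
                    d = max_distance
                else:
                    d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            dist[i, j] = dist[j, i] = min(d, max_distance)
    return list(aln.taxa), dist


def nj_tree(distances: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Tie-breaks follow taxon (input) order; raises on non-symmetric or
    negative input.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ParameterError("distance matrix must be square")
    if distances.shape[0] != len(labels):
        raise ParameterError("labels must match matrix dimension")
    if not np.allclose(distances, distances.T, atol=1e-9):
        raise ParameterError("distance matrix must be symmetric")
    if (distances < 0).any():
        raise ParameterError("distances must be non-negative")
    buf = _stdio.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for label, row in zip(labels, distances):
        buf.write(label + "," + ",".join(f"{x:.10g}" for x in row) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=buf, delimiter=",")
    tree = pdm.nj_tree()
    tree.is_rooted = False
    return tree


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Robinson-Foulds symmetric difference over non-trivial bipartitions."""
    leaves_a = {leaf.taxon.label for leaf in tree_a.leaf_node_iter()}
    leaves_b = {leaf.taxon.label for leaf in tree_b.leaf_node_iter()}
    if leaves_a != leaves_b:
        raise ParameterError(
            f"leaf sets differ: {sorted(leaves_a ^ leaves_b)}"
        )
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(
        data=tree_a.as_string(schema="newick", suppress_rooting=True),
        schema="newick", taxon_namespace=tns,
    )
    tb = dendropy.Tree.get(
        data=tree_b.as_string(schema="newick", suppress_rooting=True),
        schema="newick", taxon_namespace=tns,
    )
    ta.is_rooted = False
    tb.is_rooted = False
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(treecompare.symmetric_difference(ta, tb))
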