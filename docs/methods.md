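# Methods

`anchorpipe` re-implements, as a self-contained library and CLI, the data
processing that sits between raw target-capture reads and
inference-ready supermatrices in anchored-hybrid-enrichment (AHE)
phylogenomics: probe-baited iterative assembly with orthology and
contamination screening, site-wise curation of locus alignments,
locus-level informativeness filtering, and concatenation with explicit
partition schemes. A ground-truthed simulator generates every input the
pipeline consumes, so each stage is validated end to end without
external data.

## Assembly model

Each locus is assembled per sample from that sample's full read pool.

1. **Recruitment.** Reads sharing at least one exact k-mer (default
   k = 31) with the bait sequence or its reverse complement are
   recruited. Recruitment is monotone in k by construction.
2. **Placement.** A recruited read is placed on the growing consensus at
   the offset implied by its first shared k-mer (strand from the shared
   k-mer's orientation). Reads carry substitution error only at the
   identities involved (>= ~95%), so ungapped offset placement is exact;
   a banded alignment would recover the same offsets at much higher
   cost. An inverted k-mer index per sample makes recruitment and
   placement sub-millisecond per locus.
3. **Consensus.** Per column, a base is called where read depth reaches
   `min_depth` (default 2) *and* one base holds a strict majority; ties
   yield `N`. Undercalled columns are trimmed at the ends and masked `N`
   in the interior (flag `low_coverage`). The loop
   {recruit against the current consensus, place, re-call} runs to a
   fixpoint or `max_iterations` (default 10), extending the consensus
   beyond the bait into the flanks. Consensuses shorter than
   `min_consensus_length` (default 60 called columns, i.e. anything a
   screen could not judge) are reported `absent`.
4. **Orthology.** Reads are admitted to the consensus only at identity
   >= 1 − d_p (d_p = 0.05) over at least 60 overlapping columns; the
   first, bait-seeded round bootstraps the on-target cluster (divergent
   paralogous copies rarely share exact 31-mers with the reference).
   Lower-identity reads accumulate as a second cluster and are re-judged
   each iteration. If the second cluster holds >= `paralog_min_fraction`
   (default 0.1) of the on-target reads (and >= 3), the locus is flagged
   `paralog_detected` and the cluster closest to the reference is kept
   (ties: higher depth, then lexicographic). The 0.1 fraction sits well
   above barcode-leakage noise (a few percent of reads) and well below
   the weakest expected paralog signal (a co-captured copy contributes
   reads at a rate comparable to the target).

   Copies diverged far beyond 2·d_p share *no* exact 31-mer with the
   consensus and would be invisible to the assembly k-mer, so a second,
   short-seed scan (`paralog_scan_k` = 15) of the not-yet-placed reads
   supplies additional divergent-copy evidence: reads aligning at
   identity in [0.60, 1 − d_p) over >= 60 columns count toward the same
   threshold. Detection is thereby decoupled from consensus building.

   The public `resolve_paralogs` operation on contig-level input
   performs literal single-linkage clustering at pairwise identity
   >= 1 − d_p; the streaming read-level partition above coincides with it
   whenever two haplotype clusters are separated by >= 2·d_p.
5. **Contamination screen.** For each locus, every cross-sample pair of
   consensuses from different taxa is compared at its best ungapped
   offset; at identity >= c_i (default 0.99) over >= 60 determinate
   columns the lower-mean-depth member is flagged
   `contamination_suspect` (both, if depths tie — the suspicion is
   symmetric). Conspecific replicates can be exempted via a
   sample-to-taxon map, since identical conspecific sequences are
   biology, not index hopping.

## Curation model

Site **density** is the fraction of taxa with a determinate residue
(A/C/G/T; gaps, `N`, `?` and IUPAC ambiguity codes all count as
missing). Site **entropy** is base-2 Shannon entropy over determinate
residue frequencies only, so the DNA range is [0, 2] bits; an
all-missing column has entropy 0. Base 2 is the only convention under
which the conventional 1.5 cutoff is attainable for four states
(ln 4 ≈ 1.386 < 1.5), and it makes the cutoff sit meaningfully between
"two equally frequent states" (1.0) and "four equally frequent states"
(2.0).

Flank columns are **deleted** (not masked) unless density >= 0.60 and
entropy <= 1.5 bits; boundary values are kept on both cutoffs (a column
with exactly 60% occupancy is represented well enough, and only entropy
strictly above 1.5 marks saturation). Probe columns are never touched,
and the probe span is re-indexed after trimming, which makes the
operation idempotent. Density is computed over all taxa in the
alignment by default — a sampled-but-unrecovered taxon is missing data,
not a smaller denominator — with
`CurationConfig.density_over_recovered_taxa` switching to the
recovered-taxa interpretation for users who prefer it.

Reading frames are chosen by data rather than by eye: all three frames
are scored by total internal stop codons across taxa; the minimum wins,
ties to the lowest frame index. Codons containing gaps or ambiguity
translate to `X`; remaining internal stops are replaced by `X` and
reported per taxon as putative frame shifts or sequencing errors; a
trailing codon column consisting solely of stops is dropped as a shared
terminal stop. If more than half the sequenced taxa still show internal
stops in the best frame, the locus is flagged `frame_shift_suspect` and
its translation is withheld from the amino-acid dataset.

## Locus selection

Segregating sites are columns with >= 2 distinct determinate states;
parsimony-informative columns additionally require two states each in
>= 2 taxa. Loci enter phylogenetic analysis when recovered in >= 40% of
sampled taxa; probe-kit design keeps loci capturing in >= 60% of the
design panel. "Phylogenetically uninformative" is operationalized as
pic == 0 or amino-acid invariance (no two determinate residues differ
anywhere in the translated probe); the ranked report (pic desc,
seg_sites desc, recovery desc, locus id asc) lets users apply their own
cut.

## Supermatrix construction

Three dataset shapes: `prfl` (one DNA partition per probe region in
lexicographic locus order, followed by a single partition concatenating
all flanks — after curation the flank columns are site-homologous and
are treated as one SNP-like block, concatenated in locus order), `aa`
(one protein partition per locus, amino-acid-invariant loci excluded),
and `genewise` (per-locus files for gene-tree inference). Taxa missing
from a locus are padded with `-`; labels are normalized (whitespace to
underscore, word characters only) for Newick/partition-file safety.
Loci are sorted by id before concatenation so builds are bit-exact
regardless of file discovery order. Internally all coordinates are
0-based half-open; emitted partition files (RAxML-style or NEXUS sets)
are 1-based inclusive.

## The simulator

The generator emulates the structure AHE data is assumed to have, with
these defaults as the study conditions: 12 taxa, 40 loci, a 210 bp
in-frame probe core with 200 bp flanks per side, 100 bp reads at 20x
depth and 1% substitution error, and 85% per-locus capture probability.

* **Species tree**: Yule (pure birth, dendropy), rescaled so the
  root-to-tip depth is `tree_height` = 0.12 expected substitutions per
  site — conserved-exon divergence to a clade-level reference at which
  exact 31-mer bait seeding is realistic — with a minimum branch length
  of 0.01 so simulated taxa are distinct at species level (pairwise
  identity stays below the 0.99 contamination threshold).
* **Sequences**: JC69 (default) or K2P evolved along the tree; the probe
  evolves at 0.4x the base rate with no indels and no internal stop
  codons in frame 0 (stop-creating mutations revert to the parent
  codon); flanks evolve at 2x with indels modeled as deletions relative
  to the ancestral sequence (a deleted column is a gap in the affected
  clade). Deletion-only indels keep true-alignment bookkeeping exact;
  insertions would add columns gapped everywhere else without changing
  what the pipeline is tested on.
* **Reads**: uniform starts, random strand, per-base substitution
  error. Barcode leakage follows adjacent-index hopping: each sample
  leaks each read with probability `leakage_fraction` to one fixed
  neighbor, concentrating the signal the screen is designed to catch.
  Paralogs are injected per present (sample, locus) with probability
  `paralog_probability` as a copy mutated at `paralog_divergence` = 0.10
  per site, read-sampled at full depth.
* **Reproducibility**: one seed; independent generators for tree, root
  sequences, evolution, capture, reads, paralogs, and leakage are
  spawned from it in that fixed order, so outputs are byte-identical per
  seed.

What the simulator does **not** emulate: coalescent gene-tree
discordance, base-composition heterogeneity, rate variation across
sites, adapter/quality artifacts, codon models, and insertion events.
Passing the end-to-end tests therefore demonstrates the pipeline's
correctness under its own assumptions, not robustness to every property
of real capture data.

A companion generator reproduces the composition of the probe-kit
manifest the package models (539 base-kit + 24 legacy + 8 vision = 571
loci) with synthetic names and lengths, for exercising manifest parsing
without the original supplementary table.

## Desk-scale inference oracles

The package stops at inference-ready inputs; for validation it carries a
neighbor-joining tree builder (dendropy) over Jukes-Cantor distances
with pairwise deletion (saturated pairs capped), and Robinson-Foulds
distances over non-trivial bipartitions. The end-to-end check —
simulate, assemble, screen, MAFFT-align the surviving consensuses,
locate the probe span by bait anchoring, trim, filter at 40% recovery,
concatenate probe+flank, NJ — recovers the true topology (RF = 0) in at
least 19 of 20 seeded replicates at the default conditions with 2%
leakage. Problem sizes throughout the validation suite (12 taxa, 40
loci, 20 replicates) were chosen as the smallest at which all signals
(leakage, paralogy, saturation, dropout) are simultaneously active and
measurable.

## Numerical and degenerate-input choices

* Consensus ties at any depth yield `N`, never an arbitrary base.
* Assembly is deterministic given the configuration and input order;
  all tie-breaks (cluster choice, report ranking, placement) resolve
  lexicographically or by stated depth rules.
* JC distance for pairs with no shared determinate column, or with
  p >= 3/4, is capped at 5.0 substitutions/site.
* Empty probe spans raise; a probe span covering the whole alignment
  yields an empty flank partition with a log note.
* Unknown residue characters are mapped to `N`/`X` on input with a
  logged warning; ambiguity codes are stored but treated as missing by
  every statistic.

## Known limitations

* The assembler is a deliberate simplification: no de Bruijn contigging,
  no quality-score use, no indel-aware read placement. It is adequate
  for capture data dominated by substitution divergence, which is what
  the simulator produces and what probe regions look like in practice.
* Paralog detection requires the copy to be recruitable at the scan
  k-mer and co-captured at appreciable depth; copies below 2·d_p
  divergence are by design inside the within-locus identity band and are
  not separable.
* A sample whose target copy drops out but whose paralog is captured
  assembles the paralog with no second cluster to warn on; only
  cross-sample comparison could catch this case.
* Contamination screening compares assembled consensuses, not reads, so
  leakage into a locus that fails to assemble is invisible (and
  harmless downstream).
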