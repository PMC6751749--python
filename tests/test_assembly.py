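"""Read recruitment, iterative consensus assembly, paralog resolution,
and the cross-sample contamination screen."""

import random

import numpy as np
import pytest

from _oracles import revcomp, shared_kmer
from anchorpipe.assembly import (
    AssemblyConfig,
    AssemblyResult,
    Read,
    ReadSet,
    contamination_screen,
    iterative_assemble,
    recruit_reads,
    resolve_paralogs,
    ungapped_identity,
)
from anchorpipe.errors import ParameterError


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _tile_reads(seq, read_len=100, step=5, prefix="r"):
    reads = []
    for i, start in enumerate(range(0, len(seq) - read_len + 1, step)):
        reads.append(Read(f"{prefix}{i}", seq[start: start + read_len]))
    return reads


class TestConfigValidation:
    def test_defaults_valid(self):
        AssemblyConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k": 10},  # even
            {"k": 9},  # too small
            {"paralog_divergence": 0.0},
            {"contamination_identity": 1.5},
            {"min_depth": 0},
        ],
    )
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            AssemblyConfig(**kwargs)


class TestRecruitReads:
    def test_verbatim_reads_all_recruited(self, rng):
        bait = _random_seq(rng, 200)
        reads = _tile_reads(bait, 60, 20)
        assert recruit_reads(reads, bait, 31) == reads

    def test_unrelated_reads_rejected_per_brute_force(self, rng):
        bait = _random_seq(rng, 200)
        reads = [Read(f"x{i}", _random_seq(rng, 60)) for i in range(30)]
        recruited = recruit_reads(reads, bait, 31)
        expected = [
            r for r in reads
            if shared_kmer(bait, r.sequence, 31)
            or shared_kmer(revcomp(bait), r.sequence, 31)
        ]
        assert recruited == expected
        assert recruited == []  # 31-mer collision is essentially impossible

    def test_reverse_complement_read_recruited(self, rng):
        bait = _random_seq(rng, 200)
        read = Read("rc", revcomp(bait[50:130]))
        assert recruit_reads([read], bait, 31) == [read]

    def test_bait_shorter_than_k_rejected(self):
        with pytest.raises(ParameterError):
            recruit_reads([], "ACGT", 31)

    def test_recruitment_monotone_in_k(self, rng):
        bait = _random_seq(rng, 150)
        reads = []
        for i in range(40):
            if rng.random() < 0.5:
                start = rng.randrange(0, 90)
                seq = bait[start: start + 60]
                # sprinkle errors to vary shared k-mer lengths
                seq = "".join(
                    rng.choice("ACGT") if rng.random() < 0.05 else c for c in seq
                )
                reads.append(Read(f"m{i}", seq))
            else:
                reads.append(Read(f"m{i}", _random_seq(rng, 60)))
        for k in (11, 15, 21):
            small = {r.read_id for r in recruit_reads(reads, bait, k)}
            large = {r.read_id for r in recruit_reads(reads, bait, k + 2)}
            assert large <= small


class TestIterativeAssemble:
    def test_error_free_reads_recover_full_truth(self, rng):
        truth = _random_seq(rng, 600)
        bait = truth[200:400]
        reads = _tile_reads(truth, 100, 5)
        # double up terminal reads so the ends reach min_depth
        reads += [Read("dupL", truth[:100]), Read("dupR", truth[500:])]
        config = AssemblyConfig(min_depth=2)
        result = iterative_assemble(reads, bait, config)
        assert result.consensus == truth
        assert len(result.support) == 600
        assert result.flags == set()

    def test_no_recruited_reads_yields_absent(self, rng):
        bait = _random_seq(rng, 200)
        reads = [Read(f"x{i}", _random_seq(rng, 80)) for i in range(10)]
        result = iterative_assemble(reads, bait, AssemblyConfig())
        assert result.flags == {"absent"}
        assert result.consensus is None

    def test_depth_one_ends_trimmed_and_interior_masked(self, rng):
        truth = _random_seq(rng, 400)
        bait = truth[100:300]
        # depth 2 on [100, 180) and [220, 300), a thin interior stretch in
        # between, and single-copy overhangs on both ends
        reads = [
            Read("left", truth[60:180]),
            Read("a", truth[100:185]),
            Read("b", truth[100:180]),
            Read("c", truth[220:300]),
            Read("d", truth[215:340]),
        ]
        config = AssemblyConfig(min_depth=2, min_consensus_length=20)
        result = iterative_assemble(reads, bait, config)
        assert "low_coverage" in result.flags
        # ends below min_depth are trimmed: consensus confined to [100, 300)
        assert len(result.consensus) == 200
        called = [
            (c, t)
            for c, t in zip(result.consensus, truth[100:300])
            if c != "N"
        ]
        assert all(c == t for c, t in called)
        assert "N" in result.consensus  # interior hole masked, not deleted

    def test_deterministic_across_runs(self, rng):
        truth = _random_seq(rng, 500)
        bait = truth[150:350]
        reads = _tile_reads(truth, 90, 7)
        config = AssemblyConfig()
        r1 = iterative_assemble(reads, bait, config)
        r2 = iterative_assemble(reads, bait, config)
        assert r1.consensus == r2.consensus
        assert np.array_equal(r1.support, r2.support)


class TestResolveParalogs:
    def _diverge(self, rng, seq, rate):
        out = []
        for c in seq:
            if rng.random() < rate:
                out.append(rng.choice([b for b in "ACGT" if b != c]))
            else:
                out.append(c)
        return "".join(out)

    def test_single_cluster_unchanged_without_flag(self, rng):
        seq = _random_seq(rng, 300)
        cons, flagged = resolve_paralogs([seq], seq, 0.05)
        assert cons == seq
        assert not flagged

    def test_two_clusters_keep_reference_closest(self, rng):
        reference = _random_seq(rng, 300)
        ortholog = self._diverge(rng, reference, 0.02)
        paralog = self._diverge(rng, ortholog, 0.10)
        cons, flagged = resolve_paralogs([paralog, ortholog], reference, 0.05)
        assert flagged
        assert cons == ortholog

    def test_reference_tie_broken_by_depth(self, rng):
        reference = _random_seq(rng, 300)
        # two copies exactly equidistant from the reference: disjoint
        # mutated site sets of equal size
        a = list(reference)
        b = list(reference)
        sites = rng.sample(range(300), 40)
        for s in sites[:20]:
            a[s] = {"A": "C", "C": "A", "G": "T", "T": "G"}[a[s]]
        for s in sites[20:]:
            b[s] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[s]]
        a, b = "".join(a), "".join(b)
        cons, flagged = resolve_paralogs([a, b], reference, 0.05, depths=[3.0, 9.0])
        assert flagged
        assert cons == b

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            resolve_paralogs([], "ACGT" * 20)


class TestUngappedIdentity:
    def test_identical_and_reverse_complement(self, rng):
        seq = _random_seq(rng, 250)
        assert ungapped_identity(seq, seq) == (1.0, 250)
        ident, overlap = ungapped_identity(seq, revcomp(seq))
        assert ident == 1.0 and overlap == 250

    def test_offset_fragment(self, rng):
        seq = _random_seq(rng, 300)
        ident, overlap = ungapped_identity(seq, seq[100:200])
        assert ident == 1.0 and overlap == 100

    def test_unrelated_sequences_share_nothing(self, rng):
        assert ungapped_identity(_random_seq(rng, 100), _random_seq(rng, 100))[1] == 0


def _result(sample, depth, consensus, locus="L1"):
    support = np.full(len(consensus), depth)
    return AssemblyResult(sample, locus, consensus, support, set())


class TestContaminationScreen:
    def test_identical_pair_flags_low_depth_member(self, rng):
        seq = _random_seq(rng, 300)
        high = _result("s1", 40, seq)
        low = _result("s2", 3, seq)
        contamination_screen([high, low], 0.99)
        assert "contamination_suspect" in low.flags
        assert "contamination_suspect" not in high.flags

    def test_diverged_pairs_not_flagged(self, rng):
        seq = _random_seq(rng, 300)
        other = TestResolveParalogs()._diverge(rng, seq, 0.05)
        a, b = _result("s1", 40, seq), _result("s2", 3, other)
        contamination_screen([a, b], 0.99)
        assert not a.flags and not b.flags

    def test_conspecific_replicates_exempt(self, rng):
        seq = _random_seq(rng, 300)
        a, b = _result("s1", 40, seq), _result("s2", 3, seq)
        contamination_screen([a, b], 0.99, sample_taxon={"s1": "sp1", "s2": "sp1"})
        assert not a.flags and not b.flags

    def test_equal_depths_flag_both(self, rng):
        seq = _random_seq(rng, 300)
        a, b = _result("s1", 10, seq), _result("s2", 10, seq)
        contamination_screen([a, b], 0.99)
        assert "contamination_suspect" in a.flags
        assert "contamination_suspect" in b.flags

    def test_short_overlap_ignored(self, rng):
        seq = _random_seq(rng, 300)
        a = _result("s1", 40, seq)
        b = _result("s2", 3, seq[:40])
        contamination_screen([a, b], 0.99, min_overlap=60)
        assert not b.flags


class TestReadSetInvariants:
    def test_duplicate_read_ids_rejected(self):
        with pytest.raises(ParameterError):
            ReadSet("s", [Read("r1", "ACGT"), Read("r1", "ACGT")])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            ReadSet("s", [Read("r1", "")])
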