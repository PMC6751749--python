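"""The synthetic-data generator and its inference oracles."""

import math

import numpy as np
import pytest

from _oracles import brute_rf, jc_expected_p
from anchorpipe.curation import CurationConfig, site_profile
from anchorpipe.errors import ParameterError
from anchorpipe.simulate import (
    SimConfig,
    design_kit_manifest,
    evolve_sequence,
    jc_distance_matrix,
    manifest_table_text,
    nj_tree,
    rf_distance,
    simulate,
)
from anchorpipe.assembly import encode, decode
from anchorpipe.io import LocusAlignment

SMALL = dict(n_taxa=6, n_loci=4, depth=8)


class TestConfigValidation:
    def test_defaults_valid(self):
        SimConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_taxa": 2},
            {"probe_len": 200},  # not a codon multiple
            {"capture_probability": 1.5},
            {"probe_rate_multiplier": 1.2},  # must slow the probe down
            {"flank_rate_multiplier": 0.5},  # must speed the flanks up
            {"substitution_model": "GTR"},
        ],
    )
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SimConfig(**kwargs)


class TestDeterminismAndProvenance:
    def test_same_seed_byte_identical(self):
        a = simulate(SimConfig(seed=5, **SMALL))
        b = simulate(SimConfig(seed=5, **SMALL))
        assert a[0].newick == b[0].newick
        for s in a[1]:
            assert [(r.read_id, r.sequence) for r in a[1][s].reads] == [
                (r.read_id, r.sequence) for r in b[1][s].reads
            ]
        for locus in a[2]:
            assert a[2][locus].rows == b[2][locus].rows

    def test_different_seed_differs(self):
        a = simulate(SimConfig(seed=5, **SMALL))
        b = simulate(SimConfig(seed=6, **SMALL))
        assert a[0].newick != b[0].newick

    def test_no_leakage_no_paralogs_means_all_own(self):
        truth, _, _ = simulate(SimConfig(seed=5, **SMALL))
        assert {p.origin for p in truth.provenance} == {"own"}
        assert all(p.sample_id == p.source_sample for p in truth.provenance)

    def test_leakage_moves_reads_to_neighbor(self):
        truth, readsets, _ = simulate(
            SimConfig(seed=5, leakage_fraction=0.1, **SMALL)
        )
        leaked = [p for p in truth.provenance if p.origin == "leaked"]
        assert leaked
        assert all(p.sample_id != p.source_sample for p in leaked)
        ids = {s: {r.read_id for r in rs.reads} for s, rs in readsets.items()}
        for p in leaked:
            assert p.read_id in ids[p.sample_id]


class TestTreeShape:
    def test_branch_length_floor_and_height(self):
        truth, _, _ = simulate(SimConfig(seed=9, **SMALL))
        for edge in truth.tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= SimConfig().min_branch_length - 1e-12

    def test_structure_of_true_alignments(self):
        config = SimConfig(seed=9, **SMALL)
        truth, _, alns = simulate(config)
        for locus, aln in alns.items():
            assert aln.length == config.probe_len + 2 * config.flank_len
            assert aln.probe_span == (config.flank_len, config.flank_len + config.probe_len)
            start, end = aln.probe_span
            for row in aln.rows:
                assert "-" not in row[start:end]  # probe is indel-free
            assert truth.baits[locus] == truth.baits[locus].upper()


class TestSubstitutionModels:
    @pytest.mark.parametrize("model", ["JC69", "K2P"])
    def test_closed_form_divergence_at_10kb(self, model):
        rng = np.random.default_rng(7)
        seq = rng.integers(0, 4, 10_000).astype(np.uint8)
        t = 0.25
        evolved = evolve_sequence(seq, t, rng, model=model)
        p_obs = float((seq != evolved).mean())
        p_exp = jc_expected_p(t)  # K2P with any kappa has the same total p
        se = math.sqrt(p_exp * (1 - p_exp) / 10_000)
        assert abs(p_obs - p_exp) <= 3 * se

    def test_k2p_transitions_exceed_transversions(self):
        rng = np.random.default_rng(7)
        seq = rng.integers(0, 4, 20_000).astype(np.uint8)
        evolved = evolve_sequence(seq, 0.2, rng, model="K2P", kappa=4.0)
        diff = seq != evolved
        transition = ((seq + 2) % 4 == evolved) & diff
        ts = int(transition.sum())
        tv = int(diff.sum()) - ts
        assert ts > tv  # kappa=4 biases toward transitions

    def test_probe_has_no_internal_stops_in_frame_zero(self):
        config = SimConfig(seed=11, **SMALL)
        _, _, alns = simulate(config)
        stops = {"TAA", "TAG", "TGA"}
        for aln in alns.values():
            start, end = aln.probe_span
            for row in aln.rows:
                probe = row[start:end]
                codons = [probe[i: i + 3] for i in range(0, len(probe) - 3, 3)]
                assert not stops & set(codons[:-1] if codons else [])


class TestDropoutCalibration:
    def test_realized_recovery_within_binomial_ci(self):
        config = SimConfig(seed=13, n_taxa=10, n_loci=40, depth=4)
        truth, _, _ = simulate(config)
        n = config.n_taxa * config.n_loci
        k = sum(len(v) for v in truth.present.values())
        p = config.capture_probability
        se = math.sqrt(p * (1 - p) / n)
        assert abs(k / n - p) <= 1.96 * se + 1e-9


class TestTrimmingEnrichment:
    def test_faster_flanks_lose_more_columns(self):
        base = dict(n_taxa=10, n_loci=6, depth=4, seed=21)
        slow = SimConfig(flank_rate_multiplier=1.000001, **base)
        fast = SimConfig(flank_rate_multiplier=3.0, **base)

        def deleted_fraction(config):
            _, _, alns = simulate(config)
            removed = total = 0
            for aln in alns.values():
                profile = site_profile(aln, CurationConfig())
                flank = ~profile.in_probe
                removed += int((flank & ~profile.retained).sum())
                total += int(flank.sum())
            return removed / total

        assert deleted_fraction(fast) > deleted_fraction(slow)


class TestManifestGenerator:
    def test_published_kit_composition(self):
        manifest = design_kit_manifest()
        assert len(manifest) == 571
        assert manifest.count_origin("base-kit") == 539
        assert manifest.count_origin("legacy") == 24
        assert manifest.count_origin("vision") == 8
        text = manifest_table_text(manifest)
        assert text.startswith("locus_name\torigin\ttarget_length_bp")


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # unrooted tree ((A:2,B:3):1,(C:4,D:5)); path distances are additive
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 0, 0],
            ],
            dtype=float,
        )
        d[3, 2] = d[2, 3] = 9
        d[3, 3] = 0
        tree = nj_tree(d, labels)
        assert rf_distance(tree, _tree("((A:2,B:3):1,(C:4,D:5));")) == 0
        assert sum(e.length for e in tree.preorder_edge_iter() if e.length) == pytest.approx(15.0)

    def test_three_taxa_resolve_to_star(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = nj_tree(d, ["a", "b", "c"])
        assert len(tree.leaf_nodes()) == 3

    def test_label_permutation_preserves_topology(self):
        rng = np.random.default_rng(3)
        # distances from a fixed 5-taxon tree plus tiny tie-free jitter
        base = _tree("((a:1,b:1.2):0.5,(c:0.9,(d:1.1,e:1.3):0.4):0.3);")
        labels = ["a", "b", "c", "d", "e"]
        pdm = {
            (i, j): _patristic(base, x, y)
            for i, x in enumerate(labels)
            for j, y in enumerate(labels)
        }
        d = np.zeros((5, 5))
        for (i, j), v in pdm.items():
            d[i, j] = v
        t1 = nj_tree(d, labels)
        perm = [3, 1, 4, 0, 2]
        d2 = d[np.ix_(perm, perm)]
        t2 = nj_tree(d2, [labels[i] for i in perm])
        assert rf_distance(t1, t2) == 0

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ParameterError):
            nj_tree(np.array([[0, 1], [2, 0]], dtype=float), ["a", "b"])
        with pytest.raises(ParameterError):
            nj_tree(np.zeros((2, 3)), ["a", "b"])
        with pytest.raises(ParameterError):
            nj_tree(-np.ones((2, 2)) + np.eye(2), ["a", "b"])


def _tree(newick):
    import dendropy

    return dendropy.Tree.get(data=newick, schema="newick")


def _patristic(tree, a, b):
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    return pdm.patristic_distance(
        tns.get_taxon(a), tns.get_taxon(b)
    )


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t = _tree("((a,b),(c,d));")
        assert rf_distance(t, _tree("((a,b),(c,d));")) == 0

    def test_conflicting_quartets(self):
        assert rf_distance(_tree("((a,b),(c,d));"), _tree("((a,c),(b,d));")) == 2

    def test_matches_brute_force_on_random_eight_taxon_trees(self):
        import dendropy
        import random as pyrandom

        taxa = [f"x{i}" for i in range(8)]
        rng = pyrandom.Random(17)
        for _ in range(10):
            tns = dendropy.TaxonNamespace(taxa)
            a = dendropy.simulate.treesim.birth_death_tree(
                1.0, 0.0, num_extant_tips=8, rng=rng, taxon_namespace=tns
            )
            b = dendropy.simulate.treesim.birth_death_tree(
                1.0, 0.0, num_extant_tips=8, rng=rng, taxon_namespace=tns
            )
            for t in (a, b):
                for i, leaf in enumerate(t.leaf_node_iter()):
                    leaf.taxon = tns.get_taxon(taxa[i])
            na = a.as_string(schema="newick", suppress_rooting=True)
            nb = b.as_string(schema="newick", suppress_rooting=True)
            assert rf_distance(a, b) == brute_rf(na, nb)

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            rf_distance(_tree("((a,b),(c,d));"), _tree("((a,b),(c,e));"))


class TestJcDistances:
    def test_zero_for_identical_rows_and_symmetry(self):
        aln = LocusAlignment("x", ["a", "b"], ["ACGT" * 50, "ACGT" * 50], (0, 0))
        labels, d = jc_distance_matrix(aln)
        assert d[0, 1] == 0.0

    def test_matches_closed_form(self):
        rng = np.random.default_rng(23)
        seq = rng.integers(0, 4, 20_000).astype(np.uint8)
        evolved = evolve_sequence(seq, 0.3, rng)
        aln = LocusAlignment("x", ["a", "b"], [decode(seq), decode(evolved)], (0, 0))
        _, d = jc_distance_matrix(aln)
        assert d[0, 1] == pytest.approx(0.3, rel=0.1)
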