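import numpy as np
import pytest

from popflux.coalsim import SimulationConfig
from popflux.seqdata import (EXON, RegionAnnotation, Segment,
                             build_codon_map, validate_frame)
from popflux.siteclass import classify_columns, polarize, translate
from popflux.mkt import build_mk_table, classify_sites_mk
from popflux.substmap import GeneTree
from popflux.synthetic import (TruthLog, evolve_on_tree, make_mk_fixture,
                               make_population_alignment,
                               random_coding_sequence)


def spliced_annotation(n_codons=60, intron_length=45):
    half = (n_codons // 2) * 3
    L = n_codons * 3 + intron_length
    segs = [Segment(0, half, EXON, 0),
            Segment(half, half + intron_length, "intron"),
            Segment(half + intron_length, L, EXON, 0)]
    return RegionAnnotation(segments=segs, L=L), L, half


def make_ancestral(n_codons, intron_length, seed=0):
    ann, L, half = spliced_annotation(n_codons, intron_length)
    coding = random_coding_sequence(n_codons, np.random.default_rng(seed))
    anc = coding[:half] + "T" * intron_length + coding[half:]
    return ann, anc, L


def population_cfg(L, theta=0.01, n=10, seed=0):
    return SimulationConfig(n=n, L=L, R=0.0,
                            fixed_params={"theta_per_site": theta},
                            replicates=1, seed=seed)


class TestPopulationAlignment:
    def test_zero_mutation_rate_gives_identical_rows(self):
        ann, anc, L = make_ancestral(30, 30)
        aln, truth = make_population_alignment(
            population_cfg(L, theta=0.0), anc, ann, seed=1)
        assert not truth.entries
        assert all("".join(row) == anc for row in aln.matrix)

    def test_generated_alignment_is_in_frame(self):
        ann, anc, L = make_ancestral(60, 45)
        aln, _ = make_population_alignment(
            population_cfg(L, theta=0.02), anc, ann, outgroup_divergence=4,
            seed=2)
        assert validate_frame(aln, ann).passed

    def test_planted_class_quotas_recovered_by_classifier(self):
        ann, anc, L = make_ancestral(60, 45)
        aln, truth = make_population_alignment(
            population_cfg(L, theta=0.02, seed=4), anc, ann,
            class_mix={"synonymous": 1.0}, seed=4)
        variants = truth.of_kind("polymorphism")
        assert variants, "expected at least one variant for this seed"
        cmap = build_codon_map(ann, L)
        st = classify_columns(aln, cmap, species=["popA"])
        for e in variants:
            assert st.column_class[e["column"]] == "synonymous"

    def test_polarize_recovers_every_variant_without_outgroup_divergence(self):
        ann, anc, L = make_ancestral(60, 45)
        aln, truth = make_population_alignment(
            population_cfg(L, theta=0.02, seed=5), anc, ann,
            outgroup_divergence=0, seed=5)
        res = polarize(aln, ["out1"], focal_species="popA")
        by_col = {v.column: v for v in res.variants}
        for e in truth.of_kind("polymorphism"):
            v = by_col[e["column"]]
            assert v.derived == e["derived"]
            assert v.derived_count == len(e["carriers"])

    def test_quota_exhaustion_is_an_error(self):
        # one intron column cannot hold many variants
        ann = RegionAnnotation(segments=[Segment(0, 3, EXON, 0),
                                         Segment(3, 4, "intron")], L=4)
        cfg = SimulationConfig(n=6, L=4, R=0.0,
                               fixed_params={"theta_locus": 20.0},
                               replicates=1, seed=11)
        with pytest.raises(ValueError, match="available sites"):
            make_population_alignment(cfg, "ATGT", ann,
                                      class_mix={"intron": 1.0}, seed=11)

    def test_seed_determinism_is_byte_identical(self):
        ann, anc, L = make_ancestral(40, 30)
        a1, t1 = make_population_alignment(
            population_cfg(L, theta=0.02), anc, ann, seed=7)
        a2, t2 = make_population_alignment(
            population_cfg(L, theta=0.02), anc, ann, seed=7)
        assert np.array_equal(a1.matrix, a2.matrix)
        assert t1.entries == t2.entries

    def test_truth_log_replays_to_emitted_matrix(self):
        ann, anc, L = make_ancestral(40, 30)
        aln, truth = make_population_alignment(
            population_cfg(L, theta=0.03, n=8, seed=8), anc, ann,
            outgroup_divergence=3, seed=8)
        replay = np.tile(np.array(list(anc), dtype="U1"),
                         (aln.matrix.shape[0], 1))
        for e in truth.entries:
            for r in e["carriers"]:
                replay[r, e["column"]] = e["derived"]
        assert np.array_equal(replay, aln.matrix)


class TestEvolveOnTree:
    TREE = "((A:0.5,B:0.5):0.3,(C:0.5,D:0.5):0.3);"

    def test_zero_rates_leave_tips_identical(self):
        tree = GeneTree.from_newick(self.TREE)
        codons = ["ATG", "GGC", "CTG"]
        tips, truth = evolve_on_tree(tree, codons, 0.0, 0.0, seed=1)
        assert not truth.entries
        assert all(tips[lf] == codons for lf in "ABCD")

    def test_truth_log_replays_to_tips(self):
        tree = GeneTree.from_newick(self.TREE)
        seq = random_coding_sequence(50, np.random.default_rng(2))
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        tips, truth = evolve_on_tree(tree, codons, 0.2, 0.2, seed=3)

        def path_to(node, leaf):
            if node.is_leaf:
                return [] if node.name == leaf else None
            for ch in node.children:
                below = path_to(ch, leaf)
                if below is not None:
                    return [ch.name] + below
            return None

        paths = {leaf: path_to(tree.root, leaf) for leaf in "ABCD"}
        for leaf, path in paths.items():
            seq_now = list(codons)
            for e in truth.entries:
                if e["branch"] in path:
                    assert seq_now[e["codon"]] == e["from_codon"]
                    seq_now[e["codon"]] = e["to_codon"]
            assert seq_now == tips[leaf]

    def test_events_are_logged_once_each(self):
        tree = GeneTree.from_newick(self.TREE)
        codons = [random_coding_sequence(30, np.random.default_rng(4))[i:i+3]
                  for i in range(0, 90, 3)]
        tips, truth = evolve_on_tree(tree, codons, 0.3, 0.1, seed=5)
        for e in truth.entries:
            assert e["kind"] in ("syn", "nonsyn")
            same_aa = translate(e["from_codon"]) == translate(e["to_codon"])
            assert same_aa == (e["kind"] == "syn")

    def test_preference_bias_skews_synonymous_flux(self, dmel_pref):
        tree = GeneTree.from_newick("(A:4.0,B:0.0001);")
        codons = ["GGA"] * 300  # unpreferred Gly, one-step to preferred GGC
        _, up_truth = evolve_on_tree(tree, codons, syn_rate=0.1,
                                     nonsyn_rate=0.0, pref=dmel_pref,
                                     pref_bias=0.95, seed=6)
        to_pref = sum(1 for e in up_truth.of_kind("syn")
                      if dmel_pref.of(e["to_codon"]) == "preferred")
        total = len(up_truth.of_kind("syn"))
        assert total > 50
        assert to_pref / total > 0.7


class TestMKFixture:
    def test_round_trip_of_random_feasible_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            counts = tuple(int(x) for x in rng.integers(0, 25, size=4))
            aln, ann = make_mk_fixture(counts, n_per_species=6,
                                       seed=int(rng.integers(2 ** 31)))
            cmap = build_codon_map(ann, aln.L)
            table = build_mk_table(
                classify_sites_mk(aln, {"popA", "popB"}, {"out"}),
                classify_columns(aln, cmap))
            assert table.cells == counts

    def test_all_invariant_fixture(self):
        aln, ann = make_mk_fixture((0, 0, 0, 0), n_per_species=3, seed=1)
        assert np.unique(aln.matrix[:, 0]).size == 1

    def test_infeasible_polymorphism_rejected(self):
        with pytest.raises(ValueError, match="n_per_species"):
            make_mk_fixture((1, 0, 0, 0), n_per_species=1, seed=0)


class TestTruthLog:
    def test_tsv_rendering_includes_all_entries(self):
        log = TruthLog()
        log.add(kind="polymorphism", column=3, derived="G")
        log.add(kind="outgroup_divergence", column=7, derived="T")
        tsv = log.to_tsv()
        assert tsv.count("\n") == 3
        assert "polymorphism" in tsv and "outgroup_divergence" in tsv
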