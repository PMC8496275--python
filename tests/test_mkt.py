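import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popflux.contingency import chi_square_2x2, fisher_exact_2x2
from popflux.mkt import (FIXED_DIVERGENT, POLYMORPHIC, build_mk_table,
                         classify_sites_mk, fww_filter)
from popflux.seqdata import INGROUP, OUTGROUP, build_codon_map
from popflux.siteclass import polarize, classify_columns
from popflux.synthetic import make_mk_fixture

from conftest import population_alignment

ROLES3 = {"A": INGROUP, "B": OUTGROUP, "C": OUTGROUP}


def classify3(seqs):
    aln = population_alignment(seqs, ROLES3)
    return classify_sites_mk(aln, {"A"}, {"B", "C"})


class TestClassifySitesMK:
    def test_segregating_ingroup_site_is_polymorphic(self):
        cl = classify3({"A": ["A", "A", "G"], "B": ["A", "A"], "C": ["A"]})
        assert cl.sites[0].status == POLYMORPHIC

    def test_fixed_difference_is_divergent_with_lineage(self):
        cl = classify3({"A": ["G", "G"], "B": ["A", "A"], "C": ["A"]})
        assert cl.sites[0].status == FIXED_DIVERGENT
        assert cl.sites[0].divergent_species == "A"

    def test_polymorphic_wins_over_divergent(self):
        # A = {A,G}, B = {G,G}, C = {G}: A segregates, so polymorphic only
        cl = classify3({"A": ["A", "G"], "B": ["G", "G"], "C": ["G"]})
        assert cl.sites[0].status == POLYMORPHIC

    def test_rule_precedence_over_enumerated_three_species_patterns(self):
        # brute-force oracle over all 3-species allele patterns with
        # two samples in A and B and one in C
        bases = "AG"
        for a1 in bases:
            for a2 in bases:
                for b1 in bases:
                    for b2 in bases:
                        for c1 in bases:
                            cl = classify3({"A": [a1, a2], "B": [b1, b2],
                                            "C": [c1]})
                            expect_poly = (a1 != a2) or (b1 != b2)
                            sets = [{a1, a2}, {b1, b2}, {c1}]
                            expect_div = (not expect_poly) and any(
                                sets[i].isdisjoint(sets[j] | sets[k])
                                for i, j, k in ((0, 1, 2), (1, 0, 2),
                                                (2, 0, 1)))
                            got = cl.sites[0].status
                            if expect_poly:
                                assert got == POLYMORPHIC
                            elif expect_div:
                                assert got == FIXED_DIVERGENT
                            else:
                                assert got == "invariant"

    def test_outgroup_polymorphism_counts_as_polymorphic(self):
        cl = classify3({"A": ["G", "G"], "B": ["A", "G"], "C": ["A"]})
        assert cl.sites[0].status == POLYMORPHIC

    def test_species_with_only_missing_data_excludes_site(self):
        cl = classify3({"A": ["G", "G"], "B": ["-", "-"], "C": ["A"]})
        assert not cl.sites
        assert cl.excluded and "B" in cl.excluded[0][1]


class TestBuildMKTable:
    def test_published_combined_polymorphism_table(self):
        aln, ann = make_mk_fixture((19, 0, 19, 7), n_per_species=10, seed=0)
        cmap = build_codon_map(ann, aln.L)
        table = build_mk_table(
            classify_sites_mk(aln, {"popA", "popB"}, {"out"}),
            classify_columns(aln, cmap))
        assert table.cells == (19, 0, 19, 7)
        assert table.fisher_p() == pytest.approx(0.0156, abs=5e-4)

    def test_no_variation_gives_all_zero_table(self):
        aln, ann = make_mk_fixture((0, 0, 0, 0), n_per_species=3, seed=0)
        cmap = build_codon_map(ann, aln.L)
        table = build_mk_table(
            classify_sites_mk(aln, {"popA", "popB"}, {"out"}),
            classify_columns(aln, cmap))
        assert table.cells == (0, 0, 0, 0)
        assert table.fisher_p() == 1.0

    def test_reduction_to_single_sequence_equals_single_species_table(self):
        aln, ann = make_mk_fixture((6, 2, 5, 3), n_per_species=4, seed=5)
        # drop popB to its first sequence
        keep = [lab for lab in aln.labels
                if not lab.startswith("popB") or lab == "popB_0"]
        idx = [aln.labels.index(lab) for lab in keep]
        from popflux.seqdata import SampleAlignment
        reduced = SampleAlignment(
            labels=keep, species_of={k: aln.species_of[k] for k in keep},
            matrix=aln.matrix[idx], roles=aln.roles)
        cmap = build_codon_map(ann, aln.L)
        st = classify_columns(reduced, cmap)
        combined = build_mk_table(
            classify_sites_mk(reduced, {"popA", "popB"}, {"out"}), st)
        single = build_mk_table(
            classify_sites_mk(reduced, {"popA"}, {"popB", "out"}), st)
        assert combined.cells == single.cells


class TestFWWFilter:
    def test_singleton_below_threshold_removed(self):
        # frequency 1/10 < 0.15 -> dropped from polymorphism cells
        aln, ann = make_mk_fixture((2, 0, 3, 1), n_per_species=5, seed=3)
        cmap = build_codon_map(ann, aln.L)
        st = classify_columns(aln, cmap)
        cl = classify_sites_mk(aln, {"popA"}, {"popB", "out"})
        # popA singletons have derived frequency 1/5 = 0.2; use minor mode
        # with a synthetic frequency map to exercise both outcomes
        freqs = {s.column: 0.10 for s in cl.of_status(POLYMORPHIC)}
        filtered = fww_filter(cl, minor_freqs=freqs, frequency="minor")
        assert not filtered.of_status(POLYMORPHIC)
        freqs = {s.column: 0.20 for s in cl.of_status(POLYMORPHIC)}
        kept = fww_filter(cl, minor_freqs=freqs, frequency="minor")
        assert len(kept.of_status(POLYMORPHIC)) == len(
            cl.of_status(POLYMORPHIC))

    def test_zero_threshold_is_identity(self):
        aln, ann = make_mk_fixture((4, 1, 3, 1), n_per_species=5, seed=4)
        cl = classify_sites_mk(aln, {"popA", "popB"}, {"out"})
        pol = polarize(aln, ["out"], focal_species="popA")
        filtered = fww_filter(cl, polarized=pol, min_freq=0.0)
        # popB singletons are unpolarizable from popA's sample; restrict to
        # sites with frequencies
        assert all(s.status != POLYMORPHIC or s.column in
                   {v.column for v in pol.variants}
                   for s in filtered.sites)

    def test_divergence_cells_never_change(self):
        aln, ann = make_mk_fixture((6, 2, 7, 3), n_per_species=5, seed=6)
        cmap = build_codon_map(ann, aln.L)
        st = classify_columns(aln, cmap)
        cl = classify_sites_mk(aln, {"popA", "popB"}, {"out"})
        freqs = {s.column: 0.01 for s in cl.of_status(POLYMORPHIC)}
        filtered = fww_filter(cl, minor_freqs=freqs, frequency="minor",
                              min_freq=0.15)
        before = build_mk_table(cl, st)
        after = build_mk_table(filtered, st)
        assert (after.syn_fixed, after.nonsyn_fixed) == (
            before.syn_fixed, before.nonsyn_fixed)
        assert after.syn_poly == 0 and after.nonsyn_poly == 0

    def test_published_filtered_table_p_value(self):
        # removing two synonymous singletons from (19,0|19,7) gives the
        # published filtered MKT p = 0.031
        assert fisher_exact_2x2(17, 0, 19, 7) == pytest.approx(0.031,
                                                               abs=5e-4)


class TestFisherExact:
    @pytest.mark.parametrize("cells,expected", [
        ((19, 0, 19, 7), 0.015),
        ((9, 1, 14, 0), 0.417),
        ((8, 0, 44, 2), 1.00),
    ])
    def test_published_two_tailed_values(self, cells, expected):
        assert fisher_exact_2x2(*cells) == pytest.approx(expected, abs=1e-3)

    def test_zero_margin_is_one(self):
        assert fisher_exact_2x2(0, 0, 5, 7) == 1.0
        assert fisher_exact_2x2(3, 0, 4, 0) == 1.0

    @given(st.tuples(st.integers(0, 40), st.integers(0, 40),
                     st.integers(0, 40), st.integers(0, 40)))
    @settings(max_examples=60, deadline=None)
    def test_transpose_symmetry_and_bounds(self, cells):
        a, b, c, d = cells
        p = fisher_exact_2x2(a, b, c, d)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(fisher_exact_2x2(a, c, b, d), rel=1e-9)

    def test_one_tailed_modes_sum_to_more_than_one_with_overlap(self):
        less = fisher_exact_2x2(2, 8, 9, 1, mode="less")
        greater = fisher_exact_2x2(2, 8, 9, 1, mode="greater")
        assert less < 0.05 and greater > 0.9

    def test_agrees_with_scipy_reference(self):
        from scipy.stats import fisher_exact as scipy_fisher
        rng = np.random.default_rng(8)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 30, size=4)
            mine = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            ref = scipy_fisher([[a, b], [c, d]])[1]
            assert mine == pytest.approx(ref, rel=1e-8, abs=1e-12)
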