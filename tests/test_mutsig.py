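"""Incidence counting, Fisher testing and the permutation-null machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ncburden import mutsig
from ncburden.genome_io import MutationRecord
from ncburden.mutsig import (
    CohortDesign,
    FisherResult,
    call_significant,
    cross_cancer_overlap,
    fisher_one_sided,
    permutation_null_exact,
    permutation_null_mc,
    permutation_null_shuffle,
    rank_sets,
)

from conftest import make_catalog
from oracles import fisher_upper_tail_exact


def snv(sample, chrom, pos, cancer="breast"):
    return MutationRecord(sample, cancer, chrom, pos, "A", "G")


class TestBuildIncidence:
    def test_sample_counted_once_per_gene(self, small_design):
        catalog = make_catalog([("G1", "chr1", 0, 1000)])
        muts = [snv("C0", "chr1", p) for p in (10, 20, 30, 40, 50)]
        inc = mutsig.build_incidence(muts, catalog, small_design)
        assert inc.loc["G1", "mutated_case"] == 1

    def test_coordinate_boundary_half_open(self, small_design):
        # 1-based pos 10 is 0-based index 9: outside [10, 20); pos 11 is inside
        catalog = make_catalog([("G1", "chr1", 10, 20)])
        inc = mutsig.build_incidence([snv("C0", "chr1", 10)], catalog, small_design)
        assert inc.loc["G1", "m"] == 0
        inc = mutsig.build_incidence([snv("C0", "chr1", 11)], catalog, small_design)
        assert inc.loc["G1", "m"] == 1
        # pos 20 -> index 19, the last base of [10, 20)
        inc = mutsig.build_incidence([snv("C0", "chr1", 20)], catalog, small_design)
        assert inc.loc["G1", "m"] == 1

    def test_hand_counted_table(self, small_design):
        catalog = make_catalog(
            [("G1", "chr1", 0, 100), ("G2", "chr1", 200, 300), ("G3", "chr2", 0, 100)]
        )
        muts = [
            snv("C0", "chr1", 50), snv("C0", "chr1", 60),   # C0 in G1 (once)
            snv("C1", "chr1", 250),                          # C1 in G2
            snv("X0", "chr1", 50), snv("X0", "chr2", 50),    # X0 in G1 and G3
            snv("X1", "chr1", 150),                          # in no gene
        ]
        inc = mutsig.build_incidence(muts, catalog, small_design)
        assert inc.loc["G1"].tolist() == [1, 1, 2]
        assert inc.loc["G2"].tolist() == [1, 0, 1]
        assert inc.loc["G3"].tolist() == [0, 1, 1]

    def test_unknown_sample_errors(self, small_design):
        catalog = make_catalog([("G1", "chr1", 0, 100)])
        with pytest.raises(ValueError, match="GHOST"):
            mutsig.build_incidence([snv("GHOST", "chr1", 50)], catalog, small_design)


class TestFisherOneSided:
    def test_empty_table_p_one(self):
        assert fisher_one_sided(0, 5, 0, 5) == 1.0

    def test_hand_derived_value(self):
        # all 3 mutated samples in the 5 case draws: C(5,3)C(5,0)/C(10,3) = 1/12
        assert fisher_one_sided(3, 2, 0, 5) == pytest.approx(1 / 12)

    def test_monotone_in_extremity(self):
        assert fisher_one_sided(4, 1, 0, 5) < fisher_one_sided(3, 2, 0, 5)

    def test_negative_cell_errors(self):
        with pytest.raises(ValueError):
            fisher_one_sided(-1, 2, 3, 4)

    @given(
        st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_rational_enumeration(self, a, b, c, d):
        if a + b == 0 or a + b + c + d == 0:
            return
        assert fisher_one_sided(a, b, c, d) == pytest.approx(
            float(fisher_upper_tail_exact(a, b, c, d)), rel=1e-9
        )


class TestPermutationNull:
    def test_m_zero_never_significant(self, small_design):
        null = permutation_null_mc("g", 0, small_design, n_perm=1000, seed=1)
        assert null.threshold_p == 1.0
        assert null.empirical_p(1.0) == 1.0

    def test_exact_two_term_null(self, small_design):
        # m=1, n_case=5, n_total=10: p=0.5 w.p. 0.5 and p=1.0 w.p. 0.5
        null = permutation_null_exact("g", 1, small_design)
        assert np.allclose(null.support_p, [0.5, 1.0])
        assert np.allclose(null.probs, [0.5, 0.5])

    def test_mc_frequencies_converge_to_exact(self, small_design):
        null = permutation_null_mc("g", 1, small_design, n_perm=100_000, seed=3)
        freq_half = sum(
            cnt for p, cnt in zip(null.support_p, null.counts) if abs(p - 0.5) < 1e-9
        ) / null.n_perm
        sigma = np.sqrt(0.5 * 0.5 / null.n_perm)
        assert freq_half == pytest.approx(0.5, abs=3 * sigma)

    def test_same_seed_reproducible(self, small_design):
        a = permutation_null_mc("g", 3, small_design, n_perm=5000, seed=42)
        b = permutation_null_mc("g", 3, small_design, n_perm=5000, seed=42)
        assert np.array_equal(a.support_p, b.support_p)
        assert np.array_equal(a.counts, b.counts)
        assert a.threshold_p == b.threshold_p

    def test_gene_streams_are_order_independent(self, small_design):
        a = permutation_null_mc("geneA", 3, small_design, n_perm=2000, seed=7)
        a2 = permutation_null_mc("geneA", 3, small_design, n_perm=2000, seed=7)
        b = permutation_null_mc("geneB", 3, small_design, n_perm=2000, seed=7)
        assert np.array_equal(a.counts, a2.counts)
        assert not np.array_equal(a.counts, b.counts)  # distinct streams

    def test_point_mass_when_everyone_mutated(self, small_design):
        null = permutation_null_exact("g", small_design.n_total, small_design)
        assert len(null.support_p) == 1
        assert null.threshold_p == null.support_p[0]

    def test_small_n_perm_warns(self, small_design):
        with pytest.warns(UserWarning, match="unstable"):
            permutation_null_mc("g", 1, small_design, n_perm=50, seed=1)

    def test_empirical_p_monotone_in_extremity(self, small_design):
        # at fixed m, a more extreme observed table gives a smaller empirical p
        null = permutation_null_exact("g", 4, small_design)
        ps = [fisher_one_sided(k, 5 - k, 4 - k, 5 - (4 - k)) for k in range(5)]
        emps = [null.empirical_p(p) for p in ps]
        assert all(e1 >= e2 for e1, e2 in zip(emps, emps[1:]))  # k ascending


class TestShuffleOracle:
    def test_shuffle_matches_hypergeometric_shortcut(self):
        """The literal label-shuffle null and the hypergeometric shortcut
        agree in distribution (3-sigma check per atom at n_perm=1e4)."""
        cohort = {f"C{i}": "case" for i in range(20)}
        cohort.update({f"X{i}": "ctrl" for i in range(40)})
        design = CohortDesign("case", cohort)
        m = 8
        exact = permutation_null_exact("g", m, design)
        shuffled = permutation_null_shuffle("g", m, design, n_perm=10_000, seed=11)
        probs = dict(zip(exact.support_p, exact.probs))
        freq = dict(zip(shuffled.support_p, shuffled.counts / shuffled.n_perm))
        for p_atom, prob in probs.items():
            sigma = np.sqrt(prob * (1 - prob) / shuffled.n_perm)
            assert freq.get(p_atom, 0.0) == pytest.approx(prob, abs=max(3 * sigma, 1e-3))


class TestCallsAndSets:
    def _calls(self, n, n_sig):
        calls = []
        for i in range(n):
            p = (i + 1) / (n + 1)
            calls.append(
                mutsig.SignificanceCall(f"G{i:03d}", p, 0.01, 0.005 if i < n_sig else 0.5,
                                        i < n_sig)
            )
        return calls

    def test_significance_threshold_inclusive(self, small_design):
        null = permutation_null_exact("g", 1, small_design)
        fr = [FisherResult("g", 1, 4, 0, 5, 0.5)]
        calls = call_significant(fr, {"g": null}, alpha=0.5)
        assert calls[0].is_significant  # empirical p = 0.5 <= alpha
        calls = call_significant(fr, {"g": null}, alpha=0.49)
        assert not calls[0].is_significant

    def test_missing_null_errors(self):
        with pytest.raises(ValueError, match="g"):
            call_significant([FisherResult("g", 1, 4, 0, 5, 0.5)], {})

    def test_four_disjoint_sets_of_k(self):
        sets = rank_sets(self._calls(40, 10))
        assert sets.k == 10
        all_ids = set()
        for ids in sets.as_dict().values():
            assert len(ids) == 10
            assert not (all_ids & set(ids))
            all_ids |= set(ids)

    def test_last_set_is_tail(self):
        sets = rank_sets(self._calls(50, 10))
        assert sets.last_set == tuple(f"G{i:03d}" for i in range(40, 50))

    def test_ties_broken_by_gene_id(self):
        calls = [
            mutsig.SignificanceCall(g, 0.5, 0.01, 0.5, False) for g in "DBCA"
        ] + [mutsig.SignificanceCall("S", 0.001, 0.01, 0.005, True)]
        sets = rank_sets(calls, k=1)
        assert sets.second_set == ("A",)  # alphabetical among tied p

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError, match="4k"):
            rank_sets(self._calls(30, 10))


class TestCrossCancerOverlap:
    def _calls_for(self, sig_ids, all_ids):
        return [
            mutsig.SignificanceCall(g, i / 100, 0.01, 0.001 if g in sig_ids else 0.9,
                                    g in sig_ids)
            for i, g in enumerate(all_ids)
        ]

    def test_reference_vs_itself_is_k(self):
        ids = [f"G{i}" for i in range(10)]
        calls = {"breast": self._calls_for(ids[:3], ids)}
        v_sig, v_top = cross_cancer_overlap(calls, "breast")
        assert v_sig["breast"] == 3 and v_top["breast"] == 3

    def test_zero_overlap_with_empty_other(self):
        ids = [f"G{i}" for i in range(10)]
        calls = {
            "breast": self._calls_for(ids[:3], ids),
            "lung": self._calls_for([], ids),
        }
        v_sig, _ = cross_cancer_overlap(calls, "breast")
        assert v_sig["lung"] == 0

    def test_hand_counted_three_cancer_overlap(self):
        ids = [f"G{i}" for i in range(10)]
        calls = {
            "breast": self._calls_for(["G0", "G1", "G2"], ids),
            "ovary": self._calls_for(["G1", "G2", "G5"], ids),      # shares 2
            "skin": self._calls_for(["G7"], list(reversed(ids))),   # shares 0
        }
        v_sig, v_top = cross_cancer_overlap(calls, "breast")
        assert v_sig == {"breast": 3, "ovary": 2, "skin": 0}
        # skin sorted order is reversed: its top-3 are G9, G8, G7
        assert v_top["skin"] == 0 and v_top["ovary"] >= 2
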