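"""AMOVA variance decomposition, pairwise Phi_ST, grouping scan and UPGMA."""

import numpy as np
import pytest

from popmito import structure
from tests.conftest import make_alignment


class TestDistanceMatrix:
    def test_hand_enumeration(self, mk):
        a = mk(["AAAA", "AAAT", "AATT"])
        m = structure.individual_distance_matrix(a, outgroup="zz")
        assert m.d.tolist() == [[0, 1, 2], [1, 0, 1], [2, 1, 0]]

    def test_symmetry_on_random_alignments(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n, L = int(rng.integers(2, 10)), int(rng.integers(1, 30))
            rows = ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)]
            m = structure.individual_distance_matrix(make_alignment(rows),
                                                     outgroup="zz")
            assert np.array_equal(m.d, m.d.T)
            assert (np.diag(m.d) == 0).all()


def two_fixed_demes(mk):
    return mk(["AAAA"] * 3 + ["TTTT"] * 3, pops=["P1"] * 3 + ["P2"] * 3)


class TestAmova:
    def test_fixed_haplotypes_give_phi_st_one(self, mk):
        r = structure.amova(two_fixed_demes(mk), [["P1", "P2"]])
        assert r.phi_ST == pytest.approx(1.0)
        assert r.ssd_WP == 0.0

    def test_ssd_additivity(self, mk):
        rng = np.random.default_rng(9)
        rows = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(18)]
        pops = ["P1"] * 5 + ["P2"] * 6 + ["P3"] * 4 + ["P4"] * 3
        a = make_alignment(rows, pops=pops)
        r = structure.amova(a, [["P1", "P2"], ["P3", "P4"]])
        total = r.ssd_AG + r.ssd_APWG + r.ssd_WP
        # recompute SSD_total independently from the distance matrix
        d = structure.individual_distance_matrix(a, outgroup="zz").d
        want = d.sum() / (2 * 18)
        assert total == pytest.approx(want, rel=1e-9)
        assert r.df_AG + r.df_APWG + r.df_WP == 17
        assert (r.pct_AG + r.pct_APWG + r.pct_WP) == pytest.approx(100.0, abs=1e-6)

    def test_single_population_rejected(self, mk):
        a = mk(["AAAA", "AAAT"], pops=["P1", "P1"])
        with pytest.raises(structure.StructureError):
            structure.amova(a, [["P1"]])

    def test_empty_group_rejected(self, mk):
        with pytest.raises(ValueError):
            structure.amova(two_fixed_demes(mk), [["P1", "P2"], []])

    def test_one_group_has_no_among_group_level(self, mk):
        r = structure.amova(two_fixed_demes(mk), [["P1", "P2"]])
        assert r.phi_CT is None and r.df_AG == 0

    def test_permutation_p_reproducible_and_significantly_structured(self, mk):
        # 8 + 8 fixed demes: enough label arrangements for p < 0.05
        a = mk(["AAAA"] * 8 + ["TTTT"] * 8, pops=["P1"] * 8 + ["P2"] * 8)
        r1 = structure.amova(a, [["P1", "P2"]], permutations=199, seed=7)
        r2 = structure.amova(a, [["P1", "P2"]], permutations=199, seed=7)
        assert r1.p_ST == r2.p_ST
        assert r1.p_ST < 0.05


class TestPairwise:
    def test_two_population_amova_equals_pairwise_entry(self, mk):
        rng = np.random.default_rng(12)
        rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(12)]
        pops = ["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4
        a = make_alignment(rows, pops=pops)
        pw = structure.pairwise_phist_matrix(a, permutations=0)
        for i, pi_ in enumerate(pw.populations):
            for j in range(i + 1, len(pw.populations)):
                pj = pw.populations[j]
                ids = [s for s in a.sample_ids
                       if a.populations[s] in (pi_, pj)]
                r = structure.amova(a.subset(ids), [[pi_, pj]])
                assert pw.fst[i, j] == pytest.approx(r.phi_ST, abs=1e-12)

    def test_duplicated_population_has_no_differentiation(self, mk):
        # same haplotype pool split into two labels -> Phi_ST ~ 0, P high
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(8)]
        a = make_alignment(rows * 2, pops=["P1"] * 8 + ["P2"] * 8)
        pw = structure.pairwise_phist_matrix(a, permutations=199, seed=5)
        assert pw.fst[0, 1] <= 0.02
        assert pw.p[0, 1] > 0.2

    def test_tiny_population_flagged_nan(self, mk):
        a = mk(["AAAA", "AATT", "TTTT"], pops=["P1", "P1", "P2"])
        pw = structure.pairwise_phist_matrix(a, permutations=0)
        assert np.isnan(pw.fst[0, 1])


class TestGroupingScan:
    def test_ranked_by_phi_ct(self, metapop):
        _, aln, _ = metapop
        ing = aln.exclude_populations({"outgroup"})
        cands = [
            [["MTR", "TWR", "YLR", "CLR", "LLR", "KPE", "JGE"], ["SMR", "TSE"]],
            [["SMR", "MTR", "TWR", "YLR"], ["CLR", "LLR", "TSE", "JGE", "KPE"]],
        ]
        res = structure.grouping_scan(ing, cands, permutations=99, seed=2)
        assert len(res) == 2
        assert res[0].phi_CT >= res[1].phi_CT

    def test_single_candidate_wins_trivially(self, mk):
        a = two_fixed_demes(mk)
        res = structure.grouping_scan(a, [[["P1"], ["P2"]]], permutations=99, seed=1)
        assert len(res) == 1 and res[0].phi_CT is not None

    def test_empty_candidates_rejected(self, mk):
        with pytest.raises(ValueError):
            structure.grouping_scan(two_fixed_demes(mk), [])


class TestUpgma:
    def test_two_labels_cherry_at_half_distance(self):
        m = structure.DistanceMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        t = structure.upgma(m)
        assert t.newick == "(A:1.5,B:1.5);"

    def test_hand_agglomeration(self):
        m = structure.DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], float))
        t = structure.upgma(m)
        assert t.newick == "((A:1,B:1):3,C:4);"
        assert set(map(frozenset, t.root_children)) == {
            frozenset({"A", "B"}), frozenset({"C"})}

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(8)
        n = 7
        d = rng.uniform(1, 10, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"L{i}" for i in range(n)]
        t = structure.upgma(structure.DistanceMatrix(labels, d))
        heights = sorted(h for _, _, h in t.merges)
        want = sorted(average(squareform(d))[:, 2] / 2)
        assert np.allclose(heights, want)

    def test_non_symmetric_rejected(self):
        m = structure.DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            structure.upgma(m)

    def test_negative_distances_clamped(self):
        m = structure.DistanceMatrix(
            ["A", "B", "C"], np.array([[0, -0.01, 5], [-0.01, 0, 5], [5, 5, 0]]))
        t = structure.upgma(m)
        assert "(A:0,B:0)" in t.newick


def test_island_model_phi_st_centred_on_zero():
    """Panmictic data split into labelled demes: mean pairwise Phi_ST ~ 0."""
    from popmito.synthetic_data import simulate_coalescent_sample

    means = []
    for rep in range(50):
        a = simulate_coalescent_sample(24, 3.0, 300, seed=900 + rep)
        pops = {s: f"P{1 + i % 3}" for i, s in enumerate(a.sample_ids)}
        a.populations = pops
        pw = structure.pairwise_phist_matrix(a, permutations=0)
        iu = np.triu_indices(len(pw.populations), k=1)
        means.append(np.nanmean(pw.fst[iu]))
    assert abs(float(np.mean(means))) <= 0.02
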