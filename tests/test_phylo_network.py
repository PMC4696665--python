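"""T92 distances, NJ trees, lineage assignment and median-joining networks."""

import itertools
import math

import numpy as np
import pytest

from popmito import haplotypes, phylo_network
from popmito.structure import DistanceMatrix
from tests.conftest import make_alignment


class TestT92:
    def test_identical_pair_distance_zero(self, mk):
        m = phylo_network.t92_distance(mk(["ACGT", "ACGT"]))
        assert m.d[0, 1] == 0.0

    def test_closed_form_value(self):
        # P = Q = 0.05 at theta = 0.5
        want = -0.5 * math.log(0.85) - 0.25 * math.log(0.9)
        assert phylo_network.t92_pair(0.05, 0.05, 0.5) == pytest.approx(want)

    def test_reduces_to_k2p_at_theta_half(self):
        for P, Q in [(0.1, 0.05), (0.2, 0.1), (0.02, 0.3)]:
            k2p = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
            assert phylo_network.t92_pair(P, Q, 0.5) == pytest.approx(k2p)

    def test_saturation_marked_nan(self):
        assert math.isnan(phylo_network.t92_pair(0.5, 0.5, 0.5))

    def test_pairwise_deletion(self, mk):
        m = phylo_network.t92_distance(mk(["ANGT", "AAGT"]))
        assert m.d[0, 1] == 0.0


class TestNJ:
    def four_taxon_additive(self):
        # tree ((A:1,B:2):1,(C:3,D:4)); additive distances
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 0, 0],
        ], dtype=float)
        d[3, 2] = d[2, 3] = 7
        d[3, 3] = 0
        return labels, d

    def test_recovers_additive_tree_exactly(self):
        labels, d = self.four_taxon_additive()
        tree = phylo_network.nj_tree(DistanceMatrix(labels, d))
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, j in itertools.combinations(range(4), 2):
            got = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            assert got == pytest.approx(d[i, j], abs=1e-9)

    def test_roots_on_outgroup(self):
        labels, d = self.four_taxon_additive()
        tree = phylo_network.nj_tree(DistanceMatrix(labels, d), outgroup=["D"])
        kids = tree.seed_node.child_nodes()
        sides = [{lf.taxon.label for lf in k.leaf_iter()} for k in kids]
        assert {"D"} in sides

    def test_missing_outgroup_returns_unrooted_with_warning(self, caplog):
        labels, d = self.four_taxon_additive()
        tree = phylo_network.nj_tree(DistanceMatrix(labels, d), outgroup=["ZZ"])
        assert tree is not None
        assert any("outgroup" in r.message for r in caplog.records)

    def test_nan_distances_rejected(self):
        d = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            phylo_network.nj_tree(DistanceMatrix(["a", "b", "c"], d))


class TestBootstrap:
    def test_clear_split_gets_high_support(self, mk):
        # two tight clusters of 3 haplotypes, well separated
        rows = ["AAAAAAAAAACCCCCCCCCC", "AAAAAAAAATCCCCCCCCCC",
                "AAAAAAAATTCCCCCCCCCC", "GGGGGGGGGGTTTTTTTTTT",
                "GGGGGGGGGTTTTTTTTTTT", "GGGGGGGGTTTTTTTTTTTT",
                "AAAAAGGGGGCCCCCTTTTT"]
        ids = [f"H{i}" for i in range(6)] + ["OUT"]
        a = make_alignment(rows, ids=ids,
                           pops=["P1"] * 6 + ["outgroup"])
        sup = phylo_network.bootstrap_support(a, reps=50, seed=3, outgroup=["OUT"])
        top = max(sup.items(), key=lambda kv: (kv[1], len(kv[0])))
        assert top[1] >= 90


def two_lineage_toy():
    # lineage 1: H1,H2 near-identical; lineage 2: H3,H4; deep split
    rows = ["AAAAAAAAAA", "AAAAAAAAAT",
            "TTTTTTTAAA", "TTTTTTTAAT",
            "GGGGGGGGGG"]
    ids = ["h1", "h2", "h3", "h4", "OUT1"]
    pops = ["SMR", "SMR", "MTR", "MTR", "outgroup"]
    return make_alignment(rows, ids=ids, pops=pops)


class TestLineages:
    def test_assignment_follows_anchor_population(self):
        a = two_lineage_toy()
        table = haplotypes.collapse_haplotypes(a)
        hap_aln = haplotypes.haplotype_alignment(table)
        merged = make_alignment(hap_aln.row_strings() + ["GGGGGGGGGG"],
                                ids=hap_aln.sample_ids + ["OUT1"],
                                pops=["haplotype"] * 4 + ["outgroup"])
        dm = phylo_network.t92_distance(merged)
        tree = phylo_network.nj_tree(phylo_network._fill_nan(dm), outgroup=["OUT1"])
        res = phylo_network.assign_lineages(tree, table, a.populations,
                                            outgroup=["OUT1"],
                                            anchor_pop="SMR", anchor_lineage="B")
        assert res.lineage == {"h1": "B", "h2": "B", "h3": "A", "h4": "A"}
        assert res.counts == {"SMR": {"A": 0, "B": 2}, "MTR": {"A": 2, "B": 0}}

    def test_recovers_simulated_truth(self, metapop):
        cfg, aln, truth = metapop
        table = haplotypes.collapse_haplotypes(aln)
        hap_aln = haplotypes.haplotype_alignment(table)
        out_ids = [s for s in aln.sample_ids if aln.populations[s] == "outgroup"]
        out_rows = aln.subset(out_ids)
        merged = make_alignment(hap_aln.row_strings() + out_rows.row_strings(),
                                ids=hap_aln.sample_ids + out_ids,
                                pops=["haplotype"] * table.n_haplotypes
                                     + ["outgroup"] * len(out_ids))
        dm = phylo_network.t92_distance(merged)
        tree = phylo_network.nj_tree(phylo_network._fill_nan(dm), outgroup=out_ids)
        res = phylo_network.assign_lineages(tree, table, aln.populations,
                                            outgroup=out_ids)
        want = dict(zip(truth.sample_id, truth.lineage))
        got = {s: res.lineage[s] for s in res.lineage}
        mismatches = [s for s in got if want[s] != got[s]]
        assert mismatches == []


# --------------------------------------------------------------------------
# median-joining network

def brute_force_steiner_cost(observed, alphabet="01"):
    """Minimum spanning cost allowing ANY extra vectors (exhaustive Steiner
    search over the full hypercube; tiny inputs only)."""
    L = len(observed[0])
    universe = ["".join(p) for p in itertools.product(alphabet, repeat=L)]
    extras = [v for v in universe if v not in observed]
    best = phylo_network.mst_cost(list(observed))
    # adding up to 2 extra vectors is enough at these sizes
    for k in (1, 2):
        for combo in itertools.combinations(extras, k):
            c = phylo_network.mst_cost(list(observed) + list(combo))
            best = min(best, c)
    return best


class TestMedianJoining:
    def test_triangle_gets_median_vector(self, mk):
        a = mk(["AAA", "TTA", "ATT"])
        t = haplotypes.collapse_haplotypes(a)
        g = phylo_network.median_joining_network(t)
        med = [s for s, d in g.nodes(data=True) if not d["sampled"]]
        assert med == ["ATA"]  # per-site majority of the triplet
        assert phylo_network.network_total_cost(g) == 3
        # brute-force Steiner oracle agrees
        assert brute_force_steiner_cost(["000", "110", "011"]) == 3

    def test_chain_has_no_medians(self, mk):
        a = mk(["AA", "AT", "TT"])
        t = haplotypes.collapse_haplotypes(a)
        g = phylo_network.median_joining_network(t)
        assert all(d["sampled"] for _, d in g.nodes(data=True))
        assert g.number_of_edges() == 2

    def test_epsilon_must_be_non_negative(self, mk):
        t = haplotypes.collapse_haplotypes(mk(["AA", "AT"]))
        with pytest.raises(ValueError):
            phylo_network.median_joining_network(t, epsilon=-1)

    def test_network_invariants_on_random_haplotype_sets(self):
        rng = np.random.default_rng(21)
        for rep in range(15):
            n = int(rng.integers(4, 9))
            L = int(rng.integers(6, 14))
            rows = list({"".join(rng.choice(list("ACGT"), size=L))
                         for _ in range(n)})
            if len(rows) < 2:
                continue
            a = make_alignment(rows)
            t = haplotypes.collapse_haplotypes(a)
            g = phylo_network.median_joining_network(t)
            # spans all observed haplotypes, connected, cost <= MST cost
            sampled = {s for s, d in g.nodes(data=True) if d["sampled"]}
            assert sampled == set(rows)
            assert phylo_network.network_total_cost(g) <= \
                phylo_network.mst_cost(rows)
            for u, v, d in g.edges(data=True):
                assert d["weight"] == sum(x != y for x, y in zip(u, v))
                assert d["weight"] >= 1
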