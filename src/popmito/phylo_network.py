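"""Trees and haplotype networks: T92 distances, NJ with outgroup rooting and
site-resampling bootstrap, median-joining networks, and lineage assignment.

The Tamura (1992) three-parameter distance corrects pairwise transition (P)
and transversion (Q) proportions for G+C content theta:

    c = 2 theta (1 - theta)
    d = -c ln(1 - P/c - Q) - ((1 - c)/2) ln(1 - 2Q)

theta is the alignment-wide G+C content (not a per-pair average).  At
theta = 0.5 the formula reduces to the Kimura two-parameter distance.

The median-joining network follows Bandelt, Forster & Roehl (1999): the
minimum-spanning network (all edges belonging to some minimum spanning
tree, relaxed by epsilon) is repeatedly augmented with per-site majority
median (Steiner) vectors of mutually linked triplets whenever they reduce
the total spanning cost, then unsampled nodes that no longer help are
pruned.  Triplets are processed in lexicographic order, so the result is
deterministic.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass

import dendropy
import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .haplotypes import HaplotypeTable
from .seqio import Alignment
from .structure import DistanceMatrix

logger = logging.getLogger(__name__)

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)
_PURINES = frozenset(b"AG")
_PYRIMIDINES = frozenset(b"CT")


class RootingError(ValueError):
    """The requested outgroup cannot root the tree."""


class AssignmentError(ValueError):
    """Lineage assignment failed (ingroup not bifurcating at the root)."""


# --------------------------------------------------------------------------
# T92 distance

def gc_content(seqs: np.ndarray) -> float:
    acgt = np.isin(seqs, _ACGT)
    gc = np.isin(seqs, np.frombuffer(b"GC", dtype=np.uint8))
    return float(gc.sum() / acgt.sum())


def t92_pair(P: float, Q: float, theta: float) -> float:
    """Closed-form T92 distance from transition/transversion proportions."""
    c = 2.0 * theta * (1.0 - theta)
    x = 1.0 - P / c - Q
    y = 1.0 - 2.0 * Q
    if x <= 0 or y <= 0 or c <= 0:
        return math.nan
    return -c * math.log(x) - ((1.0 - c) / 2.0) * math.log(y)


def t92_distance(a: Alignment, theta: float | None = None) -> DistanceMatrix:
    """Pairwise T92 distances with pairwise deletion of ambiguous sites.

    Saturated pairs (logarithm argument <= 0) yield NaN with a warning.
    """
    seqs = a.seqs
    n = seqs.shape[0]
    if theta is None:
        theta = gc_content(seqs)
    ok = np.isin(seqs, _ACGT)
    purine = np.isin(seqs, np.frombuffer(b"AG", dtype=np.uint8))
    d = np.zeros((n, n))
    saturated = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                d[i, j] = d[j, i] = math.nan
                continue
            diff = (seqs[i] != seqs[j]) & both
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int(diff.sum()) - ts
            dij = t92_pair(ts / m, tv / m, theta)
            if math.isnan(dij):
                saturated += 1
            d[i, j] = d[j, i] = dij
    if saturated:
        logger.warning("%d saturated pairs: T92 distance undefined (NaN)", saturated)
    return DistanceMatrix(labels=list(a.sample_ids), d=d)


# --------------------------------------------------------------------------
# Neighbor joining

def nj_tree(m: DistanceMatrix, outgroup: list[str] | None = None) -> dendropy.Tree:
    """Saitou-Nei NJ tree, rooted on the outgroup branch when possible.

    Without a usable outgroup the unrooted tree is returned with a warning.
    NaN distances are rejected.
    """
    if len(m.labels) < 3:
        raise ValueError("NJ needs >= 3 taxa")
    if np.isnan(m.d).any():
        raise ValueError("distance matrix contains undefined (NaN) entries")
    buf = io.StringIO()
    buf.write("," + ",".join(m.labels) + "\n")
    for lab, row in zip(m.labels, m.d):
        buf.write(lab + "," + ",".join(f"{x:.12g}" for x in row) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    if outgroup:
        missing = [o for o in outgroup if o not in m.labels]
        if missing:
            logger.warning("outgroup labels %s absent; returning unrooted tree", missing)
            return tree
        tree.is_rooted = True  # treat the NJ seed node as root for MRCA lookup
        taxa = [t for t in tree.taxon_namespace if t.label in set(outgroup)]
        if len(taxa) == 1:
            node = tree.find_node_with_taxon_label(taxa[0].label)
        else:
            node = tree.mrca(taxa=taxa)
        if node is tree.seed_node or node.edge.tail_node is None:
            logger.warning("outgroup spans the root; returning unrooted tree")
            return tree
        tree.reroot_at_edge(node.edge, length1=node.edge.length / 2.0,
                            length2=node.edge.length / 2.0,
                            update_bipartitions=True)
        tree.is_rooted = True
    return tree


def ingroup_bipartitions(tree: dendropy.Tree, ingroup: set[str]) -> set[frozenset[str]]:
    """Non-trivial splits of the ingroup taxa induced by the tree's edges.

    Each split is normalised to the side of the edge away from the non-
    ingroup taxa; trivial splits (size < 2 or the full ingroup) dropped.
    """
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        part = frozenset(side & ingroup)
        if len(part) >= 2 and len(part) < len(ingroup):
            splits.add(part)
    return splits


def bootstrap_support(a: Alignment, reps: int = 100, seed: int | None = None,
                      outgroup: list[str] | None = None,
                      theta: float | None = None) -> dict[frozenset[str], float]:
    """Site-resampling bootstrap percentages for ingroup bipartitions.

    Replicate alignments are drawn by sampling columns with replacement;
    each yields a T92 NJ tree.  Saturated replicate distances are filled
    with the largest finite replicate distance so trees stay buildable.
    """
    out = set(outgroup or [])
    ing = set(a.sample_ids) - out
    dm0 = t92_distance(a, theta=theta)
    base = nj_tree(_fill_nan(dm0), outgroup=outgroup)
    wanted = ingroup_bipartitions(base, ing)
    hits = {w: 0 for w in wanted}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        cols = rng.integers(0, a.L, size=a.L)
        boot = Alignment(sample_ids=list(a.sample_ids),
                         populations=dict(a.populations),
                         seqs=a.seqs[:, cols], locus_label=a.locus_label)
        t = nj_tree(_fill_nan(t92_distance(boot, theta=theta)), outgroup=outgroup)
        found = ingroup_bipartitions(t, ing)
        for w in wanted & found:
            hits[w] += 1
    return {w: 100.0 * c / reps for w, c in hits.items()}


def _fill_nan(m: DistanceMatrix) -> DistanceMatrix:
    d = m.d.copy()
    if np.isnan(d).any():
        fill = np.nanmax(d) * 1.5 if np.isfinite(np.nanmax(d)) else 1.0
        d[np.isnan(d)] = fill
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(m.labels), d=d)


# --------------------------------------------------------------------------
# Lineage assignment

@dataclass
class LineageAssignment:
    lineage: dict[str, str]                  # sample_id -> "A"/"B"
    haplotype_lineage: dict[str, str]        # haplotype label -> "A"/"B"
    counts: dict[str, dict[str, int]]        # population -> lineage -> count


def assign_lineages(tree: dendropy.Tree, table: HaplotypeTable,
                    populations: dict[str, str],
                    outgroup: list[str] | None = None,
                    anchor_pop: str = "SMR", anchor_lineage: str = "B") -> LineageAssignment:
    """Assign every sample to one of the two basal ingroup clades.

    The clade holding the majority of ``anchor_pop`` samples takes the name
    ``anchor_lineage`` (a naming convention, not an inference); the other
    clade gets the other name.  Requires the rooted ingroup to split into
    exactly two child clades.
    """
    out = set(outgroup or [])
    root = tree.seed_node
    children = root.child_nodes()
    ingroup_node = None
    for ch in children:
        leaves = {lf.taxon.label for lf in ch.leaf_iter()}
        if not (leaves & out):
            ingroup_node = ch
    if out and ingroup_node is None:
        raise AssignmentError("could not locate the ingroup clade under the root")
    if ingroup_node is None:
        ingroup_node = root
    clades = ingroup_node.child_nodes()
    clade_leafsets = [{lf.taxon.label for lf in c.leaf_iter()} - out for c in clades]
    clade_leafsets = [s for s in clade_leafsets if s]
    if len(clade_leafsets) != 2:
        raise AssignmentError(
            f"ingroup root has {len(clade_leafsets)} child clades; expected 2 "
            "(set an explicit anchor after inspecting the tree)")

    label_of_hap = {lab: i for i, lab in enumerate(table.labels())}
    # anchor: clade with the majority of anchor_pop samples
    anchor_counts = []
    for leafset in clade_leafsets:
        c = 0
        for lab in leafset:
            hidx = label_of_hap.get(lab)
            if hidx is None:
                continue
            for sid, h in table.member_map.items():
                if h == hidx and populations.get(sid) == anchor_pop:
                    c += 1
        anchor_counts.append(c)
    other = "A" if anchor_lineage == "B" else "B"
    names = ([anchor_lineage, other] if anchor_counts[0] >= anchor_counts[1]
             else [other, anchor_lineage])

    hap_lineage: dict[str, str] = {}
    for name, leafset in zip(names, clade_leafsets):
        for lab in leafset:
            hap_lineage[lab] = name
    labels = table.labels()
    sample_lineage = {sid: hap_lineage[labels[h]] for sid, h in table.member_map.items()}
    counts: dict[str, dict[str, int]] = {}
    for sid, lin in sample_lineage.items():
        pop = populations[sid]
        counts.setdefault(pop, {"A": 0, "B": 0})
        counts[pop][lin] += 1
    return LineageAssignment(lineage=sample_lineage, haplotype_lineage=hap_lineage,
                             counts=counts)


# --------------------------------------------------------------------------
# Median-joining network

def _hamming(x: str, y: str) -> int:
    return sum(1 for a, b in zip(x, y) if a != b)


def mst_cost(nodes: list[str]) -> int:
    """Total weight of a minimum spanning tree over Hamming distances."""
    n = len(nodes)
    if n < 2:
        return 0
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = _hamming(nodes[i], nodes[j])
    return int(round(minimum_spanning_tree(d).sum()))


def _minimax_paths(nodes: list[str]) -> np.ndarray:
    """Per-pair maximum edge weight on the MST path (minimax distance)."""
    n = len(nodes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _hamming(nodes[i], nodes[j])
    mst = minimum_spanning_tree(np.triu(d)).toarray()
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(n):
            if mst[i, j] > 0:
                adj[i].append((j, mst[i, j]))
                adj[j].append((i, mst[i, j]))
    minimax = np.zeros((n, n))
    for src in range(n):
        # DFS from src, tracking max edge on path
        stack = [(src, 0.0)]
        seen = {src}
        while stack:
            node, mx = stack.pop()
            for nb, w in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    minimax[src, nb] = max(mx, w)
                    stack.append((nb, max(mx, w)))
    return minimax


def _feasible_edges(nodes: list[str], epsilon: int) -> list[tuple[int, int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network."""
    minimax = _minimax_paths(nodes)
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            dij = _hamming(nodes[i], nodes[j])
            if dij <= minimax[i, j] + epsilon:
                edges.append((i, j, dij))
    return edges


def _median_vector(u: str, v: str, w: str) -> str:
    """Per-site majority consensus; all-distinct sites take the first
    (lexicographically smallest) sequence's state."""
    first = min(u, v, w)
    out = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(first[len(out)])
    return "".join(out)


def median_joining_network(t: HaplotypeTable, epsilon: int = 0) -> nx.Graph:
    """Median-joining network of a haplotype table.

    Returns a networkx graph whose nodes are sequence strings with
    attributes ``label`` (H# for sampled, M# for medians), ``sampled``,
    and per-population ``counts``; edges carry ``weight`` = Hamming steps.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be a non-negative integer")
    if t.n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    observed = list(t.haplotypes)
    nodes = sorted(set(observed))
    changed = True
    while changed:
        changed = False
        cost = mst_cost(nodes)
        edges = _feasible_edges(nodes, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        for i in range(len(nodes)):
            for j in sorted(adj[i]):
                if j <= i:
                    continue
                for k in sorted(adj[i] & adj[j]):
                    if k <= j:
                        continue
                    med = _median_vector(nodes[i], nodes[j], nodes[k])
                    if med in nodes:
                        continue
                    if mst_cost(nodes + [med]) < cost:
                        nodes = sorted(nodes + [med])
                        changed = True
                        break
                if changed:
                    break
            if changed:
                break
    # prune unsampled vectors that no longer reduce cost
    pruning = True
    while pruning:
        pruning = False
        cost = mst_cost(nodes)
        for x in list(nodes):
            if x in observed:
                continue
            rest = [y for y in nodes if y != x]
            if mst_cost(rest) <= cost:
                nodes = rest
                pruning = True
                break

    g = nx.Graph()
    hap_label = {seq: f"H{i + 1}" for i, seq in enumerate(observed)}
    m = 0
    for seq in nodes:
        if seq in hap_label:
            idx = observed.index(seq)
            counts = {p: int(c) for p, c in zip(t.populations, t.counts[idx]) if c}
            g.add_node(seq, label=hap_label[seq], sampled=True, counts=counts)
        else:
            m += 1
            g.add_node(seq, label=f"M{m}", sampled=False, counts={})
    for i, j, w in _feasible_edges(nodes, epsilon):
        g.add_edge(nodes[i], nodes[j], weight=int(w))
    if not nx.is_connected(g):
        raise AssertionError("median-joining network must be connected")
    return g


def network_total_cost(g: nx.Graph) -> int:
    """Spanning cost of the network's node set (MST over its nodes)."""
    return mst_cost(list(g.nodes))


def write_graphml(g: nx.Graph, path) -> None:
    h = nx.Graph()
    for seq, data in g.nodes(data=True):
        h.add_node(data["label"], sequence=seq, sampled=data["sampled"],
                   counts=";".join(f"{p}:{c}" for p, c in sorted(data["counts"].items())))
    for u, v, data in g.edges(data=True):
        h.add_edge(g.nodes[u]["label"], g.nodes[v]["label"], weight=data["weight"])
    nx.write_graphml(h, path)
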