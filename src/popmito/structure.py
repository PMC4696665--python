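"""Population structure: AMOVA, pairwise Phi_ST, grouping scans and UPGMA.

AMOVA partitions squared molecular distances (here: pairwise nucleotide
difference counts, the conventional molecular distance for haplotype data)
into hierarchical variance components with the unequal-sample-size
coefficients of Excoffier, Smouse & Quattro (1992).  Significance comes
from permutation nulls with the scheme appropriate to each Phi-statistic:

* Phi_ST — permute individuals among populations (across groups);
* Phi_SC — permute individuals among populations within their group;
* Phi_CT — permute whole populations among groups.

Permutation P-values are (# permuted >= observed + 1) / (permutations + 1).
Negative variance components are retained in the Phi computations rather
than truncated at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .diversity import pairwise_diff_matrix
from .seqio import Alignment

logger = logging.getLogger(__name__)


class StructureError(ValueError):
    """Analysis needs more populations/groups than provided."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")

    def validate_symmetric(self) -> None:
        finite = np.isfinite(self.d)
        if not (finite == finite.T).all() or not np.allclose(
            self.d[finite & finite.T], self.d.T[finite & finite.T]
        ):
            raise ValueError("matrix is not symmetric")


@dataclass
class AmovaResult:
    grouping: list[list[str]]
    df_AG: int
    df_APWG: int
    df_WP: int
    ssd_AG: float
    ssd_APWG: float
    ssd_WP: float
    sigma2_a: float | None
    sigma2_b: float
    sigma2_c: float
    pct_AG: float | None
    pct_APWG: float | None
    pct_WP: float
    phi_CT: float | None
    phi_SC: float | None
    phi_ST: float
    p_CT: float | None = None
    p_SC: float | None = None
    p_ST: float | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def ssd_total(self) -> float:
        return self.ssd_AG + self.ssd_APWG + self.ssd_WP


@dataclass
class PairwiseFstMatrix:
    populations: list[str]
    fst: np.ndarray
    p: np.ndarray


def individual_distance_matrix(a: Alignment, outgroup: str = "outgroup") -> DistanceMatrix:
    """Pairwise nucleotide difference counts among ingroup individuals."""
    ing = a.exclude_populations({outgroup})
    if ing.n < 2:
        raise StructureError("need >= 2 ingroup sequences")
    return DistanceMatrix(labels=list(ing.sample_ids),
                          d=pairwise_diff_matrix(ing.seqs).astype(float))


def _ssd_of(d2: np.ndarray, idx: np.ndarray) -> float:
    """SSD of a set of individuals: sum_{i<j} d2_ij / n."""
    if idx.size < 2:
        return 0.0
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * idx.size))


def _components(d2: np.ndarray, pop_of: np.ndarray, group_of_pop: np.ndarray,
                ssd_total: float) -> dict:
    """Variance components and Phi statistics for one assignment.

    ``pop_of``: per-individual population index; ``group_of_pop``: per-
    population group index.
    """
    P = int(group_of_pop.size)
    G = int(group_of_pop.max()) + 1
    N = pop_of.size
    pop_idx = [np.flatnonzero(pop_of == p) for p in range(P)]
    n_p = np.array([ix.size for ix in pop_idx], dtype=float)
    ssd_wp = sum(_ssd_of(d2, ix) for ix in pop_idx)
    if G > 1:
        group_members = [np.flatnonzero(np.isin(pop_of, np.flatnonzero(group_of_pop == g)))
                         for g in range(G)]
        ssd_wg = sum(_ssd_of(d2, ix) for ix in group_members)
        N_g = np.array([ix.size for ix in group_members], dtype=float)
    else:
        ssd_wg = ssd_total
        N_g = np.array([float(N)])
    ssd_ag = ssd_total - ssd_wg
    ssd_apwg = ssd_wg - ssd_wp

    df_ag, df_apwg, df_wp = G - 1, P - G, N - P
    sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0

    # Excoffier et al. (1992) coefficients for unequal sample sizes
    sum_np2_by_group = np.array(
        [float((n_p[group_of_pop == g] ** 2).sum()) for g in range(G)]
    )
    if df_apwg > 0:
        n_coef = (N - (sum_np2_by_group / N_g).sum()) / df_apwg
        ms_apwg = ssd_apwg / df_apwg
        sigma_b = (ms_apwg - sigma_c) / n_coef
    else:
        sigma_b = 0.0
    if G > 1:
        n_prime = ((sum_np2_by_group / N_g).sum() - (n_p**2).sum() / N) / (G - 1)
        n_dprime = (N - (N_g**2).sum() / N) / (G - 1)
        ms_ag = ssd_ag / df_ag
        sigma_a = (ms_ag - sigma_c - n_prime * sigma_b) / n_dprime
    else:
        sigma_a = None

    tot = (sigma_a or 0.0) + sigma_b + sigma_c
    phi_st = ((sigma_a or 0.0) + sigma_b) / tot if tot != 0 else 0.0
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else 0.0
    phi_ct = (sigma_a / tot if (sigma_a is not None and tot != 0) else None)
    return {
        "ssd_ag": ssd_ag, "ssd_apwg": ssd_apwg, "ssd_wp": ssd_wp,
        "df_ag": df_ag, "df_apwg": df_apwg, "df_wp": df_wp,
        "sigma_a": sigma_a, "sigma_b": sigma_b, "sigma_c": sigma_c,
        "phi_st": phi_st, "phi_sc": phi_sc if G > 1 else None, "phi_ct": phi_ct,
        "tot": tot,
    }


def amova(a: Alignment, grouping: list[list[str]], permutations: int = 0,
          seed: int | None = None, outgroup: str = "outgroup") -> AmovaResult:
    """Hierarchical AMOVA of ``a`` under a population grouping.

    ``grouping`` lists disjoint sets of population codes covering every
    ingroup population.  A single group yields the two-level analysis
    (Phi_ST only); Phi_CT/Phi_SC are then reported as None.
    """
    ing = a.exclude_populations({outgroup})
    pops_present = ing.pop_codes()
    flat = [p for g in grouping for p in g]
    if any(len(g) == 0 for g in grouping):
        raise ValueError("grouping contains an empty group")
    if sorted(flat) != sorted(set(flat)):
        raise ValueError("a population appears in more than one group")
    if set(flat) != set(pops_present):
        raise ValueError(f"grouping does not cover populations {pops_present}")
    if len(pops_present) < 2:
        raise StructureError("AMOVA needs >= 2 populations")

    pop_order = flat
    pop_code_index = {p: i for i, p in enumerate(pop_order)}
    pop_of = np.array([pop_code_index[ing.populations[s]] for s in ing.sample_ids])
    group_of_pop = np.array([gi for gi, g in enumerate(grouping) for _ in g])
    d2 = pairwise_diff_matrix(ing.seqs).astype(float)
    ssd_total = float(d2.sum() / (2.0 * ing.n))

    obs = _components(d2, pop_of, group_of_pop, ssd_total)
    G = len(grouping)
    res = AmovaResult(
        grouping=[list(g) for g in grouping],
        df_AG=obs["df_ag"], df_APWG=obs["df_apwg"], df_WP=obs["df_wp"],
        ssd_AG=obs["ssd_ag"], ssd_APWG=obs["ssd_apwg"], ssd_WP=obs["ssd_wp"],
        sigma2_a=obs["sigma_a"], sigma2_b=obs["sigma_b"], sigma2_c=obs["sigma_c"],
        pct_AG=(100.0 * obs["sigma_a"] / obs["tot"]) if obs["sigma_a"] is not None and obs["tot"] else None,
        pct_APWG=(100.0 * obs["sigma_b"] / obs["tot"]) if G > 1 and obs["tot"] else None,
        pct_WP=(100.0 * obs["sigma_c"] / obs["tot"]) if obs["tot"] else 100.0,
        phi_CT=obs["phi_ct"], phi_SC=obs["phi_sc"], phi_ST=obs["phi_st"],
    )
    if G == 1 and obs["tot"]:
        # two-level layout: among-population percentage goes to pct_APWG
        res.pct_APWG = 100.0 * obs["sigma_b"] / obs["tot"]
    if permutations > 0:
        _permute_pvalues(res, d2, pop_of, group_of_pop, ssd_total,
                         permutations, seed)
    return res


def _permute_pvalues(res: AmovaResult, d2, pop_of, group_of_pop, ssd_total,
                     permutations: int, seed: int | None) -> None:
    rng = np.random.default_rng(seed)
    G = int(group_of_pop.max()) + 1
    obs_st, obs_sc, obs_ct = res.phi_ST, res.phi_SC, res.phi_CT

    ge_st = 0
    for _ in range(permutations):
        perm = rng.permutation(pop_of)
        c = _components(d2, perm, group_of_pop, ssd_total)
        if c["phi_st"] >= obs_st:
            ge_st += 1
    res.p_ST = (ge_st + 1) / (permutations + 1)

    if G > 1 and obs_sc is not None:
        ge_sc = 0
        group_of_ind = group_of_pop[pop_of]
        for _ in range(permutations):
            perm = pop_of.copy()
            for g in range(G):
                mask = group_of_ind == g
                perm[mask] = rng.permutation(pop_of[mask])
            c = _components(d2, perm, group_of_pop, ssd_total)
            if c["phi_sc"] is not None and c["phi_sc"] >= obs_sc:
                ge_sc += 1
        res.p_SC = (ge_sc + 1) / (permutations + 1)

    if G > 1 and obs_ct is not None:
        ge_ct = 0
        for _ in range(permutations):
            perm_groups = rng.permutation(group_of_pop)
            c = _components(d2, pop_of, perm_groups, ssd_total)
            if c["phi_ct"] is not None and c["phi_ct"] >= obs_ct:
                ge_ct += 1
        res.p_CT = (ge_ct + 1) / (permutations + 1)


def pairwise_phist_matrix(a: Alignment, permutations: int = 1000,
                          seed: int | None = None,
                          outgroup: str = "outgroup") -> PairwiseFstMatrix:
    """Phi_ST for every population pair, with permutation P-values.

    Each entry is the two-population AMOVA Phi_ST on that pair;
    populations with n < 2 are flagged and filled with NaN.
    """
    ing = a.exclude_populations({outgroup})
    pops = ing.pop_codes()
    if len(pops) < 2:
        raise StructureError("need >= 2 populations")
    sizes = {p: sum(1 for s in ing.sample_ids if ing.populations[s] == p) for p in pops}
    k = len(pops)
    fst = np.zeros((k, k))
    pmat = np.full((k, k), np.nan)
    ss = np.random.SeedSequence(seed)
    pair_seeds = iter(ss.generate_state(k * k))
    for i in range(k):
        for j in range(i + 1, k):
            s_ij = int(next(pair_seeds)) % (2**31 - 1)
            if sizes[pops[i]] < 2 or sizes[pops[j]] < 2:
                logger.warning("population with n<2 in pair (%s, %s); entry NaN",
                               pops[i], pops[j])
                fst[i, j] = fst[j, i] = np.nan
                continue
            sub_ids = [s for s in ing.sample_ids
                       if ing.populations[s] in (pops[i], pops[j])]
            sub = ing.subset(sub_ids)
            r = amova(sub, [[pops[i], pops[j]]], permutations=permutations,
                      seed=s_ij, outgroup=outgroup)
            fst[i, j] = fst[j, i] = r.phi_ST
            pmat[i, j] = pmat[j, i] = r.p_ST if r.p_ST is not None else np.nan
    np.fill_diagonal(fst, 0.0)
    return PairwiseFstMatrix(populations=pops, fst=fst, p=pmat)


def grouping_scan(a: Alignment, candidates: list[list[list[str]]],
                  permutations: int = 1000, seed: int | None = None,
                  alpha: float = 0.05, outgroup: str = "outgroup") -> list[AmovaResult]:
    """AMOVA for each candidate grouping, ranked by Phi_CT (descending).

    The top result gets a "winner" note only if its p_CT is below ``alpha``.
    Groupings without an among-group level rank last (Phi_CT undefined).
    """
    if not candidates:
        raise ValueError("empty candidate grouping list")
    ss = np.random.SeedSequence(seed)
    seeds = [int(x) % (2**31 - 1) for x in ss.generate_state(len(candidates))]
    results = [amova(a, g, permutations=permutations, seed=s, outgroup=outgroup)
               for g, s in zip(candidates, seeds)]
    results.sort(key=lambda r: (-np.inf if r.phi_CT is None else r.phi_CT),
                 reverse=True)
    top = results[0]
    if top.phi_CT is not None and top.p_CT is not None and top.p_CT < alpha:
        top.notes.append("winner")
    return results


# --------------------------------------------------------------------------
# UPGMA

@dataclass
class UpgmaTree:
    newick: str
    root_children: list[frozenset[str]]
    merges: list[tuple[frozenset[str], frozenset[str], float]]


def upgma(m: DistanceMatrix | PairwiseFstMatrix) -> UpgmaTree:
    """Size-weighted average-linkage agglomeration of a distance matrix.

    Deterministic: distance ties are broken by the lexicographically
    smallest member label of each cluster.  Negative input distances are
    clamped to 0 with a warning.  Heights are ultrametric; the Newick
    string carries branch lengths (child height subtracted).
    """
    if isinstance(m, PairwiseFstMatrix):
        m = DistanceMatrix(labels=list(m.populations), d=m.fst.copy())
    m.validate_symmetric()
    labels = m.labels
    if len(labels) < 2:
        raise ValueError("need >= 2 labels")
    d = m.d.copy()
    if (d < 0).any():
        logger.warning("negative distances clamped to 0 for UPGMA")
        d = np.clip(d, 0.0, None)

    clusters: dict[int, dict] = {
        i: {"newick": lab, "size": 1, "height": 0.0,
            "members": frozenset([lab]), "minlab": lab}
        for i, lab in enumerate(labels)
    }
    dist: dict[tuple[int, int], float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            dist[(i, j)] = float(d[i, j])
    merges: list[tuple[frozenset[str], frozenset[str], float]] = []
    next_id = len(labels)
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1],
                            min(clusters[kv[0][0]]["minlab"], clusters[kv[0][1]]["minlab"]),
                            max(clusters[kv[0][0]]["minlab"], clusters[kv[0][1]]["minlab"])),
        )
        (i, j), dmin = best
        ci, cj = clusters.pop(i), clusters.pop(j)
        h = dmin / 2.0
        first, second = (ci, cj) if ci["minlab"] <= cj["minlab"] else (cj, ci)
        nwk = (f"({first['newick']}:{h - first['height']:.10g},"
               f"{second['newick']}:{h - second['height']:.10g})")
        merges.append((first["members"], second["members"], h))
        new = {"newick": nwk, "size": ci["size"] + cj["size"], "height": h,
               "members": ci["members"] | cj["members"],
               "minlab": min(ci["minlab"], cj["minlab"])}
        # size-weighted average linkage to every remaining cluster
        newdist = {}
        for k in clusters:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            newdist[k] = (ci["size"] * dik + cj["size"] * djk) / new["size"]
        dist.pop((i, j), None)
        dist = {key: v for key, v in dist.items() if i not in key and j not in key}
        clusters[next_id] = new
        for k, v in newdist.items():
            dist[(min(next_id, k), max(next_id, k))] = v
        next_id += 1
    root_members = merges[-1]
    return UpgmaTree(
        newick=clusters[next_id - 1]["newick"] + ";",
        root_children=[root_members[0], root_members[1]],
        merges=merges,
    )


def upgma_bootstrap(a: Alignment, reps: int = 100, seed: int | None = None,
                    outgroup: str = "outgroup") -> dict[frozenset[str], float]:
    """Site-resampling bootstrap support for UPGMA clusters of populations.

    Each replicate resamples alignment columns with replacement, recomputes
    the pairwise Phi_ST matrix (no permutations) and the UPGMA tree, and
    counts occurrences of each observed cluster.  Qualitative output.
    """
    base = upgma(pairwise_phist_matrix(a, permutations=0, outgroup=outgroup))
    wanted = {frozenset(x) for pair in base.merges for x in pair[:2]}
    hits = {w: 0 for w in wanted}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        cols = rng.integers(0, a.L, size=a.L)
        boot = Alignment(sample_ids=list(a.sample_ids),
                         populations=dict(a.populations),
                         seqs=a.seqs[:, cols], locus_label=a.locus_label)
        t = upgma(pairwise_phist_matrix(boot, permutations=0, outgroup=outgroup))
        found = {frozenset(x) for pair in t.merges for x in pair[:2]}
        for w in wanted & found:
            hits[w] += 1
    return {w: 100.0 * c / reps for w, c in hits.items()}
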