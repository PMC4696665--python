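"""End-to-end pipeline: run every analysis stage on one dataset and emit
table-shaped TSV reports, Newick trees, a GraphML network and a JSON
manifest holding every computed statistic.

The manifest is a plain nested dict of numbers/strings so that re-running
with the same inputs and seed yields byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
import math
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import demography, diversity, haplotypes, neutrality, phylo_network, seqio, structure

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str | None = None
    fasta_16s: str | None = None
    fasta_coi: str | None = None
    popmap: str | None = None
    outgroup: str = "outgroup"
    anchor_pop: str = "SMR"
    anchor_lineage: str = "B"
    permutations: int = 10000
    bootstrap: int = 1000
    seed: int = 1
    rate_percent_per_myr: float = 1.42
    generation_years: float = 1.0
    groupings: list[list[list[str]]] = field(default_factory=list)
    neutrality_reps: int = 1000
    ssd_reps: int = 100
    out: str = "popmito_out"


def load_groupings(path) -> list[list[list[str]]]:
    """Candidate groupings from JSON: a list of lists of population lists."""
    with open(path) as fh:
        return json.load(fh)


def default_groupings(pops: list[str]) -> list[list[list[str]]]:
    """One-group analysis only, used when no candidates are supplied."""
    return [[list(pops)]]


def _num(x):
    if x is None:
        return None
    x = float(x)
    if math.isnan(x):
        return None
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return round(x, 10)


def read_input(cfg: PipelineConfig) -> seqio.Alignment:
    if cfg.fasta:
        return seqio.read_alignment(cfg.fasta, cfg.popmap, locus_label="combined")
    if cfg.fasta_16s and cfg.fasta_coi:
        a = seqio.read_alignment(cfg.fasta_16s, cfg.popmap, locus_label="16S")
        b = seqio.read_alignment(cfg.fasta_coi, cfg.popmap, locus_label="COI")
        return seqio.concatenate_loci(a, b)
    raise ValueError("provide --fasta or both --fasta-16s and --fasta-coi")


def run_full_pipeline(cfg: PipelineConfig, aln: seqio.Alignment | None = None) -> dict:
    """Run every stage, write reports under ``cfg.out``, return the manifest."""
    os.makedirs(cfg.out, exist_ok=True)
    manifest: dict = {"config": {
        "outgroup": cfg.outgroup, "permutations": cfg.permutations,
        "bootstrap": cfg.bootstrap, "seed": cfg.seed,
        "rate_percent_per_myr": cfg.rate_percent_per_myr,
        "generation_years": cfg.generation_years,
    }}
    t0 = time.time()
    if aln is None:
        aln = read_input(cfg)
    ing = aln.exclude_populations({cfg.outgroup})
    pops = ing.pop_codes()

    def stage(name):
        logger.info("[%s] t=%.1fs", name, time.time() - t0)

    stage("summary")
    summ = seqio.summarize_alignment(aln, exclude={cfg.outgroup})
    manifest["summary"] = seqio.summary_dict(summ)

    stage("haplotypes")
    table = haplotypes.collapse_haplotypes(aln, outgroup=cfg.outgroup)
    table.to_frame().to_csv(os.path.join(cfg.out, "haplotype_counts.tsv"), sep="\t")
    table.write_fasta(os.path.join(cfg.out, "haplotypes.fasta"))
    modal = haplotypes.modal_haplotypes(table, 2)
    manifest["haplotypes"] = {
        "n_haplotypes": table.n_haplotypes,
        "n_samples": table.n_samples,
        "modal_count": modal[0][1],
        "second_count": modal[1][1] if len(modal) > 1 else None,
    }

    stage("tree")
    hap_aln = haplotypes.haplotype_alignment(table)
    out_ids = [s for s in aln.sample_ids if aln.populations[s] == cfg.outgroup]
    tree_aln = hap_aln
    if out_ids:
        out_rows = aln.subset(out_ids)
        tree_aln = seqio.Alignment(
            sample_ids=hap_aln.sample_ids + out_ids,
            populations={**hap_aln.populations,
                         **{i: cfg.outgroup for i in out_ids}},
            seqs=np.vstack([hap_aln.seqs, out_rows.seqs]),
            locus_label="haplotypes+outgroup")
    dm = phylo_network.t92_distance(tree_aln)
    tree = phylo_network.nj_tree(phylo_network._fill_nan(dm), outgroup=out_ids or None)
    tree.write(path=os.path.join(cfg.out, "nj_haplotypes.nwk"), schema="newick")
    support = {}
    if cfg.bootstrap > 0:
        support = phylo_network.bootstrap_support(
            tree_aln, reps=cfg.bootstrap, seed=cfg.seed, outgroup=out_ids or None)
    lineage = None
    lineage_note = None
    try:
        lineage = phylo_network.assign_lineages(
            tree, table, aln.populations, outgroup=out_ids or None,
            anchor_pop=cfg.anchor_pop, anchor_lineage=cfg.anchor_lineage)
    except phylo_network.AssignmentError as e:
        lineage_note = str(e)
        logger.warning("lineage assignment unavailable: %s", e)
    if lineage is not None:
        n_lin = {lin: sum(1 for v in lineage.lineage.values() if v == lin)
                 for lin in ("A", "B")}
        h_lin = {lin: sum(1 for v in lineage.haplotype_lineage.values() if v == lin)
                 for lin in ("A", "B")}
        split = frozenset(lab for lab, lin in lineage.haplotype_lineage.items()
                          if lin == "A")
        alt = frozenset(lab for lab, lin in lineage.haplotype_lineage.items()
                        if lin == "B")
        sup = support.get(split, support.get(alt))
        manifest["lineages"] = {
            "samples": n_lin, "haplotypes": h_lin,
            "split_bootstrap_pct": _num(sup),
            "counts": {p: dict(c) for p, c in sorted(lineage.counts.items())},
        }
    else:
        manifest["lineages"] = {"error": lineage_note}

    stage("diversity+neutrality")
    rows = []
    units: list[tuple[str, seqio.Alignment]] = [(p, ing.subset(
        [s for s in ing.sample_ids if ing.populations[s] == p])) for p in pops]
    if lineage is not None:
        for lin in ("A", "B"):
            ids = [s for s, v in lineage.lineage.items() if v == lin]
            if len(ids) >= 2:
                units.append((f"lineage_{lin}", ing.subset(
                    [s for s in ing.sample_ids if s in set(ids)])))
    units.append(("total", ing))
    ss = np.random.SeedSequence(cfg.seed)
    unit_seeds = [int(x) % (2**31 - 1) for x in ss.generate_state(len(units))]
    for (name, sub), useed in zip(units, unit_seeds):
        if sub.n < 2:
            rows.append({"unit": name, "n": sub.n})
            continue
        div = diversity.diversity_result(sub)
        neu = neutrality.neutrality_stats(sub)
        p_D = p_Fs = None
        if cfg.neutrality_reps > 0 and sub.n >= 4:
            p_D, p_Fs = neutrality.neutrality_pvalues(
                sub, reps=cfg.neutrality_reps, seed=useed)
        rows.append({
            "unit": name, "n": div.n, "n_h": div.n_h,
            "h": _num(div.h), "h_sd": _num(div.h_sd),
            "pi": _num(div.pi), "pi_sd": _num(div.pi_sd),
            "k_bar": _num(div.k_bar),
            "tajimas_D": _num(neu.D), "fus_Fs": _num(neu.Fs),
            "p_D": _num(p_D), "p_Fs": _num(p_Fs),
            "sig_D": neutrality.significance_stars(p_D),
            "sig_Fs": neutrality.significance_stars(p_Fs),
        })
    div_df = pd.DataFrame(rows)
    div_df.to_csv(os.path.join(cfg.out, "diversity_table.tsv"), sep="\t", index=False)
    manifest["diversity"] = {r["unit"]: r for r in rows}

    stage("structure")
    manifest["structure"] = {}
    if len(pops) >= 2:
        pw = structure.pairwise_phist_matrix(
            ing, permutations=cfg.permutations, seed=cfg.seed)
        k = len(pw.populations)
        mat = pd.DataFrame("", index=pw.populations, columns=pw.populations)
        for i in range(k):
            for j in range(k):
                if i > j:
                    mat.iloc[i, j] = f"{pw.fst[i, j]:.3f}"
                elif i < j:
                    mat.iloc[i, j] = f"{pw.p[i, j]:.4f}"
                else:
                    mat.iloc[i, j] = "-"
        mat.to_csv(os.path.join(cfg.out, "pairwise_phist.tsv"), sep="\t")
        manifest["structure"]["pairwise_phist"] = {
            f"{pw.populations[i]}-{pw.populations[j]}": {
                "phi_st": _num(pw.fst[i, j]), "p": _num(pw.p[i, j])}
            for i in range(k) for j in range(i + 1, k)
        }
        candidates = cfg.groupings or default_groupings(pops)
        scan = structure.grouping_scan(
            ing, candidates, permutations=cfg.permutations, seed=cfg.seed)
        amova_rows = []
        for r in scan:
            amova_rows.append({
                "grouping": " | ".join(",".join(g) for g in r.grouping),
                "phi_CT": _num(r.phi_CT), "phi_SC": _num(r.phi_SC),
                "phi_ST": _num(r.phi_ST),
                "pct_AG": _num(r.pct_AG), "pct_APWG": _num(r.pct_APWG),
                "pct_WP": _num(r.pct_WP),
                "p_CT": _num(r.p_CT), "p_SC": _num(r.p_SC), "p_ST": _num(r.p_ST),
                "winner": "winner" in r.notes,
            })
        pd.DataFrame(amova_rows).to_csv(
            os.path.join(cfg.out, "amova_table.tsv"), sep="\t", index=False)
        manifest["structure"]["amova"] = amova_rows
        upg = structure.upgma(pw)
        with open(os.path.join(cfg.out, "upgma_populations.nwk"), "w") as fh:
            fh.write(upg.newick + "\n")
        manifest["structure"]["upgma"] = {
            "newick": upg.newick,
            "first_split": sorted(sorted(s) for s in upg.root_children),
        }

    stage("network")
    if table.n_haplotypes >= 2:
        net = phylo_network.median_joining_network(table)
        phylo_network.write_graphml(net, os.path.join(cfg.out, "network.graphml"))
        manifest["network"] = {
            "n_nodes": net.number_of_nodes(),
            "n_medians": sum(1 for _, d in net.nodes(data=True) if not d["sampled"]),
            "total_cost": phylo_network.network_total_cost(net),
        }

    stage("demography")
    rate = cfg.rate_percent_per_myr / 100.0 / 1e6  # %/myr -> per site per year
    demo_units = [("total", ing)]
    if lineage is not None:
        for lin in ("A", "B"):
            ids = set(s for s, v in lineage.lineage.items() if v == lin)
            if len(ids) >= 10:
                demo_units.append((f"lineage_{lin}",
                                   ing.subset([s for s in ing.sample_ids if s in ids])))
    manifest["demography"] = {}
    demo_seeds = [int(x) % (2**31 - 1)
                  for x in np.random.SeedSequence(cfg.seed + 1).generate_state(len(demo_units))]
    spec_rows = []
    for (name, sub), dseed in zip(demo_units, demo_seeds):
        spec = demography.mismatch_observed(sub)
        entry = {"n": sub.n, "mean": _num(spec.mean),
                 "modes": demography.smoothed_modes(spec.freqs),
                 "bimodal": demography.is_bimodal(spec)}
        if name != "total":
            fit = demography.fit_sudden_expansion(spec)
            p_ssd = None
            if cfg.ssd_reps > 0:
                p_ssd = demography.ssd_test(fit, sub.n, sub.L,
                                            reps=cfg.ssd_reps, seed=dseed)
            timing = demography.expansion_time(
                fit.tau, rate, cfg.generation_years, sub.L)
            entry.update({
                "tau": _num(fit.tau), "theta0": _num(fit.theta0),
                "ssd": _num(fit.ssd), "p_ssd": _num(p_ssd),
                "expansion_time_years": _num(timing.T_years),
            })
            for j, (o, e) in enumerate(zip(spec.freqs, fit.expected)):
                spec_rows.append({"unit": name, "j": j,
                                  "observed": _num(o), "expected": _num(e)})
        else:
            for j, o in enumerate(spec.freqs):
                spec_rows.append({"unit": name, "j": j,
                                  "observed": _num(o), "expected": None})
        manifest["demography"][name] = entry
    pd.DataFrame(spec_rows).to_csv(
        os.path.join(cfg.out, "mismatch_spectra.tsv"), sep="\t", index=False)

    with open(os.path.join(cfg.out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    stage("done")
    return manifest
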