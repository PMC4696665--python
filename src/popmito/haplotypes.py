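"""Collapse aligned sequences into distinct haplotypes.

A haplotype is an exact-string-identical sequence variant; matching is not
ambiguity-aware, so sequences differing only by an N are distinct unless
identical.  Labels H1..Hk follow first-appearance order in the input, which
makes every downstream artefact (networks, trees, reports) deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import Alignment, InsufficientDataError


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-population counts.

    ``counts`` is (n_haplotypes, n_populations); ``member_map`` sends every
    sample id to its haplotype index.
    """

    haplotypes: list[str]
    populations: list[str]
    counts: np.ndarray
    member_map: dict[str, int]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def labels(self) -> list[str]:
        return [f"H{i + 1}" for i in range(self.n_haplotypes)]

    def samples_of(self, index: int) -> list[str]:
        return [s for s, h in self.member_map.items() if h == index]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.labels(), columns=self.populations)
        df.index.name = "haplotype"
        return df

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for lab, seq in zip(self.labels(), self.haplotypes):
                fh.write(f">{lab}\n{seq}\n")


def collapse_haplotypes(a: Alignment, outgroup: str = "outgroup") -> HaplotypeTable:
    """Collapse the ingroup of ``a`` into distinct haplotypes.

    Order of haplotypes and of population columns is first appearance
    among the ingroup rows.
    """
    ing = a.exclude_populations({outgroup})
    if ing.n == 0:
        raise InsufficientDataError("no ingroup sequences to collapse")
    pops = ing.pop_codes()
    pop_index = {p: j for j, p in enumerate(pops)}
    hap_index: dict[str, int] = {}
    haplotypes: list[str] = []
    member_map: dict[str, int] = {}
    rows: list[tuple[int, int]] = []
    for sid, seq in zip(ing.sample_ids, ing.row_strings()):
        if seq not in hap_index:
            hap_index[seq] = len(haplotypes)
            haplotypes.append(seq)
        h = hap_index[seq]
        member_map[sid] = h
        rows.append((h, pop_index[ing.populations[sid]]))
    counts = np.zeros((len(haplotypes), len(pops)), dtype=int)
    for h, j in rows:
        counts[h, j] += 1
    return HaplotypeTable(haplotypes=haplotypes, populations=pops,
                          counts=counts, member_map=member_map)


def modal_haplotypes(t: HaplotypeTable, k: int) -> list[tuple[int, int, dict[str, int]]]:
    """Top-``k`` haplotypes by total count.

    Ties broken by first-appearance order (ascending index), so ranking is
    deterministic.  Returns (haplotype index, total count, per-population
    counts) triples in descending order of total count.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if t.n_haplotypes == 0:
        raise InsufficientDataError("empty haplotype table")
    totals = t.total_counts()
    order = sorted(range(t.n_haplotypes), key=lambda i: (-totals[i], i))
    out = []
    for i in order[:k]:
        per_pop = {p: int(c) for p, c in zip(t.populations, t.counts[i]) if c > 0}
        out.append((i, int(totals[i]), per_pop))
    return out


def haplotype_alignment(t: HaplotypeTable) -> Alignment:
    """One row per haplotype, labelled H1..Hk; populations set to 'haplotype'."""
    seqs = np.frombuffer("".join(t.haplotypes).encode("ascii"), dtype=np.uint8)
    seqs = seqs.reshape(t.n_haplotypes, len(t.haplotypes[0])).copy()
    labels = t.labels()
    return Alignment(
        sample_ids=labels,
        populations={lab: "haplotype" for lab in labels},
        seqs=seqs,
        locus_label="haplotypes",
    )
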