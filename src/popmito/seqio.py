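"""Reading, validation and summarisation of mtDNA sequence alignments.

An :class:`Alignment` couples an equal-length nucleotide matrix with a
sample-to-population map (a two-column TSV).  Alignment-level summaries
cover the quantities conventionally reported for mtDNA fragment data:
variable (segregating) sites, parsimony-informative sites, G+C content
and the transition/transversion ratio pooled over all sequence pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Residues accepted in an alignment.
IUPAC_CHARS = set(b"ACGTRYSWKMBDHVN-")
#: Unambiguous nucleotides, the only residues that enter site statistics.
UNAMBIGUOUS = b"ACGT"

_A, _C, _G, _T = (ord(c) for c in "ACGT")


class AlignmentLengthError(ValueError):
    """Rows of a FASTA alignment have unequal lengths."""


class FormatError(ValueError):
    """Malformed FASTA/popmap input (duplicate ids, bad characters...)."""


class SampleSetError(ValueError):
    """Two loci do not cover the same sample ids."""


class InsufficientDataError(ValueError):
    """Fewer sequences than the statistic requires."""


@dataclass
class Alignment:
    """Labelled equal-length nucleotide matrix plus a population map.

    ``seqs`` is an (n, L) uint8 array of upper-case ASCII codes.  ``loci``
    records half-open column ranges of the constituent loci so per-locus
    summaries remain possible after concatenation.
    """

    sample_ids: list[str]
    populations: dict[str, str]
    seqs: np.ndarray
    locus_label: str = ""
    loci: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def L(self) -> int:
        return self.seqs.shape[1]

    def population_of(self, sample_id: str) -> str:
        return self.populations[sample_id]

    def pop_codes(self) -> list[str]:
        """Population codes in order of first appearance among the rows."""
        seen: list[str] = []
        for sid in self.sample_ids:
            p = self.populations[sid]
            if p not in seen:
                seen.append(p)
        return seen

    def subset(self, ids: list[str]) -> "Alignment":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return replace(
            self,
            sample_ids=list(ids),
            populations={s: self.populations[s] for s in ids},
            seqs=self.seqs[rows],
        )

    def exclude_populations(self, exclude: set[str] | frozenset[str]) -> "Alignment":
        keep = [s for s in self.sample_ids if self.populations[s] not in exclude]
        return self.subset(keep)

    def ingroup(self, outgroup: str = "outgroup") -> "Alignment":
        return self.exclude_populations({outgroup})

    def row_strings(self) -> list[str]:
        return [bytes(r).decode("ascii") for r in self.seqs]

    def validate(self) -> None:
        if self.seqs.ndim != 2 or self.L == 0:
            raise AlignmentLengthError("alignment must be a non-empty matrix")
        if len(self.sample_ids) != self.n:
            raise FormatError("sample id count does not match row count")
        if len(set(self.sample_ids)) != self.n:
            raise FormatError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.populations]
        if missing:
            raise FormatError(f"samples missing from population map: {missing[:5]}")
        bad = set(np.unique(self.seqs)) - {ord(c) for c in map(chr, IUPAC_CHARS)}
        if bad:
            raise FormatError(
                "non-IUPAC characters in alignment: "
                + ", ".join(repr(chr(b)) for b in sorted(bad))
            )


@dataclass(frozen=True)
class AlignmentSummary:
    """Site-level summary of an alignment (ingroup by default)."""

    L: int
    S: int
    PI: int
    gc: float
    ts_tv: float  # NaN when no transversions observed


def _seq_matrix(records: list[tuple[str, str]]) -> np.ndarray:
    lengths = {len(s) for _, s in records}
    if len(lengths) != 1:
        raise AlignmentLengthError(f"ragged alignment: lengths {sorted(lengths)}")
    (L,) = lengths
    if L == 0:
        raise AlignmentLengthError("zero-length sequences")
    arr = np.frombuffer("".join(s for _, s in records).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(records), L).copy()


def read_popmap(path) -> dict[str, str]:
    """Read a two-column TSV ``sample_id<TAB>population``; '#' comments allowed."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 tab-separated fields")
            sid, pop = parts
            if sid in popmap:
                raise FormatError(f"{path}:{ln}: duplicate sample id {sid!r}")
            popmap[sid] = pop
    return popmap


def read_alignment(fasta_path, popmap_path=None, locus_label: str = "") -> Alignment:
    """Read a multi-FASTA alignment and (optionally) a population map.

    Samples absent from the popmap are assigned population ``"unassigned"``
    and reported via the module logger.
    """
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(fasta_path), "fasta")]
    if not records:
        raise FormatError(f"{fasta_path}: no FASTA records")
    if any(not s for _, s in records):
        raise FormatError(f"{fasta_path}: empty FASTA record")
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{fasta_path}: duplicate record ids")
    seqs = _seq_matrix(records)
    popmap = read_popmap(popmap_path) if popmap_path is not None else {}
    unassigned = [i for i in ids if i not in popmap]
    if unassigned:
        logger.warning("%d samples absent from popmap -> 'unassigned'", len(unassigned))
    populations = {i: popmap.get(i, "unassigned") for i in ids}
    aln = Alignment(
        sample_ids=ids,
        populations=populations,
        seqs=seqs,
        locus_label=locus_label,
        loci=[(locus_label or "locus", 0, seqs.shape[1])],
    )
    aln.validate()
    if (seqs == ord("-")).any():
        logger.warning("alignment %s contains gaps; they are ignored in site counts",
                       locus_label or fasta_path)
    return aln


def write_alignment(a: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(a.sample_ids, a.row_strings()):
            fh.write(f">{sid}\n{row}\n")


def concatenate_loci(a: Alignment, b: Alignment) -> Alignment:
    """Concatenate two loci over the same sample set, preserving ``a``'s row order."""
    if set(a.sample_ids) != set(b.sample_ids):
        only_a = sorted(set(a.sample_ids) - set(b.sample_ids))[:5]
        only_b = sorted(set(b.sample_ids) - set(a.sample_ids))[:5]
        raise SampleSetError(f"sample sets differ (a-only {only_a}, b-only {only_b})")
    if b.L == 0:
        return a
    b_ordered = b.subset(a.sample_ids)
    seqs = np.hstack([a.seqs, b_ordered.seqs])
    loci = list(a.loci) + [(name, s + a.L, e + a.L) for name, s, e in b.loci]
    label = "+".join(x for x in (a.locus_label, b.locus_label) if x)
    return Alignment(
        sample_ids=list(a.sample_ids),
        populations=dict(a.populations),
        seqs=seqs,
        locus_label=label,
        loci=loci,
    )


def base_counts(seqs: np.ndarray) -> np.ndarray:
    """(4, L) counts of A, C, G, T per column; ambiguity codes and gaps ignored."""
    return np.stack([(seqs == code).sum(axis=0) for code in (_A, _C, _G, _T)])


def summarize_alignment(a: Alignment, exclude: set[str] = frozenset({"outgroup"})) -> AlignmentSummary:
    """Variable sites, parsimony-informative sites, G+C and ts/tv ratio.

    Site statistics use only unambiguous residues.  The ts/tv ratio is the
    ratio of *summed* pairwise transition and transversion counts over all
    sequence pairs, computed per column from base counts.
    """
    ing = a.exclude_populations(set(exclude))
    if ing.n < 2:
        raise InsufficientDataError("need >= 2 ingroup sequences")
    counts = base_counts(ing.seqs)  # rows: A, C, G, T
    nA, nC, nG, nT = counts
    S = int(((counts > 0).sum(axis=0) >= 2).sum())
    PI = int(((counts >= 2).sum(axis=0) >= 2).sum())
    total = counts.sum()
    gc = float((nG.sum() + nC.sum()) / total) if total else float("nan")
    ts = float((nA * nG + nC * nT).sum())
    tv = float(((nA + nG) * (nC + nT)).sum())
    ts_tv = ts / tv if tv > 0 else float("nan")
    return AlignmentSummary(L=ing.L, S=S, PI=PI, gc=gc, ts_tv=ts_tv)


def summary_dict(s: AlignmentSummary) -> dict:
    return {"L": s.L, "S": s.S, "PI": s.PI, "gc": s.gc, "ts_tv": s.ts_tv}
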