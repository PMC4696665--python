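"""Gene (haplotype) diversity and nucleotide diversity with Nei (1987) variances.

Pairwise differences use pairwise deletion: a site contributes to d_ij only
when both residues are unambiguous (A/C/G/T), while per-site diversity keeps
the full alignment length in the denominator, matching the usual convention
for reporting pi over the analysed fragment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqio import Alignment, InsufficientDataError

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _unambiguous_mask(seqs: np.ndarray) -> np.ndarray:
    return np.isin(seqs, _ACGT)


def pairwise_diff_matrix(seqs: np.ndarray) -> np.ndarray:
    """(n, n) matrix of pairwise difference counts under pairwise deletion."""
    n = seqs.shape[0]
    ok = _unambiguous_mask(seqs)
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        both = ok[i] & ok[i + 1:]
        diff = (seqs[i] != seqs[i + 1:]) & both
        row = diff.sum(axis=1)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return d


def mean_pairwise_differences(a: Alignment) -> float:
    """k_bar, the mean number of pairwise differences per sequence pair."""
    if a.n < 2:
        raise InsufficientDataError("need >= 2 sequences")
    d = pairwise_diff_matrix(a.seqs)
    n = a.n
    return float(d.sum() / (n * (n - 1)))


@dataclass(frozen=True)
class DiversityResult:
    n: int
    n_h: int
    h: float
    h_sd: float
    pi: float
    pi_sd: float
    k_bar: float


def gene_diversity(counts) -> tuple[float, float]:
    """Nei's gene diversity h and its standard deviation from haplotype counts.

    h = n(1 - sum p_i^2)/(n - 1); the variance is Nei (1987):
    V = (2/(n(n-1))) * {2(n-2)[sum p_i^3 - (sum p_i^2)^2] + sum p_i^2 - (sum p_i^2)^2}
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise InsufficientDataError("gene diversity needs n >= 2")
    p = c / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    h = n * (1.0 - s2) / (n - 1.0)
    v = (2.0 / (n * (n - 1.0))) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    return h, math.sqrt(max(v, 0.0))


def nucleotide_diversity(a: Alignment) -> tuple[float, float, float]:
    """(pi, pi_sd, k_bar) for an alignment.

    pi = k_bar / L.  The sampling variance is Nei (1987):
    V(pi) = ((n+1)/(3(n-1)L)) pi + (2(n^2+n+3)/(9n(n-1))) pi^2
    """
    if a.n < 2:
        raise InsufficientDataError("nucleotide diversity needs n >= 2")
    k_bar = mean_pairwise_differences(a)
    n, L = a.n, a.L
    pi = k_bar / L
    v = ((n + 1) / (3.0 * (n - 1) * L)) * pi + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return pi, math.sqrt(max(v, 0.0)), k_bar


def diversity_result(a: Alignment) -> DiversityResult:
    """Combined diversity summary of an (already subset) alignment."""
    distinct = len(set(a.row_strings()))
    hap_counts: dict[str, int] = {}
    for s in a.row_strings():
        hap_counts[s] = hap_counts.get(s, 0) + 1
    h, h_sd = gene_diversity(list(hap_counts.values()))
    pi, pi_sd, k_bar = nucleotide_diversity(a)
    return DiversityResult(n=a.n, n_h=distinct, h=h, h_sd=h_sd,
                           pi=pi, pi_sd=pi_sd, k_bar=k_bar)
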