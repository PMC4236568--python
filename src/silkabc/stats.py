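"""Summary and diagnostic statistics: pi, S, Watterson's theta, Tajima's D.

The same functions serve simulated 0/1 haplotype matrices and real
nucleotide alignments (restricted to silent sites by the caller), so
simulated and observed summary statistics are computed identically.

Missing data follow pairwise deletion: a pair of sequences is compared
over the sites where both are called, and a column counts as segregating
when it shows at least two distinct non-missing states.  ``-``, ``N``,
``n`` and ``?`` are treated as missing in nucleotide data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SummaryStatVector",
    "pairwise_pi",
    "segregating_sites",
    "watterson_theta",
    "tajimas_d",
    "harmonic_number",
    "summarize_loci",
    "silent_site_projection",
    "locus_stats",
]

_MISSING = frozenset("-Nn?")

STAT_NAMES = ("s_dom", "s_wild", "pi_dom", "pi_wild")


@dataclass(frozen=True)
class SummaryStatVector:
    """Across-locus mean S and pi, separately for each population."""

    s_dom: float
    s_wild: float
    pi_dom: float
    pi_wild: float
    n_loci: int
    per_locus: np.ndarray | None = None  # (n_loci, 4), columns STAT_NAMES

    def as_array(self) -> np.ndarray:
        return np.array([self.s_dom, self.s_wild, self.pi_dom, self.pi_wild])


def _as_matrix(seqs) -> np.ndarray:
    """Coerce sequences or a matrix to a 2-D array of site states."""
    if isinstance(seqs, np.ndarray):
        if seqs.ndim != 2:
            raise ValueError("matrix input must be 2-dimensional")
        return seqs
    rows = [str(getattr(s, "seq", s)) for s in seqs]
    if len(rows) == 0:
        return np.empty((0, 0), dtype="<U1")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("sequences have unequal lengths")
    return np.array([list(r) for r in rows], dtype="<U1")


def _missing_mask(m: np.ndarray) -> np.ndarray:
    if m.dtype.kind in "iub":
        return np.zeros(m.shape, dtype=bool)
    return np.isin(m, list(_MISSING))


def pairwise_pi(seqs) -> float:
    """Mean number of pairwise differences over all unordered pairs.

    Accepts aligned nucleotide sequences (strings or Biopython records)
    or a samples x sites 0/1 matrix.  Pairs are compared over mutually
    non-missing sites (pairwise deletion).
    """
    m = _as_matrix(seqs)
    n = m.shape[0]
    if n < 2:
        raise ValueError("pairwise_pi needs at least 2 sequences")
    miss = _missing_mask(m)
    total = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            ok = ~(miss[i] | miss[j])
            total += np.count_nonzero(m[i, ok] != m[j, ok])
    return total / (n * (n - 1) / 2)


def segregating_sites(seqs) -> int:
    """Number of columns with >= 2 distinct non-missing states."""
    m = _as_matrix(seqs)
    if m.shape[0] < 2:
        raise ValueError("segregating_sites needs at least 2 sequences")
    miss = _missing_mask(m)
    count = 0
    for c in range(m.shape[1]):
        col = m[~miss[:, c], c]
        if col.size >= 2 and np.unique(col).size >= 2:
            count += 1
    return count


def harmonic_number(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i (0 for k <= 0)."""
    return sum(1.0 / i for i in range(1, k + 1))


def watterson_theta(s: float, n: int) -> float:
    """Watterson's estimator S / a_{n-1} for a sample of size n."""
    if n < 2:
        raise ValueError("watterson_theta needs n >= 2")
    if s < 0:
        raise ValueError("negative segregating-site count")
    return s / harmonic_number(n - 1)


def tajimas_d(s: float, pi: float, n: int) -> float:
    """Tajima's D from S, pi and the sample size.

    Returns ``nan`` when S = 0 (the variance term vanishes and the
    statistic is undefined).  Constants follow Tajima (1989).
    """
    if n < 2:
        raise ValueError("tajimas_d needs n >= 2")
    if s == 0:
        return math.nan
    a1 = harmonic_number(n - 1)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def summarize_loci(per_locus) -> SummaryStatVector:
    """Aggregate per-locus (S_dom, S_wild, pi_dom, pi_wild) rows.

    The summary is the arithmetic mean of each statistic across loci,
    one value per population; the per-locus table is retained for
    callers that prefer unaggregated vectors.
    """
    arr = np.asarray(per_locus, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("expected an (n_loci, 4) array of per-locus stats")
    if arr.shape[0] == 0:
        raise ValueError("no loci to summarize")
    mean = arr.mean(axis=0)
    return SummaryStatVector(
        s_dom=float(mean[0]), s_wild=float(mean[1]),
        pi_dom=float(mean[2]), pi_wild=float(mean[3]),
        n_loci=arr.shape[0], per_locus=arr,
    )


def silent_site_projection(seqs, site_mask) -> np.ndarray:
    """Restrict an alignment to the columns flagged silent in the mask."""
    m = _as_matrix(seqs)
    mask = np.asarray(site_mask, dtype=bool)
    if mask.ndim != 1 or mask.size != m.shape[1]:
        raise ValueError(
            f"mask length {mask.size} does not match alignment length "
            f"{m.shape[1]}")
    return m[:, mask]


def locus_stats(dom_seqs, wild_seqs) -> tuple[float, float, float, float]:
    """(S_dom, S_wild, pi_dom, pi_wild) for one locus, two populations."""
    return (
        float(segregating_sites(dom_seqs)),
        float(segregating_sites(wild_seqs)),
        pairwise_pi(dom_seqs),
        pairwise_pi(wild_seqs),
    )
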