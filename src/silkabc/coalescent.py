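"""Backward-in-time coalescent simulation over a compiled demography.

This is the simulation engine behind every ABC step: it realizes
genealogies under the piecewise two-population histories of
:mod:`silkabc.models`, drops infinite-sites mutations, and reduces each
locus to the per-population summary statistics (S, pi).

All waiting times are exact exponential draws; epoch boundaries are
handled by re-drawing under the new rates (valid by memorylessness of
the exponential).  There is no recombination within a locus and loci
are independent, matching the multi-locus study design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .models import DemographySpec
from .stats import SummaryStatVector, summarize_loci

__all__ = [
    "SampleConfig",
    "Genealogy",
    "HaplotypeMatrix",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_dataset",
    "epoch_arrays",
]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class SampleConfig:
    """Haploid sample sizes and locus layout for one simulated dataset."""

    n_dom: int
    n_wild: int
    n_loci: int = 1
    locus_length: int = 600

    def __post_init__(self):
        if self.n_dom < 0 or self.n_wild < 0 or self.n_dom + self.n_wild < 2:
            raise ValueError("need at least 2 sampled lineages in total")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")

    @property
    def n_total(self) -> int:
        return self.n_dom + self.n_wild


@dataclass(frozen=True)
class Genealogy:
    """A realized coalescent tree for one locus.

    Leaves are nodes ``0 .. n-1`` (dom samples first, then wild);
    internal nodes are numbered in increasing coalescence-time order.
    ``parent`` is -1 at the root; ``population`` records where each node
    was created (0=dom, 1=wild; the ancestral population is 0).
    """

    parent: np.ndarray
    time: np.ndarray
    population: np.ndarray
    lchild: np.ndarray
    rchild: np.ndarray
    n_dom: int
    n_wild: int

    @property
    def n_leaves(self) -> int:
        return self.n_dom + self.n_wild

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        out = np.zeros_like(self.time)
        has_parent = self.parent >= 0
        out[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return out

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_sets(self) -> list[np.ndarray]:
        """Leaf indices below each node (children precede parents)."""
        sets: list[np.ndarray] = []
        for v in range(len(self.parent)):
            if v < self.n_leaves:
                sets.append(np.array([v]))
            else:
                sets.append(np.concatenate(
                    [sets[self.lchild[v]], sets[self.rchild[v]]]))
        return sets


@dataclass(frozen=True)
class HaplotypeMatrix:
    """0/1 haplotypes (samples x segregating sites) under infinite sites.

    ``positions`` are continuous site positions in (0, 1); they carry no
    information for S or pi and exist so loci can be written out as
    sequences or ms-format blocks.
    """

    matrix: np.ndarray
    positions: np.ndarray
    n_dom: int
    n_wild: int
    locus_id: int = 0

    def __post_init__(self):
        if self.matrix.shape[0] != self.n_dom + self.n_wild:
            raise ValueError("row count does not match sample sizes")
        if self.matrix.shape[1] != self.positions.size:
            raise ValueError("column count does not match positions")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def dom_rows(self) -> np.ndarray:
        return self.matrix[: self.n_dom]

    def wild_rows(self) -> np.ndarray:
        return self.matrix[self.n_dom:]


def epoch_arrays(spec: DemographySpec):
    """Flatten a compiled demography into the kernel's epoch arrays."""
    starts = np.array([e.start for e in spec.epochs])
    size_dom = np.array([e.size_dom for e in spec.epochs])
    size_wild = np.array([e.size_wild for e in spec.epochs])
    m_dom = np.array([e.m_dom for e in spec.epochs])
    m_wild = np.array([e.m_wild for e in spec.epochs])
    if np.any(size_dom <= 0) or np.any(size_wild <= 0):
        raise ValueError("zero-size epoch in demography")
    return starts, size_dom, size_wild, m_dom, m_wild


def _locus_seeds(rng_seed: int, n_loci: int) -> np.ndarray:
    """Deterministic per-locus substreams from one master seed.

    Locus i's seed depends only on (rng_seed, i), so increasing the
    locus count never perturbs earlier loci.
    """
    ss = np.random.SeedSequence(rng_seed)
    state = ss.generate_state(n_loci, dtype=np.uint64)
    return (state % _SEED_MOD).astype(np.int64)


def simulate_genealogy(spec: DemographySpec, sc: SampleConfig,
                       rng_seed: int) -> Genealogy:
    """Simulate one genealogy for a single locus."""
    starts, sd, sw, md, mw = epoch_arrays(spec)
    seed = int(_locus_seeds(rng_seed, 1)[0])
    parent, time, popl, lc, rc = _kernels.simulate_genealogy_arrays(
        sc.n_dom, sc.n_wild, starts, sd, sw, md, mw, seed)
    return Genealogy(parent=parent, time=time, population=popl,
                     lchild=lc, rchild=rc,
                     n_dom=sc.n_dom, n_wild=sc.n_wild)


def drop_mutations(g: Genealogy, theta_locus: float,
                   rng_seed: int) -> HaplotypeMatrix:
    """Poisson infinite-sites mutations on a fixed genealogy.

    The mutation count is Poisson(theta_locus * L_total), with branch
    lengths in units of 4*N1 generations (this is what makes E[pi]
    equal theta in a constant-size population); each
    mutation lands on a branch with probability proportional to its
    length, at a fresh uniform position.
    """
    if theta_locus < 0:
        raise ValueError("theta_locus must be >= 0")
    rng = np.random.default_rng(rng_seed)
    blen = g.branch_lengths()
    total = blen.sum()
    k = int(rng.poisson(theta_locus * total)) if total > 0 else 0
    n = g.n_leaves
    if k == 0:
        return HaplotypeMatrix(np.zeros((n, 0), dtype=np.uint8),
                               np.empty(0), g.n_dom, g.n_wild)
    branches = rng.choice(len(blen), size=k, p=blen / total)
    positions = rng.random(k)
    order = np.argsort(positions)
    branches = branches[order]
    positions = positions[order]
    sets = g.leaf_sets()
    mat = np.zeros((n, k), dtype=np.uint8)
    for col, b in enumerate(branches):
        mat[sets[b], col] = 1
    return HaplotypeMatrix(mat, positions, g.n_dom, g.n_wild)


def simulate_dataset(spec: DemographySpec, sc: SampleConfig,
                     theta1_per_site: float, rng_seed: int,
                     locus_lengths=None, n_dom_per_locus=None,
                     n_wild_per_locus=None) -> SummaryStatVector:
    """Simulate a multi-locus dataset, reduced to summary statistics.

    Each locus gets an independent genealogy and mutations at per-locus
    theta = theta1_per_site * locus_length; the result aggregates S and
    pi per population across loci.  Per-locus sample sizes and lengths
    default to the constant values in ``sc`` but may be overridden to
    mirror a real study design.  Deterministic given ``rng_seed``.
    """
    if theta1_per_site < 0:
        raise ValueError("theta1_per_site must be >= 0")
    starts, sd, sw, md, mw = epoch_arrays(spec)

    def _per_locus(value, override, name):
        if override is None:
            return np.full(sc.n_loci, value, dtype=np.int64)
        arr = np.asarray(override, dtype=np.int64)
        if arr.size != sc.n_loci:
            raise ValueError(f"{name} size does not match n_loci")
        return arr

    n_dom = _per_locus(sc.n_dom, n_dom_per_locus, "n_dom_per_locus")
    n_wild = _per_locus(sc.n_wild, n_wild_per_locus, "n_wild_per_locus")
    lengths = _per_locus(sc.locus_length, locus_lengths, "locus_lengths")
    theta_loci = theta1_per_site * lengths.astype(float)
    seeds = _locus_seeds(rng_seed, sc.n_loci)
    per_locus = _kernels.simulate_locus_stats_batch(
        n_dom, n_wild, starts, sd, sw, md, mw, theta_loci, seeds)
    return summarize_loci(per_locus)
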