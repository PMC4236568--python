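"""Synthetic multi-locus study generator and FASTA-level I/O.

The generator emulates the real study design this package targets:
29 unlinked neutral nuclear loci, each sequenced in 6-17 domesticated
strains and 7-15 wild samples, ~600 bp of silent sites per locus, with
wild per-site diversity around theta1 = 0.0312.  The default "true"
demography is the bottleneck-gene-flow history at its published
posterior-mode parameters, so a default synthetic study reproduces the
conditions of the original inference as closely as the printed values
allow.

Binary infinite-sites haplotypes are realized as nucleotides by
drawing a random background sequence per locus, assigning each
segregating site a distinct integer position and a derived base
different from the ancestral one.  S and pi computed from the FASTA
output therefore agree exactly with the generating haplotype matrices.
All synthetic sites are silent by construction.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coalescent import HaplotypeMatrix, SampleConfig, drop_mutations, simulate_genealogy
from .models import ScaledParameters, compile_model
from .stats import SummaryStatVector, locus_stats, summarize_loci

__all__ = [
    "DEFAULT_TRUE_PARAMS",
    "StudyDesign",
    "LocusAlignment",
    "generate_synthetic_study",
    "read_study",
    "observed_stats",
    "design_from_truth",
]

# Published posterior modes of the bottleneck-gene-flow history, with
# scaled migration rates 4*N1*m back-computed from the reported
# migrants-per-generation (N1*m) figures: wild->dom 4*107.1, dom->wild
# 4*318.6.
DEFAULT_TRUE_PARAMS = ScaledParameters(
    theta1=0.0312,
    ratio_theta2=0.146392,
    ratio_thetaA=0.98953,
    ratio_thetaB1=0.94133,
    ratio_thetaB2=0.015339,
    tauD=0.00373,
    tau1=0.0025,
    tau2=0.001992,
    mig_rate_wd=428.4,
    mig_rate_dw=1274.4,
)

_SEED_MOD = 2**31 - 1
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class StudyDesign:
    """Everything needed to regenerate a synthetic study byte-for-byte."""

    n_loci: int = 29
    dom_size_range: tuple[int, int] = (6, 17)
    wild_size_range: tuple[int, int] = (7, 15)
    locus_length: int = 600
    model_id: str = "C_at_bottleneck"
    params: ScaledParameters = DEFAULT_TRUE_PARAMS
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1 or self.locus_length < 1:
            raise ValueError("n_loci and locus_length must be positive")
        for lo, hi in (self.dom_size_range, self.wild_size_range):
            if not (0 < lo <= hi):
                raise ValueError("sample-size ranges must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class LocusAlignment:
    """One locus: population-labelled aligned nucleotide sequences."""

    name: str
    dom: list[str]
    wild: list[str]

    @property
    def length(self) -> int:
        return len(self.dom[0]) if self.dom else len(self.wild[0])


def _realize_nucleotides(hm: HaplotypeMatrix, length: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Map 0/1 haplotypes onto nucleotide rows of the given length."""
    k = hm.n_sites
    if k > length:
        raise ValueError(
            f"{k} segregating sites exceed the locus length {length}")
    background = rng.choice(_BASES, size=length)
    sites = np.sort(rng.choice(length, size=k, replace=False))
    seqs = np.tile(background, (hm.matrix.shape[0], 1))
    for col, site in enumerate(sites):
        anc = background[site]
        derived = rng.choice(_BASES[_BASES != anc])
        seqs[hm.matrix[:, col] == 1, site] = derived
    return seqs


def generate_synthetic_study(design: StudyDesign, out_dir=None
                             ) -> tuple[list[LocusAlignment], dict]:
    """Simulate a study and (optionally) write per-locus FASTA files.

    Returns the loci and a truth record (JSON-serializable) holding the
    exact parameters, model, seeds and per-locus layout; rebuilding the
    design from the record and rerunning regenerates identical files.
    """
    spec = compile_model(design.params, design.model_id)
    master = np.random.default_rng(design.seed)
    loci: list[LocusAlignment] = []
    locus_records = []
    for i in range(design.n_loci):
        n_dom = int(master.integers(design.dom_size_range[0],
                                    design.dom_size_range[1] + 1))
        n_wild = int(master.integers(design.wild_size_range[0],
                                     design.wild_size_range[1] + 1))
        tree_seed, mut_seed, nuc_seed = (
            int(s) for s in master.integers(_SEED_MOD, size=3))
        sc = SampleConfig(n_dom=n_dom, n_wild=n_wild,
                          locus_length=design.locus_length)
        g = simulate_genealogy(spec, sc, tree_seed)
        hm = drop_mutations(g, design.params.theta1 * design.locus_length,
                            mut_seed)
        seqs = _realize_nucleotides(hm, design.locus_length,
                                    np.random.default_rng(nuc_seed))
        rows = ["".join(r) for r in seqs]
        name = f"locus_{i + 1:02d}"
        loci.append(LocusAlignment(name=name, dom=rows[:n_dom],
                                   wild=rows[n_dom:]))
        locus_records.append({
            "name": name, "n_dom": n_dom, "n_wild": n_wild,
            "length": design.locus_length, "tree_seed": tree_seed,
            "mutation_seed": mut_seed, "nucleotide_seed": nuc_seed,
        })
    truth = {
        "model_id": design.model_id,
        "params": asdict(design.params),
        "seed": design.seed,
        "n_loci": design.n_loci,
        "dom_size_range": list(design.dom_size_range),
        "wild_size_range": list(design.wild_size_range),
        "locus_length": design.locus_length,
        "loci": locus_records,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for locus in loci:
            records = [
                SeqRecord(Seq(s), id=f"dom_{j + 1}", description="")
                for j, s in enumerate(locus.dom)
            ] + [
                SeqRecord(Seq(s), id=f"wild_{j + 1}", description="")
                for j, s in enumerate(locus.wild)
            ]
            SeqIO.write(records, out_dir / f"{locus.name}.fasta", "fasta")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return loci, truth


def design_from_truth(truth: dict) -> StudyDesign:
    """Reconstruct the generating design from a truth record."""
    return StudyDesign(
        n_loci=truth["n_loci"],
        dom_size_range=tuple(truth["dom_size_range"]),
        wild_size_range=tuple(truth["wild_size_range"]),
        locus_length=truth["locus_length"],
        model_id=truth["model_id"],
        params=ScaledParameters(**truth["params"]),
        seed=truth["seed"],
    )


def read_study(directory, label_pattern: str = r"^(?P<pop>dom|wild)"
               ) -> list[LocusAlignment]:
    """Load per-locus FASTA alignments with population labels.

    Every record id must match ``label_pattern``, whose ``pop`` group
    (or first group) must read ``dom`` or ``wild``.  Sequences within a
    locus must be aligned (equal lengths).
    """
    directory = Path(directory)
    pattern = re.compile(label_pattern)
    paths = sorted(directory.glob("*.fasta")) + sorted(directory.glob("*.fa"))
    if not paths:
        raise FileNotFoundError(f"no loci found in {directory}")
    loci = []
    for path in paths:
        dom, wild = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            m = pattern.search(rec.id)
            if not m:
                raise ValueError(
                    f"record {rec.id!r} in {path.name} does not match the "
                    f"population label pattern {label_pattern!r}")
            pop = m.groupdict().get("pop") or m.group(1)
            if pop == "dom":
                dom.append(str(rec.seq))
            elif pop == "wild":
                wild.append(str(rec.seq))
            else:
                raise ValueError(f"unknown population label {pop!r} for "
                                 f"record {rec.id!r}")
        lengths = {len(s) for s in dom + wild}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths in {path.name}")
        loci.append(LocusAlignment(name=path.stem, dom=dom, wild=wild))
    return loci


def observed_stats(loci: list[LocusAlignment]) -> SummaryStatVector:
    """Per-population S and pi, averaged across loci."""
    per_locus = [locus_stats(l.dom, l.wild) for l in loci]
    return summarize_loci(per_locus)
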