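"""Read and write Hudson ms-style simulation output.

The format is line-oriented: a command line and RNG seeds, then one
``//`` block per replicate with ``segsites:``, ``positions:`` and one
0/1 haplotype row per sample.  It is the lingua franca for coalescent
simulators, so the writer lets external tools consume this package's
simulations and the reader lets an external simulator's output be
imported for cross-checks.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

__all__ = ["write_ms", "read_ms"]


def write_ms(loci, out, command: str = "silkabc", seeds=(1, 2, 3)) -> None:
    """Write HaplotypeMatrix-like loci (``.matrix``, ``.positions``) or
    (positions, matrix) pairs as an ms-format stream."""
    own = isinstance(out, (str, Path))
    handle = open(out, "w") if own else out
    try:
        handle.write(command + "\n")
        handle.write(" ".join(str(s) for s in seeds) + "\n")
        for locus in loci:
            if hasattr(locus, "matrix"):
                positions, matrix = locus.positions, locus.matrix
            else:
                positions, matrix = locus
            handle.write("\n//\n")
            handle.write(f"segsites: {matrix.shape[1]}\n")
            if matrix.shape[1]:
                handle.write("positions: " +
                             " ".join(f"{p:.5f}" for p in positions) + "\n")
                for row in matrix:
                    handle.write("".join(str(int(x)) for x in row) + "\n")
    finally:
        if own:
            handle.close()


def read_ms(source) -> list[tuple[np.ndarray, np.ndarray]]:
    """Parse ms-format output into (positions, 0/1 matrix) per replicate."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    blocks = text.split("//")
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for block in blocks[1:]:
        lines = [ln.strip() for ln in block.splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("segsites:"):
            raise ValueError("malformed ms block: missing segsites line")
        segsites = int(lines[0].split(":")[1])
        if segsites == 0:
            out.append((np.empty(0), np.zeros((0, 0), dtype=np.uint8)))
            continue
        if not lines[1].startswith("positions:"):
            raise ValueError("malformed ms block: missing positions line")
        positions = np.array([float(x) for x in lines[1].split()[1:]])
        if positions.size != segsites:
            raise ValueError("positions count does not match segsites")
        rows = [np.frombuffer(ln.encode(), dtype=np.uint8) - ord("0")
                for ln in lines[2:]]
        matrix = np.vstack(rows).astype(np.uint8)
        if matrix.shape[1] != segsites:
            raise ValueError("haplotype row length does not match segsites")
        if matrix.max(initial=0) > 1:
            raise ValueError("non-binary haplotype characters")
        out.append((positions, matrix))
    return out
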