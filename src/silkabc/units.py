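"""Conversion between scaled coalescent parameters and natural units.

Scaled quantities (theta = 4*Ne*mu per site, sizes relative to N1,
times in 4*N1 generations) are mapped to effective sizes and calendar
years.  N1, the modern wild effective size, is not estimated here; it
is derived from a (theta1, mu) pair or supplied in the context.  The
silkworm is univoltine-to-multivoltine but the published chronology is
consistent with one generation per year, the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ConversionContext",
    "theta_to_ne",
    "ratio_to_ne",
    "tau_to_years",
    "implied_n1",
    "conversion_table",
]


@dataclass(frozen=True)
class ConversionContext:
    """Constants needed to leave coalescent scaling.

    ``mu`` is the per-site per-generation mutation rate; ``n1`` the
    reference (modern wild) effective size; ``generations_per_year``
    converts coalescent time to calendar time.
    """

    mu: float = 1.56e-8
    n1: float = 500_000.0
    generations_per_year: float = 1.0

    def __post_init__(self):
        if self.mu <= 0 or self.n1 <= 0 or self.generations_per_year <= 0:
            raise ValueError("all conversion constants must be positive")


def theta_to_ne(theta_per_site: float, mu: float) -> float:
    """Effective size from theta = 4*Ne*mu."""
    if theta_per_site <= 0 or mu <= 0:
        raise ValueError("theta and mu must be positive")
    return theta_per_site / (4.0 * mu)


def ratio_to_ne(size_ratio: float, n1: float) -> int:
    """Effective size of a population given as a ratio to N1.

    Reported as the integer part (truncation toward zero), the
    convention used for the published size estimates; keep the float
    ``size_ratio * n1`` when exactness matters.
    """
    if size_ratio <= 0 or n1 <= 0:
        raise ValueError("size_ratio and n1 must be positive")
    return math.trunc(size_ratio * n1)


def tau_to_years(tau: float, n1: float, generations_per_year: float = 1.0) -> float:
    """Calendar years for a time in units of 4*N1 generations."""
    if n1 <= 0 or generations_per_year <= 0:
        raise ValueError("n1 and generations_per_year must be positive")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return tau * 4.0 * n1 / generations_per_year


def implied_n1(t_years: float, tau: float, generations_per_year: float = 1.0) -> float:
    """N1 consistent with a printed (years, scaled time) pair.

    The inverse of :func:`tau_to_years`; applying it to two independent
    pairs is a cheap internal-consistency check on a published table.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if generations_per_year <= 0:
        raise ValueError("generations_per_year must be positive")
    return t_years * generations_per_year / (4.0 * tau)


def conversion_table(scaled: dict[str, float], ctx: ConversionContext) -> pd.DataFrame:
    """Natural-unit table for a set of scaled parameter values.

    Size ratios (``ratio_*``) become effective sizes, times (``tau*``)
    become years, and ``theta1`` becomes the reference size N1 itself.
    """
    rows = []
    for name, value in scaled.items():
        if name.startswith("ratio_"):
            natural = ratio_to_ne(value, ctx.n1)
            unit = "individuals (Ne)"
        elif name.startswith("tau"):
            natural = tau_to_years(value, ctx.n1, ctx.generations_per_year)
            unit = "years before present"
        elif name == "theta1":
            natural = theta_to_ne(value, ctx.mu)
            unit = "individuals (Ne, from theta=4*Ne*mu)"
        else:
            natural = value
            unit = "(unchanged)"
        rows.append({"parameter": name, "scaled": value,
                     "natural": natural, "unit": unit})
    return pd.DataFrame(rows)
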