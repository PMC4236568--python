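"""Two-population domestication demographies in ms-style coalescent scaling.

The histories describe a domesticated population (``dom``, *Bombyx mori*)
and its wild progenitor (``wild``, *B. mandarina*).  Backward in time, both
populations pass through a bottleneck after their recoveries (at ``tau2``
for dom, ``tau1`` for wild) and merge into a single ancestral population at
the domestication split ``tauD``.  The four scenarios differ only in when
lineages may migrate between the two daughter populations:

* ``A_no_flow``        -- never
* ``B_continuous``     -- on the whole interval (0, tauD)
* ``C_at_bottleneck``  -- during the domestication bottleneck (tau2, tauD)
* ``D_after_bottleneck`` -- after the bottleneck ended, i.e. on (0, tau2)

Three direction variants of the bottleneck-gene-flow scenario restrict
migration to one forward-time direction (``DIR_d_to_w``, ``DIR_w_to_d``)
or keep both (``DIR_bi``).

Scaling conventions (Hudson's ms):

* time in units of 4*N1 generations, where N1 is the modern wild
  effective size (the reference population);
* population sizes relative to N1 (the modern wild size is 1.0);
* migration rates M = 4*N1*m, where m is the per-generation fraction of
  the recipient population replaced by migrants.

Direction names refer to *forward-time* gene flow.  Backward in time a
forward flow wild->dom moves sampled dom lineages into the wild
population, so ``mig_rate_wd`` is the backward movement rate of lineages
currently in dom, and ``mig_rate_dw`` the rate for lineages in wild.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "MODEL_IDS",
    "DIRECTION_IDS",
    "ScaledParameters",
    "Epoch",
    "DemographySpec",
    "validate_parameters",
    "compile_model",
    "direction_variant",
]

MODEL_IDS = ("A_no_flow", "B_continuous", "C_at_bottleneck", "D_after_bottleneck")
DIRECTION_IDS = ("DIR_bi", "DIR_d_to_w", "DIR_w_to_d")


@dataclass(frozen=True)
class ScaledParameters:
    """The eight demographic parameters plus scaled migration rates.

    ``theta1`` is the per-site population mutation rate 4*N1*mu of the
    modern wild population; all sizes are ratios to N1 and all times are
    in units of 4*N1 generations, counted backward from the present.
    """

    theta1: float
    ratio_theta2: float
    ratio_thetaA: float
    ratio_thetaB1: float
    ratio_thetaB2: float
    tauD: float
    tau1: float
    tau2: float
    mig_rate_wd: float = 0.0  # forward wild -> dom, scaled 4*N1*m
    mig_rate_dw: float = 0.0  # forward dom -> wild


@dataclass(frozen=True)
class Epoch:
    """One constant-rate interval of backward time.

    ``m_dom`` / ``m_wild`` are the backward per-lineage movement rates of
    lineages currently in the dom / wild population (units 1 / 4*N1
    generations).  In the ancestral epoch both sizes equal the ancestral
    relative size and migration is zero.
    """

    start: float
    end: float
    size_dom: float
    size_wild: float
    m_dom: float = 0.0
    m_wild: float = 0.0
    ancestral: bool = False

    @property
    def span(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class DemographySpec:
    """A fully resolved piecewise-constant two-population history."""

    model_id: str
    params: ScaledParameters
    epochs: tuple[Epoch, ...]
    split_time: float

    def migration_window(self) -> tuple[float, float] | None:
        """Interval on which any migration is active, or None."""
        active = [e for e in self.epochs if e.m_dom > 0 or e.m_wild > 0]
        if not active:
            return None
        return (min(e.start for e in active), max(e.end for e in active))

    def to_table(self) -> str:
        """Plain-text epoch table (one row per epoch)."""
        lines = ["start\tend\tsize_dom\tsize_wild\tm_dom\tm_wild\tancestral"]
        for e in self.epochs:
            end = "inf" if math.isinf(e.end) else f"{e.end:.6g}"
            lines.append(
                f"{e.start:.6g}\t{end}\t{e.size_dom:.6g}\t{e.size_wild:.6g}"
                f"\t{e.m_dom:.6g}\t{e.m_wild:.6g}\t{int(e.ancestral)}"
            )
        return "\n".join(lines)

    def to_ms_command(self, n_dom: int, n_wild: int, theta_locus: float,
                      n_reps: int = 1) -> str:
        """Equivalent ``ms`` invocation (population 1 = dom, 2 = wild).

        Useful for cross-validating against external ms-compatible
        simulators; events are emitted in increasing backward time.
        """
        p = self.params
        parts = [
            f"ms {n_dom + n_wild} {n_reps} -t {theta_locus:g}",
            f"-I 2 {n_dom} {n_wild}",
            f"-n 1 {p.ratio_theta2:g} -n 2 1.0",
        ]
        first = self.epochs[0]
        # backward movement of lineages in pop i at rate M_ij = ms -m i j
        if first.m_dom > 0:
            parts.append(f"-m 1 2 {first.m_dom:g}")
        if first.m_wild > 0:
            parts.append(f"-m 2 1 {first.m_wild:g}")
        prev = first
        for e in self.epochs[1:]:
            t = e.start
            if e.ancestral:
                parts.append(f"-ej {t:g} 1 2 -en {t:g} 2 {e.size_dom:g}")
                break
            if e.size_dom != prev.size_dom:
                parts.append(f"-en {t:g} 1 {e.size_dom:g}")
            if e.size_wild != prev.size_wild:
                parts.append(f"-en {t:g} 2 {e.size_wild:g}")
            if e.m_dom != prev.m_dom:
                parts.append(f"-em {t:g} 1 2 {e.m_dom:g}")
            if e.m_wild != prev.m_wild:
                parts.append(f"-em {t:g} 2 1 {e.m_wild:g}")
            prev = e
        return " ".join(parts)


def validate_parameters(p: ScaledParameters, model_id: str) -> list[str]:
    """Return every violated invariant; an empty list means compilable.

    Validation never raises: :func:`compile_model` is the operation that
    refuses invalid input.
    """
    v: list[str] = []
    if model_id not in MODEL_IDS and model_id not in DIRECTION_IDS:
        v.append(f"unknown model id {model_id!r}")
    for name in ("theta1", "ratio_theta2", "ratio_thetaA",
                 "ratio_thetaB1", "ratio_thetaB2"):
        val = getattr(p, name)
        if not (val > 0) or not math.isfinite(val):
            v.append(f"non-positive size: {name}={val}")
    for name in ("tauD", "tau1", "tau2"):
        val = getattr(p, name)
        if not (val > 0) or not math.isfinite(val):
            v.append(f"non-positive time: {name}={val}")
    if p.tau1 >= p.tauD:
        v.append(f"recovery predates split: tau1={p.tau1} >= tauD={p.tauD}")
    if p.tau2 >= p.tauD:
        v.append(f"recovery predates split: tau2={p.tau2} >= tauD={p.tauD}")
    if p.mig_rate_wd < 0 or p.mig_rate_dw < 0:
        v.append("negative migration rate")
    if model_id == "A_no_flow" and (p.mig_rate_wd > 0 or p.mig_rate_dw > 0):
        v.append("model A admits no migration but a rate is nonzero")
    if model_id in ("DIR_d_to_w", "DIR_w_to_d", "DIR_bi") \
            and p.mig_rate_wd == 0 and p.mig_rate_dw == 0:
        v.append("direction variant requires a nonzero migration rate")
    return v


def _c_window(p: ScaledParameters, rule: str) -> tuple[float, float]:
    # bottleneck gene-flow window; the domestication bottleneck ends at tau2
    if rule == "tau2":
        return (p.tau2, p.tauD)
    if rule == "tau1":
        return (p.tau1, p.tauD)
    if rule == "min":
        return (min(p.tau1, p.tau2), p.tauD)
    if rule == "max":
        return (max(p.tau1, p.tau2), p.tauD)
    raise ValueError(f"unknown bottleneck-window rule {rule!r}")


def compile_model(p: ScaledParameters, model_id: str,
                  c_window: str = "tau2") -> DemographySpec:
    """Compile parameters into an executable piecewise history.

    ``c_window`` selects when bottleneck-restricted gene flow stops being
    active (going backward): by default at the end of the domestication
    bottleneck (``tau2``); alternatives tie it to the wild recovery
    (``"tau1"``) or to the min/max of the two.

    Raises ``ValueError`` when :func:`validate_parameters` reports
    violations.
    """
    violations = validate_parameters(p, model_id)
    if violations:
        raise ValueError("invalid parameters: " + "; ".join(violations))

    if model_id == "A_no_flow":
        window = None
    elif model_id == "B_continuous":
        window = (0.0, p.tauD)
    elif model_id in ("C_at_bottleneck",) + DIRECTION_IDS:
        window = _c_window(p, c_window)
    elif model_id == "D_after_bottleneck":
        window = (0.0, p.tau2)
    else:  # pragma: no cover - guarded by validation
        raise ValueError(f"unknown model id {model_id!r}")

    m_dom = p.mig_rate_wd  # backward: dom lineage came from wild
    m_wild = p.mig_rate_dw
    if model_id == "DIR_d_to_w":
        m_dom = 0.0
    elif model_id == "DIR_w_to_d":
        m_wild = 0.0

    bounds = sorted({0.0, p.tau1, p.tau2, p.tauD})
    epochs: list[Epoch] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        size_dom = p.ratio_theta2 if hi <= p.tau2 else p.ratio_thetaB2
        size_wild = 1.0 if hi <= p.tau1 else p.ratio_thetaB1
        mid = 0.5 * (lo + hi)
        active = window is not None and window[0] < mid < window[1]
        epochs.append(Epoch(
            start=lo, end=hi, size_dom=size_dom, size_wild=size_wild,
            m_dom=m_dom if active else 0.0,
            m_wild=m_wild if active else 0.0,
        ))
    epochs.append(Epoch(
        start=p.tauD, end=math.inf,
        size_dom=p.ratio_thetaA, size_wild=p.ratio_thetaA,
        ancestral=True,
    ))
    return DemographySpec(model_id=model_id, params=p,
                          epochs=tuple(epochs), split_time=p.tauD)


def direction_variant(p: ScaledParameters, direction: str,
                      c_window: str = "tau2") -> DemographySpec:
    """Compile one of the three gene-flow-direction variants.

    The base history is the bottleneck-gene-flow scenario; ``direction``
    keeps both rates (``DIR_bi``) or zeroes the one that is absent.
    Direction names are forward-time.  Raises if the retained rate(s) of a
    one-way variant are zero.
    """
    if direction not in DIRECTION_IDS:
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "DIR_d_to_w":
        p = replace(p, mig_rate_wd=0.0)
        if p.mig_rate_dw == 0:
            raise ValueError("DIR_d_to_w requires mig_rate_dw > 0")
    elif direction == "DIR_w_to_d":
        p = replace(p, mig_rate_dw=0.0)
        if p.mig_rate_wd == 0:
            raise ValueError("DIR_w_to_d requires mig_rate_wd > 0")
    elif p.mig_rate_wd == 0 and p.mig_rate_dw == 0:
        raise ValueError("DIR_bi requires a nonzero migration rate")
    return compile_model(p, direction, c_window=c_window)
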