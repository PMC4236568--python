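"""Rejection-regression approximate Bayesian computation.

The workflow mirrors the classic multi-locus ABC recipe:

1. draw parameter vectors from their priors;
2. simulate a dataset under each draw and reduce it to the summary
   statistics (per-population mean S and pi across loci);
3. keep the fraction of draws whose statistics fall closest (scaled
   Euclidean distance) to the observed statistics;
4. adjust the accepted draws by weighted local-linear regression of the
   (log) parameters on the statistics, with Epanechnikov weights over
   distance (Beaumont-style rejection-regression);
5. summarize the adjusted, weighted sample by its KDE mode and the
   equal-tailed 95% interval.

Statistic columns are scaled by their median absolute deviation over
the reference table before distances are computed, which makes the
accepted set invariant to the units of any one statistic.  Parameters
are log-transformed for the regression (they are all strictly positive)
and back-transformed afterwards, which also keeps adjusted draws inside
the positive orthant.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, median_abs_deviation

from .coalescent import SampleConfig, simulate_dataset
from .models import ScaledParameters, compile_model, validate_parameters
from .stats import STAT_NAMES, SummaryStatVector

__all__ = [
    "Prior",
    "PriorSpec",
    "ReferenceTable",
    "RejectionResult",
    "PosteriorSample",
    "model_param_names",
    "default_priors",
    "draw_priors",
    "build_reference_table",
    "rejection_sample",
    "regression_adjust",
    "posterior_summary",
    "weighted_quantile",
]

log = logging.getLogger("silkabc")

BASE_PARAM_NAMES = (
    "theta1", "ratio_theta2", "ratio_thetaA", "ratio_thetaB1",
    "ratio_thetaB2", "tauD", "tau1", "tau2",
)

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class Prior:
    """A uniform or log-uniform prior on one scalar parameter."""

    family: str
    low: float
    high: float

    def __post_init__(self):
        if self.family not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError("prior bounds must be finite")
        if not self.low < self.high:
            raise ValueError("prior requires low < high")
        if self.family == "loguniform" and self.low <= 0:
            raise ValueError("log-uniform prior requires low > 0")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        return np.exp(rng.uniform(np.log(self.low), np.log(self.high), size=n))

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x)
        return (x >= self.low) & (x <= self.high)


@dataclass(frozen=True)
class PriorSpec:
    """Ordered per-parameter priors for one demographic model."""

    priors: dict[str, Prior]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.priors)

    def replace(self, **overrides: Prior) -> "PriorSpec":
        new = dict(self.priors)
        for name, prior in overrides.items():
            if name not in new:
                raise KeyError(f"{name!r} is not a parameter of this spec")
            new[name] = prior
        return PriorSpec(new)


def model_param_names(model_id: str) -> tuple[str, ...]:
    """Free parameters of a model (schema of its reference table)."""
    if model_id == "A_no_flow":
        return BASE_PARAM_NAMES
    if model_id == "DIR_d_to_w":
        return BASE_PARAM_NAMES + ("mig_rate_dw",)
    if model_id == "DIR_w_to_d":
        return BASE_PARAM_NAMES + ("mig_rate_wd",)
    return BASE_PARAM_NAMES + ("mig_rate_wd", "mig_rate_dw")


def default_priors(model_id: str) -> PriorSpec:
    """Broad defaults: log-uniform times on (1e-4, 0.1), log-uniform
    size ratios on (1e-3, 10), uniform per-site theta1 on (0.001, 0.1),
    log-uniform scaled migration rates on (0.1, 1e3).

    These are deliberately wide enough to contain the published
    posterior intervals and are meant to be overridden from config for
    any serious analysis.
    """
    table = {
        "theta1": Prior("uniform", 0.001, 0.1),
        "ratio_theta2": Prior("loguniform", 1e-3, 10.0),
        "ratio_thetaA": Prior("loguniform", 1e-3, 10.0),
        "ratio_thetaB1": Prior("loguniform", 1e-3, 10.0),
        "ratio_thetaB2": Prior("loguniform", 1e-3, 10.0),
        "tauD": Prior("loguniform", 1e-4, 0.1),
        "tau1": Prior("loguniform", 1e-4, 0.1),
        "tau2": Prior("loguniform", 1e-4, 0.1),
        "mig_rate_wd": Prior("loguniform", 0.1, 1e3),
        "mig_rate_dw": Prior("loguniform", 0.1, 1e3),
    }
    return PriorSpec({name: table[name] for name in model_param_names(model_id)})


def draw_priors(ps: PriorSpec, n: int, rng_seed: int) -> pd.DataFrame:
    """n i.i.d. draws from every prior, reproducible by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    return pd.DataFrame({name: prior.draw(n, rng)
                         for name, prior in ps.priors.items()})


def params_from_row(row, model_id: str) -> ScaledParameters:
    """Build ScaledParameters from a reference-table row (mapping)."""
    kwargs = {name: float(row[name]) for name in BASE_PARAM_NAMES}
    names = model_param_names(model_id)
    for mig in ("mig_rate_wd", "mig_rate_dw"):
        kwargs[mig] = float(row[mig]) if mig in names else 0.0
    return ScaledParameters(**kwargs)


@dataclass(frozen=True)
class ReferenceTable:
    """Paired (parameter draw, simulated summary statistics) rows."""

    model_id: str
    params: pd.DataFrame
    stats: np.ndarray  # (n_rows, 4), columns STAT_NAMES
    seed: int
    n_redraws: int = 0

    @property
    def n_rows(self) -> int:
        return len(self.params)

    def save(self, path) -> None:
        """TSV of parameters+statistics, with a JSON sidecar."""
        path = Path(path)
        df = self.params.copy()
        for k, name in enumerate(STAT_NAMES):
            df[name] = self.stats[:, k]
        df.to_csv(path, sep="\t", index=False)
        sidecar = {
            "model_id": self.model_id, "seed": self.seed,
            "n_rows": self.n_rows, "n_redraws": self.n_redraws,
            "param_names": list(self.params.columns),
            "stat_names": list(STAT_NAMES), "schema_version": 1,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        df = pd.read_csv(path, sep="\t")
        stats = df[list(STAT_NAMES)].to_numpy()
        params = df[meta["param_names"]]
        return cls(model_id=meta["model_id"], params=params, stats=stats,
                   seed=meta["seed"], n_redraws=meta["n_redraws"])


def build_reference_table(model_id: str, ps: PriorSpec, n_sims: int,
                          sc: SampleConfig, rng_seed: int,
                          c_window: str = "tau2", locus_lengths=None,
                          n_dom_per_locus=None,
                          n_wild_per_locus=None) -> ReferenceTable:
    """Prior-predictive simulation: the substrate of all ABC steps.

    Prior draws violating the model's parameter invariants (e.g. a
    recovery time beyond the split) are rejected and redrawn; the
    redraw count is recorded on the result.
    """
    if set(ps.names) != set(model_param_names(model_id)):
        raise ValueError(
            f"prior spec parameters {ps.names} do not match model "
            f"{model_id} ({model_param_names(model_id)})")
    rng = np.random.default_rng(rng_seed)
    draws = draw_priors(ps, n_sims, int(rng.integers(_SEED_MOD)))
    n_redraws = 0
    for _ in range(1000):
        bad = np.array([
            bool(validate_parameters(params_from_row(row, model_id), model_id))
            for row in draws.to_dict("records")])
        if not bad.any():
            break
        n_redraws += int(bad.sum())
        redraw = draw_priors(ps, int(bad.sum()), int(rng.integers(_SEED_MOD)))
        draws.loc[bad, :] = redraw.to_numpy()
    else:
        raise RuntimeError("could not draw valid parameters from the priors")
    if n_redraws:
        log.info("reference table %s: %d invalid prior draws redrawn",
                 model_id, n_redraws)

    row_seeds = rng.integers(_SEED_MOD, size=n_sims)
    stats = np.empty((n_sims, 4))
    for i, row in enumerate(draws.to_dict("records")):
        p = params_from_row(row, model_id)
        spec = compile_model(p, model_id, c_window=c_window)
        sv = simulate_dataset(
            spec, sc, p.theta1, int(row_seeds[i]),
            locus_lengths=locus_lengths, n_dom_per_locus=n_dom_per_locus,
            n_wild_per_locus=n_wild_per_locus)
        stats[i] = sv.as_array()
    return ReferenceTable(model_id=model_id, params=draws, stats=stats,
                          seed=rng_seed, n_redraws=n_redraws)


@dataclass(frozen=True)
class RejectionResult:
    """Accepted reference-table subset, with scaled distances."""

    model_id: str
    params: pd.DataFrame
    stats: np.ndarray
    distances: np.ndarray
    threshold: float  # largest accepted distance (acceptance radius)
    scale: np.ndarray  # per-statistic MAD over the reference table
    observed: np.ndarray
    n_reference: int


def _mad_scale(stats: np.ndarray) -> np.ndarray:
    scale = median_abs_deviation(stats, axis=0)
    if np.any(scale == 0):
        bad = [STAT_NAMES[i] for i in np.nonzero(scale == 0)[0]]
        raise ValueError(
            f"statistic column(s) {bad} have zero spread in the reference "
            "table; cannot scale distances")
    return scale


def rejection_sample(rt: ReferenceTable, observed: SummaryStatVector,
                     acceptance_fraction: float) -> RejectionResult:
    """Keep the ceil(fraction * n) rows nearest to the observed vector.

    Distance is Euclidean over MAD-scaled statistic columns; ties at the
    cutoff are broken deterministically by row index.
    """
    if not 0 < acceptance_fraction <= 1:
        raise ValueError("acceptance_fraction must be in (0, 1]")
    obs = observed.as_array() if isinstance(observed, SummaryStatVector) \
        else np.asarray(observed, dtype=float)
    if not np.all(np.isfinite(obs)):
        raise ValueError("observed statistics must be finite")
    scale = _mad_scale(rt.stats)
    z = (rt.stats - obs) / scale
    distances = np.sqrt((z**2).sum(axis=1))
    k = math.ceil(acceptance_fraction * rt.n_rows)
    idx = np.argsort(distances, kind="stable")[:k]
    idx = np.sort(idx)
    return RejectionResult(
        model_id=rt.model_id,
        params=rt.params.iloc[idx].reset_index(drop=True),
        stats=rt.stats[idx], distances=distances[idx],
        threshold=float(distances[idx].max()), scale=scale, observed=obs,
        n_reference=rt.n_rows)


@dataclass(frozen=True)
class PosteriorSample:
    """Accepted draws, their regression-adjusted values and weights."""

    model_id: str
    raw: pd.DataFrame
    adjusted: pd.DataFrame
    weights: np.ndarray
    distances: np.ndarray
    threshold: float
    observed: np.ndarray
    regression_applied: bool = True

    def summary(self) -> pd.DataFrame:
        return posterior_summary(self)


def _epanechnikov(distances: np.ndarray, radius: float) -> np.ndarray:
    if radius == 0:
        return np.ones_like(distances)
    return np.clip(1.0 - (distances / radius) ** 2, 0.0, 1.0)


def regression_adjust(accepted: RejectionResult,
                      observed: SummaryStatVector | np.ndarray | None = None
                      ) -> PosteriorSample:
    """Weighted local-linear adjustment of the accepted draws.

    Each log-parameter is regressed on the (scaled) statistic offsets
    from the observed vector with Epanechnikov kernel weights; the
    adjusted draw is the fitted value at the observed statistics plus
    the draw's residual.  When every accepted statistic row equals the
    observed vector the adjustment is the identity.  A rank-deficient
    design falls back to the rejection-only posterior.
    """
    if observed is None:
        obs = accepted.observed
    elif isinstance(observed, SummaryStatVector):
        obs = observed.as_array()
    else:
        obs = np.asarray(observed, dtype=float)
    n, p = accepted.stats.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} accepted rows, got {n}")
    weights = _epanechnikov(accepted.distances, accepted.threshold)
    if not weights.any():  # all rows at the radius; fall back to uniform
        weights = np.ones(n)
    diffs = (accepted.stats - obs) / accepted.scale
    if not diffs.any():
        return PosteriorSample(
            model_id=accepted.model_id, raw=accepted.params,
            adjusted=accepted.params.copy(), weights=weights,
            distances=accepted.distances, threshold=accepted.threshold,
            observed=obs, regression_applied=False)
    y = np.log(accepted.params.to_numpy())
    x = np.column_stack([np.ones(n), diffs])
    sw = np.sqrt(weights)
    coef, _, rank, _ = np.linalg.lstsq(x * sw[:, None], y * sw[:, None],
                                       rcond=None)
    if rank < x.shape[1]:
        log.warning("regression design is rank deficient (%d < %d); "
                    "keeping the rejection-only posterior", rank, x.shape[1])
        return PosteriorSample(
            model_id=accepted.model_id, raw=accepted.params,
            adjusted=accepted.params.copy(), weights=weights,
            distances=accepted.distances, threshold=accepted.threshold,
            observed=obs, regression_applied=False)
    adjusted_log = y - diffs @ coef[1:]
    adjusted = pd.DataFrame(np.exp(adjusted_log),
                            columns=accepted.params.columns)
    return PosteriorSample(
        model_id=accepted.model_id, raw=accepted.params, adjusted=adjusted,
        weights=weights, distances=accepted.distances,
        threshold=accepted.threshold, observed=obs)


def weighted_quantile(values, q, weights) -> np.ndarray:
    """Quantile(s) of a weighted sample (inverse weighted ECDF)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cdf = (np.cumsum(w) - 0.5 * w) / w.sum()
    return np.interp(q, cdf, v)


def posterior_summary(sample: PosteriorSample) -> pd.DataFrame:
    """Mode (Gaussian-KDE argmax, Silverman bandwidth) and equal-tailed
    95% interval per parameter, from the weighted adjusted draws."""
    draws = sample.adjusted
    if len(draws) < 10:
        raise ValueError("need at least 10 draws to summarize")
    w = sample.weights
    if not w.any():
        w = np.ones(len(draws))
    rows = []
    for name in draws.columns:
        x = draws[name].to_numpy()
        lo, hi = weighted_quantile(x, [0.025, 0.975], w)
        if np.ptp(x) == 0:
            mode = float(x[0])
        else:
            kde = gaussian_kde(x, weights=w, bw_method="silverman")
            grid = np.linspace(x.min(), x.max(), 512)
            mode = float(grid[np.argmax(kde(grid))])
        rows.append({"parameter": name, "mode": mode,
                     "lower95": float(lo), "upper95": float(hi)})
    return pd.DataFrame(rows).set_index("parameter")
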