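"""Model comparison: acceptance-rate Bayes factors and marginal-likelihood
model probabilities.

Two devices are provided.

* Posterior-predictive acceptance rates: for each candidate demography,
  parameters are drawn from its ABC posterior, the domesticated-
  population statistic (S or pi) is re-simulated, and a simulation is
  "acceptable" when its relative deviation from the observed value is
  strictly below a tolerance delta.  The Bayes factor K of a model is
  its acceptance rate divided by that of the no-gene-flow (isolation)
  reference model, computed separately per statistic.

* Marginal-likelihood scores (e.g. thermodynamic-integration scores
  produced by an external sampler) are combined into per-model
  probabilities on the likelihood scale (via log-sum-exp) and into
  pairwise log Bayes factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .abc import PosteriorSample, params_from_row
from .coalescent import SampleConfig, simulate_dataset
from .models import compile_model, validate_parameters
from .stats import STAT_NAMES

__all__ = [
    "ModelComparisonResult",
    "posterior_predictive_acceptance",
    "bayes_factor_K",
    "model_probabilities",
    "log_bayes_factor",
    "compare_models_K",
    "marginal_likelihood_report",
]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class ModelComparisonResult:
    """Per-model, per-statistic acceptance rates and Bayes factors."""

    reference_model: str
    delta: float
    n_sims: int
    rates: pd.DataFrame  # index model, columns statistic -> acceptance rate
    k: pd.DataFrame      # same shape, K relative to the reference

    def to_table(self) -> pd.DataFrame:
        """Long-form (statistic, model, K) report."""
        rows = []
        for stat in self.k.columns:
            for model in self.k.index:
                rows.append({"statistic": stat, "model": model,
                             "K": self.k.loc[model, stat],
                             "acceptance_rate": self.rates.loc[model, stat]})
        return pd.DataFrame(rows)


def _default_simulator(model_id, sc, c_window="tau2", locus_lengths=None,
                       n_dom_per_locus=None, n_wild_per_locus=None):
    def run(row, seed):
        p = params_from_row(row, model_id)
        spec = compile_model(p, model_id, c_window=c_window)
        return simulate_dataset(
            spec, sc, p.theta1, seed, locus_lengths=locus_lengths,
            n_dom_per_locus=n_dom_per_locus,
            n_wild_per_locus=n_wild_per_locus)
    return run


def posterior_predictive_acceptance(posterior: PosteriorSample,
                                    observed_stat: float,
                                    statistic_selector: str,
                                    n_sims: int, delta: float,
                                    rng_seed: int,
                                    sc: SampleConfig | None = None,
                                    simulator=None,
                                    use_weights: bool = True) -> float:
    """Fraction of posterior-predictive simulations within delta.

    ``statistic_selector`` names the statistic compared (one of
    ``s_dom``, ``s_wild``, ``pi_dom``, ``pi_wild``); acceptance is
    |simulated - observed| / |observed| < delta with strict inequality.
    ``simulator`` (row, seed) -> SummaryStatVector may be injected;
    otherwise the model's own coalescent simulator is used and ``sc``
    is required.
    """
    if observed_stat == 0:
        raise ValueError("observed statistic is zero: relative distance undefined")
    if statistic_selector not in STAT_NAMES:
        raise ValueError(f"unknown statistic {statistic_selector!r}")
    if len(posterior.adjusted) == 0:
        raise ValueError("posterior sample is empty")
    if simulator is None:
        if sc is None:
            raise ValueError("need a SampleConfig when no simulator is injected")
        simulator = _default_simulator(posterior.model_id, sc)
    stat_idx = STAT_NAMES.index(statistic_selector)
    rng = np.random.default_rng(rng_seed)
    w = posterior.weights if use_weights else np.ones(len(posterior.adjusted))
    if not w.any():
        w = np.ones(len(posterior.adjusted))
    rows = posterior.adjusted.to_dict("records")
    # regression adjustment can push a draw past a hard constraint
    # (e.g. a recovery beyond the split); only compilable draws can be
    # re-simulated, so restrict to those and renormalize the weights
    valid = np.array([
        not validate_parameters(params_from_row(r, posterior.model_id),
                                posterior.model_id)
        for r in rows])
    if not valid.any():
        raise ValueError("no compilable draws in the posterior sample")
    w = np.where(valid, w, 0.0)
    draw_idx = rng.choice(len(rows), size=n_sims, p=w / w.sum())
    seeds = rng.integers(_SEED_MOD, size=n_sims)
    accepted = 0
    for i in range(n_sims):
        sv = simulator(rows[draw_idx[i]], int(seeds[i]))
        sim = sv.as_array()[stat_idx]
        if abs(sim - observed_stat) / abs(observed_stat) < delta:
            accepted += 1
    return accepted / n_sims


def bayes_factor_K(rate_model: float, rate_reference: float) -> float:
    """Relative acceptance rate against the isolation reference model."""
    if rate_reference <= 0:
        raise ValueError(
            "reference acceptance rate is zero; increase the number of "
            "posterior-predictive simulations or the tolerance delta")
    return rate_model / rate_reference


def model_probabilities(log_mls) -> np.ndarray:
    """Per-model probabilities mL_i / sum_j mL_j from log scores.

    Computed with a max-shifted exponentiation (log-sum-exp), so adding
    any constant to all scores leaves the result unchanged.
    """
    scores = np.asarray(list(log_mls.values()) if isinstance(log_mls, dict)
                        else log_mls, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two models")
    if not np.all(np.isfinite(scores)):
        raise ValueError("log marginal likelihoods must be finite")
    return np.exp(scores - logsumexp(scores))


def log_bayes_factor(log_ml_1: float, log_ml_2: float) -> float:
    """LBF = ln mL(model 1) - ln mL(model 2)."""
    if not (math.isfinite(log_ml_1) and math.isfinite(log_ml_2)):
        raise ValueError("log marginal likelihoods must be finite")
    return log_ml_1 - log_ml_2


def marginal_likelihood_report(log_mls: dict[str, float],
                               reference: str | None = None) -> pd.DataFrame:
    """Score / LBF / probability table from per-model log scores.

    LBF is taken against ``reference`` (default: the best-scoring
    model, which then has LBF 0 by construction).
    """
    probs = model_probabilities(log_mls)
    if reference is None:
        reference = max(log_mls, key=log_mls.get)
    ref_score = log_mls[reference]
    return pd.DataFrame([
        {"model": m, "log_mL": s,
         "LBF": log_bayes_factor(s, ref_score),
         "probability": float(p)}
        for (m, s), p in zip(log_mls.items(), probs)
    ])


def compare_models_K(posteriors: dict[str, PosteriorSample],
                     observed, statistics=("pi_dom", "s_dom"),
                     reference_model: str = "A_no_flow",
                     n_sims: int = 10_000, delta: float = 0.01,
                     rng_seed: int = 0, sc: SampleConfig | None = None,
                     simulators: dict | None = None) -> ModelComparisonResult:
    """Acceptance-rate Bayes factors for several fitted models.

    ``observed`` is the observed SummaryStatVector (or an array in
    STAT_NAMES order); K is reported separately per statistic, with the
    isolation model as reference.
    """
    obs = observed.as_array() if hasattr(observed, "as_array") \
        else np.asarray(observed, dtype=float)
    if reference_model not in posteriors:
        raise ValueError(f"reference model {reference_model!r} not fitted")
    rng = np.random.default_rng(rng_seed)
    rates = pd.DataFrame(index=list(posteriors), columns=list(statistics),
                         dtype=float)
    for model, post in posteriors.items():
        simulator = (simulators or {}).get(model)
        for stat in statistics:
            rates.loc[model, stat] = posterior_predictive_acceptance(
                post, float(obs[STAT_NAMES.index(stat)]), stat,
                n_sims, delta, int(rng.integers(_SEED_MOD)),
                sc=sc, simulator=simulator)
    k = pd.DataFrame({
        stat: [bayes_factor_K(rates.loc[m, stat],
                              rates.loc[reference_model, stat])
               for m in rates.index]
        for stat in rates.columns}, index=rates.index)
    return ModelComparisonResult(reference_model=reference_model,
                                 delta=delta, n_sims=n_sims,
                                 rates=rates, k=k)
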