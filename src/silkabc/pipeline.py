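"""End-to-end pipeline: data -> statistics -> ABC -> model choice ->
unit conversion -> direction analysis.

A single config (YAML or dict) drives the whole run; every stage writes
a plain-text report into the output directory together with the seeds
that produced it, so re-running an identical config reproduces every
number.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abc as abc_mod
from .abc import default_priors, Prior, PriorSpec
from .coalescent import SampleConfig
from .direction import direction_model_choice
from .models import MODEL_IDS
from .selection import compare_models_K
from .synthetic import (StudyDesign, ScaledParameters, generate_synthetic_study,
                        observed_stats, read_study)
from .units import ConversionContext, conversion_table, theta_to_ne

__all__ = ["default_config", "validate_config", "run_pipeline"]

log = logging.getLogger("silkabc")

_SEED_MOD = 2**31 - 1


def default_config() -> dict:
    """A small, complete demo configuration (synthetic data)."""
    return {
        "seed": 1,
        "study": {"type": "synthetic", "n_loci": 29, "locus_length": 600},
        "abc": {"models": list(MODEL_IDS), "n_sims": 10_000,
                "acceptance_fraction": 0.01, "priors": {}},
        "selection": {"n_sims": 2_000, "delta": 0.01,
                      "statistics": ["pi_dom", "s_dom"],
                      "reference_model": "A_no_flow"},
        "direction": {"enabled": True, "n_sims_per_model": 2_000,
                      "acceptance_fraction": 0.01},
        "conversion": {"mu": 1.56e-8, "generations_per_year": 1.0},
    }


def validate_config(config: dict) -> dict:
    """Schema-check a config, filling defaults; raises before any work."""
    cfg = default_config()
    for section, values in config.items():
        if section == "seed":
            cfg["seed"] = int(values)
            continue
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        for key, val in values.items():
            if key not in cfg[section] and not (
                    section == "study" or key in ("params", "model_id",
                                                  "path", "label_pattern")):
                raise ValueError(f"unknown key {section}.{key}")
            cfg[section][key] = val
    for m in cfg["abc"]["models"]:
        if m not in MODEL_IDS:
            raise ValueError(f"unknown model id {m!r}")
    if cfg["selection"]["reference_model"] not in cfg["abc"]["models"]:
        raise ValueError("reference model is not among the fitted models")
    return cfg


def _priors_for(model_id: str, overrides: dict) -> PriorSpec:
    ps = default_priors(model_id)
    usable = {k: Prior(v["family"], float(v["low"]), float(v["high"]))
              for k, v in overrides.items() if k in ps.names}
    return ps.replace(**usable) if usable else ps


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute every stage and write all reports under ``out_dir``.

    Returns a results bundle: observed statistics, per-model posterior
    summaries, the Bayes-factor table, the unit-conversion table for
    the best model and the direction report.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    rng = np.random.default_rng(cfg["seed"])
    bundle: dict = {"config_hash": cfg_hash}

    # --- stage 1: data ---------------------------------------------------
    study = cfg["study"]
    try:
        if study.get("type", "synthetic") == "synthetic":
            design_kwargs = {k: v for k, v in study.items()
                             if k in ("n_loci", "locus_length", "model_id")}
            if "params" in study:
                design_kwargs["params"] = ScaledParameters(**study["params"])
            design = StudyDesign(seed=int(rng.integers(_SEED_MOD)),
                                 **design_kwargs)
            loci, truth = generate_synthetic_study(design, out / "data")
            bundle["truth"] = truth
        else:
            loci = read_study(study["path"],
                              study.get("label_pattern", r"^(?P<pop>dom|wild)"))
    except Exception as exc:
        raise RuntimeError(f"[stage data] {exc}") from exc

    obs = observed_stats(loci)
    n_dom_per_locus = [len(l.dom) for l in loci]
    n_wild_per_locus = [len(l.wild) for l in loci]
    lengths = [l.length for l in loci]
    sc = SampleConfig(n_dom=max(n_dom_per_locus), n_wild=max(n_wild_per_locus),
                      n_loci=len(loci), locus_length=max(lengths))
    obs_df = pd.DataFrame([{
        "s_dom": obs.s_dom, "s_wild": obs.s_wild,
        "pi_dom": obs.pi_dom, "pi_wild": obs.pi_wild, "n_loci": obs.n_loci}])
    obs_df.to_csv(out / "observed_stats.tsv", sep="\t", index=False)
    bundle["observed"] = obs

    # --- stage 2: per-model ABC ------------------------------------------
    posteriors = {}
    summaries = {}
    try:
        for model_id in cfg["abc"]["models"]:
            ps = _priors_for(model_id, cfg["abc"]["priors"])
            rt = abc_mod.build_reference_table(
                model_id, ps, int(cfg["abc"]["n_sims"]), sc,
                int(rng.integers(_SEED_MOD)),
                locus_lengths=lengths, n_dom_per_locus=n_dom_per_locus,
                n_wild_per_locus=n_wild_per_locus)
            accepted = abc_mod.rejection_sample(
                rt, obs, float(cfg["abc"]["acceptance_fraction"]))
            post = abc_mod.regression_adjust(accepted)
            posteriors[model_id] = post
            summaries[model_id] = post.summary()
            summaries[model_id].to_csv(out / f"posterior_{model_id}.tsv",
                                       sep="\t")
            log.info("ABC %s: %d accepted of %d (%d prior redraws)",
                     model_id, len(post.adjusted), rt.n_rows, rt.n_redraws)
    except Exception as exc:
        raise RuntimeError(f"[stage abc] {exc}") from exc
    bundle["posteriors"] = posteriors
    bundle["summaries"] = summaries

    # --- stage 3: model selection -----------------------------------------
    try:
        sel = cfg["selection"]
        comparison = compare_models_K(
            posteriors, obs, statistics=tuple(sel["statistics"]),
            reference_model=sel["reference_model"],
            n_sims=int(sel["n_sims"]), delta=float(sel["delta"]),
            rng_seed=int(rng.integers(_SEED_MOD)), sc=sc)
        comparison.to_table().to_csv(out / "bayes_factors.tsv", sep="\t",
                                     index=False)
    except Exception as exc:
        raise RuntimeError(f"[stage selection] {exc}") from exc
    bundle["model_comparison"] = comparison
    best = comparison.k.mean(axis=1).idxmax()
    bundle["best_model"] = best

    # --- stage 4: unit conversion -----------------------------------------
    try:
        conv = cfg["conversion"]
        summ = summaries[best]
        theta1_mode = summ.loc["theta1", "mode"]
        ctx = ConversionContext(
            mu=float(conv["mu"]),
            n1=theta_to_ne(theta1_mode, float(conv["mu"])),
            generations_per_year=float(conv["generations_per_year"]))
        table = conversion_table(summ["mode"].to_dict(), ctx)
        table.to_csv(out / "conversion.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"[stage conversion] {exc}") from exc
    bundle["conversion"] = table

    # --- stage 5: direction analysis ---------------------------------------
    if cfg["direction"]["enabled"]:
        try:
            # fix the demography to the inferred history (two-stage, as in
            # MCMC direction samplers); fall back to free nuisance
            # parameters when the modes violate the time ordering
            from .abc import params_from_row
            from .direction import pinned_base_priors
            from .models import validate_parameters
            modes = summaries[best]["mode"].to_dict()
            pinned = abc_mod.params_from_row(
                {**{k: modes.get(k, 1.0) for k in abc_mod.BASE_PARAM_NAMES}},
                "A_no_flow")
            base_prior = (None if validate_parameters(pinned, "A_no_flow")
                          else pinned_base_priors(pinned))
            dres = direction_model_choice(
                obs, base_prior, int(cfg["direction"]["n_sims_per_model"]),
                int(rng.integers(_SEED_MOD)), sc,
                acceptance_fraction=float(
                    cfg["direction"]["acceptance_fraction"]),
                locus_lengths=lengths, n_dom_per_locus=n_dom_per_locus,
                n_wild_per_locus=n_wild_per_locus)
            dres.to_table().to_csv(out / "direction.tsv", sep="\t",
                                   index=False)
            bundle["direction"] = dres
        except Exception as exc:
            raise RuntimeError(f"[stage direction] {exc}") from exc

    (out / "run.json").write_text(json.dumps({
        "config": cfg, "config_hash": cfg_hash,
        "best_model": best,
    }, indent=2, default=str))
    return bundle


def load_config(path) -> dict:
    """Read a YAML (or JSON) config file."""
    text = Path(path).read_text()
    return yaml.safe_load(text)
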