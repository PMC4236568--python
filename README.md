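# silkabc

Coalescent simulation and approximate Bayesian computation (ABC) for
the demographic history of silkworm domestication.

The domesticated silkworm *Bombyx mori* diverged from its wild
progenitor *B. mandarina* through a domestication bottleneck, and the
two still exchange genes.  Given multi-locus silent-site variation in
both populations, this package asks: which of four two-population
scenarios — no gene flow, continuous gene flow, gene flow *during* the
bottleneck, or gene flow *after* it — best explains the data; what are
the effective sizes and the timing of domestication; and in which
direction did the gene flow run?

It is written for population geneticists who want the whole inference
chain — coalescent simulator, summary statistics, rejection–regression
ABC, acceptance-rate Bayes factors, direction analysis and unit
conversion — as ordinary, tested Python functions rather than a chain
of command-line tools.

## The model in brief

All histories share a backbone in `ms` scaling (sizes relative to the
modern wild effective size N₁, time in units of 4 N₁ generations,
migration M = 4 N₁ m): an ancestral population of relative size
θ_a/θ₁ splits at τ_D into two bottlenecked daughters (θ_b2/θ₁
domesticated, θ_b1/θ₁ wild) that recover to their modern sizes (θ₂/θ₁
and 1) at τ₂ and τ₁.  Each dataset is summarised by the across-locus
means of the segregating-site count S and nucleotide diversity π per
population.  Inference is classic rejection ABC with local-linear
regression adjustment (Epanechnikov-weighted, on log parameters);
model choice uses the relative posterior-predictive acceptance rate
(the Bayes factor K) against the no-gene-flow reference model, with
|sim − obs|/|obs| < δ = 0.01 as the acceptance rule.  Scaled estimates
convert to natural units through θ = 4 N_e μ and T = τ · 4 N₁
generations (μ = 1.56 × 10⁻⁸/bp/generation).

See `docs/methods.md` for assumptions, defaults and known limitations.

## Worked example

Generate a synthetic 29-locus study under the bottleneck-gene-flow
history at its published posterior modes, then re-infer the parameters:

```python
from silkabc.abc import (default_priors, build_reference_table,
                         rejection_sample, regression_adjust)
from silkabc.coalescent import SampleConfig
from silkabc.synthetic import StudyDesign, generate_synthetic_study, observed_stats
from silkabc.units import ConversionContext, conversion_table, theta_to_ne

loci, truth = generate_synthetic_study(StudyDesign(seed=42), "study_data")
obs = observed_stats(loci)
print(f"observed: S_dom={obs.s_dom:.2f} S_wild={obs.s_wild:.2f} "
      f"pi_dom={obs.pi_dom:.2f} pi_wild={obs.pi_wild:.2f} ({obs.n_loci} loci)")

sc = SampleConfig(n_dom=17, n_wild=15, n_loci=29, locus_length=600)
rt = build_reference_table(
    "C_at_bottleneck", default_priors("C_at_bottleneck"), 20_000, sc, 1,
    n_dom_per_locus=[len(l.dom) for l in loci],
    n_wild_per_locus=[len(l.wild) for l in loci])
post = regression_adjust(rejection_sample(rt, obs, 0.01))
summary = post.summary()
print(summary.round(5))
```

which prints

```text
observed: S_dom=54.34 S_wild=54.72 pi_dom=20.51 pi_wild=20.37 (29 loci)
                   mode  lower95    upper95
parameter
theta1          0.03007  0.00765    0.08931
ratio_theta2    0.26580  0.00228    7.01367
ratio_thetaA    1.03511  0.46026    7.58690
ratio_thetaB1   0.13657  0.00132    2.68260
ratio_thetaB2   0.22138  0.00513    7.91703
tauD            0.00668  0.00052    0.08801
tau1            0.00103  0.00011    0.02537
tau2            0.00080  0.00012    0.02309
mig_rate_wd    26.81102  0.19988  970.70357
mig_rate_dw    18.97256  0.11068  675.14102
```

The per-site θ₁ mode 0.0301 recovers the generating value 0.0312; the
split-time mode τ_D = 0.0067 sits above the generating 0.00373 but the
95% interval (0.00052, 0.088) covers it — at 2×10⁴ simulations the
posteriors are honest but wide (the original analysis used 2×10⁶ per
model).  Converting to natural units:

```python
ctx = ConversionContext(mu=1.56e-8,
                        n1=theta_to_ne(summary.loc["theta1", "mode"], 1.56e-8))
print(conversion_table(summary["mode"].to_dict(), ctx).to_string(index=False))
```

turns `theta1 = 0.0301` into N₁ ≈ 482,000 individuals and
`tauD = 0.0067` into ≈ 12,900 years before present (one generation per
year).

The same machinery is exposed on the command line:

```bash
silkabc synth --seed 42 --n-loci 29 --out study_data
silkabc stats study_data
silkabc run --config demo.yaml --out results_dir
```

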