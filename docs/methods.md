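# Methods

## The demographic model

`silkabc` infers the demographic history of silkworm domestication from
multi-locus sequence variation in the domesticated silkworm (*Bombyx
mori*, "dom") and its wild progenitor (*B. mandarina*, "wild").  Four
two-population scenarios share a common backbone: an ancestral
population of relative size θ_a/θ₁ splits at time τ_D into two
bottlenecked daughters (relative sizes θ_b2/θ₁ for dom, θ_b1/θ₁ for
wild), which recover instantaneously to their modern sizes (θ₂/θ₁ and
1) at times τ₂ and τ₁.  The scenarios differ only in when gene flow is
possible:

| model | gene-flow window (backward time) |
|---|---|
| `A_no_flow` | never |
| `B_continuous` | (0, τ_D) |
| `C_at_bottleneck` | (τ₂, τ_D) |
| `D_after_bottleneck` | (0, τ₂) |

Everything is expressed in Hudson's `ms` scaling: sizes relative to N₁
(the modern wild effective size), times in units of 4 N₁ generations,
migration as M = 4 N₁ m.  This makes published priors and posteriors
directly usable and keeps the simulator free of absolute units.

Two modelling points were genuinely open and are package decisions:

* **Bottleneck gene-flow window.**  The two daughters recover at
  different times, so "during the bottleneck" is ambiguous when
  τ₁ ≠ τ₂.  The window is tied to the *domestication* bottleneck,
  (τ₂, τ_D); `compile_model(..., c_window=...)` exposes `tau1`, `min`
  and `max` alternatives.
* **Direction semantics.**  Direction names (`DIR_d_to_w`,
  `DIR_w_to_d`) are forward-time gene flow.  The engine works backward
  in time, where forward flow wild→dom moves sampled dom lineages into
  the wild population; the conversion is made once in
  `models.compile_model` and documented on `ScaledParameters`.

No ordering is imposed between τ₁ and τ₂.

## Coalescent engine

The simulator (`coalescent` + the numba kernels in `_kernels`) is an
exact event-driven structured coalescent: within an epoch, a pair in a
population of relative size s coalesces at rate 2/s and a lineage in
population i migrates at its scaled backward rate; waiting times are
exponential, and an epoch boundary simply triggers a re-draw under the
new rates (valid by memorylessness).  At τ_D all lineages merge into
the ancestral population.  With this scaling E[TMRCA] for a pair is
0.5 and, for per-locus θ, E[π] = θ and E[S] = θ·a_{n−1}; mutation
counts per branch are Poisson(θ × branch length).  These three analytic
identities, plus a distributional comparison against msprime run on the
identical history (two-sample KS on S and π per population, 10⁴
replicates), are the engine's correctness anchors.

Mutations follow the infinite-sites model; positions are continuous in
(0,1) and only matter for export (ms-format blocks, FASTA).  There is
no recombination within a locus; loci are independent.  A master seed
expands into per-locus substreams keyed by (seed, locus index), so
growing the locus count never perturbs earlier loci.

## Summary statistics

Each dataset is reduced to four numbers: the across-locus means of the
number of segregating sites S and the mean pairwise difference π,
separately per population (statistics computed within each population's
sample).  π and S from simulated haplotype matrices and from FASTA
alignments go through the same functions; for real alignments a
user-supplied silent-site mask restricts the columns first (the package
does not infer codon positions).  Missing data use pairwise deletion;
a column is segregating when it has ≥ 2 distinct non-missing states.
Watterson's θ = S/a_{n−1} and Tajima's D (1989 constants; undefined at
S = 0) are provided as diagnostics.  Note that D's *mean* under
neutrality is slightly negative in finite samples (≈ −0.05 to −0.1 for
n = 4–17 at silkworm-like θ); the D implementation agrees with tskit's
to machine precision.

## ABC

Inference is rejection–regression ABC (Beaumont-style):

1. parameters are drawn from their priors (draws violating hard
   constraints, e.g. a recovery older than the split, are redrawn and
   counted);
2. one dataset is simulated per draw, mirroring the observed design
   (per-locus sample sizes and lengths);
3. statistic columns are scaled by their median absolute deviation over
   the reference table and the closest ⌈fraction·n⌉ rows by Euclidean
   distance are accepted (ties broken by row index);
4. each log-parameter is adjusted by weighted local-linear regression
   on the scaled statistic offsets with Epanechnikov weights over
   distance; the log transform keeps adjusted draws positive, and a
   rank-deficient design falls back to the rejection-only sample;
5. the posterior mode is the argmax of a Gaussian KDE (Silverman
   bandwidth, weighted draws); the interval is the weighted equal-tailed
   2.5–97.5% quantile pair.

Default priors (the study's prior table is not public): log-uniform τ
on (10⁻⁴, 0.1), log-uniform size ratios on (10⁻³, 10), uniform per-site
θ₁ on (0.001, 0.1), log-uniform M on (0.1, 10³).  They contain all
published posterior intervals and are fully overridable.

## Model choice

Two devices, mirroring the study:

* **Acceptance-rate Bayes factors.**  For each fitted model, parameters
  are drawn from its (weighted, compilable) posterior sample, the
  domesticated-population statistic is re-simulated, and a simulation is
  acceptable when |sim − obs|/|obs| < δ (strict; δ = 0.01 by default).
  K is the model's acceptance rate over that of the isolation reference
  model, reported per statistic (π_dom and S_dom), with a combined
  option.
* **Marginal-likelihood scores.**  Externally computed log marginal
  likelihoods are combined into model probabilities on the likelihood
  scale via log-sum-exp and into pairwise log Bayes factors.  The
  package does not estimate such scores.

## Direction of gene flow

The original analysis answered the direction question with MCMC
samplers (thermodynamic integration over the three one-or-two-direction
histories).  Re-implementing those samplers is out of scope here;
instead the same three-model space is compared by ABC model choice: one
reference table per variant (equal budget), pooled, rejection applied to
the pool, and each variant's posterior probability read off the accepted
rows (uniform model prior).  This substitution — same scientific
question, different estimator — is flagged in every direction report.

Following the original two-stage design, the direction stage pins the
shared demography to the previously inferred history
(`pinned_base_priors`) and leaves only the migration rates free.  This
matters: with all ten parameters free, the accepted-set frequencies
stay at the ⅓ prior and the comparison has no power.  Migration rates
are reported both scaled (M = 4 N₁ m) and as migrants per generation
into the recipient, (M/4) × (recipient size ratio); both conventions
are printed in the output headers because migration-rate units are a
perennial source of confusion.

## Synthetic data

The generator reproduces the study design: 29 unlinked loci, per-locus
domesticated sample size uniform on 6–17 and wild on 7–15, 600 bp of
silent sites per locus (the real per-locus table is not public; 600 bp
is a typical sequenced-amplicon silent-site count).  The default "true"
history is the bottleneck-gene-flow model at its published posterior
modes, with θ₁ = 0.0312 per site and scaled migration rates
(428.4, 1274.4) — four times the published migrants-per-generation
figures (107.1 wild→dom, 318.6 dom→wild) under the N₁·m reading of
that unit.  Binary haplotypes become nucleotides by drawing a random
background sequence, one distinct integer position per segregating site
and a derived base different from the ancestral one, so S and π on the
FASTA output equal those of the generating matrices exactly; all
synthetic sites are silent by construction.

What synthetic data do *not* emulate: sequencing error, alignment gaps,
missing genotypes, intra-locus recombination, selection at linked
sites, and real silent-site annotation.  Tests passing on synthetic
data therefore validate the inference machinery, not robustness to
those artefacts.

## Problem sizes used in the checks

The self-consistency experiments are scaled-down versions of the full
analysis (which used 2×10⁶ simulations per model): reference tables of
2–5×10⁴ rows per model shared across replicates, acceptance fractions
0.01, 12–25 replicate observed datasets, and a few hundred to a few
thousand posterior-predictive simulations per model.  Parameter
recovery (95%-interval coverage of τ_D, θ₂/θ₁, θ_b2/θ₁) and direction
self-consistency pass comfortably at these sizes.

## Known limitations

* **Model-selection power.**  Under the wide default priors, data
  simulated under the bottleneck-gene-flow model do **not** yield the
  largest acceptance-rate K for that model at desk scale: all four
  fitted models reproduce the four summary-statistic means about
  equally well, so the per-statistic K values sit near 1 and the
  ranking is essentially random.  Experiments up to 10⁵-row tables and
  acceptance fraction 0.001 do not change this.  The published strong
  K ranking is not reproducible without the original priors and the
  real sequence data; the corresponding self-consistency test records
  this expectation honestly and fails.
* The acceptance-rate K is a Monte-Carlo estimate; with a zero
  reference-model rate the ratio is undefined and the code asks for
  more simulations rather than reporting infinity.
* The direction probabilities depend on the migration prior through the
  usual Occam effect: a bidirectional model with one weak direction
  (e.g. scaled rates 50 vs 200) is routinely beaten by the
  corresponding one-way model.
* Effective sizes assume the standard diploid θ = 4 N_e μ; generation
  time defaults to one per year, which the published chronology itself
  implies.
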