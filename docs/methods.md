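# Methods

`paraclock` implements two computations used to characterize the last
universal common ancestor (LUCA): Bayesian divergence-time estimation on
gene trees rooted at a pre-LUCA gene duplication, with *cross-bracing* of
the mirrored speciation nodes; and probabilistic post-processing of
ancestral gene-content reconstructions into confidence categories, sampled
ancestral genomes, and LOESS-based predictions of proteome and genome
size. This note records the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Cross-braced dating model

### Trees and braces

The input is a rooted binary tree whose root is a gene duplication: each
descendant subtree contains one paralogue's copy of the same species
history, so internal nodes come in mirrored sets that represent a single
speciation event. Brace labels (`#k` in the extended Newick grammar) mark
such sets. Within each set one node (the first in preorder) is the
*driver*; the rest are *mirrors* whose age is literally the same parameter
(a reparameterization, not a penalty), so driver and mirror ages are
bit-identical in every MCMC sample, never merely equal in distribution.
Calibration information written on any braced node applies to the whole
set, and conflicting calibrations on one label are rejected at parse time.
A label on a single node is accepted with a warning and treated as
unbraced. Three bracing strategies are supported: `A` (all labelled sets),
`B` (only sets carrying a fossil calibration), `none`.

### Time prior

Ages are in Ga (1 time unit = 10^9 yr); I/O accepts Ma and converts.
Calibrated nodes contribute a calibration density:

* **Two-sided `B(tmin, tmax)`** — a uniform core holding
  `1 − εL − εR` of the mass, with `ε = 0.025` per soft side by default.
  Beyond a *soft* maximum the density decays exponentially with rate
  `h/εR` (h = core height), which holds exactly `εR` mass and is
  continuous at the bound. Below a soft minimum an exponential rise is
  fitted by root-finding so the truncated-at-zero tail holds exactly `εL`
  mass while staying continuous; when the bound is too close to zero for
  that (mass would not fit under a continuous tail), a flat left tail of
  exactly `εL` mass is used instead. A *hard* bound admits zero mass.
* **One-sided `U(tmax)`** — uniform on (0, tmax) plus the same soft right
  tail. **One-sided `L(tmin)`** — exponential body above the bound with
  decay length `0.5·tmin` (the sources specify the tail mass, not the
  shape; this keeps the prior concentrated within a factor ~2 of the
  bound), plus the soft left tail.

Every density integrates to 1 and each soft tail holds its stated mass to
1e−6 by quadrature (tested). Consequently the 2.5% and 97.5% points of an
isolated calibration are its bounds, which is what the prior-recovery
experiment checks by sampling.

Uncalibrated node ages are conditionally uniform between the age of their
nearest calibrated-or-root ancestor and the largest minimum-age constraint
among their calibrated descendants, subject to parent > child everywhere
(the uniform kernel; the birth–death parameters λ = μ = 1, ρ = 0.1 are
accepted in configuration and ignored whenever bracing is active, matching
the reference behaviour). Infeasible joint hard bounds (a hard descendant
minimum at or above a hard ancestral maximum) are detected before
sampling.

### Rate priors

Per alignment partition, with independent parameters across partitions
sharing one age vector:

* mean rate μr ~ Gamma(shape 2, rate 2.5) — mean 0.8 substitutions/site/Ga,
  matching the empirically motivated prior for deep divergences;
* σ² ~ Gamma(shape 1, rate 10) — mean 0.1.

**GBM (autocorrelated)**: log rates evolve along the tree by Brownian
motion, `log r_child ~ N(log r_parent − σ²Δt/2, σ²Δt)`; the drift term
makes the child rate mean-preserving (`E[r_child|r_parent] = r_parent`,
verified by quadrature). The root rate is lognormal about μr with one
unit of variance σ². An edge's rate is the arithmetic mean of its
endpoint node rates. **ILN (independent lognormal)**: branch rates are
i.i.d. lognormal with expectation μr and log-variance σ². **strict**: all
edges at μr. In both relaxed models σ² = 0 degenerates to the strict
clock (any rate deviation has zero density).

### Likelihood

Branch lengths are durations × edge rates. The likelihood is either

* **exact** — Felsenstein pruning over compressed site patterns for JC69,
  a Poisson amino-acid model, or LG (+F), optionally with 4-category
  mean-of-category discrete-gamma rates (agrees with phangorn to printed
  precision and with exhaustive state enumeration to 1e−10 on small
  trees); or
* **approximate** — the second-order expansion
  `logL0 + gᵀ(b−b̂) + ½(b−b̂)ᵀH(b−b̂)` around the branch-length MLE. The
  package computes b̂ by L-BFGS-B with an analytic pruning gradient
  (outside/inside partials), initialized from ordinary-least-squares
  branch lengths on saturation-capped pairwise distances — without that
  initialization the quasi-Newton search can step onto the saturation
  plateau, where the projected gradient vanishes. The Hessian is a
  central finite difference of the analytic gradient. A best-effort
  reader for the PAML `in.BV`/rst2 container is provided (b, g, H per
  partition; bit-exactness not attempted), plus a documented JSON format.

### Sampler

Component-wise Metropolis–Hastings:

* free node ages (drivers, unbraced internals, root): sliding-window
  proposals reflected into the currently feasible interval (max of child
  ages, min of parent ages across the whole mirrored set);
* node/branch rates, μr, σ²: log-scale multiplier proposals;
* one **rate–time scaling move** per sweep: ages × c, rates and μr ÷ c
  with the Jacobian `c^(n_ages − n_rates)`. Branch lengths are invariant,
  so the likelihood cancels; this move decorrelates the joint drift of
  all ages against all rates, which is the slow direction under GBM and
  is what makes short chains honest about posterior width.

Step widths auto-tune during burn-in toward 20–40% acceptance. Default
production settings are 4 chains, 10^4 burn-in, 10^5 iterations thinned
to 10^4 samples; tests and desk-scale experiments shrink these. All
chain seeds derive deterministically from one user seed and are recorded
in traces and the provenance manifest; identical configurations rerun to
byte-identical traces. Incremental caches (quadratic-likelihood residual,
per-edge prior terms) are refreshed after burn-in to eliminate
floating-point drift.

### Diagnostics

Rank-normalized split-chain R-hat (maximum of the location and folded
forms), bulk ESS (FFT autocovariances, Geyer initial-monotone
truncation), and tail ESS (minimum ESS of the 2.5%/97.5% quantile
indicators). Bulk ESS and R-hat agree with arviz to 1e−10; tail ESS
within a couple of percent (we rank-normalize the indicator sequence).
Thresholds follow the usual practice for timetree inference: R-hat ≤
1.05, bulk/tail ESS ≥ 100. Chain filtering removes a chain only when (a)
its per-parameter medians deviate from the pooled medians by more than a
MAD multiple (default 5) and (b) removing it brings the worst R-hat below
threshold; the rule and constants are recorded in the report because the
original protocol names the step ("flagging and removal of problematic
chains") without a criterion. HPD intervals are the shortest window
containing ⌈level·n⌉ sorted samples.

## Gene-content post-processing

Inputs are per-family presence probabilities (PPs) at the ancestor from
gene-tree/species-tree reconciliation, typically per run and per
species-tree topology, with the fraction of archaeal and bacterial
genomes sampling each family. The module collapses runs by the median,
assigns four nested confidence categories (PP ≥ 0.75 / 0.50, inclusive;
sampling > 1% in both domains, strict), and draws Bernoulli "sampled
genomes" from the PP vector — families treated as independent because
the reconstruction provides no covariance. Genome size and proteome size
are predicted by passing the per-replicate family counts through a LOESS
curve trained on modern genomes (KO-family count → genome size in Mb, or
protein-coding gene count). LOESS is a tricube-weighted local polynomial
(span 0.75, degree 2 by default, both recorded in the model object);
prediction beyond the training KO range is an error unless explicitly
overridden. The 95% interval is a normal approximation combining the
smoother's pointwise standard error with the across-replicate spread —
the interval-combination rule in the original description is unstated,
so this explicit choice is recorded in the model tag. Presence
probability rather than copy number drives the prediction. Topology
agreement between two PP columns is the Pearson correlation on complete
pairs.

## Synthetic data: what it emulates, and what it does not

`simulate_braced_timetree` builds a duplication-rooted tree whose
paralogue subtrees repeat one species history at identical true ages;
topologies follow the Yule labelled-history distribution (uniform random
joins) with internal ages as uniform order statistics below the species
root (at 0.8 × the duplication-root age by default). Rates come from the
chosen clock; sequences evolve by Markov simulation under the stationary
model; calibration windows are soft-uniform and contain the truth by
construction; the content generator links genome size → protein count
(900 proteins/Mb, lognormal noise) → binomially detected KO count, and
produces a PP vector rescaled so its implied expected family count equals
the chosen true genome's KO count — the property a calibrated
reconciliation should have.

Desk-scale dating experiments use 10 species × 2 paralogues × 500
nucleotide sites under JC69 at a root age of 1.0 (the scale of the
six-tip worked example): at a 4.5-Ga root with the prior-mean rate,
nucleotide data saturates and branch lengths become unidentifiable,
whereas the real analyses use amino-acid models whose 20-state alphabet
saturates far more slowly. Passing coverage and recovery tests therefore
demonstrates the correctness of the machinery — priors, bracing,
approximation, sampler, diagnostics, LOESS propagation — under matched
model conditions; they do not certify calibration accuracy on the real
alignments, which additionally face model misspecification,
among-partition conflict, and fossil-calibration error. Reproducing the
paper-scale numbers (LUCA at ~4.2 Ga, a 2.75-Mb genome) requires the
deposited alignments, calibrations and reconciliation tables and long
MCMC runs.

## Problem sizes in the validation experiments

Coverage uses 40 replicates per clock model with one chain of 400
burn-in + 1,600 kept iterations (thinned by 4) per replicate —
sufficient because the scaling move keeps the CI width honest (verified
against 4× longer two-chain runs). Prior recovery uses 10^5 retained
prior samples; content recovery uses 50 synthetic worlds of 80 training
genomes and 2,000 families; the likelihood oracle enumerates all
ancestral states on 3–5-tip trees. These sizes were chosen so each
experiment gives stable pass/fail behaviour across seeds.

## Known limitations

* The birth–death kernel for uncalibrated ages is implemented only as the
  uniform (λ = μ) special case; arbitrary birth–death time priors are out
  of scope.
* The exact-likelihood path inside the sampler recomputes full pruning per
  proposal and is only practical for small trees; production-scale runs
  should use the quadratic approximation, as the reference pipeline does.
* One-sided minimum calibrations use an explicit exponential body; other
  implementations use heavy-tailed (Cauchy-like) shapes, so marginal
  priors above a bare minimum bound are not comparable shape-for-shape.
* `in.BV` parsing is best-effort: it recovers b, g and H but not the
  optimum log-likelihood (absent from the format), which only shifts
  reported log-likelihoods by a constant.
* σ² is independent across partitions (whether the original analyses
  shared it is unstated); sharing would need a small extension of the
  partition state.
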