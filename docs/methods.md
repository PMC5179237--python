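# Methods notes

## Scope and data model

The package starts from ROI-averaged BOLD time series (nodes × timepoints,
delimited text); it does not touch volumes, preprocessing, or parcellation.
A cohort is a set of subjects sharing one node set, a node → module
partition, a module → group table (sensory-motor / association / other), and
a subject table with group label, pre/post scores per instrument, and a mean
framewise-displacement (FD) motion covariate consumed as given.

Nodes are excluded listwise across the cohort: a node with a constant or
non-finite series in *any* subject ("missing coverage") is dropped for
*all* subjects, since per-module statistics under a fixed partition require
a common node set.  The coverage test is exact range equality to zero, not a
variance epsilon, so a constant-valued series always flags.

## Graph construction conventions

* Pearson r per node pair, clipped to ±(1 − 1e−7) before `atanh` so Fisher z
  stays finite on degenerate (r = ±1) pairs; the matrix diagonal is stored
  as NaN and never treated as an edge.
* Proportional thresholding keeps the `floor(d·P)` strongest pairs of the
  `P = n(n−1)/2` distinct pairs.  Ranking uses **signed** z by default —
  most-positive first, the convention of the functional-atlas literature
  this analysis follows; an `ranking="absolute"` flag ranks by |z| instead.
  At the default 2–10% densities the two rarely differ, because strongly
  negative correlations essentially never enter the top percentiles.
* Ties at the cutoff break by lexicographic node-pair order after the value
  sort, making graphs deterministic and permutation-equivariant on tie-free
  input.  Floor rounding means the realised density never exceeds the
  requested one; edge sets are nested across increasing densities.

## Modularity

`Q = Σᵢ (eᵢᵢ − aᵢ²)` is computed by direct edge counting under the fixed
partition; `aᵢ` is the fraction of edge *ends* in module i (so `Σ aᵢ = 1`
exactly), isolated nodes contribute nothing.  Sub-network (group) modularity
is the unweighted mean of `qᵢ` over the modules of a group, matching the
"average over sub-networks" convention; a size-weighted option exists.

The spectral alternative is Newman's leading-eigenvector method: recursive
bisection on the generalised modularity matrix, each split refined by a
deterministic Kernighan–Lin-style pass, followed by a whole-partition
single-node-move local search that only ever increases Q.  The refinement is
on by default: the raw eigenvector split alone recovered 3×6-node planted
blocks in only 63/100 runs and could end below the planted partition's Q,
whereas with refinement recovery is 100/100 and the result never falls below
the planted Q in our benchmarks.  Everything is deterministic for a given
graph (ties in the eigenvector sign split send zero components to the
positive side; node moves scan in index order).

## Segregation

`S = (Z̄w − Z̄b)/Z̄w` per module on the **unthresholded** z matrix; `Z̄w`
averages unordered within-module pairs (diagonal never included), `Z̄b`
averages all (module, non-module) pairs rather than per-partner-module
means.  Variants: `all` (z as-is), `positive` (drop z < 0 from both means;
an empty between set defines `Z̄b = 0`, hence S = 1), `absolute` (|z|, which
coincides exactly with `all` on non-negative matrices).  A module of size 1
or with `Z̄w = 0` is an error rather than a silent NaN.

## Statistics

* Spearman correlations use average ranks and the t-approximation on
  n − 2 df (matching rho(df)-style reporting); a seeded permutation p is
  available.
* Partial correlations residualise x and y on the controls plus intercept by
  least squares and correlate residuals, df = n − 2 − k; they operate on raw
  values (the rank-based flag exists) because the design contrasts them with
  the rank correlations.
* BCa intervals resample subjects in (x, y) pairs, B = 2000 by default;
  bias-correction z₀ from the bootstrap distribution, acceleration from
  jackknife skewness.  Resamples where either variable collapses to a
  constant are redrawn (capped), a constant bootstrap distribution collapses
  the interval to a point, and endpoints are clipped to [−1, 1].  With
  z₀ = a = 0 the interval reduces to the percentile interval, which the test
  suite asserts.  Implemented in-package (vectorised) because the redraw
  semantics and paired resampling are part of the contract;
  scipy's BCa serves as an independent oracle in tests.
* Comparison of the two groups' correlations converts Spearman estimates to
  the Pearson scale (`r = 2 sin(πρ/6)`, exact under bivariate normality),
  Fisher-transforms, and uses the normal statistic with SE
  `√(1/(n₁−3) + 1/(n₂−3))`.  This classical recipe is mildly liberal for
  rank correlations at n ≈ 15: its empirical size in our simulations is
  ≈ 0.06–0.07 at nominal 0.05, which the acceptance band acknowledges.
* The 2×2 mixed ANOVA (pingouin backend) reports the group × time
  interaction F on (1, N − 2) with partial eta-squared; every call asserts
  the algebraic identity F = t² of the pooled-variance t on gain scores.
  The fully degenerate 0/0 case (no interaction and no subject × time
  variance) is defined as F = 0, p = 1.
* All p-values are two-sided and **uncorrected**; the pipeline runs many
  correlations, so downstream interpretation must account for multiplicity.

## Synthetic cohort generator

The generator emulates the study design, not the biology: two groups
(14 control / 15 trained by default), one instrument, block-structured
multivariate-normal time series (unit variance, within-module correlation
set by a per-subject "strength", constant between-module correlation), and
gains built through a Gaussian copula so that rank correlations can be
planted exactly (Spearman ρ ↔ latent Pearson 2 sin(πρ/6)).

Default conditions: 60 nodes in 6 modules (2 sensory-motor, 4 association),
T = 120 timepoints (a 4-minute scan at TR = 2 s), subject strength uniform
on (0.12, 0.35) with between-module r = 0.10, planted trained-group
modularity–gain Spearman 0.65, baseline–gain Spearman −0.70 in both groups,
FD drawn independently.  A 255-node, 14-module preset mirrors the
post-exclusion scale of the 264-ROI atlas; its module sizes are plausible
for that atlas but synthetic, not the published ROI table.

Two generator-design points deserve emphasis:

* **Why the narrow strength interval.**  Binarised modularity saturates once
  the within/between correlation gap dwarfs the sampling noise of a
  T = 120 correlation estimate (~0.09 SE): every top-density edge falls
  within modules and Q stops responding to strength.  The default regime
  keeps the gap comparable to that noise, so measured Q is a strongly
  monotone readout of strength (rank correlation ≈ 0.97) while spanning a
  realistic Q range (~0.2–0.8 over the sweep).  The wide-gap regime
  (e.g. within 0.6 / between 0.05) remains available and is what the
  structure-demonstration tests use.
* **Attenuation-compensated planting.**  The analysis observes *measured*
  modularity, a noisy transform of strength, which attenuates the planted
  rank correlation.  `strength_attenuation` (default 0.97, calibrated once
  for the default configuration) divides the latent strength loading so the
  planted population correlation lands on measured modularity; set it to 1
  to plant on true strength.
* **Joint feasibility.**  Both planted dependencies share the unit-variance
  latent gain, so their converted loadings must satisfy α² + β² ≤ 1.
  A trained-group target of 0.65 together with a baseline–gain dependence of
  −0.80 on independent latents violates this bound — no generating
  distribution exists with baseline ⊥ strength — so the default
  baseline–gain target is −0.70, the strongest round value leaving noise
  headroom; infeasible combinations raise at spec construction with the
  computed loadings in the message.  The −0.80 dependence is exercised with
  the strength channel off, where it is feasible.
* Setting `strength_scope="association"` plants strength variation only in
  association-group modules (sensory-motor modules keep a fixed within-r of
  0.45): association sub-network q then predicts the trained group's gain
  while sensory-motor q carries only a small mechanical echo (shared edge
  budget), reproducing the sub-network dissociation.

What the generator does **not** emulate: hemodynamics, temporal
autocorrelation, motion artefacts (FD is an independent covariate, not a
contaminant), spatial structure, or heavy-tailed score distributions.
Passing tests therefore validate the pipeline's statistical machinery and
its sensitivity under the design's sample sizes — not robustness to realistic
fMRI noise.

The subject-level Spearman estimator at n = 15 is biased toward zero
(population 0.65 → expected estimate ≈ 0.62); recovery checks compare the
*mean* recovered estimate against the planted value with a band that absorbs
this.

Seeding: one spec seed feeds named substreams (copula latents, per-subject
time series, FD), so all outputs are bit-identical across runs and
independent of how many subjects precede a given one.

## Pipeline and problem sizes

The pipeline is a pure function of (inputs, config, seed); tables re-run
byte-identical, `provenance.json` records config hash, seed and versions,
and the metrics stage is cached on a content hash of the time series,
partition and graph-relevant config, so statistics-only changes skip graph
recomputation.

Test-suite problem sizes are chosen for exhaustiveness per minute: oracle
equivalence on 200 random ≤8-node graphs, spectral recovery on 100 planted
18-node graphs, BCa coverage on 1000 replicates of n = 15 (B = 2000),
comparison size on 2000 null simulations, and end-to-end recovery on
200 cohorts at the 60-node default (the 255-node preset is smoke-tested;
results at the two scales agree in our calibration runs).

## Known limitations

* Modularity is defined for unweighted, undirected graphs only; no
  Louvain/Infomap alternatives, by design.
* The BCa redraw policy makes degenerate data an error rather than a wider
  interval; near-constant variables at small n can exhaust the redraw cap.
* The correlation-comparison test inherits the liberal size noted above.
* Segregation's positive-only variant defines `Z̄b = 0` on an empty between
  set; data where *within*-module positives are absent is an error, not a
  fallback.
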