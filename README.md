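# modgain

Does a more modular resting-state brain network at baseline predict who will
benefit from cognitive training?  `modgain` implements the full analysis
pipeline for that question in older-adult training studies: it turns
per-subject ROI time series into functional-connectivity graphs, quantifies
the modular organisation of each subject's network, and relates those
baseline network metrics to pre/post training gains in a two-group
(trained vs wait-list control) design.  A seeded synthetic-cohort generator
with planted effect sizes makes every stage verifiable without access to
subject data.

It is intended for researchers analysing resting-state fMRI in intervention
studies, and for anyone who wants a tested, reproducible reference
implementation of the modularity / segregation biomarker analysis.

## The metrics

**Connectivity.** For each subject, node pairs are Pearson-correlated over
time and Fisher z-transformed, `z = atanh(r)`.  Binary undirected graphs are
built by keeping the top `d` fraction of node pairs by connection strength
(`d` = 2%, 4%, ..., 10% by default); metrics are averaged (or trapezoidally
integrated) over this density sweep.

**Modularity** of a graph under a node-to-module partition (the bundled
scheme follows the standard 264-ROI functional atlas communities):

    Q = Σᵢ (eᵢᵢ − aᵢ²)

where `eᵢᵢ` is the fraction of edges with both ends in module *i* and `aᵢ`
the fraction of edge ends attached to module *i*.  Per-module contributions
`qᵢ = eᵢᵢ − aᵢ²` are averaged over "sensory-motor" (auditory, somatomotor,
visual) and "association" (cingulo-opercular, default mode, attention,
fronto-parietal, salience) module groups.  A deterministic spectral
alternative (Newman leading-eigenvector maximisation) derives
subject-specific modules instead of the fixed scheme.

**Segregation** works on the unthresholded z matrix, so weak connections
count too:

    S = (Z̄w − Z̄b) / Z̄w

with `Z̄w`/`Z̄b` the mean within-/between-module z, in three sign-handling
variants (as-is, positive-only, absolute).

**Statistics.** Gains are `post − pre`.  Baseline metrics are related to
gains per group with Spearman correlations (BCa bootstrap 95% CIs, 2000
resamples), partial Pearson correlations controlling baseline score or head
motion, a comparison of the two groups' correlations (Spearman → Pearson via
`r = 2 sin(πρ/6)`, then Fisher z), and a 2×2 mixed ANOVA (group × time) with
partial eta-squared.

## Worked example

```python
import modgain as mg
from modgain import io as mio

spec = mg.SimSpec(seed=42)                      # 29 subjects, planted rho 0.65
ts_list, cohort = mg.simulate_cohort(spec)
mio.write_run_dir(ts_list, cohort, spec.partition, "run42", sim_spec=spec)

cfg = mg.RunConfig(run_dir="run42", out_dir="results42", seed=42)
mg.run_pipeline(cfg)
```

or, equivalently, from the shell:

```sh
modgain simulate --out run42 --seed 42
modgain run --run-dir run42 --out results42 --seed 42
```

`results42/correlations.tsv` then contains (whole-brain modularity rows):

```
analysis                           group    metric  estimate  n   p        ci_lo   ci_hi
spearman_gain                      Control  Q       0.182     14  0.533    -0.501  0.674
spearman_gain                      SMART    Q       0.689     15  0.0045    0.197  0.917
partial_gain_controlling_baseline  SMART    Q       0.960     15  5.2e-08
partial_gain_controlling_motion    SMART    Q       0.633     15  0.015
```

and `results42/anova.tsv`:

```
instrument  F      df1  df2  p      eta_p2
TOSL        5.42   1    27   0.028  0.167
```

Read: in this simulated cohort the trained (SMART) group's baseline
whole-brain modularity correlates with its training gain (ρ = 0.69,
n = 15, BCa CI excludes zero) while the wait-list control group's does not
(ρ = 0.18) — the planted dissociation, recovered end to end.  The ANOVA row
is the group × time interaction on the cognitive score.  `metrics.tsv` holds
the underlying per-subject, per-density network metrics, and
`provenance.json` records the config hash and seed that produced them.

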