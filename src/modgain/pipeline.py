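"""End-to-end orchestration: time series in, tidy metric and statistics tables out.

Stages, matching the analysis design:

1. listwise node exclusion across the cohort;
2. Fisher-z connectivity per subject;
3. density sweep (top 2-10% of connections in 2% steps by default) and
   fixed-partition modularity per density, whole-brain and per module, with
   sensory-motor / association group means; optional subject-specific
   spectral modules; threshold aggregates (mean and trapezoidal integral);
4. segregation on the unthresholded matrices under the requested sign
   variant;
5. statistics: gain scores, per-group Spearman correlations of each baseline
   metric with gain (BCa bootstrap CIs on the headline metrics), partial
   correlations controlling baseline score and motion, between-group
   comparison of correlations, the 2x2 mixed ANOVA, and group matching tests.

The pipeline is a pure function of (inputs, config, seed); result tables are
byte-identical across re-runs.  The metrics stage is cached on a content hash
of its inputs so statistics-only config changes do not recompute graphs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .graph_construction import (
    DEFAULT_DENSITIES,
    ConnectivityMatrix,
    ROITimeSeries,
    compute_connectivity,
    exclude_missing_nodes,
    threshold_by_density,
)
from .network_metrics import (
    ModulePartition,
    aggregate_over_densities,
    modularity_fixed_partition,
    module_segregation,
    spectral_partition,
    subnetwork_modularity,
)
from .training_stats import (
    CohortTable,
    bca_ci,
    compare_independent_correlations,
    gain,
    group_baseline_tests,
    mixed_anova_2x2,
    partial_pearson,
    spearman,
)
from . import io as mio

__all__ = ["RunConfig", "run_pipeline", "compute_metrics", "mean_adjacency_visual"]

SEG_VARIANTS = ("all", "positive", "absolute")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (serialisable to/from YAML)."""

    run_dir: str = "."
    out_dir: str = "results"
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    aggregate: str = "mean"  # "mean" or "integrate"
    clustering: str = "fixed"  # "fixed", "spectral", "both"
    segregation_variant: str = "all"
    ranking: str = "signed"
    bootstrap_B: int = 2000
    seed: int = 0
    analyses: tuple[str, ...] = ("metrics", "stats")

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.densities)
        if not d or any(not 0 < x <= 1 for x in d) or any(np.diff(d) <= 0):
            raise ValueError("densities must be strictly increasing in (0, 1]")
        self.densities = d
        if self.bootstrap_B < 200:
            raise ValueError("bootstrap_B must be at least 200")
        if self.aggregate not in ("mean", "integrate"):
            raise ValueError(f"unknown aggregate mode {self.aggregate!r}")
        if self.clustering not in ("fixed", "spectral", "both"):
            raise ValueError(f"unknown clustering {self.clustering!r}")
        if self.segregation_variant not in SEG_VARIANTS:
            raise ValueError(f"unknown segregation variant {self.segregation_variant!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**d)

    def content_hash(self) -> str:
        keys = {
            "densities": list(self.densities),
            "clustering": self.clustering,
            "ranking": self.ranking,
        }
        return hashlib.sha256(json.dumps(keys, sort_keys=True).encode()).hexdigest()[:12]


def _subject_metric_rows(
    cm: ConnectivityMatrix,
    partition: ModulePartition,
    cfg: RunConfig,
) -> list[dict]:
    rows: list[dict] = []
    sid = cm.subject_id

    def add(metric, scope, density, value, variant=""):
        rows.append(
            dict(subject=sid, metric=metric, scope=scope,
                 density=str(density), variant=variant, value=float(value))
        )

    whole: dict[float, float] = {}
    groups: dict[str, dict[float, float]] = {"sensory-motor": {}, "association": {}}
    per_mod: dict[str, dict[float, float]] = {m: {} for m in partition.modules}
    spectral: dict[float, float] = {}
    for d in cfg.densities:
        g = threshold_by_density(cm, d, ranking=cfg.ranking)
        if cfg.clustering in ("fixed", "both"):
            prof = modularity_fixed_partition(g, partition)
            whole[d] = prof.Q
            add("Q", "whole-brain", d, prof.Q)
            for m, st in prof.per_module.items():
                per_mod[m][d] = st.q_i
                add("q_module", m, d, st.q_i)
            for grp in ("sensory-motor", "association"):
                if partition.modules_in_group(grp):
                    v = subnetwork_modularity(prof, partition, grp)
                    groups[grp][d] = v
                    add("q_group", grp, d, v)
        if cfg.clustering in ("spectral", "both"):
            _, Qs = spectral_partition(g)
            spectral[d] = Qs
            add("Q_spectral", "whole-brain", d, Qs)
    for agg in ("mean", "integrate"):
        if len(cfg.densities) < 2 and agg == "integrate":
            continue
        if whole:
            add("Q", "whole-brain", agg, aggregate_over_densities(whole, agg))
            for grp, vals in groups.items():
                if vals:
                    add("q_group", grp, agg, aggregate_over_densities(vals, agg))
            for m, vals in per_mod.items():
                if vals:
                    add("q_module", m, agg, aggregate_over_densities(vals, agg))
        if spectral:
            add("Q_spectral", "whole-brain", agg,
                aggregate_over_densities(spectral, agg))

    for variant in SEG_VARIANTS:
        seg = module_segregation(cm, partition, variant=variant)
        add("segregation", "whole-brain", "unthresholded", seg.whole_brain, variant)
        for grp, v in seg.group_means.items():
            add("segregation", grp, "unthresholded", v, variant)
        for m, (_, _, s) in seg.per_module.items():
            add("segregation", m, "unthresholded", s, variant)
    return rows


def compute_metrics(
    ts_list: list[ROITimeSeries],
    partition: ModulePartition,
    cfg: RunConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Exclusion + connectivity + network metrics for a whole cohort.

    Returns the long-format metric table (subject, metric, scope, density,
    variant, value) and the list of excluded node ids.
    """
    cohort_ts, excluded = exclude_missing_nodes(ts_list)
    part = partition.restrict(cohort_ts[0].node_ids)
    rows: list[dict] = []
    for ts in cohort_ts:
        cm = compute_connectivity(ts)
        rows.extend(_subject_metric_rows(cm, part, cfg))
    return pd.DataFrame(rows), excluded


def _metric_wide(metrics: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Per-subject columns of the headline baseline metrics."""
    agg = cfg.aggregate if len(cfg.densities) > 1 else "mean"
    sel = {
        "Q": ("Q", "whole-brain", agg, ""),
        "Q_sensorimotor": ("q_group", "sensory-motor", agg, ""),
        "Q_association": ("q_group", "association", agg, ""),
        "segregation": ("segregation", "whole-brain", "unthresholded",
                        cfg.segregation_variant),
        "segregation_sensorimotor": ("segregation", "sensory-motor",
                                     "unthresholded", cfg.segregation_variant),
        "segregation_association": ("segregation", "association",
                                    "unthresholded", cfg.segregation_variant),
        "Q_spectral": ("Q_spectral", "whole-brain", agg, ""),
    }
    out = {}
    for name, (metric, scope, density, variant) in sel.items():
        sub = metrics[
            (metrics["metric"] == metric)
            & (metrics["scope"] == scope)
            & (metrics["density"] == density)
            & (metrics["variant"] == variant)
        ]
        if not sub.empty:
            out[name] = sub.set_index("subject")["value"]
    return pd.DataFrame(out)


def run_stats(
    metrics: pd.DataFrame,
    cohort: CohortTable,
    cfg: RunConfig,
    instrument: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Correlation, partial-correlation, comparison and ANOVA tables."""
    instrument = instrument or cohort.instruments[0]
    wide = _metric_wide(metrics, cfg)
    sub = cohort.rows(instrument).drop_duplicates("subject_id").set_index("subject_id")
    g = gain(cohort, instrument)
    data = wide.join(sub[["group", "score_pre", "fd"]], how="inner")
    data["gain"] = g

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    corr_rows, groups_res = [], {}
    for metric in wide.columns:
        per_group = {}
        for grp in ("Control", "SMART"):
            d = data[data["group"] == grp]
            res = spearman(d[metric], d["gain"])
            ci = bca_ci(
                d[metric].to_numpy(), d["gain"].to_numpy(),
                statistic="spearman", B=cfg.bootstrap_B, rng=rng,
            )
            per_group[grp] = res
            corr_rows.append(
                dict(analysis="spearman_gain", group=grp, metric=metric,
                     estimate=res.estimate, n=res.n, df=res.df, p=res.p,
                     ci_lo=ci[0], ci_hi=ci[1])
            )
        p_cmp = compare_independent_correlations(per_group["SMART"],
                                                 per_group["Control"])
        corr_rows.append(
            dict(analysis="group_comparison", group="SMART-vs-Control",
                 metric=metric, estimate=np.nan,
                 n=per_group["SMART"].n + per_group["Control"].n,
                 df=np.nan, p=p_cmp, ci_lo=np.nan, ci_hi=np.nan)
        )
        groups_res[metric] = per_group

    headline = "Q" if "Q" in wide.columns else wide.columns[0]
    for control_name, col in (("baseline", "score_pre"), ("motion", "fd")):
        for grp in ("Control", "SMART"):
            d = data[data["group"] == grp]
            res = partial_pearson(d[headline], d["gain"], d[col].to_numpy()[None, :])
            corr_rows.append(
                dict(analysis=f"partial_gain_controlling_{control_name}",
                     group=grp, metric=headline, estimate=res.estimate, n=res.n,
                     df=res.df, p=res.p, ci_lo=np.nan, ci_hi=np.nan)
            )

    baseline_rows = []
    aov = mixed_anova_2x2(cohort, instrument)
    anova_df = pd.DataFrame(
        [dict(instrument=instrument, F=aov.F, df1=aov.df[0], df2=aov.df[1],
              p=aov.p, eta_p2=aov.eta_p2)]
    )
    for var in ("score_pre", "fd"):
        stat, dfree, p = group_baseline_tests(
            CohortTable(cohort.rows(instrument)), var, kind="continuous"
        )
        baseline_rows.append(dict(analysis="group_matching", variable=var,
                                  statistic=stat, df=dfree, p=p))

    return {
        "correlations": pd.DataFrame(corr_rows),
        "anova": anova_df,
        "matching": pd.DataFrame(baseline_rows),
    }


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all configured stages; returns the output directory.

    Writes ``metrics.tsv``, ``correlations.tsv``, ``anova.tsv``,
    ``matching.tsv``, ``excluded_nodes.txt`` and ``provenance.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        ts_list, cohort, partition = mio.read_run_dir(cfg.run_dir)
    except Exception as err:  # noqa: BLE001 - surface the failing stage
        raise RuntimeError(f"stage 'load': {err}") from err

    cache = out / f"metrics-{_inputs_hash(cfg)}.tsv"
    if cache.exists():
        metrics = pd.read_csv(cache, sep="\t", keep_default_na=False,
                              dtype={"density": str, "variant": str})
        excluded: list[str] = _read_excluded(out)
    else:
        try:
            metrics, excluded = compute_metrics(ts_list, partition, cfg)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"stage 'metrics': {err}") from err
        metrics.to_csv(cache, sep="\t", index=False, float_format="%.12g")
        (out / "excluded_nodes.txt").write_text("\n".join(excluded) + "\n")
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.12g")

    if "stats" in cfg.analyses:
        try:
            tables = run_stats(metrics, cohort, cfg)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"stage 'stats': {err}") from err
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.12g")

    prov = {
        "package": "modgain",
        "version": __version__,
        "config": _jsonable(asdict(cfg)),
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "bootstrap_B": cfg.bootstrap_B,
        "n_subjects": len(ts_list),
        "excluded_nodes": excluded,
        "numpy": np.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=2) + "\n")
    return out


def _jsonable(d):
    if isinstance(d, dict):
        return {k: _jsonable(v) for k, v in d.items()}
    if isinstance(d, (list, tuple)):
        return [_jsonable(v) for v in d]
    return d


def _read_excluded(out: Path) -> list[str]:
    f = out / "excluded_nodes.txt"
    if not f.exists():
        return []
    return [x for x in f.read_text().splitlines() if x]


def _inputs_hash(cfg: RunConfig) -> str:
    h = hashlib.sha256(cfg.content_hash().encode())
    run = Path(cfg.run_dir)
    for f in sorted((run / "timeseries").glob("*.tsv")) + [run / "partition.tsv"]:
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()[:12]


def mean_adjacency_visual(
    cm: ConnectivityMatrix,
    densities: tuple[float, ...] = DEFAULT_DENSITIES,
    ranking: str = "signed",
) -> np.ndarray:
    """Edge persistence across the density sweep, in [0, 1].

    Entrywise mean of the binary adjacency matrices over thresholds: 1 means
    the connection survives every threshold, 0 none.  Used for visualising a
    subject's module structure without privileging one density.
    """
    if not densities:
        raise ValueError("need at least one density")
    acc = np.zeros((cm.n_nodes, cm.n_nodes))
    for d in densities:
        acc += threshold_by_density(cm, d, ranking=ranking).adjacency
    return acc / len(densities)


def plot_mean_adjacency(
    mean_adj: np.ndarray,
    partition: ModulePartition,
    node_ids: list[str],
    path: str | Path,
) -> None:
    """Heatmap of edge persistence with nodes sorted by module."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = partition.labels_for(node_ids)
    order = np.argsort(labels, kind="stable")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mean_adj[np.ix_(order, order)], vmin=0, vmax=1, cmap="viridis")
    bounds = np.flatnonzero(np.diff(labels[order])) + 0.5
    for b in bounds:
        ax.axhline(b, color="w", lw=0.5)
        ax.axvline(b, color="w", lw=0.5)
    fig.colorbar(im, ax=ax, label="proportion of thresholds with edge")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
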