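"""Statistics linking baseline network metrics to cognitive-training gains.

The analyses mirror a pre/post two-group training design:

* gain scores (post - pre) per instrument;
* Spearman rank correlations (small samples, robust to extreme values), with
  two-sided p from the t-approximation on n - 2 df;
* partial Pearson correlations controlling nuisance covariates (baseline
  score, in-scanner motion) by residual regression;
* 95% bias-corrected and accelerated (BCa) bootstrap confidence intervals,
  resampling subjects in pairs;
* comparison of two independent correlations: Spearman estimates are first
  converted to Pearson scale by r = 2 sin(pi * rho / 6), then Fisher
  z-transformed and compared with a normal test;
* 2 (group) x 2 (time) mixed ANOVA with partial eta-squared; its interaction
  F equals the squared pooled-variance t on gain scores, an identity this
  module asserts on every call;
* group matching tests (two-sample t, 2x2 chi-square).

All p-values are two-sided and uncorrected for multiple comparisons; callers
running many correlations should keep that in mind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "CohortTable",
    "CorrelationResult",
    "AnovaResult",
    "gain",
    "spearman",
    "partial_pearson",
    "bca_ci",
    "spearman_to_pearson",
    "compare_independent_correlations",
    "mixed_anova_2x2",
    "group_baseline_tests",
]

GROUPS = ("Control", "SMART")


@dataclass
class CorrelationResult:
    estimate: float
    n: int
    df: int
    p: float
    kind: str  # "spearman" or "partial-pearson"
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.estimate <= 1.0:
            raise ValueError("correlation estimate outside [-1, 1]")
        if self.ci is not None:
            lo, hi = self.ci
            if not (-1.0 - 1e-12 <= lo <= hi <= 1.0 + 1e-12):
                raise ValueError("CI bounds must be ordered and within [-1, 1]")


@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    eta_p2: float


class CohortTable:
    """Per-subject table: group, pre/post scores per instrument, covariates.

    Wraps a long-format DataFrame with columns ``subject_id``, ``group``
    (Control/SMART), ``instrument``, ``score_pre``, ``score_post`` plus any
    covariate columns (``fd``, network metrics, ...).  Gains are always
    derived as post - pre, never stored.
    """

    REQUIRED = ("subject_id", "group", "instrument", "score_pre", "score_post")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns {missing}")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    @property
    def instruments(self) -> list[str]:
        return sorted(self.df["instrument"].unique())

    def rows(self, instrument: str) -> pd.DataFrame:
        sub = self.df[self.df["instrument"] == instrument]
        if sub.empty:
            raise ValueError(f"no rows for instrument {instrument!r}")
        return sub

    def subjects(self, group: str | None = None) -> list[str]:
        df = self.df if group is None else self.df[self.df["group"] == group]
        return sorted(df["subject_id"].unique())


def gain(ct: CohortTable, instrument: str) -> pd.Series:
    """Per-subject gain = score_post - score_pre (improvement positive)."""
    sub = ct.rows(instrument)
    for col in ("score_pre", "score_post"):
        bad = sub.loc[sub[col].isna(), "subject_id"].tolist()
        if bad:
            raise ValueError(f"missing {col} for subjects {bad}")
    g = sub["score_post"] - sub["score_pre"]
    g.index = pd.Index(sub["subject_id"], name="subject_id")
    return g


def _check_pair(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    return x, y


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p from the t-approximation on n - 2 df (scipy's default),
    matching df-style reporting such as rho(13) for n = 15.
    """
    x, y = _check_pair(x, y, 4)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    n = len(x)
    if abs(rho) == 1.0:
        p = 0.0  # scipy returns nan at the boundary of the t-approximation
    return CorrelationResult(estimate=float(rho), n=n, df=n - 2, p=float(p),
                             kind="spearman")


def spearman_permutation_p(x, y, n_perm: int = 10000, rng=None) -> float:
    """Seeded permutation p-value for the Spearman estimate (two-sided)."""
    x, y = _check_pair(x, y, 4)
    rng = np.random.default_rng(rng)
    obs = abs(stats.spearmanr(x, y).statistic)
    count = 0
    for _ in range(n_perm):
        count += abs(stats.spearmanr(x, rng.permutation(y)).statistic) >= obs - 1e-12
    return (count + 1) / (n_perm + 1)


def partial_pearson(x, y, controls, use_ranks: bool = False) -> CorrelationResult:
    """Pearson correlation of x and y after regressing out control covariates.

    Both x and y are residualised on the controls (plus an intercept) by least
    squares; the correlation of the residuals is tested on n - 2 - k df, k the
    number of controls.  ``use_ranks=True`` rank-transforms everything first
    (a Spearman-flavoured partial correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.asarray(controls, dtype=float))
    if C.shape[0] == len(x) and C.ndim == 2 and C.shape[1] != len(x):
        C = C.T  # accept (n, k) or (k, n)
    k = C.shape[0]
    n = len(x)
    if y.shape != x.shape or C.shape[1] != n:
        raise ValueError("x, y and controls must share the sample dimension")
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} for {k} controls, got n = {n}")
    if use_ranks:
        x = stats.rankdata(x)
        y = stats.rankdata(y)
        C = np.apply_along_axis(stats.rankdata, 1, C)
    X = np.column_stack([np.ones(n), C.T])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear controls; design matrix is rank-deficient")
    beta_x, *_ = np.linalg.lstsq(X, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    rx = x - X @ beta_x
    ry = y - X @ beta_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is fully explained by the controls")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(estimate=r, n=n, df=df, p=p, kind="partial-pearson")


# ---------------------------------------------------------------------------
# BCa bootstrap

def _rowwise_rank_corr(xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Spearman rho per row of paired (B, n) resample arrays."""
    rx = stats.rankdata(xb, axis=1)
    ry = stats.rankdata(yb, axis=1)
    return _rowwise_pearson(rx, ry)


def _rowwise_pearson(xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


_STATS = {"spearman": _rowwise_rank_corr, "pearson": _rowwise_pearson}


def _bca_interval(
    theta_hat: float,
    boot: np.ndarray,
    jack: np.ndarray,
    level: float,
) -> tuple[float, float]:
    """BCa endpoints from a bootstrap distribution and jackknife replicates.

    Bias correction z0 comes from the fraction of bootstrap replicates below
    the point estimate; acceleration a from the skewness of the jackknife
    influence values.  With z0 = 0 and a = 0 this reduces to the percentile
    interval.
    """
    alpha = (1.0 - level) / 2.0
    if np.ptp(boot) == 0:  # degenerate: every resample gives the same value
        return float(boot[0]), float(boot[0])
    prop = np.mean(boot < theta_hat)
    prop = min(max(prop, 1.0 / (len(boot) + 1)), 1.0 - 1.0 / (len(boot) + 1))
    z0 = stats.norm.ppf(prop)
    d = jack.mean() - jack
    denom = 6.0 * (np.sum(d**2)) ** 1.5
    a = float(np.sum(d**3) / denom) if denom > 0 else 0.0
    out = []
    for za in (stats.norm.ppf(alpha), stats.norm.ppf(1.0 - alpha)):
        adj = stats.norm.cdf(z0 + (z0 + za) / (1.0 - a * (z0 + za)))
        out.append(float(np.quantile(boot, adj)))
    return out[0], out[1]


def bca_ci(
    x,
    y,
    statistic: str = "spearman",
    B: int = 2000,
    level: float = 0.95,
    rng=None,
    max_redraw_rounds: int = 100,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI for a paired correlation.

    Subjects are resampled with replacement in (x, y) pairs; ``B`` bootstrap
    replicates feed the bias correction, a leave-one-out jackknife feeds the
    acceleration.  Resamples in which x or y collapses to a constant (the
    statistic is undefined there) are redrawn, up to ``max_redraw_rounds``
    rounds.  Reproducible for a fixed seed.
    """
    x, y = _check_pair(x, y, 5)
    if B < 200:
        raise ValueError("B must be at least 200")
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    stat = _STATS[statistic]
    rng = np.random.default_rng(rng)
    n = len(x)
    theta_hat = float(stat(x[None, :], y[None, :])[0])

    idx = rng.integers(0, n, size=(B, n))
    xb, yb = x[idx], y[idx]
    for _ in range(max_redraw_rounds):
        degen = (np.ptp(xb, axis=1) == 0) | (np.ptp(yb, axis=1) == 0)
        if not degen.any():
            break
        redo = rng.integers(0, n, size=(int(degen.sum()), n))
        xb[degen], yb[degen] = x[redo], y[redo]
    else:
        raise ValueError("could not draw non-degenerate resamples")
    boot = stat(xb, yb)

    jack_idx = np.array([np.delete(np.arange(n), i) for i in range(n)])
    jx, jy = x[jack_idx], y[jack_idx]
    if np.any(np.ptp(jx, axis=1) == 0) or np.any(np.ptp(jy, axis=1) == 0):
        raise ValueError("jackknife resample degenerate; data nearly constant")
    jack = stat(jx, jy)

    lo, hi = _bca_interval(theta_hat, boot, jack, level)
    lo = float(np.clip(lo, -1.0, 1.0))
    hi = float(np.clip(hi, -1.0, 1.0))
    return lo, hi


# ---------------------------------------------------------------------------
# comparing correlations between independent groups

def spearman_to_pearson(rho: float) -> float:
    """Convert a Spearman rho to the Pearson scale: r = 2 sin(pi * rho / 6).

    Exact for bivariate normal data; maps 0 -> 0 and +/-1 -> +/-1.
    """
    return float(2.0 * np.sin(np.pi * rho / 6.0))


def compare_independent_correlations(
    r1: CorrelationResult, r2: CorrelationResult
) -> float:
    """Two-sided p for the difference of two independent correlations.

    Spearman estimates are first moved to the Pearson scale via
    ``spearman_to_pearson``; both are Fisher z-transformed and compared with
    z = (z1 - z2) / sqrt(1/(n1-3) + 1/(n2-3)) against the standard normal.
    """
    vals = []
    for res in (r1, r2):
        r = res.estimate
        if abs(r) >= 1.0:
            raise ValueError("cannot compare a correlation of magnitude 1")
        if res.kind == "spearman":
            r = spearman_to_pearson(r)
        if abs(r) >= 1.0:
            raise ValueError("cannot compare a correlation of magnitude 1")
        if res.n < 4:
            raise ValueError("need n >= 4 in both groups")
        vals.append((np.arctanh(r), res.n))
    (z1, n1), (z2, n2) = vals
    z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z)))


def mixed_anova_2x2(ct: CohortTable, instrument: str) -> AnovaResult:
    """Group x time interaction from a 2x2 mixed ANOVA on pre/post scores.

    Reports the interaction F on (1, N - 2) df with partial eta-squared.  The
    interaction F is algebraically the square of the pooled-variance
    independent-samples t on gain scores; the identity is asserted here as a
    numerical cross-check on every call.
    """
    sub = ct.rows(instrument)
    for grp in GROUPS:
        if (sub["group"] == grp).sum() < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 subjects")
    long = pd.melt(
        sub,
        id_vars=["subject_id", "group"],
        value_vars=["score_pre", "score_post"],
        var_name="time",
        value_name="score",
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        aov = pg.mixed_anova(
            data=long, dv="score", within="time", between="group",
            subject="subject_id",
        )
    row = aov[aov["Source"] == "Interaction"].iloc[0]
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    F, p, np2 = float(row["F"]), float(row[p_col]), float(row["np2"])
    if not np.isfinite(F) and float(row["SS"]) == 0.0:
        # no interaction and no subject-by-time variance at all: F is 0/0
        F, p, np2 = 0.0, 1.0, 0.0
    res = AnovaResult(F=F, df=(int(row["DF1"]), int(row["DF2"])), p=p, eta_p2=np2)
    g = sub["score_post"] - sub["score_pre"]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = stats.ttest_ind(
            g[sub["group"] == GROUPS[1]], g[sub["group"] == GROUPS[0]],
            equal_var=True,
        ).statistic
    t2 = 0.0 if not np.isfinite(t) and F == 0.0 else t**2
    if not np.isclose(F, t2, rtol=1e-9, atol=1e-9):
        raise AssertionError(
            f"interaction F = {F} violates the t^2 identity (t^2 = {t2})"
        )
    return res


def group_baseline_tests(ct: CohortTable, variable: str, kind: str = "continuous"):
    """Group matching test at baseline: pooled t (continuous) or 2x2 chi-square.

    ``variable`` names a column of the cohort table (or ``"score_pre"`` of an
    instrument via ``rows``).  Returns ``(statistic, df, p)``.  The chi-square
    uses no continuity correction.
    """
    df = ct.df.drop_duplicates("subject_id")
    if variable not in df.columns:
        raise ValueError(f"unknown variable {variable!r}")
    a = df.loc[df["group"] == GROUPS[0], variable]
    b = df.loc[df["group"] == GROUPS[1], variable]
    if kind == "continuous":
        res = stats.ttest_ind(a, b, equal_var=True)
        return float(res.statistic), len(a) + len(b) - 2, float(res.pvalue)
    if kind == "categorical":
        table = pd.crosstab(df["group"], df[variable]).to_numpy()
        if table.shape != (2, 2):
            raise ValueError("categorical matching test expects a 2x2 table")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("empty margin; expected counts of zero")
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), int(dof), float(p)
    raise ValueError(f"unknown test kind {kind!r}")
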