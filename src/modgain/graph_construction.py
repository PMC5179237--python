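"""Per-subject ROI time series -> Fisher-z connectivity -> density-thresholded graphs.

The entry point of the pipeline is a node x timepoint matrix of BOLD signal
averaged within each region of interest (ROI).  Pairwise Pearson correlations
between node time series are variance-stabilised with the Fisher z-transform
(atanh).  Binary, undirected graphs are then obtained by keeping only the top
fraction of node pairs by connection strength ("proportional density
thresholding"), the standard construction in resting-state graph analysis.

Conventions fixed here and relied on downstream:

* the diagonal of a connectivity matrix is never an edge; it is stored as NaN;
* thresholding ranks *signed* z values (most positive first) by default, with
  an ``ranking="absolute"`` option;
* the edge count at density ``d`` is ``floor(d * P)`` with ``P = n(n-1)/2``;
* ties at the cutoff are broken by lexicographic node-pair order, so output is
  deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ROITimeSeries",
    "ConnectivityMatrix",
    "BinaryGraph",
    "default_missing_rule",
    "exclude_missing_nodes",
    "compute_connectivity",
    "threshold_by_density",
]

#: correlations of exactly +/-1 are clipped to +/-(1 - R_CLIP) before atanh
R_CLIP = 1e-7


@dataclass
class ROITimeSeries:
    """BOLD time series for one subject, one row per node.

    Parameters
    ----------
    subject_id : str
        Opaque subject label.
    data : ndarray, shape (n_nodes, n_timepoints)
        Signal in arbitrary units.
    node_ids : sequence of str
        Unique node labels aligned with the rows of ``data``.
    """

    subject_id: str
    data: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (nodes x timepoints)")
        if not self.node_ids:
            self.node_ids = [str(i + 1) for i in range(self.data.shape[0])]
        self.node_ids = [str(n) for n in self.node_ids]
        if len(self.node_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.node_ids)} node ids for {self.data.shape[0]} rows"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 timepoints per node")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def subset(self, keep: Sequence[str]) -> "ROITimeSeries":
        """Return a copy restricted to ``keep`` (original node order preserved)."""
        keep_set = set(keep)
        idx = [i for i, n in enumerate(self.node_ids) if n in keep_set]
        return ROITimeSeries(
            subject_id=self.subject_id,
            data=self.data[idx].copy(),
            node_ids=[self.node_ids[i] for i in idx],
        )


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node Fisher-z correlation matrix; diagonal stored as NaN."""

    z: np.ndarray
    node_ids: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if len(self.node_ids) != n:
            raise ValueError("node_ids length must match matrix size")
        off = self.z[~np.eye(n, dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal entries must be finite")
        if not np.allclose(self.z, self.z.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph at one connection density."""

    adjacency: np.ndarray
    density: float
    node_ids: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = self.adjacency.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[str, str]]:
        """Edges as (node_i, node_j) label pairs with i < j in node order."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu, ju] == 1
        return [
            (self.node_ids[i], self.node_ids[j])
            for i, j in zip(iu[mask], ju[mask])
        ]


def default_missing_rule(ts: ROITimeSeries) -> np.ndarray:
    """Flag nodes with zero variance or any non-finite sample.

    This operationalises "missing coverage": a region outside the field of
    view yields a constant (usually zero) or undefined series after averaging.
    Returns a boolean mask over nodes (True = flagged).
    """
    nonfinite = ~np.isfinite(ts.data).all(axis=1)
    with np.errstate(invalid="ignore"):
        # range, not std: a constant series must flag exactly, without float fuzz
        novar = np.ptp(np.nan_to_num(ts.data), axis=1) == 0
    return nonfinite | novar


def exclude_missing_nodes(
    cohort: Sequence[ROITimeSeries],
    rule: Callable[[ROITimeSeries], np.ndarray] = default_missing_rule,
) -> tuple[list[ROITimeSeries], list[str]]:
    """Drop, for *every* subject, any node that fails ``rule`` in *any* subject.

    Cohort-level analyses with a fixed node partition require all subjects to
    share one node set, so coverage failures are excluded listwise.  Node order
    of survivors is preserved.

    Returns ``(reduced cohort, excluded node ids)``; raises ``ValueError`` if
    subjects disagree on the node set or no node survives.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    ref = cohort[0].node_ids
    for ts in cohort[1:]:
        if ts.node_ids != ref:
            raise ValueError(
                f"subject {ts.subject_id!r} has a different node set than "
                f"subject {cohort[0].subject_id!r}"
            )
    flagged = np.zeros(len(ref), dtype=bool)
    for ts in cohort:
        flagged |= rule(ts)
    excluded = [n for n, f in zip(ref, flagged) if f]
    if len(excluded) == len(ref):
        raise ValueError(
            f"all {len(ref)} nodes excluded by rule {getattr(rule, '__name__', rule)!r}"
        )
    keep = [n for n in ref if n not in set(excluded)]
    return [ts.subset(keep) for ts in cohort], excluded


def compute_connectivity(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson-correlate every node pair and Fisher z-transform the result.

    ``z[i, j] = atanh(r_ij)`` for i != j; perfect correlations are clipped to
    +/-(1 - 1e-7) so z stays finite.  The diagonal is set to NaN and is never
    treated as an edge downstream.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints to correlate")
    if not np.isfinite(ts.data).all():
        bad = [ts.node_ids[i] for i in np.where(~np.isfinite(ts.data).all(axis=1))[0]]
        raise ValueError(f"non-finite samples in nodes {bad}")
    spread = np.ptp(ts.data, axis=1)
    if np.any(spread == 0):
        bad = [ts.node_ids[i] for i in np.where(spread == 0)[0]]
        raise ValueError(f"zero-variance nodes {bad}; exclude before correlating")
    r = np.corrcoef(ts.data)
    r = np.clip(r, -1.0 + R_CLIP, 1.0 - R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # corrcoef is symmetric up to float noise; make exact
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z=z, node_ids=list(ts.node_ids), subject_id=ts.subject_id)


def _ranked_pairs(cm: ConnectivityMatrix, ranking: str) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pair indices sorted strongest-first, ties lexicographic."""
    iu, ju = np.triu_indices(cm.n_nodes, k=1)
    vals = cm.z[iu, ju]
    if ranking == "absolute":
        vals = np.abs(vals)
    elif ranking != "signed":
        raise ValueError(f"unknown ranking {ranking!r}")
    # lexsort: last key is primary -> sort by -value, then i, then j
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def threshold_by_density(
    cm: ConnectivityMatrix, density: float, ranking: str = "signed"
) -> BinaryGraph:
    """Binarise a connectivity matrix at a proportional connection density.

    The ``floor(density * P)`` strongest node pairs (``P = n(n-1)/2``) become
    edges.  ``ranking="signed"`` (default) takes the most positive z first;
    ``ranking="absolute"`` ranks by magnitude.

    Raises ``ValueError`` if the density yields zero edges.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    n = cm.n_nodes
    n_pairs = n * (n - 1) // 2
    n_edges = int(np.floor(density * n_pairs))
    if n_edges == 0:
        raise ValueError(
            f"density {density} retains 0 of {n_pairs} pairs; increase density"
        )
    iu, ju = _ranked_pairs(cm, ranking)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[:n_edges], ju[:n_edges]] = 1
    adj += adj.T
    return BinaryGraph(
        adjacency=adj, density=density, node_ids=list(cm.node_ids),
        subject_id=cm.subject_id,
    )


#: the density sweep used throughout: top 2-10% of connections in 2% steps
DEFAULT_DENSITIES: tuple[float, ...] = (0.02, 0.04, 0.06, 0.08, 0.10)
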