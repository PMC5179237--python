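"""Modularity (fixed partition and spectral) and module segregation.

Whole-brain modularity of a binary graph under a node partition is

    Q = sum_i (e_ii - a_i^2)

where ``e_ii`` is the fraction of edges with both endpoints in module *i* and
``a_i`` is the fraction of edge *ends* attached to module *i* (so
``sum_i a_i = 1``).  ``q_i = e_ii - a_i^2`` is the per-module contribution;
sub-network ("sensory-motor" vs "association cortex") modularity is the
unweighted mean of ``q_i`` over the modules in a group.

Segregation works on the *unthresholded* Fisher-z matrix:

    S_i = (Zw_i - Zb_i) / Zw_i

with ``Zw_i`` the mean z over within-module node pairs and ``Zb_i`` the mean z
over pairs linking module *i* to any other module.  ``S = 1`` means no
between-module connectivity; ``S = 0`` means within equals between.  Sign
handling comes in three variants: use z as-is, drop negative z, or take |z|.

The spectral alternative is Newman's leading-eigenvector modularity
maximisation: recursive bisection on the (generalised) modularity matrix with
a Kernighan-Lin-style refinement of each split, stopping when no split
increases Q.  The whole procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_construction import BinaryGraph, ConnectivityMatrix

__all__ = [
    "SENSORY_MOTOR_MODULES",
    "ASSOCIATION_MODULES",
    "ModulePartition",
    "ModuleStats",
    "ModularityProfile",
    "SegregationProfile",
    "modularity_fixed_partition",
    "spectral_partition",
    "subnetwork_modularity",
    "module_segregation",
    "aggregate_over_densities",
]

# Module-to-group scheme for the 264-ROI functional atlas: primary
# sensory/motor systems vs higher-order "association cortex" systems.
SENSORY_MOTOR_MODULES = (
    "auditory",
    "somatomotor-hand",
    "somatomotor-mouth",
    "visual",
)
ASSOCIATION_MODULES = (
    "cingulo-opercular",
    "default mode",
    "dorsal attention",
    "fronto-parietal",
    "salience",
    "ventral attention",
)


@dataclass
class ModulePartition:
    """A node -> module assignment plus a module -> group classification.

    ``group_of`` maps each module label to ``"sensory-motor"``,
    ``"association"`` or ``"other"``; modules absent from ``group_of``
    default to ``"other"``.
    """

    assignment: dict[str, str]
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("empty partition")
        for mod, grp in self.group_of.items():
            if grp not in ("sensory-motor", "association", "other"):
                raise ValueError(f"unknown group {grp!r} for module {mod!r}")

    @property
    def modules(self) -> list[str]:
        """Module labels in order of first appearance over nodes."""
        seen: dict[str, None] = {}
        for m in self.assignment.values():
            seen.setdefault(m)
        return list(seen)

    @property
    def m(self) -> int:
        return len(self.modules)

    def group(self, module: str) -> str:
        return self.group_of.get(module, "other")

    def modules_in_group(self, group: str) -> list[str]:
        return [m for m in self.modules if self.group(m) == group]

    def labels_for(self, node_ids: list[str]) -> np.ndarray:
        """Integer module index per node, aligned to ``node_ids``.

        Raises ``KeyError`` naming the first node missing from the partition.
        """
        index = {m: k for k, m in enumerate(self.modules)}
        out = np.empty(len(node_ids), dtype=int)
        for i, n in enumerate(node_ids):
            if n not in self.assignment:
                raise KeyError(f"node {n!r} missing from partition")
            out[i] = index[self.assignment[n]]
        return out

    def restrict(self, node_ids: list[str]) -> "ModulePartition":
        """Partition restricted to ``node_ids`` (e.g. after node exclusion)."""
        sub = {n: self.assignment[n] for n in node_ids}
        return ModulePartition(assignment=sub, group_of=dict(self.group_of))

    @classmethod
    def from_labels(
        cls,
        node_ids: list[str],
        labels: list[str] | np.ndarray,
        group_of: dict[str, str] | None = None,
    ) -> "ModulePartition":
        return cls(
            assignment={n: str(l) for n, l in zip(node_ids, labels)},
            group_of=dict(group_of or {}),
        )


@dataclass
class ModuleStats:
    """Per-module edge fractions at one density: e_ii, a_i and q_i = e_ii - a_i^2."""

    e_ii: float
    a_i: float

    @property
    def q_i(self) -> float:
        return self.e_ii - self.a_i**2


@dataclass
class ModularityProfile:
    """Fixed-partition modularity decomposition at one connection density."""

    density: float
    per_module: dict[str, ModuleStats]
    Q: float

    def q_values(self, modules: list[str] | None = None) -> np.ndarray:
        mods = modules if modules is not None else list(self.per_module)
        return np.array([self.per_module[m].q_i for m in mods])


@dataclass
class SegregationProfile:
    """Per-module segregation S = (Zw - Zb)/Zw from the unthresholded matrix."""

    variant: str
    per_module: dict[str, tuple[float, float, float]]  # module -> (Zw, Zb, S)
    whole_brain: float
    group_means: dict[str, float]


def modularity_fixed_partition(g: BinaryGraph, p: ModulePartition) -> ModularityProfile:
    """Decompose Q = sum_i (e_ii - a_i^2) for a graph under a fixed partition.

    Isolated nodes contribute nothing to e_ii or a_i.  Raises ``ValueError``
    on an edgeless graph (the edge fractions are undefined) and ``KeyError``
    if a graph node is missing from the partition.
    """
    L = g.n_edges
    if L == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    labels = p.labels_for(g.node_ids)
    mods = p.modules
    A = g.adjacency
    deg = A.sum(axis=1).astype(float)
    # a_i: fraction of edge ends in module i
    a = np.bincount(labels, weights=deg, minlength=len(mods)) / (2.0 * L)
    # e_ii: fraction of edges with both ends in module i
    e = np.zeros(len(mods))
    for k in range(len(mods)):
        idx = labels == k
        e[k] = A[np.ix_(idx, idx)].sum() / 2.0 / L
    per = {m: ModuleStats(e_ii=float(e[k]), a_i=float(a[k])) for k, m in enumerate(mods)}
    Q = float(np.sum(e - a**2))
    return ModularityProfile(density=g.density, per_module=per, Q=Q)


def _leading_split(Bg: np.ndarray) -> np.ndarray | None:
    """Sign split from the leading eigenvector of a generalised modularity matrix.

    Returns a +/-1 vector, or None if the leading eigenvalue is not positive
    (the subgraph is indivisible).  Components at exactly zero join the
    positive side, a fixed tie-break.
    """
    vals, vecs = np.linalg.eigh(Bg)
    if vals[-1] <= 1e-12:
        return None
    lead = vecs[:, -1]
    s = np.where(lead >= 0.0, 1.0, -1.0)
    if np.all(s == 1.0) or np.all(s == -1.0):
        return None
    return s


def _kl_refine(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin-style fine-tuning: move each node once, keep the best state."""
    s = s.copy()
    best_s, best_gain = s.copy(), 0.0
    moved = np.zeros(len(s), dtype=bool)
    gain = 0.0
    for _ in range(len(s)):
        # delta of flipping node v: dQ proportional to -4 s_v (Bg s)_v + 4 Bg_vv
        Bs = Bg @ s
        deltas = -4.0 * s * Bs + 4.0 * np.diag(Bg)
        deltas[moved] = -np.inf
        v = int(np.argmax(deltas))
        gain += deltas[v]
        s[v] = -s[v]
        moved[v] = True
        if gain > best_gain + 1e-12:
            best_gain, best_s = gain, s.copy()
    return best_s


def _node_move_refine(A: np.ndarray, lab: np.ndarray, L: int,
                      max_sweeps: int = 200) -> np.ndarray:
    """Greedy single-node community moves until no move increases Q.

    Deterministic: nodes scanned in index order, destination chosen as the
    first community with the largest positive gain.  Only ever increases Q,
    so it repairs greedy bisection mistakes without adding randomness.
    """
    lab = lab.copy()
    deg = A.sum(axis=1).astype(float)
    two_L = 2.0 * L
    for _ in range(max_sweeps):
        improved = False
        K = np.bincount(lab, weights=deg, minlength=lab.max() + 1)
        for v in range(len(lab)):
            c = lab[v]
            # edges from v into each community
            a = np.bincount(lab[A[v] > 0], weights=A[v][A[v] > 0].astype(float),
                            minlength=len(K))
            gains = (a - a[c]) / L - deg[v] * (K - (K[c] - deg[v])) / (L * two_L)
            gains[c] = 0.0
            d = int(np.argmax(gains))
            if gains[d] > 1e-12:
                lab[v] = d
                K[c] -= deg[v]
                K[d] += deg[v]
                improved = True
        if not improved:
            break
    return lab


def spectral_partition(
    g: BinaryGraph, fine_tune: bool = True
) -> tuple[ModulePartition, float]:
    """Subject-specific modules by leading-eigenvector modularity maximisation.

    Recursive bisection on the generalised modularity matrix; a split is kept
    only if it increases Q, and recursion stops when no subgraph is divisible.
    A deterministic Kernighan-Lin-style node-move refinement follows each
    bisection (Newman's recommended pairing; on small noisy graphs the raw
    eigenvector split alone misses plantings it should find).  Both stages are
    deterministic for a given graph; ``fine_tune=False`` disables the
    refinement.

    Returns the partition (modules labelled ``"c1"``, ``"c2"``, ... in
    discovery order) and its modularity Q.
    """
    L = g.n_edges
    if L == 0:
        raise ValueError("spectral partition undefined for an edgeless graph")
    A = g.adjacency.astype(float)
    deg = A.sum(axis=1)
    B = A - np.outer(deg, deg) / (2.0 * L)

    communities: list[np.ndarray] = []

    def recurse(idx: np.ndarray) -> None:
        if len(idx) == 1:
            communities.append(idx)
            return
        Bg = B[np.ix_(idx, idx)]
        Bg = Bg - np.diag(Bg.sum(axis=1))
        s = _leading_split(Bg)
        if s is not None and fine_tune:
            s = _kl_refine(Bg, s)
            if np.all(s == s[0]):
                s = None
        if s is None:
            communities.append(idx)
            return
        dQ = float(s @ Bg @ s) / (4.0 * L)
        if dQ <= 1e-12:
            communities.append(idx)
            return
        recurse(idx[s > 0])
        recurse(idx[s < 0])

    recurse(np.arange(g.n_nodes))

    lab = np.empty(g.n_nodes, dtype=int)
    for k, idx in enumerate(communities):
        lab[idx] = k
    if fine_tune:
        lab = _node_move_refine(A, lab, L)

    # relabel in discovery order so output is independent of internal indices
    order: dict[int, str] = {}
    labels = np.empty(g.n_nodes, dtype=object)
    for i, k in enumerate(lab):
        labels[i] = order.setdefault(int(k), f"c{len(order) + 1}")
    part = ModulePartition.from_labels(g.node_ids, labels)
    Q = modularity_fixed_partition(g, part).Q
    return part, Q


def subnetwork_modularity(
    mp: ModularityProfile,
    p: ModulePartition,
    group: str,
    size_weighted: bool = False,
) -> float:
    """Mean per-module q_i over the modules of one group at one density.

    Unweighted by default; ``size_weighted=True`` weights each module by its
    node count.
    """
    mods = p.modules_in_group(group)
    if not mods:
        raise ValueError(f"no modules in group {group!r}")
    q = mp.q_values(mods)
    if not size_weighted:
        return float(q.mean())
    sizes = np.array(
        [sum(1 for v in p.assignment.values() if v == m) for m in mods], dtype=float
    )
    return float(np.average(q, weights=sizes))


def _masked_mean(vals: np.ndarray, variant: str, *, empty_is_zero: bool) -> float:
    """Mean under a sign-handling variant; NaN means 'no pairs'."""
    if variant == "positive":
        vals = vals[vals > 0]
        if vals.size == 0:
            if empty_is_zero:
                return 0.0
            return np.nan
    elif variant == "absolute":
        vals = np.abs(vals)
    elif variant != "all":
        raise ValueError(f"unknown segregation variant {variant!r}")
    if vals.size == 0:
        return np.nan
    return float(vals.mean())


def module_segregation(
    cm: ConnectivityMatrix, p: ModulePartition, variant: str = "all"
) -> SegregationProfile:
    """Per-module, whole-brain and group-mean segregation of a z-matrix.

    ``variant`` is one of ``"all"`` (use z as-is), ``"positive"`` (drop
    negative z from both means) or ``"absolute"`` (use |z|).  Works on the
    unthresholded matrix, so weak connections below any density cutoff still
    contribute.  In the positive-only variant an empty between-module set
    yields Zb = 0 (hence S = 1).

    Raises ``ValueError`` for a module of size 1 or Zw = 0.
    """
    labels = p.labels_for(cm.node_ids)
    mods = p.modules
    z = cm.z
    per: dict[str, tuple[float, float, float]] = {}
    for k, m in enumerate(mods):
        inside = labels == k
        if inside.sum() < 2:
            raise ValueError(f"module {m!r} has fewer than 2 nodes")
        block = z[np.ix_(inside, inside)]
        iu, ju = np.triu_indices(int(inside.sum()), k=1)
        zw = _masked_mean(block[iu, ju], variant, empty_is_zero=False)
        between = z[np.ix_(inside, ~inside)].ravel()
        if between.size:
            zb = _masked_mean(between, variant, empty_is_zero=True)
        else:  # single-module partition: no between pairs exist
            zb = 0.0
        if not np.isfinite(zw) or zw == 0.0:
            raise ValueError(f"module {m!r} has Zw = 0; segregation undefined")
        per[m] = (zw, zb, (zw - zb) / zw)
    s_vals = np.array([v[2] for v in per.values()])
    group_means = {}
    for grp in ("sensory-motor", "association"):
        gm = p.modules_in_group(grp)
        if gm:
            group_means[grp] = float(np.mean([per[m][2] for m in gm]))
    return SegregationProfile(
        variant=variant,
        per_module=per,
        whole_brain=float(s_vals.mean()),
        group_means=group_means,
    )


def aggregate_over_densities(
    values: dict[float, float], mode: str = "mean"
) -> float:
    """Collapse a density -> value sweep to one number.

    ``mode="mean"`` is the arithmetic mean over thresholds; ``mode="integrate"``
    is the trapezoidal area under the curve over the density axis (an AUC,
    which weights unevenly spaced sweeps by spacing).
    """
    if not values:
        raise ValueError("no values to aggregate")
    d = np.array(sorted(values))
    if np.any(np.diff(d) <= 0):
        raise ValueError("densities must be strictly increasing")
    v = np.array([values[k] for k in d])
    if mode == "mean":
        return float(v.mean())
    if mode == "integrate":
        if len(d) < 2:
            raise ValueError("need at least 2 densities to integrate")
        return float(np.trapezoid(v, d))
    raise ValueError(f"unknown aggregation mode {mode!r}")
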