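"""Readers and writers for the pipeline's delimited-text formats.

All formats are plain TSV:

* time series — one row per node, first column the node id, remaining
  columns timepoints (header row of timepoint labels);
* connectivity matrix — square, node ids as header row and first column,
  diagonal written as ``NA``;
* binary graph — same square layout with 0/1 entries, plus an edge-list
  form (``node_i<TAB>node_j``, one line per edge, i < j in node order);
* partition — two columns (node_id, module); module groups — two columns
  (module, group);
* cohort table — the subject table consumed by the statistics stage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graph_construction import BinaryGraph, ConnectivityMatrix, ROITimeSeries
from .network_metrics import ModulePartition
from .training_stats import CohortTable

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_connectivity",
    "write_connectivity",
    "write_graph",
    "write_edge_list",
    "read_partition",
    "write_partition",
    "read_cohort",
    "write_cohort",
    "write_run_dir",
    "read_run_dir",
]


def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        ts.data,
        index=pd.Index(ts.node_ids, name="node_id"),
        columns=[f"t{j + 1}" for j in range(ts.n_timepoints)],
    )
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_timeseries(path: str | Path, subject_id: str | None = None) -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ROITimeSeries(
        subject_id=subject_id or Path(path).stem,
        data=df.to_numpy(dtype=float),
        node_ids=[str(i) for i in df.index],
    )


def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.z, index=cm.node_ids, columns=cm.node_ids)
    df.index.name = "node_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_connectivity(path: str | Path, subject_id: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return ConnectivityMatrix(
        z=df.to_numpy(dtype=float),
        node_ids=[str(i) for i in df.index],
        subject_id=subject_id,
    )


def write_graph(g: BinaryGraph, path: str | Path) -> None:
    df = pd.DataFrame(g.adjacency, index=g.node_ids, columns=g.node_ids)
    df.index.name = "node_id"
    df.to_csv(path, sep="\t")


def write_edge_list(g: BinaryGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\n")
        for a, b in g.edge_list():
            fh.write(f"{a}\t{b}\n")


def write_partition(p: ModulePartition, node_path: str | Path,
                    group_path: str | Path | None = None) -> None:
    pd.DataFrame(
        {"node_id": list(p.assignment), "module": list(p.assignment.values())}
    ).to_csv(node_path, sep="\t", index=False)
    if group_path is not None:
        mods = p.modules
        pd.DataFrame(
            {"module": mods, "group": [p.group(m) for m in mods]}
        ).to_csv(group_path, sep="\t", index=False)


def read_partition(node_path: str | Path,
                   group_path: str | Path | None = None) -> ModulePartition:
    nodes = pd.read_csv(node_path, sep="\t", dtype=str)
    group_of: dict[str, str] = {}
    if group_path is not None:
        gdf = pd.read_csv(group_path, sep="\t", dtype=str)
        group_of = dict(zip(gdf["module"], gdf["group"]))
    return ModulePartition(
        assignment=dict(zip(nodes["node_id"], nodes["module"])), group_of=group_of
    )


def write_cohort(ct: CohortTable, path: str | Path) -> None:
    ct.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort(path: str | Path) -> CohortTable:
    return CohortTable(pd.read_csv(path, sep="\t"))


def write_run_dir(
    ts_list: list[ROITimeSeries],
    cohort: CohortTable,
    partition: ModulePartition,
    out_dir: str | Path,
    sim_spec=None,
) -> Path:
    """Lay out a run directory in the exact formats the pipeline consumes."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    for ts in ts_list:
        write_timeseries(ts, out / "timeseries" / f"{ts.subject_id}.tsv")
    write_partition(partition, out / "partition.tsv", out / "module_groups.tsv")
    write_cohort(cohort, out / "cohort.tsv")
    if sim_spec is not None:
        with open(out / "simspec.yaml", "w") as fh:
            yaml.safe_dump(sim_spec.to_dict(), fh, sort_keys=False)
    return out


def read_run_dir(run_dir: str | Path):
    """Load (time series, cohort, partition) from a run directory."""
    run = Path(run_dir)
    ts_files = sorted((run / "timeseries").glob("*.tsv"))
    if not ts_files:
        raise FileNotFoundError(f"no time-series files under {run / 'timeseries'}")
    ts_list = [read_timeseries(f) for f in ts_files]
    cohort = read_cohort(run / "cohort.tsv")
    groups = run / "module_groups.tsv"
    partition = read_partition(
        run / "partition.tsv", groups if groups.exists() else None
    )
    return ts_list, cohort, partition


def save_simspec(spec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def load_simspec(path: str | Path):
    from .synthetic_data import SimSpec

    with open(path) as fh:
        return SimSpec.from_dict(yaml.safe_load(fh))
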