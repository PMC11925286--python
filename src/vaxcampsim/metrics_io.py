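"""Diagnostics and file I/O.

Structural diagnostics: anti-vaccine cluster statistics (sizes of the
connected components of the subgraph induced by negative adopters) and
target-neighborhood histograms (for each targeted neutral agent, a count
binned by its number of anti-vaccine and neutral neighbors, averaged over
simulations).  File formats: two-column whitespace edge lists with '#'
comments and GraphML for networks; CSV for trajectories, histograms and
results; JSON for run metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .campaigns import TargetSet
from .network import ContactNetwork, components_of_subset, neighborhood_counts
from .opinion import NEGATIVE, NEUTRAL, OpinionTrajectory, Population

__all__ = [
    "ClusterStats",
    "NeighborhoodHistogram",
    "anti_cluster_stats",
    "target_neighborhood_histogram",
    "merge_histograms",
    "read_network",
    "write_network",
    "trajectory_to_frame",
    "write_results",
]


@dataclass
class ClusterStats:
    """Sizes of anti-vaccine clusters, sorted descending."""

    sizes: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def largest(self) -> int:
        return self.sizes[0] if self.sizes else 0

    @property
    def total(self) -> int:
        return sum(self.sizes)


@dataclass
class NeighborhoodHistogram:
    """Average number of targeted agents per (n_minus, n_zero) profile.

    ``cells`` maps (x, y) = (anti-vaccine neighbor count, neutral
    neighbor count) to the average count over ``n_simulations`` runs.
    A profile absent from ``cells`` means no targeted agent ever had it
    (the 'x' marker case), distinct from a cell averaging to 0.0.
    """

    cells: dict[tuple[int, int], float]
    snapshot_step: int
    n_simulations: int = 1

    @property
    def total(self) -> float:
        """Average number of targeted neutral agents at the snapshot."""
        return float(sum(self.cells.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"n_minus": x, "n_zero": y, "avg_count": v}
            for (x, y), v in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["n_minus", "n_zero", "avg_count"])


def anti_cluster_stats(net: ContactNetwork, pop: Population) -> ClusterStats:
    """Connected components of the anti-vaccine-induced subgraph."""
    negatives = np.flatnonzero(pop.states == NEGATIVE)
    comps = components_of_subset(net, negatives)
    return ClusterStats(sizes=sorted((len(c) for c in comps), reverse=True))


def target_neighborhood_histogram(
    net: ContactNetwork,
    pop: Population,
    targets: TargetSet,
    snapshot_step: int,
) -> NeighborhoodHistogram:
    """Bin the currently targeted *neutral* agents by neighborhood profile
    (one simulation's snapshot; average several with
    :func:`merge_histograms`)."""
    cells: dict[tuple[int, int], float] = {}
    for i in targets.node_ids():
        if pop.states[i] != NEUTRAL:
            continue
        n_minus, n_zero, _ = neighborhood_counts(net, pop.states, int(i))
        cells[(n_minus, n_zero)] = cells.get((n_minus, n_zero), 0.0) + 1.0
    return NeighborhoodHistogram(cells=cells, snapshot_step=snapshot_step)


def merge_histograms(hists: list[NeighborhoodHistogram]) -> NeighborhoodHistogram:
    """Average single-run histograms taken at the same snapshot step."""
    if not hists:
        raise ValueError("no histograms to merge")
    steps = {h.snapshot_step for h in hists}
    if len(steps) != 1:
        raise ValueError(f"histograms taken at different steps: {sorted(steps)}")
    n = len(hists)
    cells: dict[tuple[int, int], float] = {}
    for h in hists:
        for key, v in h.cells.items():
            cells[key] = cells.get(key, 0.0) + v
    return NeighborhoodHistogram(
        cells={k: v / n for k, v in cells.items()},
        snapshot_step=hists[0].snapshot_step,
        n_simulations=n,
    )


# ---------------------------------------------------------------------------
# network I/O


def read_network(path: str | Path, fmt: str = "edgelist") -> ContactNetwork:
    """Read an undirected network, relabeling nodes to 0..N-1.

    Edge lists are two whitespace-separated columns; lines starting with
    '#' are comments.  Duplicate edges are collapsed; self-loops are
    rejected.  The label -> id mapping is stored on the returned object
    as ``label_mapping``.
    """
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        g = nx.Graph(g)
    elif fmt == "edgelist":
        g = nx.Graph()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                text = line.strip()
                if not text or text.startswith("#"):
                    continue
                parts = text.split()
                if len(parts) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected two columns, got {text!r}"
                    )
                u, v = parts[0], parts[1]
                if u == v:
                    raise ValueError(f"{path}:{lineno}: self-loop {u}-{v} rejected")
                g.add_edge(u, v)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'edgelist' or 'graphml'")
    def _label_key(lab):
        try:
            return (0, int(lab), "")
        except (TypeError, ValueError):
            return (1, 0, str(lab))

    labels = sorted(g.nodes(), key=_label_key)
    mapping = {lab: idx for idx, lab in enumerate(labels)}
    edges = np.array(
        [(mapping[u], mapping[v]) for u, v in g.edges()], dtype=np.int64
    ).reshape(-1, 2)
    net = ContactNetwork(n_nodes=len(labels), edges=edges)
    net.label_mapping = mapping  # type: ignore[attr-defined]
    return net


def write_network(net: ContactNetwork, path: str | Path, fmt: str = "edgelist") -> None:
    """Write a network; edge lists get a header comment recording N, k, p
    and the generation seed."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
        return
    if fmt != "edgelist":
        raise ValueError(f"unknown format {fmt!r}; use 'edgelist' or 'graphml'")
    with open(path, "w") as fh:
        fh.write(
            f"# N={net.n_nodes} k={net.mean_degree_k} "
            f"p={net.rewiring_p} seed={net.seed}\n"
        )
        for u, v in np.sort(net.edges, axis=1)[
            np.lexsort((net.edges.min(axis=1), net.edges.max(axis=1)))
        ]:
            fh.write(f"{u} {v}\n")


# ---------------------------------------------------------------------------
# results I/O


def trajectory_to_frame(traj: OpinionTrajectory) -> pd.DataFrame:
    """Per-step opinion counts as a tidy frame (step 0 = initial state)."""
    return pd.DataFrame(
        {
            "step": np.arange(len(traj.n_negative)),
            "n_negative": traj.n_negative,
            "n_neutral": traj.n_neutral,
            "n_positive": traj.n_positive,
        }
    )


def _format_float(x: float) -> str:
    return f"{x:.6g}"


def write_results(
    results: list, out_dir: str | Path, metadata: dict | None = None
) -> dict:
    """Write scenario-level and replicate-level CSVs plus JSON metadata.

    ``results`` is a list of :class:`~vaxcampsim.experiment.AggregateResult`.
    Returns a manifest of written paths.  Output is deterministic: rows
    follow input order and floats are written with 6 significant digits.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scen_rows = []
    rep_rows = []
    for idx, res in enumerate(results):
        key = json.dumps(res.scenario_key, sort_keys=True)
        scen_rows.append(
            {
                "scenario": key,
                "mean_Sr": _format_float(res.mean_s_r),
                "ci95": _format_float(res.ci95_halfwidth),
                "n": res.n_replicates,
            }
        )
        n_nets, n_runs = res.replicates.shape
        for i in range(n_nets):
            for j in range(n_runs):
                rep_rows.append(
                    {
                        "scenario": key,
                        "network": i,
                        "run": j,
                        "Sr": int(res.replicates[i, j]),
                    }
                )
    scen_path = out / "scenarios.csv"
    rep_path = out / "replicates.csv"
    meta_path = out / "metadata.json"
    pd.DataFrame(scen_rows).to_csv(scen_path, index=False)
    pd.DataFrame(rep_rows).to_csv(rep_path, index=False)
    with open(meta_path, "w") as fh:
        json.dump(metadata or {}, fh, indent=2, sort_keys=True, default=str)
    return {"scenarios": str(scen_path), "replicates": str(rep_path),
            "metadata": str(meta_path)}
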