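"""Directed trajectory network and linear three-disease trajectories.

Selected directed pairs become edges; chaining through shared nodes yields
trajectories; three-node paths are scored against the cohort by strict
onset orderings and ranked by participant count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import Cohort
from .matching import PairEstimate

EDGELIST_COLUMNS = (
    "source", "target", "or_point", "ci_low", "ci_high",
    "source_count", "target_count",
)


@dataclass
class TrajectoryNetwork:
    graph: nx.DiGraph  # node attr: patient_count; edge attrs: or_point, ci_low, ci_high

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def roles(self, n_hubs: int = 4) -> dict[str, object]:
        """Start nodes (in 0 / out > 0), end nodes (out 0 / in > 0) and the
        top-``n_hubs`` nodes by total degree."""
        g = self.graph
        start = sorted(
            n for n in g if g.in_degree(n) == 0 and g.out_degree(n) > 0
        )
        end = sorted(
            n for n in g if g.out_degree(n) == 0 and g.in_degree(n) > 0
        )
        by_degree = sorted(g.nodes, key=lambda n: (-(g.in_degree(n) + g.out_degree(n)), n))
        return {"start": start, "end": end, "hubs": by_degree[:n_hubs]}

    @property
    def has_cycle(self) -> bool:
        return not nx.is_directed_acyclic_graph(self.graph)


@dataclass
class LinearTrajectory:
    d1: str
    d2: str
    d3: str
    median_onset_age_d1: Optional[float]  # among the n_12 stem persons by default
    n_12: int  # persons with d1 strictly before d2, whole cohort
    median_t12: Optional[float]  # years d1 -> d2 among those persons
    n_123: int  # persons with d1 < d2 < d3 strictly
    median_t23: Optional[float]  # years d2 -> d3 among those persons

    @property
    def path(self) -> tuple[str, str, str]:
        return (self.d1, self.d2, self.d3)


def build_network(selected: Sequence[PairEstimate], cohort: Cohort) -> TrajectoryNetwork:
    """Graph of selected directed pairs with cohort patient counts per node."""
    g = nx.DiGraph()
    patient_counts: dict[str, int] = {}
    for e in cohort.events:
        patient_counts[e.disease] = patient_counts.get(e.disease, 0) + 1
    for est in selected:
        if est.source == est.target:
            raise ValueError(f"self-loop {est.source} -> {est.target}")
        if not est.or_point > 1.0:
            raise ValueError(
                f"edge {est.source}->{est.target} has OR {est.or_point} <= 1; "
                "only selected pairs may enter the network"
            )
        g.add_edge(
            est.source, est.target,
            or_point=float(est.or_point),
            ci_low=float(est.ci_low),
            ci_high=float(est.ci_high),
        )
    for n in g.nodes:
        g.nodes[n]["patient_count"] = int(patient_counts.get(n, 0))
    return TrajectoryNetwork(graph=g)


def chain_trajectories(
    network: TrajectoryNetwork, max_length: int = 4
) -> tuple[list[tuple[str, ...]], bool]:
    """All simple directed paths with 2..max_length nodes, deduplicated and
    sorted; the flag reports whether the graph contains a cycle (paths are
    cycle-safe: a node never repeats within a path)."""
    g = network.graph
    paths: set[tuple[str, ...]] = set()

    def extend(path: tuple[str, ...]) -> None:
        if len(path) >= 2:
            paths.add(path)
        if len(path) >= max_length:
            return
        for nxt in g.successors(path[-1]):
            if nxt not in path:  # truncate cycles
                extend(path + (nxt,))

    for node in g.nodes:
        extend((node,))
    return sorted(paths, key=lambda p: (len(p), p)), network.has_cycle


def linear_trajectories(
    cohort: Cohort,
    network: TrajectoryNetwork,
    age_among: str = "stem",
) -> list[LinearTrajectory]:
    """Score every three-node path d1 -> d2 -> d3 in the network.

    ``n_12`` counts strict d1-before-d2 orderings in the whole cohort (not
    only network-selected persons); ``median_onset_age_d1`` is computed
    among those stem persons by default, or among the full-chain ``n_123``
    persons with ``age_among="chain"``.
    """
    if age_among not in ("stem", "chain"):
        raise ValueError("age_among must be 'stem' or 'chain'")
    triples = [p for p in chain_trajectories(network, max_length=3)[0] if len(p) == 3]
    ages = cohort.onset_ages()
    out: list[LinearTrajectory] = []
    for d1, d2, d3 in triples:
        a1, a2, a3, t12, t23 = [], [], [], [], []
        chain_a1 = []
        for person in ages.values():
            x1, x2, x3 = person.get(d1), person.get(d2), person.get(d3)
            if x1 is not None and x2 is not None and x1 < x2:
                a1.append(x1)
                t12.append(x2 - x1)
                if x3 is not None and x2 < x3:
                    chain_a1.append(x1)
                    t23.append(x3 - x2)
        n_12, n_123 = len(t12), len(t23)
        age_pool = a1 if age_among == "stem" else chain_a1
        out.append(
            LinearTrajectory(
                d1=d1, d2=d2, d3=d3,
                median_onset_age_d1=float(np.median(age_pool)) if age_pool else None,
                n_12=n_12,
                median_t12=float(np.median(t12)) if t12 else None,
                n_123=n_123,
                median_t23=float(np.median(t23)) if t23 else None,
            )
        )
    return out


def rank_trajectories(
    rows: Iterable[LinearTrajectory], k: int = 10
) -> list[LinearTrajectory]:
    """Top-k by n_123 descending; ties broken by n_12 descending then by
    lexicographic path — a stable total order."""
    ordered = sorted(rows, key=lambda r: (-r.n_123, -r.n_12, r.path))
    return ordered[:k]


def trajectories_frame(rows: Iterable[LinearTrajectory]) -> pd.DataFrame:
    data = [
        {
            "rank": i + 1, "d1": r.d1, "d2": r.d2, "d3": r.d3,
            "median_onset_age_d1": r.median_onset_age_d1,
            "n_12": r.n_12, "median_t12": r.median_t12,
            "n_123": r.n_123, "median_t23": r.median_t23,
        }
        for i, r in enumerate(rows)
    ]
    return pd.DataFrame(
        data,
        columns=["rank", "d1", "d2", "d3", "median_onset_age_d1",
                 "n_12", "median_t12", "n_123", "median_t23"],
    )


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_network(
    network: TrajectoryNetwork, path: str | Path, format: str = "edgelist"
) -> None:
    """Write the network as a delimited edge list or GraphML."""
    g = network.graph
    if format == "edgelist":
        rows = [
            {
                "source": u, "target": v,
                "or_point": d["or_point"], "ci_low": d["ci_low"], "ci_high": d["ci_high"],
                "source_count": g.nodes[u]["patient_count"],
                "target_count": g.nodes[v]["patient_count"],
            }
            for u, v, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=list(EDGELIST_COLUMNS)).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_edgelist(path: str | Path) -> TrajectoryNetwork:
    df = pd.read_csv(path, sep="\t", comment="#")
    g = nx.DiGraph()
    for row in df.itertuples(index=False):
        g.add_edge(
            row.source, row.target,
            or_point=float(row.or_point),
            ci_low=float(row.ci_low),
            ci_high=float(row.ci_high),
        )
        g.nodes[row.source]["patient_count"] = int(row.source_count)
        g.nodes[row.target]["patient_count"] = int(row.target_count)
    return TrajectoryNetwork(graph=g)
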