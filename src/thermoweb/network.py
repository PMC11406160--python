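"""Temperature-stamped bipartite feasibility networks.

An interaction between a consumer and a resource is mechanically feasible
when the consumer's (temperature-adjusted) bite force is at least the
resource's required cutting force; equality counts as feasible.  The edge
set of a :class:`FeasibilityNetwork` is therefore a deterministic function
of the node traits and the temperature.  Because warming under a
temperature-size rule with alpha < 1 only shrinks bite forces, edge sets at
higher temperatures are nested inside those at lower temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .biomech import TemperatureSizeRule, bite_force_at_temperature
from .community import Consumer, Resource, SchemaError

__all__ = [
    "FeasibilityNetwork",
    "build_network",
    "infer_feasibility_threshold",
    "write_edge_list",
    "read_edge_list",
    "to_networkx",
    "write_graphml",
]

EDGE_LIST_COLUMNS = ("consumer_id", "resource_id", "weight_mn", "temperature_c")


@dataclass(frozen=True)
class FeasibilityNetwork:
    """Bipartite graph of mechanically possible links at one temperature.

    ``weights`` holds the per-edge force surplus (bite - cutting, mN, always
    >= 0).  ``bite_forces`` and ``cutting_forces`` carry the node traits the
    network was built from; they may be empty for networks read back from an
    edge list (isolated nodes and traits are not stored in that format).
    """

    temperature: float
    consumer_ids: tuple[str, ...]
    resource_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    bite_forces: dict[str, float] = field(default_factory=dict)
    cutting_forces: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known_c, known_r = set(self.consumer_ids), set(self.resource_ids)
        for c, r in self.edges:
            if c not in known_c or r not in known_r:
                raise ValueError(f"edge ({c!r}, {r!r}) references unknown node ids")
        for edge, w in self.weights.items():
            if w < 0:
                raise ValueError(f"edge {edge!r} has negative force surplus {w!r}")

    @property
    def n_consumers(self) -> int:
        return len(self.consumer_ids)

    @property
    def n_resources(self) -> int:
        return len(self.resource_ids)

    def consumer_neighbors(self, consumer_id: str) -> set[str]:
        if consumer_id not in set(self.consumer_ids):
            raise KeyError(f"unknown consumer id {consumer_id!r}")
        return {r for c, r in self.edges if c == consumer_id}

    def resource_neighbors(self, resource_id: str) -> set[str]:
        if resource_id not in set(self.resource_ids):
            raise KeyError(f"unknown resource id {resource_id!r}")
        return {c for c, r in self.edges if r == resource_id}


def build_network(
    consumers: Sequence[Consumer],
    resources: Sequence[Resource],
    temperature: float,
    rule: TemperatureSizeRule,
) -> FeasibilityNetwork:
    """Construct the feasibility network at ``temperature``.

    An edge (consumer, resource) exists iff the consumer's bite force at
    ``temperature`` (after the temperature-size adjustment of its body
    mass) is >= the resource's cutting force; ties produce an edge.  Edge
    weight is the force surplus in mN.
    """
    if len(consumers) == 0 or len(resources) == 0:
        raise ValueError("build_network requires non-empty consumer and resource sets")

    bites = np.array(
        [bite_force_at_temperature(c, temperature, rule) for c in consumers]
    )
    cuts = np.array([r.cutting_force for r in resources])
    feasible = bites[:, None] >= cuts[None, :]

    edges = {}
    for i, j in zip(*np.nonzero(feasible)):
        edges[(consumers[i].id, resources[j].id)] = float(bites[i] - cuts[j])

    return FeasibilityNetwork(
        temperature=float(temperature),
        consumer_ids=tuple(c.id for c in consumers),
        resource_ids=tuple(r.id for r in resources),
        edges=frozenset(edges),
        weights=edges,
        bite_forces={c.id: float(b) for c, b in zip(consumers, bites)},
        cutting_forces={r.id: float(r.cutting_force) for r in resources},
    )


def infer_feasibility_threshold(
    network: FeasibilityNetwork,
    resources: Optional[Sequence[Resource]] = None,
) -> dict[str, tuple[float, float]]:
    """Recover per-consumer bite-force intervals from the observed links.

    This is trait matching in its simplest form: for each consumer the
    interval ``[max cutting force among linked resources, min cutting force
    among unlinked resources)`` must contain the consumer's true bite force
    whenever the network was produced by :func:`build_network`.  Consumers
    with no links get lower bound 0; consumers linked to everything get
    upper bound +inf.
    """
    if resources is not None:
        cut_by_id = {r.id: r.cutting_force for r in resources}
    else:
        cut_by_id = dict(network.cutting_forces)
    missing = set(network.resource_ids) - set(cut_by_id)
    if missing:
        raise ValueError(
            f"no cutting force available for resource id(s): {sorted(missing)}"
        )

    intervals: dict[str, tuple[float, float]] = {}
    for cid in network.consumer_ids:
        linked = network.consumer_neighbors(cid)
        linked_cuts = [cut_by_id[r] for r in network.resource_ids if r in linked]
        unlinked_cuts = [cut_by_id[r] for r in network.resource_ids if r not in linked]
        lo = max(linked_cuts) if linked_cuts else 0.0
        hi = min(unlinked_cuts) if unlinked_cuts else math.inf
        intervals[cid] = (lo, hi)
    return intervals


def write_edge_list(network: FeasibilityNetwork, path: str | Path) -> None:
    """Write the network as a TSV edge list with one row per feasible link."""
    rows = sorted(network.edges)
    frame = pd.DataFrame(
        {
            "consumer_id": [c for c, _ in rows],
            "resource_id": [r for _, r in rows],
            "weight_mn": [network.weights.get(e, np.nan) for e in rows],
            "temperature_c": network.temperature,
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> FeasibilityNetwork:
    """Read an edge-list TSV written by :func:`write_edge_list` (or conforming).

    Isolated nodes are not represented in the format, so the returned
    network's node sets contain only nodes with at least one edge.
    """
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed edge list {path}: {exc}") from exc
    missing = [c for c in EDGE_LIST_COLUMNS[:3] if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"edge list {path} is missing required column(s): {', '.join(missing)}"
        )
    weights = {}
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            w = float(row.weight_mn)
        except (TypeError, ValueError):
            raise SchemaError(
                f"edge list {path} line {i + 2}: weight_mn is not numeric "
                f"({row.weight_mn!r})"
            ) from None
        if w < 0:
            raise SchemaError(
                f"edge list {path} line {i + 2}: negative force surplus {w!r}"
            )
        weights[(str(row.consumer_id), str(row.resource_id))] = w
    if "temperature_c" in frame.columns and len(frame) > 0:
        temperature = float(frame["temperature_c"].iloc[0])
    else:
        temperature = math.nan
    consumer_ids = tuple(dict.fromkeys(c for c, _ in weights))
    resource_ids = tuple(dict.fromkeys(r for _, r in weights))
    return FeasibilityNetwork(
        temperature=temperature,
        consumer_ids=consumer_ids,
        resource_ids=resource_ids,
        edges=frozenset(weights),
        weights=weights,
    )


def to_networkx(network: FeasibilityNetwork) -> nx.Graph:
    """Convert to a networkx bipartite graph with trait attributes on nodes."""
    graph = nx.Graph()
    graph.graph["temperature_c"] = network.temperature
    for cid in network.consumer_ids:
        attrs = {"bipartite": 0, "kind": "consumer"}
        if cid in network.bite_forces:
            attrs["bite_force_mn"] = network.bite_forces[cid]
        graph.add_node(cid, **attrs)
    for rid in network.resource_ids:
        attrs = {"bipartite": 1, "kind": "resource"}
        if rid in network.cutting_forces:
            attrs["cutting_force_mn"] = network.cutting_forces[rid]
        graph.add_node(rid, **attrs)
    for (c, r) in sorted(network.edges):
        graph.add_edge(c, r, weight_mn=network.weights.get((c, r), math.nan))
    return graph


def write_graphml(network: FeasibilityNetwork, path: str | Path) -> None:
    nx.write_graphml(to_networkx(network), str(path))
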