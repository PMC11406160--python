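"""Structural metrics on feasibility networks.

Covers node-level degree, group-level generality, network-level connectance,
robustness to progressive node removal (attack-tolerance curves and their
area), and edge turnover between temperature layers of a multilayer stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import FeasibilityNetwork

__all__ = [
    "degree",
    "degrees",
    "generality",
    "connectance",
    "RobustnessResult",
    "robustness",
    "link_turnover",
    "REMOVAL_STRATEGIES",
]

REMOVAL_STRATEGIES = ("random", "most-connected-first", "toughest-resource-first")


def degree(network: FeasibilityNetwork, consumer_id: str) -> int:
    """Number of resources the consumer can feasibly interact with."""
    return len(network.consumer_neighbors(consumer_id))


def degrees(network: FeasibilityNetwork) -> dict[str, int]:
    """Degree of every consumer, in consumer order."""
    counts = {cid: 0 for cid in network.consumer_ids}
    for c, _ in network.edges:
        counts[c] += 1
    return counts


def generality(network: FeasibilityNetwork, weighted: bool = False) -> float:
    """Mean niche breadth of the consumer guild.

    Unweighted (default): the arithmetic mean consumer degree.  Weighted:
    the mean over consumers of the exponential of the Shannon entropy of
    each consumer's edge weights (force surplus), i.e. the effective number
    of resources per consumer; zero-degree consumers contribute 0.
    """
    if network.n_consumers == 0:
        raise ValueError("generality requires at least one consumer")
    if not weighted:
        return len(network.edges) / network.n_consumers

    totals = []
    for cid in network.consumer_ids:
        ws = np.array(
            [network.weights[(cid, r)] for r in network.consumer_neighbors(cid)]
        )
        ws = ws[ws > 0]
        if ws.size == 0:
            # all-zero or no weights: fall back on the count of links
            totals.append(float(len(network.consumer_neighbors(cid))))
            continue
        p = ws / ws.sum()
        totals.append(float(np.exp(-(p * np.log(p)).sum())))
    return float(np.mean(totals))


def connectance(network: FeasibilityNetwork) -> float:
    """Realised fraction of possible consumer-resource links, in [0, 1]."""
    if network.n_consumers == 0 or network.n_resources == 0:
        raise ValueError("connectance requires at least one consumer and one resource")
    return len(network.edges) / (network.n_consumers * network.n_resources)


@dataclass(frozen=True)
class RobustnessResult:
    """Attack-tolerance curve and its area.

    ``removal_fractions`` runs from 0 to 1 in steps of one removed node;
    ``surviving_fraction`` is the fraction of the dependent guild still
    holding at least one link after each removal (averaged over replicates
    for the random strategy).  ``robustness_r`` is the trapezoidal area
    under the curve, in [0, 1]: 1 means no secondary extinctions until the
    very end, 0.5 is the single-consumer/single-resource baseline.
    """

    removal_fractions: np.ndarray
    surviving_fraction: np.ndarray
    robustness_r: float
    removal_strategy: str
    n_replicates: int
    seed: Optional[int]


def _incidence(network: FeasibilityNetwork, remove: str) -> np.ndarray:
    """Boolean matrix of survivors (rows) x removal candidates (columns)."""
    c_index = {cid: i for i, cid in enumerate(network.consumer_ids)}
    r_index = {rid: j for j, rid in enumerate(network.resource_ids)}
    mat = np.zeros((len(c_index), len(r_index)), dtype=bool)
    for c, r in network.edges:
        mat[c_index[c], r_index[r]] = True
    return mat if remove == "resources" else mat.T


def _curve_for_orders(incidence: np.ndarray, orders: np.ndarray) -> np.ndarray:
    """Mean surviving-fraction curve over removal orders.

    ``orders`` has shape (n_replicates, n_removed); each row is a
    permutation of removal-candidate indices.  A dependent node goes
    secondarily extinct at the step where its last partner is removed;
    nodes with no partners count as extinct from the first step.
    """
    n_dep, n_rem = incidence.shape
    n_rep = orders.shape[0]
    # position[t, j] = 1-based step at which candidate j is removed in replicate t
    position = np.empty((n_rep, n_rem), dtype=np.int64)
    rows = np.arange(n_rep)[:, None]
    position[rows, orders] = np.arange(1, n_rem + 1)[None, :]
    # extinction step of each dependent = max removal position among partners
    masked = np.where(incidence[None, :, :], position[:, None, :], 0)
    ext_step = masked.max(axis=2)  # (n_rep, n_dep); 0 for isolated nodes
    steps = np.arange(1, n_rem + 1)
    surviving = (ext_step[:, :, None] > steps[None, None, :]).mean(axis=1)
    return surviving.mean(axis=0)


def robustness(
    network: FeasibilityNetwork,
    strategy: str = "random",
    n_replicates: int = 100,
    seed: Optional[int] = None,
    remove: str = "resources",
) -> RobustnessResult:
    """Secondary-extinction robustness under progressive node removal.

    Nodes on the ``remove`` side (resources by default) are deleted one at
    a time following ``strategy``; a node on the other side suffers a
    secondary extinction when its degree reaches zero.  The surviving
    fraction is recorded after every removal, the point (0, 1) is
    prepended, and ``robustness_r`` is the trapezoidal area under the curve
    of surviving fraction versus removal fraction.

    Strategies: ``random`` (uniform removal order, averaged over
    ``n_replicates`` with ``seed``), ``most-connected-first`` (descending
    initial degree, ties by node order), and ``toughest-resource-first``
    (descending required cutting force; resources only, and the network
    must carry cutting forces).
    """
    if strategy not in REMOVAL_STRATEGIES:
        raise ValueError(
            f"unknown removal strategy {strategy!r}; choose from {REMOVAL_STRATEGIES}"
        )
    if remove not in ("resources", "consumers"):
        raise ValueError(f"remove must be 'resources' or 'consumers', got {remove!r}")
    if network.n_resources == 0 or network.n_consumers == 0:
        raise ValueError("robustness requires a non-empty bipartite network")

    incidence = _incidence(network, remove)
    n_rem = incidence.shape[1]
    removed_ids = network.resource_ids if remove == "resources" else network.consumer_ids

    if strategy == "random":
        rng = np.random.default_rng(seed)
        orders = np.array([rng.permutation(n_rem) for _ in range(n_replicates)])
        n_used = n_replicates
    else:
        if strategy == "most-connected-first":
            keys = incidence.sum(axis=0)
        else:  # toughest-resource-first
            if remove != "resources":
                raise ValueError(
                    "toughest-resource-first applies to resource removal only"
                )
            if not network.cutting_forces:
                raise ValueError(
                    "toughest-resource-first requires cutting forces on the network"
                )
            keys = np.array([network.cutting_forces[r] for r in removed_ids])
        # stable sort on -key keeps node order for ties
        orders = np.argsort(-keys, kind="stable")[None, :]
        n_used = 1

    surviving = _curve_for_orders(incidence, orders)
    fractions = np.concatenate([[0.0], np.arange(1, n_rem + 1) / n_rem])
    curve = np.concatenate([[1.0], surviving])
    area = float(np.trapezoid(curve, fractions))
    return RobustnessResult(
        removal_fractions=fractions,
        surviving_fraction=curve,
        robustness_r=area,
        removal_strategy=strategy,
        n_replicates=n_used,
        seed=seed,
    )


def link_turnover(
    network_a: FeasibilityNetwork, network_b: FeasibilityNetwork
) -> float:
    """Jaccard dissimilarity of the two layers' edge sets, in [0, 1].

    0 for identical layers, 1 for disjoint non-empty layers; defined as 0
    when both layers are empty.  For nested layers (warming under shrinkage)
    this reduces to ``1 - |edges_hot| / |edges_cold|``.
    """
    union = network_a.edges | network_b.edges
    if not union:
        return 0.0
    inter = network_a.edges & network_b.edges
    return 1.0 - len(inter) / len(union)
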