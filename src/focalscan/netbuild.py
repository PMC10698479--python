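"""Construction of weighted, exposure-normalized social networks.

Edge weights are dyadic interaction rates: the number of recorded dyadic
interactions divided by the co-presence exposure of the dyad — observation
hours for focal-animal sampling (FAS), scan session counts for
all-occurrence sampling (ABS). Node order is lexicographic by id so matrices
are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .obsdata import Behaviour, GroupRoster, Method, exposure_matrix

__all__ = ["WeightedNetwork", "build_network", "binary_adjacency", "restrict_to_present",
           "to_edge_list", "write_graphml"]


@dataclass
class WeightedNetwork:
    """A symmetric (or directed) nonnegative interaction-rate matrix.

    ``W[i, j]`` is events per exposure unit (per hour for FAS, per session
    for ABS); ``exposure`` holds the per-dyad denominators and
    ``zero_exposure`` flags dyads whose exposure was zero (their weight is
    stored as 0 rather than missing).
    """

    node_ids: tuple[str, ...]
    W: np.ndarray
    behaviour: Behaviour
    method: Method
    exposure: np.ndarray
    zero_exposure: np.ndarray = field(default=None)
    directed: bool = False

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        n = len(self.node_ids)
        if n < 2:
            raise ValueError("a network needs at least 2 nodes")
        if self.W.shape != (n, n):
            raise ValueError(f"W shape {self.W.shape} does not match {n} nodes")
        if not np.all(np.isfinite(self.W)) or np.any(self.W < 0):
            raise ValueError("W must be finite and nonnegative")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have zero diagonal")
        if not self.directed and not np.allclose(self.W, self.W.T):
            raise ValueError("undirected network requires symmetric W")
        if self.zero_exposure is None:
            self.zero_exposure = self.exposure <= 0
            np.fill_diagonal(self.zero_exposure, False)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def index(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.W[self.index(i), self.index(j)])


def build_network(
    events,
    roster: GroupRoster,
    sessions,
    behaviour: Behaviour | str,
    method: Method | str,
    directed: bool = False,
    exposure_mode: str = "observation_hours",
) -> WeightedNetwork:
    """Build the rate network for one behaviour recorded by one method.

    Counts events per ordered dyad, symmetrizes (unless ``directed``), and
    divides elementwise by the co-presence exposure. Dyads with zero exposure
    get weight 0 and are flagged in ``zero_exposure``.
    """
    behaviour = Behaviour(behaviour)
    method = Method(method)
    ids, E = exposure_matrix(roster, sessions, method, mode=exposure_mode)
    idx = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    C = np.zeros((n, n))
    for e in events:
        if e.behaviour is not behaviour or e.method is not method:
            continue
        if e.actor_id not in idx or e.recipient_id not in idx:
            missing = e.actor_id if e.actor_id not in idx else e.recipient_id
            raise KeyError(
                f"event participant {missing!r} is not in roster {roster.group_id}"
            )
        C[idx[e.actor_id], idx[e.recipient_id]] += 1
    counts = C if directed else C + C.T
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(E > 0, counts / np.where(E > 0, E, 1.0), 0.0)
    np.fill_diagonal(W, 0.0)
    return WeightedNetwork(
        node_ids=tuple(ids), W=W, behaviour=behaviour, method=method,
        exposure=E, directed=directed,
    )


def binary_adjacency(net: WeightedNetwork) -> np.ndarray:
    """0/1 adjacency: an edge wherever the rate is positive."""
    A = (net.W > 0).astype(float)
    if net.directed:
        A = np.maximum(A, A.T)
    np.fill_diagonal(A, 0.0)
    return A


def restrict_to_present(net: WeightedNetwork, roster: GroupRoster, at_time: float) -> WeightedNetwork:
    """Submatrix over individuals resident at ``at_time``.

    Mirrors the field situation in which a departed individual's edges
    disappear from the group's network.
    """
    keep = [k for k, nid in enumerate(net.node_ids) if roster[nid].resident(at_time)]
    if len(keep) < 2:
        raise ValueError(
            f"fewer than 2 individuals resident at t={at_time} in group {roster.group_id}"
        )
    sel = np.ix_(keep, keep)
    return replace(
        net,
        node_ids=tuple(net.node_ids[k] for k in keep),
        W=net.W[sel].copy(),
        exposure=net.exposure[sel].copy(),
        zero_exposure=net.zero_exposure[sel].copy(),
    )


def to_edge_list(net: WeightedNetwork) -> pd.DataFrame:
    """Edge-list frame (i, j, weight, exposure, behaviour, method); for
    undirected networks only the upper triangle is emitted."""
    rows = []
    n = net.n
    for a in range(n):
        rng = range(n) if net.directed else range(a + 1, n)
        for b in rng:
            if a == b or net.W[a, b] == 0:
                continue
            rows.append(
                (net.node_ids[a], net.node_ids[b], net.W[a, b], net.exposure[a, b],
                 net.behaviour.value, net.method.value)
            )
    return pd.DataFrame(rows, columns=["i", "j", "weight", "exposure", "behaviour", "method"])


def write_graphml(net: WeightedNetwork, path) -> None:
    """Minimal GraphML export (node ids, edge weights) for interoperability."""
    root = ET.Element("graphml", xmlns="http://graphml.graphdrawing.org/xmlns")
    ET.SubElement(root, "key", id="w", **{"for": "edge", "attr.name": "weight", "attr.type": "double"})
    graph = ET.SubElement(
        root, "graph", id=f"{net.behaviour.value}-{net.method.value}",
        edgedefault="directed" if net.directed else "undirected",
    )
    for nid in net.node_ids:
        ET.SubElement(graph, "node", id=nid)
    for _, row in to_edge_list(net).iterrows():
        edge = ET.SubElement(graph, "edge", source=str(row["i"]), target=str(row["j"]))
        data = ET.SubElement(edge, "data", key="w")
        data.text = repr(float(row["weight"]))
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
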