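"""The three local and three global social network metrics.

Conventions: degree and density are unweighted (an edge wherever the rate is
positive); eigenvector, betweenness, modularity and centralization are
weighted. Local metrics are rescaled to [0, 1] to be comparable across group
sizes: degree by (n-1), eigenvector to max 1, betweenness by the number of
node pairs excluding the focal node. Betweenness uses edge length 1/weight
(stronger ties are shorter), counting all geodesics Brandes-style.
Centralization is the Freeman-style sum of eigenvector-centrality
differences from the most central node, normalized by the same sum for a
star of equal size. Modularity is weighted Newman-Girvan Q maximized by
deterministic greedy agglomeration, with exact partition enumeration
available for small groups.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np

from .netbuild import WeightedNetwork, binary_adjacency

__all__ = [
    "MetricSet",
    "UndefinedMetricError",
    "PowerIterationError",
    "degree_centrality",
    "eigenvector_centrality",
    "betweenness_centrality",
    "density",
    "modularity",
    "partition_modularity",
    "centralization",
    "compute_metrics",
    "GLOBAL_METRICS",
    "LOCAL_METRICS",
]

LOCAL_METRICS = ("degree", "eigenvector", "betweenness")
GLOBAL_METRICS = ("density", "modularity", "centralization")


class UndefinedMetricError(ValueError):
    """The metric is undefined on this network (e.g. no edges at all)."""


class PowerIterationError(RuntimeError):
    """Power iteration failed to converge; carries the last iterate."""

    def __init__(self, message, iterate):
        super().__init__(message)
        self.iterate = iterate


def _as_matrix(net) -> np.ndarray:
    if isinstance(net, WeightedNetwork):
        W = net.W
        if net.directed:
            W = W + W.T
        return W
    W = np.asarray(net, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("expected a square weight matrix or a WeightedNetwork")
    return W


def degree_centrality(net) -> np.ndarray:
    """Unweighted degree / (n - 1), in [0, 1]."""
    A = binary_adjacency(net) if isinstance(net, WeightedNetwork) else (_as_matrix(net) > 0).astype(float)
    n = A.shape[0]
    return A.sum(axis=1) / (n - 1)


def eigenvector_centrality(net, tol: float = 1e-10, max_iter: int = 100_000) -> np.ndarray:
    """Leading eigenvector of W by power iteration, max-normalized to [0, 1].

    An all-zero network returns all zeros. On a disconnected network the
    dominant component carries the vector and the rest is ~0; a structure
    warning is emitted. Iteration uses a diagonal shift (which leaves
    eigenvectors unchanged) so bipartite-like spectra still converge.
    """
    W = _as_matrix(net)
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return np.zeros(n)
    M = W + wmax * np.eye(n)  # shift: same eigenvectors, guaranteed spectral gap
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        x_new = M @ x
        x_new /= np.linalg.norm(x_new)
        if np.abs(x_new - x).max() < tol:
            x = x_new
            break
        x = x_new
    else:
        raise PowerIterationError(
            f"eigenvector centrality did not converge in {max_iter} iterations", x
        )
    x = np.abs(x)
    if _n_components(W) > 1:
        warnings.warn(
            "network is disconnected; eigenvector centrality reflects the dominant component",
            stacklevel=2,
        )
    return x / x.max()


def _n_components(W: np.ndarray) -> int:
    n = W.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = 0
    for s in range(n):
        if seen[s]:
            continue
        comps += 1
        stack = [s]
        seen[s] = True
        while stack:
            u = stack.pop()
            for v in np.nonzero(W[u] > 0)[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
    return comps


def betweenness_centrality(net) -> np.ndarray:
    """Weighted betweenness (edge length = 1/weight), Brandes accumulation,
    normalized by (n-1)(n-2)/2 so values lie in [0, 1]."""
    W = _as_matrix(net)
    n = W.shape[0]
    bc = np.zeros(n)
    if n < 3:
        return bc
    # adjacency lists of (neighbour, length)
    nbrs = [list(zip(np.nonzero(W[u] > 0)[0], 1.0 / W[u][W[u] > 0])) for u in range(n)]
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        preds: list[list[int]] = [[] for _ in range(n)]
        dist[s] = 0.0
        sigma[s] = 1.0
        order: list[int] = []
        done = np.zeros(n, dtype=bool)
        heap = [(0.0, s)]
        while heap:
            d, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            order.append(u)
            for v, length in nbrs[u]:
                alt = d + length
                if alt < dist[v]:
                    dist[v] = alt
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (alt, v))
                elif alt == dist[v] and not done[v]:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for u in reversed(order):
            for p in preds[u]:
                delta[p] += sigma[p] / sigma[u] * (1.0 + delta[u])
            if u != s:
                bc[u] += delta[u]
    bc /= 2.0  # each unordered pair counted from both endpoints
    return bc / ((n - 1) * (n - 2) / 2.0)


def density(net) -> float:
    """Unweighted density: dyads with a positive rate / possible dyads."""
    A = binary_adjacency(net) if isinstance(net, WeightedNetwork) else (_as_matrix(net) > 0).astype(float)
    n = A.shape[0]
    return float(A.sum() / 2.0 / (n * (n - 1) / 2.0))


def partition_modularity(net, labels) -> float:
    """Weighted Newman-Girvan Q of a given partition (labels per node)."""
    W = _as_matrix(net)
    labels = np.asarray(labels)
    two_m = W.sum()
    if two_m == 0:
        raise UndefinedMetricError("modularity is undefined on an all-zero network")
    k = W.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        q += W[np.ix_(mask, mask)].sum() / two_m - (k[mask].sum() / two_m) ** 2
    return float(q)


def _partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, max_label: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0)


def _modularity_exact(W: np.ndarray):
    two_m = W.sum()
    k = W.sum(axis=1)
    B = W / two_m - np.outer(k, k) / two_m**2
    best_q, best_labels = -np.inf, None
    for labels in _partitions(W.shape[0]):
        q = 0.0
        for c in range(labels.max() + 1):
            mask = labels == c
            q += B[np.ix_(mask, mask)].sum()
        if q > best_q + 1e-15:
            best_q, best_labels = q, labels
    return float(best_q), best_labels


def _modularity_greedy(W: np.ndarray):
    """Deterministic greedy agglomeration (CNM-style), lexicographic tie-break.

    Communities are labelled by their smallest node index; among equal
    modularity gains the lexicographically smallest label pair is merged.
    """
    n = W.shape[0]
    two_m = W.sum()
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    e = {  # normalized cross weights between current communities
        (i, j): W[i, j] / two_m for i in range(n) for j in range(i + 1, n) if W[i, j] > 0
    }
    a = {i: W[i].sum() / two_m for i in range(n)}
    while True:
        best = None
        for (i, j), eij in e.items():
            gain = 2.0 * (eij - a[i] * a[j])
            if gain <= 1e-12:
                continue
            if best is None or gain > best[0] + 1e-15 or (
                abs(gain - best[0]) <= 1e-15 and (i, j) < best[1]
            ):
                best = (gain, (i, j))
        if best is None:
            break
        i, j = best[1]
        members[i].extend(members.pop(j))
        a[i] += a.pop(j)
        new_e = {}
        for (p, q), val in e.items():
            if (p, q) == (i, j):
                continue
            p2 = i if p == j else p
            q2 = i if q == j else q
            key = (min(p2, q2), max(p2, q2))
            new_e[key] = new_e.get(key, 0.0) + val
        e = new_e
    labels = np.empty(n, dtype=int)
    for lab, (_, mem) in enumerate(sorted(members.items())):
        labels[mem] = lab
    return partition_modularity(W, labels), labels


def modularity(net, exact: bool = False):
    """Best-found weighted modularity and its partition.

    The default algorithm is deterministic greedy agglomeration;
    ``exact=True`` enumerates every partition (small groups only, n <= 12)
    and guarantees the global optimum. Returns ``(Q, labels)``.
    """
    W = _as_matrix(net)
    if W.sum() == 0:
        raise UndefinedMetricError("modularity is undefined on an all-zero network")
    n = W.shape[0]
    if exact:
        if n > 12:
            raise ValueError("exact modularity enumeration is limited to n <= 12")
        return _modularity_exact(W)
    return _modularity_greedy(W)


def centralization(net) -> float:
    """Freeman-style eigenvector centralization.

    Sum of (c_max - c_i) over nodes, divided by the same sum for a star of
    equal size (for which the max-normalized eigenvector is 1 at the hub and
    1/sqrt(n-1) at each leaf, giving normalizer (n-1) - sqrt(n-1)). Bounded
    by [0, 1] on connected binary graphs, where the star attains the
    maximum. On weighted or disconnected networks the eigenvector can
    concentrate on a single heavy dyad, so the index may modestly exceed 1;
    its hard supremum is (n-2) / ((n-1) - sqrt(n-1)).
    """
    W = _as_matrix(net)
    n = W.shape[0]
    if n < 3:
        raise UndefinedMetricError("centralization needs at least 3 nodes")
    if W.max() == 0:
        raise UndefinedMetricError("centralization is undefined on an all-zero network")
    c = eigenvector_centrality(W)
    return float((c.max() - c).sum() / ((n - 1) - np.sqrt(n - 1)))


@dataclass
class MetricSet:
    """All six metrics for one network; undefined globals are NaN + flagged."""

    node_ids: tuple[str, ...]
    degree: np.ndarray
    eigenvector: np.ndarray
    betweenness: np.ndarray
    density: float
    modularity: float
    modularity_partition: np.ndarray | None
    centralization: float
    flags: dict

    def local(self, name: str) -> np.ndarray:
        return getattr(self, name)


def compute_metrics(net: WeightedNetwork, modularity_exact: bool = False) -> MetricSet:
    """Compute the full metric set with the package's conventions."""
    flags: dict = {"zero_exposure_dyads": int(np.count_nonzero(net.zero_exposure) // 2)}
    W = _as_matrix(net)
    n = W.shape[0]
    deg = degree_centrality(net)
    dens = density(net)
    if W.max() == 0:
        eig = np.zeros(n)
        btw = np.zeros(n)
        q, part, cent = np.nan, None, np.nan
        flags["modularity_undefined"] = True
        flags["centralization_undefined"] = True
    else:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            eig = eigenvector_centrality(W)
        if caught:
            flags["disconnected"] = True
        btw = betweenness_centrality(W)
        q, part = modularity(W, exact=modularity_exact)
        if n >= 3:
            cent = float((eig.max() - eig).sum() / ((n - 1) - np.sqrt(n - 1)))
        else:
            cent = np.nan
            flags["centralization_undefined"] = True
    return MetricSet(
        node_ids=net.node_ids if isinstance(net, WeightedNetwork) else tuple(map(str, range(n))),
        degree=deg, eigenvector=eig, betweenness=btw,
        density=dens, modularity=q, modularity_partition=part,
        centralization=cent, flags=flags,
    )
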