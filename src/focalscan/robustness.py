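"""Network robustness: cumulative-effort trajectories and bootstrap uncertainty.

Two diagnostics for whether a network built from observation data has
stabilized: (1) metric trajectories over cumulative monthly datasets, which
should flatten as fewer new edges appear; and (2) an uncertainty index — the
width of the 95% interval of a metric's bootstrap distribution obtained by
reshuffling, for every event, the recipient identity uniformly among
co-resident group members — which should shrink with effort.

A "month" is a fixed 30-day block from the dataset origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import netmetrics
from ._util import as_seedseq
from .netbuild import WeightedNetwork, build_network, restrict_to_present
from .obsdata import Behaviour, GroupRoster, Method, filter_period

__all__ = [
    "MONTH_SECONDS",
    "AccumulationCurve",
    "UncertaintyIndex",
    "PeriodNetwork",
    "cumulative_networks",
    "metric_trajectory",
    "uncertainty_index",
    "uncertainty_trajectory",
    "stabilization_effort",
    "plot_trajectories",
]

MONTH_SECONDS = 30 * 86400.0


@dataclass
class PeriodNetwork:
    period_index: int  # 1-based month ordinal
    period_end: float
    cumulative_effort: float  # hours (FAS) or session count (ABS)
    network: WeightedNetwork


@dataclass
class AccumulationCurve:
    metric: str
    period_index: np.ndarray
    cumulative_effort: np.ndarray  # nondecreasing
    value: np.ndarray
    undefined: np.ndarray  # flagged (not dropped) entries


@dataclass
class UncertaintyIndex:
    metric: str
    width: float  # 97.5th minus 2.5th percentile of the bootstrap distribution
    period_index: int | None = None
    cumulative_effort: float | None = None
    n_replicates: int = 0
    note: str | None = None


def _metric_value(net: WeightedNetwork, metric: str) -> float:
    """Scalar summary: group mean for local metrics, scalar for global ones."""
    return _metric_from_matrix(net.W, metric)


def _metric_from_matrix(W: np.ndarray, metric: str) -> float:
    if metric == "degree":
        return float(np.mean(netmetrics.degree_centrality(W)))
    if metric == "eigenvector":
        if W.max() == 0:
            return np.nan
        return float(np.mean(netmetrics.eigenvector_centrality(W)))
    if metric == "betweenness":
        return float(np.mean(netmetrics.betweenness_centrality(W)))
    if metric == "density":
        return netmetrics.density(W)
    if metric == "modularity":
        try:
            return netmetrics.modularity(W, exact=False)[0]
        except netmetrics.UndefinedMetricError:
            return np.nan
    if metric == "centralization":
        try:
            return netmetrics.centralization(W)
        except netmetrics.UndefinedMetricError:
            return np.nan
    raise ValueError(f"unknown metric {metric!r}")


def _origin(events, sessions) -> float:
    times = [s.start for s in sessions] + [e.timestamp for e in events]
    if not times:
        raise ValueError("no events or sessions to anchor the period grid")
    return min(times)


def cumulative_networks(
    events,
    roster: GroupRoster,
    sessions,
    behaviour: Behaviour | str,
    method: Method | str,
    period_seconds: float = MONTH_SECONDS,
    cumulative: bool = True,
    exposure_mode: str = "observation_hours",
) -> list[PeriodNetwork]:
    """One network per period: all data up to the period's end (default) or
    the period's own data only, restricted to individuals resident then.

    Cumulative effort is observation hours (FAS) or session count (ABS) of
    the sessions entering each network.
    """
    behaviour = Behaviour(behaviour)
    method = Method(method)
    events = [e for e in events if e.behaviour is behaviour and e.method is method]
    t0 = _origin(events, sessions)
    t_max = max([s.end for s in sessions] + [e.timestamp for e in events])
    n_periods = max(1, int(np.ceil((t_max - t0) / period_seconds)))
    out = []
    for k in range(1, n_periods + 1):
        end = t0 + k * period_seconds
        start = t0 + (k - 1) * period_seconds if not cumulative else t0
        ev_k = filter_period(events, start, end)
        sess_k = [s for s in sessions if start <= s.start < end]
        net = build_network(ev_k, roster, sess_k, behaviour, method, exposure_mode=exposure_mode)
        net = restrict_to_present(net, roster, at_time=end - 1e-6)
        if method is Method.FAS:
            effort = sum(s.duration for s in sess_k) / 3600.0
        else:
            effort = float(len(sess_k))
        out.append(PeriodNetwork(period_index=k, period_end=end, cumulative_effort=effort, network=net))
    return out


def metric_trajectory(period_nets: list[PeriodNetwork], metric: str) -> AccumulationCurve:
    """Per-period metric values (group mean for local metrics).

    Undefined values (e.g. modularity of an early empty network) are kept in
    place as NaN and flagged, so the effort axis stays aligned.
    """
    if len(period_nets) < 2:
        raise ValueError("a trajectory needs at least 2 periods")
    values = np.array([_metric_value(pn.network, metric) for pn in period_nets])
    return AccumulationCurve(
        metric=metric,
        period_index=np.array([pn.period_index for pn in period_nets]),
        cumulative_effort=np.array([pn.cumulative_effort for pn in period_nets]),
        value=values,
        undefined=np.isnan(values),
    )


def _reshuffle_setup(events, roster: GroupRoster):
    """Precompute, per event, the index arrays needed to redraw recipients
    uniformly among co-resident members other than the actor."""
    ids = roster.ids
    idx = {v: k for k, v in enumerate(ids)}
    actor_idx = np.array([idx[e.actor_id] for e in events], dtype=np.intp)
    flat: list[int] = []
    offsets = np.empty(len(events), dtype=np.intp)
    counts = np.empty(len(events), dtype=np.intp)
    for k, e in enumerate(events):
        cands = [idx[i] for i in roster.resident_ids(e.timestamp) if i != e.actor_id]
        if not cands:
            raise ValueError(
                f"event at t={e.timestamp} has no co-resident recipient candidates"
            )
        offsets[k] = len(flat)
        counts[k] = len(cands)
        flat.extend(cands)
    return ids, actor_idx, np.array(flat, dtype=np.intp), offsets, counts


def uncertainty_index(
    events,
    roster: GroupRoster,
    sessions,
    behaviour: Behaviour | str,
    method: Method | str,
    metric: str,
    B: int = 1000,
    seed=None,
    exposure_mode: str = "observation_hours",
) -> UncertaintyIndex:
    """Bootstrap uncertainty: reshuffle every event's recipient, rebuild the
    network, recompute the metric, B times; width = q97.5 - q2.5.

    In a 2-individual group the reshuffle is the identity and the width is
    exactly 0 (returned with a note). Each replicate conserves the actor
    marginal and the total event count by construction.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    behaviour = Behaviour(behaviour)
    method = Method(method)
    events = [e for e in events if e.behaviour is behaviour and e.method is method]
    if not events:
        raise ValueError("no events for the requested behaviour/method")
    ids, E = _exposure(roster, sessions, method, exposure_mode)
    ids2, actor_idx, flat, offsets, counts = _reshuffle_setup(events, roster)
    assert ids == ids2
    n = len(ids)
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    for b in range(B):
        draws = (rng.random(len(events)) * counts).astype(np.intp)
        recip = flat[offsets + draws]
        C = np.zeros((n, n))
        np.add.at(C, (actor_idx, recip), 1.0)
        counts_sym = C + C.T
        with np.errstate(divide="ignore", invalid="ignore"):
            W = np.where(E > 0, counts_sym / np.where(E > 0, E, 1.0), 0.0)
        np.fill_diagonal(W, 0.0)
        vals[b] = _metric_from_matrix(W, metric)
    width = float(np.nanquantile(vals, 0.975) - np.nanquantile(vals, 0.025))
    note = None
    if n == 2:
        note = "group of size 2: recipient reshuffle is the identity; width is 0"
    return UncertaintyIndex(metric=metric, width=width, n_replicates=B, note=note)


def _exposure(roster, sessions, method, exposure_mode):
    from .obsdata import exposure_matrix

    return exposure_matrix(roster, sessions, method, mode=exposure_mode)


def uncertainty_trajectory(
    events,
    roster: GroupRoster,
    sessions,
    behaviour: Behaviour | str,
    method: Method | str,
    metric: str,
    B: int = 1000,
    seed=None,
    period_seconds: float = MONTH_SECONDS,
    cumulative: bool = True,
    exposure_mode: str = "observation_hours",
) -> list[UncertaintyIndex]:
    """Monthly uncertainty widths over cumulative (default) or per-month data."""
    behaviour = Behaviour(behaviour)
    method = Method(method)
    ev = [e for e in events if e.behaviour is behaviour and e.method is method]
    t0 = _origin(ev, sessions)
    t_max = max([s.end for s in sessions] + [e.timestamp for e in ev])
    n_periods = max(1, int(np.ceil((t_max - t0) / period_seconds)))
    seeds = as_seedseq(seed).spawn(n_periods)
    out = []
    for k in range(1, n_periods + 1):
        end = t0 + k * period_seconds
        start = t0 + (k - 1) * period_seconds if not cumulative else t0
        ev_k = filter_period(ev, start, end)
        sess_k = [s for s in sessions if start <= s.start < end]
        if not ev_k:
            out.append(UncertaintyIndex(metric=metric, width=np.nan, period_index=k,
                                        n_replicates=0, note="no events in window"))
            continue
        ui = uncertainty_index(ev_k, roster, sess_k, behaviour, method, metric,
                               B=B, seed=seeds[k - 1], exposure_mode=exposure_mode)
        ui.period_index = k
        if method is Method.FAS:
            ui.cumulative_effort = sum(s.duration for s in sess_k) / 3600.0
        else:
            ui.cumulative_effort = float(len(sess_k))
        out.append(ui)
    return out


def stabilization_effort(curve: AccumulationCurve, epsilon: float = 0.05):
    """Smallest cumulative effort after which every subsequent relative
    change of the metric stays below ``epsilon``.

    Returns ``(effort, stabilized)``; ``stabilized`` is False (with effort
    None) when the curve keeps fluctuating to the end.
    """
    v = curve.value
    if len(v) < 3:
        raise ValueError("stabilization needs at least 3 periods")
    rel = np.full(len(v), np.nan)
    for k in range(1, len(v)):
        prev, cur = v[k - 1], v[k]
        if np.isnan(prev) or np.isnan(cur):
            rel[k] = np.inf  # undefined periods cannot count as stable
        else:
            denom = max(abs(prev), 1e-12)
            rel[k] = abs(cur - prev) / denom
    # the final period is excluded: with no subsequent change to check it
    # would declare stability vacuously
    for k in range(len(v) - 1):
        if np.all(rel[k + 1:] < epsilon):
            return float(curve.cumulative_effort[k]), True
    return None, False


def plot_trajectories(curves, ax=None, label_fmt="{metric}", **plot_kw):
    """Plot accumulation curves (value vs cumulative effort), one line each."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for curve in curves:
        ax.plot(curve.cumulative_effort, curve.value,
                marker="o", label=label_fmt.format(metric=curve.metric), **plot_kw)
    ax.set_xlabel("cumulative effort")
    ax.set_ylabel("metric value")
    ax.legend()
    return ax
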