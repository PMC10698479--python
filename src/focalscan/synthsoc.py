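"""Synthetic macaque-group generator and observation-process simulator.

Emulates the study system end-to-end with no field data: groups of adults
with a dominance hierarchy, matrilines and a species-typical social style
(tolerant vs despotic), demographic turnover from a constant departure
hazard, latent dyadic interaction-rate matrices per behaviour (grooming,
huddling, aggression), and both observation protocols — 10-minute focal
follows (~2 per subject per week) and 12 weekly 10-minute scan sessions with
imperfect visibility and detection. Dyadic events are independent Poisson
processes; all outputs are byte-reproducible from the master seed via a
hierarchical seed derivation (master -> group -> process).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .obsdata import (
    Behaviour,
    FocalSession,
    GroupRoster,
    Individual,
    Method,
    ObservationEvent,
    ScanSession,
    write_events,
    write_focal_sessions,
    write_roster,
    write_scan_sessions,
)

__all__ = [
    "SpeciesStyle",
    "GroupConfig",
    "ScenarioConfig",
    "LatentStructure",
    "SimulatedGroup",
    "Scenario",
    "STYLE_PRESETS",
    "make_population",
    "latent_rates",
    "simulate_fas",
    "simulate_abs",
    "make_scenario",
    "study_design_config",
]

DAY = 86400.0
MONTH_DAYS = 30
# scenario origin: 2020-01-06 (a Monday), in seconds since the time origin
ORIGIN = 1578268800.0


@dataclass(frozen=True)
class SpeciesStyle:
    """Species-typical social style parameters.

    despotism in [0, 1] steers grooming up the hierarchy and concentrates
    aggression down-rank (1 = fully unidirectional); kin_bias >= 0 scales the
    within-matriline grooming preference. Base rates are mean dyadic event
    rates in events per hour per ordered dyad. Huddling carries its own kin
    bias, identical across the presets, so the styles differ in huddling
    *frequency* (the rarity multiplier) rather than structure — rare
    huddling, not differently organized huddling, is what distinguishes the
    despotic presets.
    """

    name: str
    despotism: float
    kin_bias: float
    groom_rate: float
    huddle_rate: float
    aggression_rate: float
    aggression_downrank_bias: float = 1.0
    huddle_rarity: float = 1.0
    huddle_kin_bias: float = 1.0  # style-independent: the styles differ in huddling *frequency*

    def __post_init__(self):
        if not 0.0 <= self.despotism <= 1.0:
            raise ValueError("despotism must lie in [0, 1]")
        if self.kin_bias < 0:
            raise ValueError("kin_bias must be >= 0")
        for r in (self.groom_rate, self.huddle_rate, self.aggression_rate, self.huddle_rarity):
            if r < 0:
                raise ValueError("rates must be >= 0")


STYLE_PRESETS: dict[str, SpeciesStyle] = {
    # tolerant: even grooming, frequent huddling, mild aggression
    "tolerant_bonnet": SpeciesStyle(
        name="tolerant_bonnet", despotism=0.15, kin_bias=0.8,
        groom_rate=0.06, huddle_rate=0.05, aggression_rate=0.02,
        aggression_downrank_bias=0.5, huddle_rarity=1.0,
    ),
    # despotic: rank-skewed grooming, rare huddling, frequent down-rank aggression
    "despotic_rhesus": SpeciesStyle(
        name="despotic_rhesus", despotism=0.85, kin_bias=1.5,
        groom_rate=0.05, huddle_rate=0.05, aggression_rate=0.04,
        aggression_downrank_bias=1.5, huddle_rarity=0.15,
    ),
    # despotic with essentially no huddling
    "despotic_longtailed": SpeciesStyle(
        name="despotic_longtailed", despotism=0.80, kin_bias=1.5,
        groom_rate=0.05, huddle_rate=0.05, aggression_rate=0.035,
        aggression_downrank_bias=1.5, huddle_rarity=0.01,
    ),
}


@dataclass
class GroupConfig:
    name: str
    size: int
    style: str  # preset key
    retention: float = 0.8  # expected fraction resident for the whole study
    months: int = 6

    def __post_init__(self):
        if self.size < 2:
            raise ValueError("group size must be >= 2")
        if not 0.0 < self.retention <= 1.0:
            raise ValueError("retention must lie in (0, 1]")
        if self.style not in STYLE_PRESETS:
            raise ValueError(f"unknown style preset {self.style!r}")
        if self.months < 0:
            raise ValueError("months must be >= 0")


@dataclass
class ScenarioConfig:
    groups: list[GroupConfig]
    fas_follows_per_subject_week: int = 2
    fas_duration: float = 600.0
    abs_sessions_per_week: int = 12
    abs_duration: float = 600.0
    visibility: float = 0.9      # P(resident is visible in a scan session)
    detection: float = 0.75      # ABS detection efficiency (Poisson thinning)
    seed: int = 0

    def __post_init__(self):
        if self.fas_follows_per_subject_week < 1 or self.abs_sessions_per_week < 1:
            raise ValueError("schedules must be positive")
        if not 0.0 < self.visibility <= 1.0:
            raise ValueError("visibility must lie in (0, 1]")
        if not 0.0 < self.detection <= 1.0:
            raise ValueError("detection must lie in (0, 1]")

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["groups"] = [GroupConfig(**g) for g in payload["groups"]]
        return cls(**payload)


@dataclass
class LatentStructure:
    """Ground-truth social structure of one group."""

    ids: tuple[str, ...]               # lexicographic order
    rank: np.ndarray                   # 1 = most dominant
    matriline: np.ndarray              # cluster labels
    rates: dict[str, np.ndarray] = field(default_factory=dict)  # behaviour -> ordered-dyad rates (events/h)


def study_design_config(seed: int = 0, months: dict[str, int] | None = None) -> ScenarioConfig:
    """The eight-group study design: three despotic rhesus groups, three
    despotic long-tailed groups and two tolerant bonnet groups, with the
    study's whole-study retention fractions and per-species study spans."""
    months = months or {"despotic_rhesus": 18, "despotic_longtailed": 17, "tolerant_bonnet": 10}
    spec = [
        ("MG", 24, "despotic_rhesus", 0.75),
        ("RG", 34, "despotic_rhesus", 0.79),
        ("HG", 34, "despotic_rhesus", 0.69),
        ("Pirate", 26, "despotic_longtailed", 0.80),
        ("Entrance", 27, "despotic_longtailed", 0.71),
        ("Hulk", 26, "despotic_longtailed", 0.84),
        ("SG", 19, "tolerant_bonnet", 0.83),
        ("LG", 60, "tolerant_bonnet", 0.71),
    ]
    groups = [
        GroupConfig(name=n, size=s, style=st, retention=r, months=months[st])
        for (n, s, st, r) in spec
    ]
    return ScenarioConfig(groups=groups, seed=seed)


# ---------------------------------------------------------------------------
# Population and latent structure
# ---------------------------------------------------------------------------

def _make_group_population(gcfg: GroupConfig, rng: np.random.Generator):
    n = gcfg.size
    study_seconds = gcfg.months * MONTH_DAYS * DAY
    width = len(str(max(n - 1, 1)))
    ids = [f"{gcfg.name}-{k:0{width}d}" for k in range(n)]
    sexes = np.where(rng.random(n) < 0.6, "F", "M")
    # constant departure hazard calibrated so E[whole-study retention] = target
    if gcfg.retention >= 1.0 or study_seconds == 0:
        exits = np.full(n, np.inf)
    else:
        hazard = -np.log(gcfg.retention) / study_seconds
        exits = rng.exponential(1.0 / hazard, size=n)
    members = [
        Individual(
            id=ids[k], sex=str(sexes[k]), group_id=gcfg.name, entry_time=ORIGIN,
            exit_time=None if exits[k] >= study_seconds else ORIGIN + float(exits[k]),
        )
        for k in range(n)
    ]
    roster = GroupRoster(group_id=gcfg.name, members=members)
    rank = rng.permutation(n) + 1  # rank[k] for ids[k]; 1 = top
    # matrilines are strongly size-skewed in macaque groups: draw membership
    # probabilities from a flat Dirichlet rather than assigning uniformly
    n_mat = max(2, n // 5)
    mat_probs = rng.dirichlet(np.ones(n_mat))
    matriline = rng.choice(n_mat, size=n, p=mat_probs)
    structure = LatentStructure(ids=tuple(ids), rank=rank, matriline=matriline)
    structure.rates = latent_rates(structure, STYLE_PRESETS[gcfg.style])
    return roster, structure


def make_population(config: ScenarioConfig, seed=None):
    """Rosters and latent structures for every group in the scenario.

    Entry is at the study origin; exits follow a constant departure hazard
    calibrated so the expected whole-study retention matches the group's
    target. Returns ``{group_name: (GroupRoster, LatentStructure)}``.
    """
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    out = {}
    for gcfg, ss in zip(config.groups, master.spawn(len(config.groups))):
        rng = np.random.default_rng(ss.spawn(3)[0])
        out[gcfg.name] = _make_group_population(gcfg, rng)
    return out


def latent_rates(structure: LatentStructure, style: SpeciesStyle) -> dict[str, np.ndarray]:
    """Ground-truth ordered-dyad rate matrices (events/hour) per behaviour.

    Grooming is biased toward matriline members and up the hierarchy
    (proportional to exp(kin_bias * kin + 2 * despotism * rank_score of the
    recipient)); huddling is symmetric with the matriline bias and the
    species rarity multiplier; aggression concentrates on down-rank dyads,
    with the up-rank share shrinking linearly to 0 at despotism 1. Each
    matrix is normalized so its off-diagonal mean equals the style's base
    rate.
    """
    n = len(structure.ids)
    off = ~np.eye(n, dtype=bool)
    same_mat = (structure.matriline[:, None] == structure.matriline[None, :]).astype(float)
    rank_score = (n - structure.rank) / max(n - 1, 1)  # 1 = most dominant

    def normalized(raw, base):
        raw = raw.copy()
        np.fill_diagonal(raw, 0.0)
        mean = raw[off].mean()
        return raw * (base / mean) if mean > 0 else raw * 0.0

    d, k = style.despotism, style.kin_bias
    groom = np.exp(k * same_mat + 2.0 * d * rank_score[None, :]) * off
    rates = {"grooming": normalized(groom, style.groom_rate)}

    huddle = np.exp(style.huddle_kin_bias * same_mat) * off
    rates["huddling"] = normalized(huddle, style.huddle_rate * style.huddle_rarity)

    down = structure.rank[:, None] < structure.rank[None, :]  # actor outranks recipient
    gap = np.abs(structure.rank[:, None] - structure.rank[None, :]) / max(n, 1)
    agg = np.where(down, 1.0 + d * style.aggression_downrank_bias * gap, 1.0 - d) * off
    rates["aggression"] = normalized(agg, style.aggression_rate)
    return rates


# ---------------------------------------------------------------------------
# Observation-process simulators
# ---------------------------------------------------------------------------

def _poisson_events(rng, structure, rate_pairs, session, behaviour, method):
    """Draw one session's events. ``rate_pairs`` yields
    (i_idx, j_idx, mean_count, p_i_is_actor) over unordered dyads."""
    events = []
    for i, j, mean, p_actor_i in rate_pairs:
        count = rng.poisson(mean)
        for _ in range(count):
            actor, recipient = (i, j) if rng.random() < p_actor_i else (j, i)
            events.append(
                ObservationEvent(
                    timestamp=session.start + rng.random() * session.duration,
                    behaviour=Behaviour(behaviour),
                    actor_id=structure.ids[actor],
                    recipient_id=structure.ids[recipient],
                    method=method,
                    session_id=session.session_id,
                )
            )
    return events


def simulate_fas(
    roster: GroupRoster,
    structure: LatentStructure,
    config: ScenarioConfig,
    months: int,
    seed=None,
):
    """Simulate focal-animal sampling: randomized daily focal order,
    targeting ``fas_follows_per_subject_week`` 10-minute follows per subject.

    During a follow of focal i, each behaviour's events with each co-resident
    j are Poisson with mean (rate[i, j] + rate[j, i]) * duration; the actor
    is i with probability rate[i, j] / (rate[i, j] + rate[j, i]). Only events
    involving the focal are recorded. Returns (events, sessions).
    """
    rng = np.random.default_rng(seed)
    ids = structure.ids
    idx = {v: k for k, v in enumerate(ids)}
    dur_h = config.fas_duration / 3600.0
    n_days = months * MONTH_DAYS
    sessions: list[FocalSession] = []
    events: list[ObservationEvent] = []
    counter = 0
    for week_start in range(0, n_days, 7):
        week_days = list(range(week_start, min(week_start + 7, n_days)))
        t_week = ORIGIN + week_start * DAY
        subjects = [i for i in ids if roster[i].resident(t_week)]
        follows = []  # (day, focal)
        for subj in subjects:
            days = rng.choice(week_days, size=min(config.fas_follows_per_subject_week, len(week_days)), replace=False)
            follows.extend((int(day), subj) for day in days)
        per_day_slot: dict[int, int] = {}
        rng.shuffle(follows)  # randomize daily focal order
        follows.sort(key=lambda f: f[0])  # stable: random order within day
        for day, focal in follows:
            slot = per_day_slot.get(day, 0)
            per_day_slot[day] = slot + 1
            start = ORIGIN + day * DAY + 8 * 3600.0 + slot * config.fas_duration
            if not roster[focal].resident(start):
                continue
            counter += 1
            session = FocalSession(
                session_id=f"{roster.group_id}:FAS:{counter:05d}",
                focal_id=focal, start=start, duration=config.fas_duration,
            )
            sessions.append(session)
            fi = idx[focal]
            copresent = [idx[j] for j in ids if j != focal and roster[j].resident(start)]
            for behaviour, lam in structure.rates.items():
                pairs = []
                for ji in copresent:
                    total = lam[fi, ji] + lam[ji, fi]
                    if total <= 0:
                        continue
                    pairs.append((fi, ji, total * dur_h, lam[fi, ji] / total))
                events.extend(_poisson_events(rng, structure, pairs, session, behaviour, Method.FAS))
    return events, sessions


def simulate_abs(
    roster: GroupRoster,
    structure: LatentStructure,
    config: ScenarioConfig,
    months: int,
    seed=None,
):
    """Simulate all-occurrence scan sessions: ``abs_sessions_per_week``
    10-minute sessions, each with an independent Bernoulli(visibility)
    visible subset of the residents recorded at session start; events among
    visible ordered dyads are Poisson with mean rate * duration * detection.
    Returns (events, sessions)."""
    rng = np.random.default_rng(seed)
    ids = structure.ids
    dur_h = config.abs_duration / 3600.0
    n_days = months * MONTH_DAYS
    sessions: list[ScanSession] = []
    events: list[ObservationEvent] = []
    counter = 0
    hours = (13, 14, 15, 16)
    for week_start in range(0, n_days, 7):
        week_days = list(range(week_start, min(week_start + 7, n_days)))
        slots = [(d, h) for d in week_days for h in hours]
        take = min(config.abs_sessions_per_week, len(slots))
        chosen = sorted(rng.choice(len(slots), size=take, replace=False))
        for c in chosen:
            day, hour = slots[c]
            start = ORIGIN + day * DAY + hour * 3600.0
            residents = [i for i in ids if roster[i].resident(start)]
            visible = [i for i in residents if rng.random() < config.visibility]
            counter += 1
            session = ScanSession(
                session_id=f"{roster.group_id}:ABS:{counter:05d}",
                start=start, duration=config.abs_duration,
                visible_ids=frozenset(visible),
            )
            sessions.append(session)
            if len(visible) < 2:
                continue
            id_pos = {v: k for k, v in enumerate(ids)}
            vis_idx = [id_pos[i] for i in visible]
            for behaviour, lam in structure.rates.items():
                pairs = []
                for a_pos, ai in enumerate(vis_idx):
                    for bi in vis_idx[a_pos + 1:]:
                        total = lam[ai, bi] + lam[bi, ai]
                        if total <= 0:
                            continue
                        pairs.append((ai, bi, total * dur_h * config.detection, lam[ai, bi] / total))
                events.extend(_poisson_events(rng, structure, pairs, session, behaviour, Method.ABS))
    return events, sessions


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGroup:
    config: GroupConfig
    roster: GroupRoster
    structure: LatentStructure
    events: list[ObservationEvent]
    focal_sessions: list[FocalSession]
    scan_sessions: list[ScanSession]


@dataclass
class Scenario:
    config: ScenarioConfig
    groups: dict[str, SimulatedGroup]

    def write_csv(self, outdir) -> None:
        """Serialize to the observation-data CSV schemas (one directory per
        group) plus the ground-truth rate matrices."""
        import pathlib

        outdir = pathlib.Path(outdir)
        for name, g in self.groups.items():
            gdir = outdir / name
            gdir.mkdir(parents=True, exist_ok=True)
            write_roster(g.roster, gdir / "roster.csv")
            write_events(g.events, gdir / "events.csv")
            write_focal_sessions(g.focal_sessions, gdir / "focal_sessions.csv")
            write_scan_sessions(g.scan_sessions, gdir / "scan_sessions.csv")
            rows = []
            for behaviour, lam in g.structure.rates.items():
                for a, i in enumerate(g.structure.ids):
                    for b, j in enumerate(g.structure.ids):
                        if a != b and lam[a, b] > 0:
                            rows.append((behaviour, i, j, lam[a, b]))
            import pandas as pd

            pd.DataFrame(rows, columns=["behaviour", "actor", "recipient", "rate_per_hour"]).to_csv(
                gdir / "truth_rates.csv", index=False
            )
        self.config.to_yaml(outdir / "scenario.yaml")


def make_scenario(config: ScenarioConfig, seed=None) -> Scenario:
    """Simulate the full scenario: populations, both observation protocols
    (scheduled at disjoint times of day: follows 08-12h, scans 13-17h), and
    ground-truth rates, hierarchically seeded from the master seed."""
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    groups: dict[str, SimulatedGroup] = {}
    for gcfg, ss in zip(config.groups, master.spawn(len(config.groups))):
        s_pop, s_fas, s_abs = ss.spawn(3)
        rng = np.random.default_rng(s_pop)
        roster, structure = _make_group_population(gcfg, rng)
        fas_events, fas_sessions = simulate_fas(roster, structure, config, gcfg.months, seed=s_fas)
        abs_events, abs_sessions = simulate_abs(roster, structure, config, gcfg.months, seed=s_abs)
        _assert_protocol_invariants(fas_events, fas_sessions, abs_events, abs_sessions)
        groups[gcfg.name] = SimulatedGroup(
            config=gcfg, roster=roster, structure=structure,
            events=fas_events + abs_events,
            focal_sessions=fas_sessions, scan_sessions=abs_sessions,
        )
    return Scenario(config=config, groups=groups)


def _assert_protocol_invariants(fas_events, fas_sessions, abs_events, abs_sessions):
    focal_of = {s.session_id: s.focal_id for s in fas_sessions}
    for e in fas_events:
        assert focal_of[e.session_id] in (e.actor_id, e.recipient_id), \
            "FAS event does not involve the focal subject"
    visible_of = {s.session_id: s.visible_ids for s in abs_sessions}
    for e in abs_events:
        vis = visible_of[e.session_id]
        assert e.actor_id in vis and e.recipient_id in vis, \
            "ABS event involves a non-visible individual"
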