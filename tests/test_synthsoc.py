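"""Synthetic generator: demography, latent rates, and both observation processes."""

import numpy as np
import pytest

from focalscan.netbuild import build_network
from focalscan.obsdata import (
    Method,
    read_events,
    read_focal_sessions,
    read_roster,
    read_scan_sessions,
)
from focalscan.synthsoc import (
    STYLE_PRESETS,
    GroupConfig,
    LatentStructure,
    ScenarioConfig,
    SpeciesStyle,
    latent_rates,
    make_population,
    make_scenario,
    study_design_config,
    simulate_abs,
    simulate_fas,
)


def flat_style(groom=3.0, huddle=0.0, aggression=0.0):
    """No despotism, no kin bias: every dyad shares the same rate."""
    return SpeciesStyle(name="flat", despotism=0.0, kin_bias=0.0,
                        groom_rate=groom, huddle_rate=huddle,
                        aggression_rate=aggression)


def two_person_config(months, style_key=None, **kw):
    cfg = ScenarioConfig(groups=[GroupConfig(name="P", size=2, style="tolerant_bonnet",
                                             retention=1.0, months=months)], **kw)
    return cfg


class TestPopulation:
    def test_full_retention_no_departures(self):
        cfg = ScenarioConfig(groups=[GroupConfig("G", 20, "tolerant_bonnet",
                                                 retention=1.0, months=6)], seed=1)
        roster, _ = make_population(cfg)["G"]
        assert all(m.exit_time is None for m in roster.members)

    def test_retention_calibration_monte_carlo(self):
        # closed form: P(Exp(hazard) > T) = retention with hazard = -ln(r)/T;
        # 4 x 10^4 simulated individuals (200 groups of 200) keep the
        # Monte-Carlo error well inside the +/-0.01 band
        cfg = ScenarioConfig(groups=[GroupConfig(f"G{k:03d}", 200, "tolerant_bonnet",
                                                 retention=0.75, months=12)
                                     for k in range(200)], seed=2)
        pops = make_population(cfg)
        stayed = sum(m.exit_time is None
                     for roster, _ in pops.values() for m in roster.members)
        assert stayed / 40_000 == pytest.approx(0.75, abs=0.01)

    def test_seed_determinism(self, tmp_path):
        cfg = ScenarioConfig(groups=[GroupConfig("G", 15, "despotic_rhesus",
                                                 retention=0.8, months=3)], seed=9)
        r1, s1 = make_population(cfg)["G"]
        r2, s2 = make_population(cfg)["G"]
        assert r1 == r2
        assert np.array_equal(s1.rank, s2.rank)
        assert all(np.array_equal(s1.rates[b], s2.rates[b]) for b in s1.rates)

    def test_invalid_retention_rejected(self):
        with pytest.raises(ValueError):
            GroupConfig("G", 10, "tolerant_bonnet", retention=0.0, months=3)


class TestLatentRates:
    def make_structure(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return LatentStructure(
            ids=tuple(f"i{k:02d}" for k in range(n)),
            rank=rng.permutation(n) + 1,
            matriline=rng.integers(0, 3, n),
        )

    def test_no_bias_gives_uniform_grooming(self):
        s = self.make_structure()
        lam = latent_rates(s, flat_style(groom=2.0))["grooming"]
        off = lam[~np.eye(10, dtype=bool)]
        assert np.allclose(off, 2.0)

    def test_full_despotism_zeroes_uprank_aggression(self):
        s = self.make_structure()
        style = SpeciesStyle(name="tyrant", despotism=1.0, kin_bias=0.0,
                             groom_rate=1.0, huddle_rate=0.0, aggression_rate=1.0)
        lam = latent_rates(s, style)["aggression"]
        up = s.rank[:, None] > s.rank[None, :]  # actor outranked by recipient
        assert np.all(lam[up] == 0.0)
        assert lam[~up & ~np.eye(10, dtype=bool)].min() > 0

    def test_despotism_raises_gini_of_grooming_received(self):
        def gini(x):
            x = np.sort(x)
            n = len(x)
            return (2 * np.arange(1, n + 1) - n - 1) @ x / (n * x.sum())

        s = self.make_structure()
        tolerant = SpeciesStyle("t", despotism=0.0, kin_bias=0.8, groom_rate=1.0,
                                huddle_rate=0.0, aggression_rate=0.0)
        despotic = SpeciesStyle("d", despotism=0.9, kin_bias=0.8, groom_rate=1.0,
                                huddle_rate=0.0, aggression_rate=0.0)
        g_tol = gini(latent_rates(s, tolerant)["grooming"].sum(axis=0))
        g_desp = gini(latent_rates(s, despotic)["grooming"].sum(axis=0))
        assert g_desp > g_tol

    def test_huddling_symmetric_and_rarity_scaled(self):
        s = self.make_structure()
        style = STYLE_PRESETS["despotic_rhesus"]
        lam = latent_rates(s, style)["huddling"]
        assert np.allclose(lam, lam.T)
        off = ~np.eye(10, dtype=bool)
        assert lam[off].mean() == pytest.approx(style.huddle_rate * style.huddle_rarity)


class TestSimulateFas:
    def test_zero_rates_no_events(self):
        cfg = ScenarioConfig(groups=[GroupConfig("P", 2, "tolerant_bonnet",
                                                 retention=1.0, months=2)], seed=3)
        roster, structure = make_population(cfg)["P"]
        structure.rates = {b: np.zeros((2, 2)) for b in structure.rates}
        events, sessions = simulate_fas(roster, structure, cfg, months=2, seed=4)
        assert events == [] and len(sessions) > 0

    def test_poisson_mean_one_event_per_follow(self):
        # dyad rate 6/h, 10-min follows: mean 1.0 event per follow
        cfg = ScenarioConfig(groups=[GroupConfig("P", 2, "tolerant_bonnet",
                                                 retention=1.0, months=170)],
                             fas_follows_per_subject_week=7, seed=5)
        roster, structure = make_population(cfg)["P"]
        rng = np.random.default_rng(0)
        lam = np.array([[0.0, 3.0], [3.0, 0.0]])
        structure.rates = {"grooming": lam, "huddling": np.zeros((2, 2)),
                          "aggression": np.zeros((2, 2))}
        events, sessions = simulate_fas(roster, structure, cfg, months=170, seed=6)
        n_follows = len(sessions)
        assert n_follows >= 10_000
        assert len(events) / n_follows == pytest.approx(1.0, abs=0.03)

    def test_same_seed_identical_log(self):
        cfg = ScenarioConfig(groups=[GroupConfig("G", 8, "despotic_rhesus",
                                                 retention=0.9, months=2)], seed=7)
        roster, structure = make_population(cfg)["G"]
        e1, s1 = simulate_fas(roster, structure, cfg, months=2, seed=11)
        e2, s2 = simulate_fas(roster, structure, cfg, months=2, seed=11)
        assert e1 == e2 and s1 == s2

    def test_all_events_involve_focal(self):
        cfg = ScenarioConfig(groups=[GroupConfig("G", 10, "tolerant_bonnet",
                                                 retention=0.9, months=2)], seed=8)
        roster, structure = make_population(cfg)["G"]
        events, sessions = simulate_fas(roster, structure, cfg, months=2, seed=12)
        focal = {s.session_id: s.focal_id for s in sessions}
        assert events
        for e in events:
            assert focal[e.session_id] in (e.actor_id, e.recipient_id)


class TestSimulateAbs:
    def test_tiny_visibility_no_events(self):
        cfg = ScenarioConfig(groups=[GroupConfig("G", 10, "tolerant_bonnet",
                                                 retention=1.0, months=2)],
                             visibility=1e-9, seed=9)
        roster, structure = make_population(cfg)["G"]
        events, sessions = simulate_abs(roster, structure, cfg, months=2, seed=13)
        assert events == []
        assert all(len(s.visible_ids) <= 1 for s in sessions)

    def test_full_visibility_matches_fas_rate_law(self):
        # v=1, eta=1: expected per-dyad session counts equal the in-session
        # Poisson means of the focal protocol
        cfg = ScenarioConfig(groups=[GroupConfig("P", 2, "tolerant_bonnet",
                                                 retention=1.0, months=60)],
                             visibility=1.0, detection=1.0,
                             abs_sessions_per_week=28, seed=10)
        roster, structure = make_population(cfg)["P"]
        lam = np.array([[0.0, 3.0], [3.0, 0.0]])
        structure.rates = {"grooming": lam, "huddling": np.zeros((2, 2)),
                          "aggression": np.zeros((2, 2))}
        events, sessions = simulate_abs(roster, structure, cfg, months=60, seed=14)
        mean = len(events) / len(sessions)
        assert mean == pytest.approx(1.0, abs=0.05)  # 6/h * (1/6)h

    def test_halving_detection_halves_event_count(self):
        counts = {}
        for det in (1.0, 0.5):
            cfg = ScenarioConfig(groups=[GroupConfig("G", 12, "tolerant_bonnet",
                                                     retention=1.0, months=12)],
                                 visibility=1.0, detection=det,
                                 abs_sessions_per_week=28, seed=11)
            roster, structure = make_population(cfg)["G"]
            events, sessions = simulate_abs(roster, structure, cfg, months=12, seed=15)
            counts[det] = len(events) / len(sessions)
        assert counts[0.5] / counts[1.0] == pytest.approx(0.5, abs=0.05)

    def test_events_only_among_visible(self):
        cfg = ScenarioConfig(groups=[GroupConfig("G", 12, "despotic_rhesus",
                                                 retention=0.9, months=2)],
                             visibility=0.6, seed=12)
        roster, structure = make_population(cfg)["G"]
        events, sessions = simulate_abs(roster, structure, cfg, months=2, seed=16)
        visible = {s.session_id: s.visible_ids for s in sessions}
        assert events
        for e in events:
            assert {e.actor_id, e.recipient_id} <= visible[e.session_id]


class TestScenario:
    def test_paper_design_round_trips_through_readers(self, tmp_path):
        cfg = study_design_config(seed=21)
        # scaled-down spans keep the fixture fast; the design shape is intact
        for g in cfg.groups:
            g.months = 1
        scn = make_scenario(cfg)
        assert len(scn.groups) == 8
        scn.write_csv(tmp_path)
        for name, g in scn.groups.items():
            roster = read_roster(tmp_path / name / "roster.csv")
            events = read_events(tmp_path / name / "events.csv")
            focal = read_focal_sessions(tmp_path / name / "focal_sessions.csv")
            scans = read_scan_sessions(tmp_path / name / "scan_sessions.csv")
            assert roster.ids == g.roster.ids
            assert len(events) == len(g.events)
            assert len(focal) == len(g.focal_sessions)
            assert len(scans) == len(g.scan_sessions)
        cfg2 = ScenarioConfig.from_yaml(tmp_path / "scenario.yaml")
        assert cfg2 == cfg

    def test_zero_months_empty_logs_valid_rosters(self):
        cfg = ScenarioConfig(groups=[GroupConfig("G", 6, "tolerant_bonnet",
                                                 retention=1.0, months=0)], seed=22)
        scn = make_scenario(cfg)
        g = scn.groups["G"]
        assert g.events == [] and g.focal_sessions == [] and g.scan_sessions == []
        assert len(g.roster.members) == 6

    def test_fas_and_abs_sessions_disjoint_in_time(self):
        cfg = ScenarioConfig(groups=[GroupConfig("G", 8, "tolerant_bonnet",
                                                 retention=1.0, months=2)], seed=23)
        scn = make_scenario(cfg)
        g = scn.groups["G"]
        for f in g.focal_sessions:
            for s in g.scan_sessions:
                assert f.end <= s.start or s.end <= f.start

    def test_byte_reproducibility(self, tmp_path):
        cfg = ScenarioConfig(groups=[GroupConfig("G", 10, "despotic_rhesus",
                                                 retention=0.8, months=2)], seed=24)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_scenario(cfg).write_csv(d1)
        make_scenario(cfg).write_csv(d2)
        for name in ("roster.csv", "events.csv", "focal_sessions.csv",
                     "scan_sessions.csv", "truth_rates.csv"):
            assert (d1 / "G" / name).read_bytes() == (d2 / "G" / name).read_bytes()

    def test_estimated_degree_recovers_truth_with_ample_effort(self):
        # "ample" here: an intensified schedule (6 follows/subject/week, 24
        # scans/week) over 3 years, enough for per-dyad rates to converge
        cfg = ScenarioConfig(groups=[GroupConfig("G", 15, "tolerant_bonnet",
                                                 retention=1.0, months=36)],
                             fas_follows_per_subject_week=6,
                             abs_sessions_per_week=24, seed=25)
        scn = make_scenario(cfg)
        g = scn.groups["G"]
        truth = g.structure.rates["grooming"]
        true_strength = (truth + truth.T).sum(axis=1)
        for method, sessions in (("FAS", g.focal_sessions), ("ABS", g.scan_sessions)):
            net = build_network(g.events, g.roster, sessions, "grooming", method)
            est_strength = net.W.sum(axis=1)
            r = np.corrcoef(true_strength, est_strength)[0, 1]
            assert r > 0.9, f"{method} recovery r={r:.3f}"
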