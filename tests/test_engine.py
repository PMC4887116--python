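"""Stochastic assembly engine: event semantics, determinism, and agreement
with exact continuous-time Markov-chain oracles on toy systems."""

import math
from dataclasses import replace

import numpy as np
import pytest

from capsidsim.corrections import AVOGADRO
from capsidsim.engine import (
    ASSOCIATION,
    CLOSURE,
    DISSOCIATION,
    NEVER,
    Assembly,
    SimConfig,
    Simulation,
    draw_event_time,
    exponential_time,
    run_ensemble,
    run_trajectory,
    steric_join_check,
)
from capsidsim.ruleset import make_ruleset


def per_pair_rate(kon: float, n_subunits: int, conc_uM: float = 15.6) -> float:
    """Independent conversion of a bimolecular on-rate to a stochastic rate."""
    volume_L = n_subunits / (conc_uM * 1e-6 * AVOGADRO)
    return kon / (AVOGADRO * volume_L)


class TestEventTimeSampling:
    def test_inverse_cdf_median(self):
        lam = 3.7
        assert exponential_time(lam, 0.5) == pytest.approx(math.log(2) / lam)

    def test_zero_rate_never_fires(self):
        assert exponential_time(0.0, 0.5) == NEVER

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            exponential_time(-1.0, 0.5)
        with pytest.raises(ValueError):
            exponential_time(1.0, 0.0)

    def test_mean_of_draws(self):
        rng = np.random.default_rng(123)
        lam, n = 2.0, 10_000
        draws = np.array([draw_event_time(lam, rng) for _ in range(n)])
        se = 1 / lam / math.sqrt(n)
        assert abs(draws.mean() - 1 / lam) < 3 * se


class TestEventEnumeration:
    def test_two_free_monomers_triangle_single_event(self, triangle_ruleset):
        sim = Simulation(
            triangle_ruleset,
            config=SimConfig(n_subunits=2, seed=0),
            assemblies=[Assembly(0, frozenset(), frozenset()),
                        Assembly(1, frozenset(), frozenset())],
        )
        events = sim.pending_events()
        assert len(events) == 1
        assert events[0].kind == ASSOCIATION
        assert events[0].rate == pytest.approx(
            per_pair_rate(triangle_ruleset.bond_classes["pentagon"].kon, 2)
        )

    def test_bonded_dimer_single_dissociation(self, triangle_ruleset):
        sim = Simulation(
            triangle_ruleset,
            config=SimConfig(n_subunits=2, seed=0),
            assemblies=[Assembly(0, frozenset({0, 1}), frozenset({(0, 1)}))],
        )
        events = sim.pending_events()
        assert [e.kind for e in events] == [DISSOCIATION]
        assert events[0].rate == triangle_ruleset.bond_classes["pentagon"].koff

    def test_empty_state_no_events(self, triangle_ruleset):
        sim = Simulation(
            triangle_ruleset, config=SimConfig(n_subunits=0, seed=0), assemblies=[]
        )
        assert sim.pending_events() == []

    def test_ccmv_monomer_pair_has_two_contact_types(self, ccmv_ruleset):
        """A free dimer pair can form a pentagon-ring or hexagon-ring contact."""
        sim = Simulation(
            ccmv_ruleset,
            config=SimConfig(n_subunits=2, seed=0),
            assemblies=[Assembly(0, frozenset(), frozenset()),
                        Assembly(1, frozenset(), frozenset())],
        )
        events = sim.pending_events()
        assert len(events) == 2
        rates = sorted(e.rate for e in events)
        expected = sorted(
            per_pair_rate(ccmv_ruleset.bond_classes[c].kon, 2)
            for c in ("pentagon", "hexagon")
        )
        assert rates == pytest.approx(expected)


class TestStericJoinCheck:
    def test_monomer_always_joins_free_edge(self, ccmv_lattice):
        a = Assembly(0, frozenset({0}), frozenset())
        b = Assembly(1, frozenset(), frozenset())
        y = sorted(ccmv_lattice.neighbors[0])[0]
        ok, merged = steric_join_check(ccmv_lattice, a, b, (0, y))
        assert ok and merged == {0, y}

    def test_occupied_target_is_hindered(self, ccmv_lattice):
        y = sorted(ccmv_lattice.neighbors[0])[0]
        a = Assembly(0, frozenset({0, y}), frozenset({(min(0, y), max(0, y))}))
        b = Assembly(1, frozenset(), frozenset())
        ok, merged = steric_join_check(ccmv_lattice, a, b, (0, y))
        assert not ok and merged is None

    def test_complementary_dodecahedron_halves_complete(self, dodeca_lattice):
        g = dodeca_lattice.graph
        half = {0} | set(g.neighbors(0))  # a 6-wheel
        rest = set(g.nodes) - half
        a = Assembly(0, frozenset(half), dodeca_lattice.induced_edges(frozenset(half)))
        b = Assembly(1, frozenset(rest), dodeca_lattice.induced_edges(frozenset(rest)))
        x, y = next(
            (u, v)
            for u in sorted(half)
            for v in sorted(g.neighbors(u))
            if v in rest
        )
        ok, merged = steric_join_check(dodeca_lattice, a, b, (x, y))
        assert ok and merged == set(g.nodes)


class TestEventApplication:
    def test_monomer_pair_forms_single_bond_dimer(self, triangle_ruleset):
        sim = Simulation(
            triangle_ruleset,
            config=SimConfig(n_subunits=2, seed=3, time_limit=50.0),
        )
        log = sim.run()
        first = log.records[0]
        assert (first.kind, first.size_i, first.size_j, first.product_size) == (
            ASSOCIATION, 1, 1, 2,
        )
        # a dimer occupies two adjacent slots of the 3-cycle: exactly 1 bond
        lat = triangle_ruleset.lattice
        assert len(lat.induced_edges(frozenset({0, 1}))) == 1

    def test_implied_ring_closure_on_triangle(self, triangle_ruleset):
        """Dimer + monomer closes the 3-ring: one event, three bonds."""
        sim = Simulation(
            triangle_ruleset,
            config=SimConfig(n_subunits=3, seed=5, time_limit=1e6),
            assemblies=[
                Assembly(0, frozenset({0, 1}), frozenset({(0, 1)})),
                Assembly(1, frozenset(), frozenset()),
            ],
        )
        log = sim.run()
        rec = log.records[0]
        assert (rec.kind, rec.size_i, rec.size_j, rec.product_size) == (
            ASSOCIATION, 2, 1, 3,
        )
        trimer = next(iter(sim.assemblies.values()))
        assert len(trimer.bonds) == 3
        assert log.completed

    def test_implied_closure_counts_on_ccmv_pentagon(self, ccmv_ruleset):
        """Filling the last slot of a pentamer ring forms 2 bonds at once."""
        lat = ccmv_ruleset.lattice
        ring = next(r for r in lat.rings if r.kind == "pentagon")
        path = frozenset(ring.nodes[:4])
        sim = Simulation(
            ccmv_ruleset,
            config=SimConfig(n_subunits=5, seed=1, time_limit=1e-9),
            assemblies=[
                Assembly(0, path, lat.induced_edges(path)),
                Assembly(1, frozenset(), frozenset()),
            ],
        )
        shape, inv = sim._canonical(sim.assemblies[0])
        closing = [
            (y, classes)
            for y, classes in sim._free_neighbor_modes(shape)
            if sum(n for _, n in classes) >= 2
        ]
        assert closing, "no multi-contact placement found for the open pentamer"
        y, classes = closing[0]
        merged = frozenset(shape) | {y}
        assert len(lat.induced_edges(merged)) == len(lat.induced_edges(frozenset(shape))) + sum(
            n for _, n in classes
        )

    def test_bridge_dissociation_splits(self, triangle_ruleset):
        """Breaking the only bond of a dimer yields two free monomers."""
        sim = Simulation(
            triangle_ruleset,
            config=SimConfig(n_subunits=2, seed=7, time_limit=20.0),
            assemblies=[Assembly(0, frozenset({0, 1}), frozenset({(0, 1)}))],
        )
        log = sim.run()
        rec = log.records[0]
        assert (rec.kind, rec.size_i, rec.size_j, rec.product_size) == (
            DISSOCIATION, 1, 1, 2,
        )

    def test_ring_bond_break_does_not_split(self, triangle_ruleset):
        """One bond of a closed 3-ring breaks: still one 3-mer, then the open
        contact re-closes as a fast closure event."""
        nodes = frozenset({0, 1, 2})
        lat = triangle_ruleset.lattice
        sim = Simulation(
            triangle_ruleset,
            config=SimConfig(n_subunits=3, seed=11, time_limit=5.0,
                             stop_on_completion=False),
            assemblies=[Assembly(0, nodes, lat.induced_edges(nodes))],
        )
        log = sim.run()
        kinds = [r.kind for r in log.records[:2]]
        assert kinds[0] == DISSOCIATION
        assert log.records[0].size_j == 0  # no split
        assert log.records[0].product_size == 3
        assert kinds[1] in (CLOSURE, DISSOCIATION)
        assert any(r.kind == CLOSURE for r in log.records[:10])

    def test_linear_trimer_bridge_break(self, dodeca_ruleset):
        """Breaking a bridge of a path trimer gives a dimer and a monomer."""
        g = dodeca_ruleset.lattice.graph
        a = 0
        b = sorted(g.neighbors(a))[0]
        c = next(
            n for n in sorted(g.neighbors(b)) if n != a and not g.has_edge(n, a)
        )
        nodes = frozenset({a, b, c})
        bonds = frozenset({(min(a, b), max(a, b)), (min(b, c), max(b, c))})
        assert dodeca_ruleset.lattice.induced_edges(nodes) == bonds  # genuine path
        sim = Simulation(
            dodeca_ruleset,
            config=SimConfig(n_subunits=3, seed=13, time_limit=1e6,
                             stop_on_completion=False),
            kon_scale=1e-12,  # isolate dissociation behaviour
            assemblies=[Assembly(0, nodes, bonds)],
        )
        log = sim.run()
        rec = log.records[0]
        assert rec.kind == DISSOCIATION
        assert (rec.size_i, rec.size_j, rec.product_size) == (2, 1, 3)


class TestTrajectories:
    def test_zero_on_rates_empty_log(self, triangle_ruleset):
        log = run_trajectory(
            triangle_ruleset, config=SimConfig(n_subunits=3, seed=0, time_limit=5.0),
            kon_scale=0.0,
        )
        assert len(log.records) == 0
        assert log.final_time == 5.0
        assert not log.completed

    def test_identical_seed_identical_log(self, dodeca_ruleset):
        cfg = SimConfig(n_subunits=12, seed=99, time_limit=10.0)
        a = run_trajectory(dodeca_ruleset, config=cfg)
        b = run_trajectory(dodeca_ruleset, config=cfg)
        assert a.records == b.records
        assert a.final_time == b.final_time

    def test_ensemble_reproducible_and_consistent(self, dodeca_ruleset):
        cfg = SimConfig(n_subunits=12, seed=0, time_limit=5.0)
        e1 = run_ensemble(dodeca_ruleset, config=cfg, reps=4, base_seed=17)
        e2 = run_ensemble(dodeca_ruleset, config=cfg, reps=4, base_seed=17)
        assert all(x.records == y.records for x, y in zip(e1, e2))
        solo = run_trajectory(dodeca_ruleset, config=replace(cfg, seed=17))
        assert e1[0].records == solo.records

    def test_mass_conservation_along_trajectories(self, dodeca_ruleset):
        """Total subunit count is invariant after every event (checked by
        replaying the census, which raises on any imbalance)."""
        from capsidsim.analysis import mass_fraction_series

        for seed in range(6):
            log = run_trajectory(
                dodeca_ruleset,
                config=SimConfig(n_subunits=12, seed=seed, time_limit=20.0),
            )
            mf = mass_fraction_series(log)
            assert np.allclose(mf.fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_assembly_size_never_exceeds_lattice(self, dodeca_ruleset):
        for seed in (21, 22):
            log = run_trajectory(
                dodeca_ruleset,
                config=SimConfig(n_subunits=12, seed=seed, time_limit=20.0),
            )
            for rec in log.records:
                assert rec.product_size <= dodeca_ruleset.capsid_size
            if log.completed:
                assert log.records[-1].product_size == dodeca_ruleset.capsid_size

    def test_completed_capsid_has_all_bonds(self, triangle_ruleset):
        sim = Simulation(
            triangle_ruleset, config=SimConfig(n_subunits=3, seed=1, time_limit=1e6)
        )
        log = sim.run()
        assert log.completed
        capsid = max(sim.assemblies.values(), key=lambda a: a.size)
        assert capsid.bonds == triangle_ruleset.lattice.induced_edges(capsid.nodes)

    def test_first_event_time_matches_exponential_race(self, triangle_ruleset):
        """With a single possible event at rate L, the mean first-event time
        over many seeds is 1/L (irreversible monomer+monomer toy)."""
        rate = per_pair_rate(triangle_ruleset.bond_classes["pentagon"].kon, 2)
        n = 400
        times = []
        for seed in range(n):
            sim = Simulation(
                triangle_ruleset,
                config=SimConfig(n_subunits=2, seed=seed, time_limit=1e9),
                koff_scale=0.0,  # irreversible: exactly one event ever fires
            )
            log = sim.run()
            times.append(log.records[0].time)
        se = (1 / rate) / math.sqrt(n)
        assert abs(np.mean(times) - 1 / rate) < 3 * se


# ---------------------------------------------------------------- CTMC oracle


def triangle_generator(r_on: float, koff: float, rc: float) -> np.ndarray:
    """Exact generator of the 3-subunit triangle system, derived from first
    principles independently of the engine.

    Lumped states: 0 = three free monomers, 1 = dimer + monomer,
    2 = open trimer (one ring contact broken), 3 = closed trimer.

    Rates: three monomer pairs each associate at ``r_on``; the dimer gains
    the third subunit through one placement that forms two contacts (2*r_on)
    and closes the ring instantly; each of the three ring bonds breaks at
    ``koff`` without splitting; from the open trimer either of the two
    remaining bonds breaks (2*koff, splitting off a monomer) or the open
    contact re-closes at ``rc``.
    """
    q = np.zeros((4, 4))
    q[0, 1] = 3 * r_on
    q[1, 0] = koff
    q[1, 3] = 2 * r_on
    q[3, 2] = 3 * koff
    q[2, 3] = rc
    q[2, 1] = 2 * koff
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    from scipy.linalg import null_space

    ns = null_space(q.T)
    pi = ns[:, 0]
    return pi / pi.sum()


def classify_triangle_states(log, time_limit: float) -> np.ndarray:
    """Time-weighted occupancy of the four lumped triangle states from a log."""
    occ = np.zeros(4)
    state = 0
    t_prev = 0.0
    for rec in log.records:
        occ[state] += rec.time - t_prev
        t_prev = rec.time
        if rec.kind == ASSOCIATION:
            state = 1 if rec.product_size == 2 else 3
        elif rec.kind == CLOSURE:
            state = 3
        else:  # dissociation
            if rec.size_j == 0:
                state = 2
            elif rec.product_size == 2:
                state = 0
            else:  # open trimer splits
                state = 1
    occ[state] += time_limit - t_prev
    return occ / occ.sum()


class TestMasterEquationOracle:
    def run_and_compare(self, ruleset, kon_scale, koff_scale, seed, time_limit=4000.0):
        cfg = SimConfig(
            n_subunits=3, seed=seed, time_limit=time_limit, stop_on_completion=False
        )
        log = run_trajectory(ruleset, config=cfg, kon_scale=kon_scale,
                             koff_scale=koff_scale)
        assert len(log.records) >= 10_000
        r_on = per_pair_rate(ruleset.bond_classes["pentagon"].kon, 3) * kon_scale
        koff = ruleset.bond_classes["pentagon"].koff * koff_scale
        pi = stationary_distribution(
            triangle_generator(r_on, koff, ruleset.ring_closure_rate)
        )
        emp = classify_triangle_states(log, time_limit)

        # 3-sigma tolerance from batch means over 20 trajectory segments
        n_batch = 20
        edges = np.linspace(0, time_limit, n_batch + 1)
        batches = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sub_occ = np.zeros(4)
            state, t_prev = 0, 0.0
            for rec in log.records:
                t_clip = min(max(rec.time, lo), hi)
                p_clip = min(max(t_prev, lo), hi)
                sub_occ[state] += t_clip - p_clip
                t_prev = rec.time
                if rec.kind == ASSOCIATION:
                    state = 1 if rec.product_size == 2 else 3
                elif rec.kind == CLOSURE:
                    state = 3
                elif rec.size_j == 0:
                    state = 2
                elif rec.product_size == 2:
                    state = 0
                else:
                    state = 1
            sub_occ[state] += max(time_limit, lo) - min(max(t_prev, lo), hi)
            total = sub_occ.sum()
            if total > 0:
                batches.append(sub_occ / total)
        sem = np.std(batches, axis=0, ddof=1) / math.sqrt(len(batches))
        for s in range(4):
            tol = max(3 * sem[s], 5e-3)
            assert abs(emp[s] - pi[s]) < tol, (
                f"state {s}: empirical {emp[s]:.4f} vs exact {pi[s]:.4f} "
                f"(tol {tol:.4f})"
            )
        return emp, pi

    def test_occupancies_match_exact_solution(self, triangle_ruleset):
        self.run_and_compare(triangle_ruleset, 1.0, 1.0, seed=2024)

    def test_detailed_balance_rate_scaling(self, triangle_ruleset):
        """Scaling on-rates by a and off-rates by b shifts the stationary
        assembled:free odds by (a/b) per bond, verified exactly on the
        oracle and statistically on the engine."""
        r_on = per_pair_rate(triangle_ruleset.bond_classes["pentagon"].kon, 3)
        koff = triangle_ruleset.bond_classes["pentagon"].koff
        rc = triangle_ruleset.ring_closure_rate
        alpha, beta = 3.0, 0.5
        pi0 = stationary_distribution(triangle_generator(r_on, koff, rc))
        pi1 = stationary_distribution(
            triangle_generator(alpha * r_on, beta * koff, rc)
        )
        # dimer state has one bond: odds shift by exactly alpha/beta
        odds0 = pi0[1] / pi0[0]
        odds1 = pi1[1] / pi1[0]
        assert odds1 / odds0 == pytest.approx(alpha / beta, rel=1e-9)
        # engine agrees with the scaled oracle too
        self.run_and_compare(
            triangle_ruleset, alpha, beta, seed=4048, time_limit=3000.0
        )


class TestKineticMonotonicity:
    def test_time_to_max_decreases_with_on_rate(self, dodeca_ruleset):
        """Statistical check: faster binding reaches the maximum assembly
        size sooner on the 12-subunit toy capsid."""
        from capsidsim.analysis import trajectory_summary

        means = []
        for kon_scale in (0.5, 50.0):
            logs = run_ensemble(
                dodeca_ruleset,
                config=SimConfig(n_subunits=12, time_limit=60.0),
                reps=8, base_seed=7, kon_scale=kon_scale,
            )
            means.append(np.mean([trajectory_summary(l).time_to_max for l in logs]))
        assert means[1] < means[0]
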