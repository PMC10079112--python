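"""Mutation operators, pleiotropy constraints, and selection rules."""

import collections

import numpy as np
import pytest
from scipy import stats

from pleiosim.evolution import (
    EvolutionParams,
    PopulationExtinct,
    apply_pleiotropy,
    cull_population,
    fitness_percentiles,
    mutate_host,
    mutate_parasite,
    reproduce_hosts,
    reproduce_parasites,
)
from pleiosim.infection import Parasite
from pleiosim.network import init_random_network

from conftest import make_net

EP = EvolutionParams()


class TestApplyPleiotropy:
    def test_none_leaves_network_unchanged(self, rng):
        net = init_random_network(rng)
        assert apply_pleiotropy(net, "none", rng) is net

    def test_fixed_down_installs_single_locked_repressor(self, rng):
        net = init_random_network(rng)
        out = apply_pleiotropy(net, "fixed-down", rng)
        pleio = out.pleiotropy
        assert pleio.mode == "fixed-down"
        assert pleio.locked == frozenset([(pleio.node_id, "E")])
        assert out.edges[(pleio.node_id, "E")] == -1.0

    def test_fixed_up_installs_activator(self, rng):
        out = apply_pleiotropy(init_random_network(rng), "fixed-up", rng)
        (edge,) = out.pleiotropy.locked
        assert out.edges[edge] == 1.0

    def test_fixed_random_locks_initial_incident_edges(self, rng):
        net = init_random_network(rng)
        out = apply_pleiotropy(net, "fixed-random", rng)
        pleio = out.pleiotropy
        expected = {e for e in net.edges if pleio.node_id in e}
        assert pleio.locked == frozenset(expected)

    def test_slow_marks_node_without_locks(self, rng):
        out = apply_pleiotropy(init_random_network(rng), "slow", rng)
        assert out.pleiotropy.mode == "slow"
        assert out.pleiotropy.locked == frozenset()

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_pleiotropy(init_random_network(rng), "sideways", rng)


class TestMutateHost:
    def test_zero_rate_returns_parent_object(self, rng):
        net = init_random_network(rng)
        params = EvolutionParams(host_mutation_rate=0.0)
        child, mtype = mutate_host(net, params, rng)
        assert child is net and mtype is None

    def test_structural_invariants_hold_under_mutation_stream(self, rng):
        net = apply_pleiotropy(init_random_network(rng), "fixed-down", rng)
        for _ in range(2000):
            net, _ = mutate_host(net, EP, rng, force=True)
            roles = [n.role for n in net.nodes]
            assert roles.count("detector") == 1 and roles.count("effector") == 1
            assert ("D", "E") not in net.edges
            assert all(-1 <= w <= 1 for w in net.edges.values())

    def test_locked_repressor_survives_mutated_offspring(self, rng):
        parent = apply_pleiotropy(init_random_network(rng), "fixed-down", rng)
        edge = next(iter(parent.pleiotropy.locked))
        for _ in range(3000):
            child, _ = mutate_host(parent, EP, rng, force=True)
            assert child.edges.get(edge) == -1.0

    def test_duplication_copies_incident_edges(self, rng):
        # S1 has in-degree 2 (from D and S2) and out-degree 1 (to E):
        # duplication adds one node and three edges
        net = make_net({("D", "S1"): 0.4, ("S2", "S1"): -0.2, ("S1", "E"): 0.9})
        params = EvolutionParams(host_mutation_weights=(0, 0, 0, 0, 1.0))
        for _ in range(20):
            child, mtype = mutate_host(net, params, rng, force=True)
            assert mtype == "dup_protein"
            if child.size == net.size + 1 and ("S4", "E") in child.edges:
                assert len(child.edges) == len(net.edges) + 3
                assert child.edges[("D", "S4")] == 0.4
                assert child.edges[("S2", "S4")] == -0.2
                break
        else:
            pytest.fail("duplication of S1 never drawn")

    def test_duplication_copies_self_edge_as_self_edge(self, rng):
        net = make_net({("S1", "S1"): 0.7}, n_signaling=1)
        params = EvolutionParams(host_mutation_weights=(0, 0, 0, 0, 1.0))
        child, _ = mutate_host(net, params, rng, force=True)
        assert child.edges[("S2", "S2")] == 0.7
        assert ("S1", "S2") not in child.edges and ("S2", "S1") not in child.edges

    def test_deletion_never_removes_protected_nodes(self, rng):
        net = apply_pleiotropy(init_random_network(rng), "fixed-up", rng)
        pleio_id = net.pleiotropy.node_id
        params = EvolutionParams(host_mutation_weights=(0, 0, 0, 1.0, 0))
        for _ in range(200):
            child, _ = mutate_host(net, params, rng, force=True)
            ids = {n.id for n in child.nodes}
            assert {"D", "E", pleio_id} <= ids

    def test_slow_node_edges_effectively_frozen_at_extreme_factor(self, rng):
        net = apply_pleiotropy(init_random_network(rng), "slow", rng)
        slow = net.pleiotropy.node_id
        params = EvolutionParams(
            slow_factor=1e12,
            host_mutation_weights=(0.25, 0.25, 0.5, 0, 0),  # edge mutations only
        )
        before = {e: w for e, w in net.edges.items() if slow in e}
        changed_other = 0
        for _ in range(500):
            child, mtype = mutate_host(net, params, rng, force=True)
            after = {e: w for e, w in child.edges.items() if slow in e}
            assert after == before
            if mtype is not None:
                changed_other += 1
        assert changed_other > 0  # other edges still evolve

    def test_mutation_type_frequencies(self, rng):
        counts = collections.Counter()
        net = init_random_network(rng)
        for _ in range(20000):
            _, mtype = mutate_host(net, EP, rng, force=True)
            counts[mtype] += 1
        observed = [counts[m] for m in ("add_edge", "del_edge", "alter_weight", "del_protein", "dup_protein")]
        _, p = stats.chisquare(observed, f_exp=np.array(EP.host_mutation_weights) * 20000)
        assert p > 1e-4


class TestMutateParasite:
    def test_zero_rate_copy(self, rng):
        p = Parasite("S1", 0.3)
        q = mutate_parasite(p, ["S1", "S2"], EvolutionParams(parasite_mutation_rate=0.0), rng)
        assert q is not p and q.target == "S1" and q.manipulation == 0.3

    def test_retarget_with_single_choice_is_identity(self, rng):
        params = EvolutionParams(parasite_mutation_weights=(1.0, 0.0))
        q = mutate_parasite(Parasite("S1", -0.5), ["S1"], params, rng, force=True)
        assert q.target == "S1" and q.manipulation == -0.5

    def test_retarget_reweight_balance(self, rng):
        p = Parasite("S1", 0.25)
        retargets = reweights = 0
        for _ in range(10000):
            q = mutate_parasite(p, ["S1", "S2", "S3"], EP, rng, force=True)
            if q.manipulation != p.manipulation:
                reweights += 1
            else:
                retargets += 1
        # binomial(10^4, .5): 3 sigma = 150
        assert abs(retargets - 5000) < 150


class TestPercentilesAndCulling:
    def test_worked_percentiles(self):
        perc = fitness_percentiles([1.0, 2.0, 3.0, 4.0, 5.0])
        assert perc[3] == pytest.approx(0.75)  # 3 of 4 peers below
        assert perc[4] == pytest.approx(1.0)  # top of the population
        tied = fitness_percentiles([1.0, 2.0, 2.0, 3.0])
        assert tied[1] == tied[2]

    def test_death_cap_respected(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            fitness = rng.uniform(0, 1, n)
            flags = rng.random(n) < 0.5
            survivors, deaths = cull_population(fitness, flags, EP, rng)
            assert len(deaths) <= int(np.ceil(EP.death_cap * n))
            assert len(survivors) + len(deaths) == n

    def test_excess_infection_deaths_restored(self, rng):
        # 40% flagged dead with a 30% cap: exactly 30% die
        n = 100
        fitness = np.linspace(0.1, 1.0, n)
        flags = np.zeros(n, bool)
        flags[:40] = True
        survivors, deaths = cull_population(fitness, flags, EP, rng)
        assert len(deaths) == 30
        assert set(deaths) <= set(range(40))

    def test_top_fitness_host_never_dies(self, rng):
        params = EvolutionParams(death_cap=1.0)
        fitness = [0.1, 0.4, 0.6, 0.9]
        for _ in range(500):
            survivors, _ = cull_population(fitness, [False] * 4, params, rng)
            assert 3 in survivors

    def test_seventy_fifth_percentile_death_rate(self, rng):
        # focal host has 3 of 4 peers strictly below: percentile .75,
        # death probability .25; cap lifted so every host is evaluated
        params = EvolutionParams(death_cap=1.0)
        fitness = [0.1, 0.2, 0.3, 0.7, 0.9]
        died = 0
        trials = 20000
        for _ in range(trials):
            survivors, _ = cull_population(fitness, [False] * 5, params, rng)
            died += 3 not in survivors
        assert died / trials == pytest.approx(0.25, abs=0.02)


class TestReproduction:
    def test_population_replenished_from_single_survivor(self, rng):
        parents = reproduce_hosts([0.5], 7, rng)
        assert parents == [0] * 7

    def test_empty_survivor_set_signals_extinction(self, rng):
        with pytest.raises(PopulationExtinct):
            reproduce_hosts([], 3, rng)

    def test_offspring_counts_follow_fitness_weights(self, rng):
        counts = collections.Counter(reproduce_hosts([0.2, 0.8], 20000, rng))
        ratio = counts[1] / counts[0]
        assert ratio == pytest.approx(4.0, rel=0.15)

    @pytest.mark.parametrize(
        "load,quota", [(0.0, 1), (0.2, 1), (0.33, 1), (0.34, 2), (0.5, 2), (0.66, 2), (0.67, 3), (0.9, 3), (1.0, 3)]
    )
    def test_offspring_quota_bins(self, load, quota, rng):
        # a single high-load parent beside a zero-load one: the ranked cycle
        # takes the full quota from the high-load parent first
        survivors = [Parasite("S1", 0.0, load), Parasite("S2", 0.0, 0.0)]
        params = EvolutionParams(parasite_mutation_rate=0.0)
        offspring = reproduce_parasites(survivors, quota, ["S1", "S2"], params, rng)
        assert [o.target for o in offspring] == ["S1"] * quota

    def test_zero_loads_round_robin(self, rng):
        survivors = [Parasite(f"S{i+1}", 0.0, 0.0) for i in range(3)]
        params = EvolutionParams(parasite_mutation_rate=0.0)
        offspring = reproduce_parasites(survivors, 5, ["S1", "S2", "S3"], params, rng)
        assert [o.target for o in offspring] == ["S1", "S2", "S3", "S1", "S2"]

    def test_parasite_extinction_signal(self, rng):
        with pytest.raises(PopulationExtinct):
            reproduce_parasites([], 3, ["S1"], EP, rng)
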