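"""Mutation, death, and reproduction for hosts and parasites.

Hosts evolve by rare structural mutations of their signaling network (edge
gain/loss/re-weighting, protein deletion/duplication); parasites by
retargeting or re-weighting their single manipulation. Selection acts through
a percentile rule: up to a capped fraction of each population dies per
generation, with infection-killed hosts dying first and the remainder dying
with probability one minus their fitness percentile; survivors then reproduce
with probability equal to their percentile until the population is
replenished.

Four pleiotropy constraints restrict the evolvability of one designated
signaling protein: its initial edges may be frozen (fixed-random), it may
carry a frozen up- or downregulatory edge onto the effector (fixed-up /
fixed-down), or its edges may simply mutate 100x more slowly (slow).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .infection import Parasite
from .network import (
    Node,
    PLEIOTROPY_MODES,
    PleiotropyRecord,
    RegulatoryNetwork,
    SIGNALING,
    as_generator,
)

HOST_MUTATIONS = ("add_edge", "del_edge", "alter_weight", "del_protein", "dup_protein")
PARASITE_MUTATIONS = ("retarget", "reweight")


@dataclass(frozen=True)
class EvolutionParams:
    host_mutation_rate: float = 5e-3
    parasite_mutation_rate: float = 1e-2
    host_mutation_weights: tuple = (0.25, 0.25, 0.3, 0.1, 0.1)  # order: HOST_MUTATIONS
    parasite_mutation_weights: tuple = (0.5, 0.5)  # order: PARASITE_MUTATIONS
    death_cap: float = 0.3
    slow_factor: float = 100.0

    def __post_init__(self):
        if abs(sum(self.host_mutation_weights) - 1.0) > 1e-9:
            raise ValueError("host mutation weights must sum to 1")
        if abs(sum(self.parasite_mutation_weights) - 1.0) > 1e-9:
            raise ValueError("parasite mutation weights must sum to 1")
        for r in (self.host_mutation_rate, self.parasite_mutation_rate, self.death_cap):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def apply_pleiotropy(net: RegulatoryNetwork, mode: str, rng) -> RegulatoryNetwork:
    """Designate one initial signaling protein as pleiotropic and install the
    constraint for ``mode``. ``none`` returns the network unchanged."""
    if mode not in PLEIOTROPY_MODES:
        raise ValueError(f"unknown pleiotropy mode {mode!r}")
    if mode == "none":
        return net
    rng = as_generator(rng)
    sig = net.signaling_ids
    node_id = sig[int(rng.integers(len(sig)))]
    edges = dict(net.edges)
    if mode == "fixed-random":
        locked = frozenset(
            (s, d) for (s, d) in edges if node_id in (s, d)
        )
    elif mode in ("fixed-up", "fixed-down"):
        w = 1.0 if mode == "fixed-up" else -1.0
        edge = (node_id, net.effector_id)
        edges[edge] = w
        locked = frozenset([edge])
    else:  # slow
        locked = frozenset()
    return RegulatoryNetwork(
        net.nodes, edges, PleiotropyRecord(node_id, mode, locked), net.lineage_id
    )


def _fresh_signaling_id(net: RegulatoryNetwork) -> str:
    top = 0
    for n in net.nodes:
        if n.id.startswith("S"):
            try:
                top = max(top, int(n.id[1:]))
            except ValueError:
                pass
    return f"S{top + 1}"


_MAX_RESAMPLES = 100


def mutate_host(
    net: RegulatoryNetwork,
    params: EvolutionParams,
    rng,
    force: bool = False,
):
    """Return (offspring network, mutation type).

    With probability ``host_mutation_rate`` (always, if ``force``) one
    mutation is applied; otherwise the parent's network object itself is
    returned (clonal offspring share genotypes). Locked pleiotropic edges are
    never added over, deleted, or re-weighted; under the slow constraint,
    mutations touching the pleiotropic node's edges are accepted with
    probability 1/slow_factor and otherwise yield an unmutated copy.
    """
    rng = as_generator(rng)
    if not force and rng.random() >= params.host_mutation_rate:
        return net, None

    pleio = net.pleiotropy
    slow_node = pleio.node_id if (pleio and pleio.mode == "slow") else None
    locked = net.locked_edges
    det, eff = net.detector_id, net.effector_id
    ids = [n.id for n in net.nodes]

    for _ in range(_MAX_RESAMPLES):
        mtype = HOST_MUTATIONS[
            int(rng.choice(len(HOST_MUTATIONS), p=params.host_mutation_weights))
        ]

        if mtype == "add_edge":
            pair = None
            for _ in range(_MAX_RESAMPLES):
                src = ids[int(rng.integers(len(ids)))]
                dst = ids[int(rng.integers(len(ids)))]
                if (src, dst) == (det, eff) or (src, dst) in net.edges:
                    continue
                pair = (src, dst)
                break
            if pair is None:
                continue  # (nearly) fully wired; resample mutation type
            if slow_node in pair and rng.random() >= 1.0 / params.slow_factor:
                return _clone(net), None
            edges = dict(net.edges)
            edges[pair] = float(rng.uniform(-1.0, 1.0))
            return RegulatoryNetwork(net.nodes, edges, pleio, net.lineage_id), mtype

        if mtype in ("del_edge", "alter_weight"):
            candidates = [e for e in net.edges if e not in locked]
            if not candidates:
                continue
            edge = candidates[int(rng.integers(len(candidates)))]
            if slow_node in edge and rng.random() >= 1.0 / params.slow_factor:
                return _clone(net), None
            edges = dict(net.edges)
            if mtype == "del_edge":
                del edges[edge]
            else:
                edges[edge] = float(rng.uniform(-1.0, 1.0))
            return RegulatoryNetwork(net.nodes, edges, pleio, net.lineage_id), mtype

        if mtype == "del_protein":
            protected = {det, eff}
            if pleio:
                protected.add(pleio.node_id)
                for s, d in locked:
                    protected.update((s, d))
            candidates = [n.id for n in net.nodes if n.id not in protected]
            if not candidates:
                continue
            victim = candidates[int(rng.integers(len(candidates)))]
            nodes = [n for n in net.nodes if n.id != victim]
            edges = {
                (s, d): w for (s, d), w in net.edges.items() if victim not in (s, d)
            }
            return RegulatoryNetwork(nodes, edges, pleio, net.lineage_id), mtype

        if mtype == "dup_protein":
            candidates = [n.id for n in net.nodes if n.role == SIGNALING]
            if not candidates:
                continue
            orig = candidates[int(rng.integers(len(candidates)))]
            new_id = _fresh_signaling_id(net)
            nodes = list(net.nodes) + [Node(new_id, SIGNALING)]
            edges = dict(net.edges)
            for (s, d), w in net.edges.items():
                if s == orig and d == orig:
                    edges[(new_id, new_id)] = w  # self-edge copies as self-edge
                elif s == orig:
                    edges[(new_id, d)] = w
                elif d == orig:
                    edges[(s, new_id)] = w
            # a duplicated pleiotropic protein's copy is unconstrained
            return RegulatoryNetwork(nodes, edges, pleio, net.lineage_id), mtype

    return _clone(net), None  # no legal mutation found


def _clone(net: RegulatoryNetwork) -> RegulatoryNetwork:
    return RegulatoryNetwork(net.nodes, net.edges, net.pleiotropy, net.lineage_id)


def mutate_parasite(
    p: Parasite,
    signaling_ids: Sequence[str],
    params: EvolutionParams,
    rng,
    force: bool = False,
) -> Parasite:
    """With probability ``parasite_mutation_rate``, retarget to a uniformly
    chosen signaling protein or redraw the manipulation weight (.5/.5)."""
    rng = as_generator(rng)
    if not signaling_ids:
        raise ValueError("no signaling proteins to target")
    if not force and rng.random() >= params.parasite_mutation_rate:
        return p.copy()
    which = PARASITE_MUTATIONS[
        int(rng.choice(len(PARASITE_MUTATIONS), p=params.parasite_mutation_weights))
    ]
    if which == "retarget":
        target = signaling_ids[int(rng.integers(len(signaling_ids)))]
        return Parasite(target, p.manipulation)
    return Parasite(p.target, float(rng.uniform(-1.0, 1.0)))


def fitness_percentiles(values: Sequence[float]) -> np.ndarray:
    """Fraction of the *rest* of the population with strictly lower fitness;
    ties share a percentile. The top of a strictly ordered population sits at
    the 100th percentile (death probability 0), and an individual with 75% of
    its peers below it sits at the 75th (death probability 0.25)."""
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    if n == 1:
        return np.ones(1)
    order = np.sort(arr)
    below = np.searchsorted(order, arr, side="left")
    return below / (n - 1)


def _death_budget(n: int, cap: float) -> int:
    return int(round(cap * n))


def cull_population(
    fitness: Sequence[float],
    priority_dead: Sequence[bool],
    params: EvolutionParams,
    rng,
):
    """Return (survivor index array, death index array).

    Individuals flagged ``priority_dead`` (infection-killed hosts; cleared or
    host-killing parasites) die first. If they exceed the death cap, the
    excess are restored at random. Otherwise the remaining individuals are
    visited in random order, each dying with probability 1 - percentile,
    until all have been evaluated once or the cap is reached.
    """
    rng = as_generator(rng)
    fitness = np.asarray(fitness, dtype=float)
    flags = np.asarray(priority_dead, dtype=bool)
    n = len(fitness)
    cap = _death_budget(n, params.death_cap)

    dead = list(np.flatnonzero(flags))
    if len(dead) > cap:
        restored = rng.choice(len(dead), size=len(dead) - cap, replace=False)
        keep = set(int(dead[i]) for i in restored)
        dead = [i for i in dead if int(i) not in keep]
    dead_set = set(int(i) for i in dead)

    budget = cap - len(dead_set)
    candidates = np.flatnonzero(~flags)
    if budget > 0 and len(candidates) > 0:
        perc = fitness_percentiles(fitness[candidates])
        order = rng.permutation(len(candidates))
        for j in order:
            if budget == 0:
                break
            if rng.random() < 1.0 - perc[j]:
                dead_set.add(int(candidates[j]))
                budget -= 1

    survivors = np.array([i for i in range(n) if i not in dead_set], dtype=int)
    deaths = np.array(sorted(dead_set), dtype=int)
    return survivors, deaths


def reproduce_hosts(
    survivor_fitness: Sequence[float],
    n_offspring: int,
    rng,
):
    """Draw parent indices for ``n_offspring`` new hosts.

    Survivors reproduce in a fitness-weighted manner: each draw picks a
    parent with probability proportional to its fitness W (a survivor can
    reproduce repeatedly), until the population is replenished. Within a
    clonal population this reduces to uniform draws.
    """
    rng = as_generator(rng)
    fit = np.asarray(survivor_fitness, dtype=float)
    if len(fit) == 0:
        raise PopulationExtinct("no surviving hosts")
    if n_offspring <= 0:
        return []
    weights = fit / fit.sum()
    return [int(i) for i in rng.choice(len(fit), size=n_offspring, p=weights)]


class PopulationExtinct(Exception):
    """Raised when a population has no survivors left to reproduce."""


def _offspring_quota(load: float) -> int:
    if load <= 0.33:
        return 1
    if load <= 0.66:
        return 2
    return 3


def reproduce_parasites(
    survivors: Sequence[Parasite],
    n_offspring: int,
    signaling_ids: Sequence[str],
    params: EvolutionParams,
    rng,
):
    """Produce ``n_offspring`` parasites by load-based quotas.

    Parents are taken highest cumulative load first, each contributing
    1/2/3 offspring for loads in [0,.33] / (.33,.66] / (.66,1], cycling
    through the list until the population is replenished.
    """
    rng = as_generator(rng)
    if not survivors:
        raise PopulationExtinct("no surviving parasites")
    ranked = sorted(
        range(len(survivors)), key=lambda i: (-survivors[i].cumulative_load, i)
    )
    offspring = []
    while len(offspring) < n_offspring:
        for i in ranked:
            parent = survivors[i]
            for _ in range(_offspring_quota(parent.cumulative_load)):
                if len(offspring) == n_offspring:
                    break
                offspring.append(mutate_parasite(parent, signaling_ids, params, rng))
            if len(offspring) == n_offspring:
                break
    return offspring
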