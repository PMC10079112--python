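"""Infection episodes and fitness.

A parasite is modelled as one extra protein grafted onto the host network for
the duration of an infection: it activates the detector (weight +1),
replicates through a self-edge (+0.8), manipulates one signaling protein with
its evolved signed weight, and is killed by the effector (-1). The infection
runs for at most 20 steps — the host's reproductive lifespan — ending early
on clearance (parasite below 1e-2) or host death (normalized parasite area
above 0.9).

Host fitness is W = exp(-(E*_pre + V*Area + E*_post + ProtCost)): the cost of
constitutive investment, parasite-induced damage, lingering post-infection
investment, and a genome-size cost that kicks in above 10 proteins. Parasite
fitness is the normalized area itself, a proxy for transmission.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import (
    CompiledDynamics,
    DynamicsParams,
    NetworkState,
    RegulatoryNetwork,
    SIGNALING,
    _kernel,
    healthy_equilibrium,
)

CLEARED = "cleared"
MANAGED = "managed"
HOST_DEATH = "host_death"
UNINFECTED = "uninfected"  # plumbing value for per-host records


@dataclass
class Parasite:
    """Targets one host signaling protein with a signed manipulation weight."""

    target: str
    manipulation: float
    cumulative_load: float = 0.0

    def __post_init__(self):
        if not -1.0 <= self.manipulation <= 1.0:
            raise ValueError("manipulation must lie in [-1, 1]")

    def copy(self) -> "Parasite":
        return Parasite(self.target, self.manipulation, self.cumulative_load)


@dataclass(frozen=True)
class FitnessParams:
    virulence: float = 1.0
    clearance_threshold: float = 1e-2
    death_area_threshold: float = 0.9
    max_infection_steps: int = 20
    size_cost_threshold: int = 10
    size_cost_slope: float = 1.1

    def __post_init__(self):
        if min(
            self.virulence,
            self.clearance_threshold,
            self.death_area_threshold,
            self.max_infection_steps,
            self.size_cost_threshold,
            self.size_cost_slope,
        ) < 0:
            raise ValueError("fitness parameters must be nonnegative")


@dataclass(frozen=True)
class InfectionRecord:
    """Time courses and summary of one infection episode."""

    effector_trace: tuple
    parasite_trace: tuple
    outcome: str
    area: float
    effector_pre: float
    effector_post: float
    effector_peak: float


@dataclass(frozen=True)
class AugmentedNetwork:
    """Host network plus parasite node, in kernel-ready matrix form.

    The parasite occupies the last index. ``extra_edges`` lists the four
    connections the attachment adds; the host network itself is untouched.
    """

    net: RegulatoryNetwork
    compiled: CompiledDynamics
    parasite_index: int
    extra_edges: tuple


def attach_parasite(net: RegulatoryNetwork, parasite: Parasite) -> AugmentedNetwork:
    """Graft the parasite onto the host graph (non-destructively)."""
    roles = {n.id: n.role for n in net.nodes}
    if roles.get(parasite.target) != SIGNALING:
        raise ValueError("parasite must target a signaling protein")
    base = net.compiled()
    n = len(net.nodes)
    up = np.zeros((n + 1, n + 1))
    down = np.zeros((n + 1, n + 1))
    outdeg = np.zeros(n + 1)
    up[:n, :n] = base.up
    down[:n, :n] = base.down
    outdeg[:n] = base.outdeg
    det = net.index_of(net.detector_id)
    eff = net.index_of(net.effector_id)
    tgt = net.index_of(parasite.target)
    p = n
    # parasite -> detector (+1), parasite self-replication (+0.8),
    # parasite -> target (manipulation), effector -> parasite (-1)
    up[det, p] = 1.0
    up[p, p] = 0.8
    if parasite.manipulation >= 0:
        up[tgt, p] = parasite.manipulation
    else:
        down[tgt, p] = -parasite.manipulation
    down[p, eff] = 1.0
    outdeg[p] = 3.0
    outdeg[eff] += 1.0
    extra = (
        ("parasite", net.detector_id, 1.0),
        ("parasite", "parasite", 0.8),
        ("parasite", parasite.target, parasite.manipulation),
        (net.effector_id, "parasite", -1.0),
    )
    return AugmentedNetwork(net, CompiledDynamics(up, down, outdeg), p, extra)


def run_infection(
    net: RegulatoryNetwork,
    parasite: Parasite,
    dyn: DynamicsParams,
    fit: FitnessParams,
    start_state: Optional[NetworkState] = None,
    fixed_horizon: bool = False,
) -> InfectionRecord:
    """Run one infection episode from the host's healthy equilibrium.

    Termination conditions are evaluated after every step in order: lifespan
    elapsed (managed), clearance, running-area death. With ``fixed_horizon``
    the episode always runs the full lifespan (used by knockout analysis,
    where intact and perturbed trajectories must have equal length).

    Episodes are cached on the network object keyed by the parasite's
    (target, manipulation); dynamics are deterministic so this is exact.
    """
    cache_key = None
    if start_state is None:
        cache_key = (parasite.target, parasite.manipulation, fixed_horizon, dyn, fit)
        cached = net._infection_cache.get(cache_key)
        if cached is not None:
            return cached
        eq = healthy_equilibrium(net, dyn)
        start_state = eq.state
        effector_pre = eq.effector_pre
    else:
        effector_pre = float(start_state.active[net.index_of(net.effector_id)])

    aug = attach_parasite(net, parasite)
    eff = net.index_of(net.effector_id)
    p = aug.parasite_index
    x = np.append(start_state.active, dyn.parasite_initial_active)

    eff_trace: list = []
    par_trace: list = []
    outcome = MANAGED
    if not fixed_horizon and x[p] < fit.clearance_threshold:
        outcome = CLEARED
    else:
        par_sum = 0.0
        for t in range(1, fit.max_infection_steps + 1):
            x = _kernel(x, aug.compiled, dyn.use_coef)
            eff_trace.append(float(x[eff]))
            par_trace.append(float(x[p]))
            par_sum += x[p]
            if fixed_horizon:
                continue
            # clearance first (tie broken in the host's favor), then death by
            # running area, then lifespan elapsed
            if x[p] < fit.clearance_threshold:
                outcome = CLEARED
                break
            if par_sum / fit.max_infection_steps > fit.death_area_threshold:
                outcome = HOST_DEATH
                break
            if t == fit.max_infection_steps:
                outcome = MANAGED
                break
        if fixed_horizon:
            if x[p] < fit.clearance_threshold:
                outcome = CLEARED
            elif par_sum / fit.max_infection_steps > fit.death_area_threshold:
                outcome = HOST_DEATH
            else:
                outcome = MANAGED

    area = float(np.clip(sum(par_trace) / fit.max_infection_steps, 0.0, 1.0))
    effector_post = eff_trace[-1] if eff_trace else effector_pre
    effector_peak = max([effector_pre] + eff_trace)
    record = InfectionRecord(
        effector_trace=tuple(eff_trace),
        parasite_trace=tuple(par_trace),
        outcome=outcome,
        area=area,
        effector_pre=effector_pre,
        effector_post=effector_post,
        effector_peak=effector_peak,
    )
    if cache_key is not None:
        net._infection_cache[cache_key] = record
    return record


def uninfected_record(effector_pre: float) -> InfectionRecord:
    """Record for a host that escaped infection this generation: constitutive
    investment is paid twice (pre and post), no parasite damage."""
    return InfectionRecord(
        effector_trace=(),
        parasite_trace=(),
        outcome=UNINFECTED,
        area=0.0,
        effector_pre=effector_pre,
        effector_post=effector_pre,
        effector_peak=effector_pre,
    )


def protein_cost(network_size: int, fit: FitnessParams) -> float:
    if network_size <= fit.size_cost_threshold:
        return 0.0
    return fit.size_cost_slope * (network_size - fit.size_cost_threshold)


def host_fitness(
    rec: Optional[InfectionRecord],
    net: RegulatoryNetwork,
    fit: FitnessParams,
) -> float:
    """W = exp(-(E*_pre + V*Area + E*_post + ProtCost)), in (0, 1]."""
    cost = protein_cost(net.size, fit)
    if rec is None:
        exponent = cost
    else:
        exponent = rec.effector_pre + fit.virulence * rec.area + rec.effector_post + cost
    return float(np.exp(-exponent))


def parasite_fitness(rec: InfectionRecord) -> float:
    """Normalized area of the infection time course, in [0, 1]."""
    return rec.area
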