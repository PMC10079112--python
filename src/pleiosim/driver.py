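"""Orchestration of coevolution and competition simulations.

A generation runs: healthy equilibria for all hosts -> random infection of a
fixed fraction of hosts, paired one-to-one with the parasite population ->
infection episodes -> fitness -> capped, percentile-based death in both
populations -> replenishing reproduction. Coevolution iterates this for a
fixed number of generations; competition first evolves a pleiotropic and a
non-pleiotropic population separately, then merges them into one arena until
one host type goes extinct or a generation cap declares a draw.

All randomness flows from one master seed through named substreams
(init, pairing, mutation, culling, reproduction), so runs are exactly
reproducible and a change to one phase's draw pattern does not scramble the
others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .evolution import (
    EvolutionParams,
    PopulationExtinct,
    apply_pleiotropy,
    cull_population,
    mutate_host,
    reproduce_hosts,
    reproduce_parasites,
)
from .infection import (
    CLEARED,
    FitnessParams,
    HOST_DEATH,
    InfectionRecord,
    MANAGED,
    Parasite,
    UNINFECTED,
    host_fitness,
    run_infection,
    uninfected_record,
)
from .network import (
    DynamicsParams,
    RegulatoryNetwork,
    healthy_equilibrium,
    init_random_network,
)

PLEIOTROPIC = "pleiotropic"
NON_PLEIOTROPIC = "non_pleiotropic"

_STREAM_NAMES = ("init", "pairing", "mutation", "culling", "reproduction")


class Streams:
    """Named RNG substreams spawned from one master seed."""

    def __init__(self, seed):
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        self.seed_sequence = ss
        for name, child in zip(_STREAM_NAMES, ss.spawn(len(_STREAM_NAMES))):
            setattr(self, name, np.random.default_rng(child))

    def spawn(self) -> "Streams":
        return Streams(self.seed_sequence.spawn(1)[0])


@dataclass(frozen=True)
class SimulationConfig:
    infection_chance: float = 0.5
    pleiotropy_mode: str = "none"
    n_hosts: int = 500
    n_generations: int = 500
    seed: int = 0
    n_signaling: int = 3
    competition_max_generations: int = 1000
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    fitness: FitnessParams = field(default_factory=FitnessParams)
    evolution: EvolutionParams = field(default_factory=EvolutionParams)

    def __post_init__(self):
        if not 0.0 <= self.infection_chance <= 1.0:
            raise ValueError("infection_chance must lie in [0, 1]")
        if self.n_hosts <= 0:
            raise ValueError("n_hosts must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("evolution",):
            for wkey in ("host_mutation_weights", "parasite_mutation_weights"):
                d[key][wkey] = list(d[key][wkey])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "dynamics" in d and isinstance(d["dynamics"], dict):
            d["dynamics"] = DynamicsParams(**d["dynamics"])
        if "fitness" in d and isinstance(d["fitness"], dict):
            d["fitness"] = FitnessParams(**d["fitness"])
        if "evolution" in d and isinstance(d["evolution"], dict):
            e = dict(d["evolution"])
            for wkey in ("host_mutation_weights", "parasite_mutation_weights"):
                if wkey in e:
                    e[wkey] = tuple(e[wkey])
            d["evolution"] = EvolutionParams(**e)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class Host:
    id: int
    network: RegulatoryNetwork
    ptype: Optional[str] = None  # competition label; inherited by offspring

    @property
    def lineage_id(self):
        return self.network.lineage_id


@dataclass
class GenerationSummary:
    generation: int
    n_hosts: int
    mean_fitness: float
    median_fitness: float
    mean_parasite_load: float
    n_cleared: int
    n_managed: int
    n_dead: int
    n_uninfected: int
    mean_inducibility: float
    mean_network_size: float
    mean_connectivity: float
    n_pleiotropic: int
    n_non_pleiotropic: int

    def __post_init__(self):
        counts = self.n_cleared + self.n_managed + self.n_dead + self.n_uninfected
        if counts != self.n_hosts:
            raise ValueError("outcome counts must sum to population size")


def _summarize(generation, hosts, records, fitness, loads) -> GenerationSummary:
    outcomes = [r.outcome for r in records]
    inducibilities = [
        analysis.inducibility(r) for r in records if r.outcome != UNINFECTED
    ]
    return GenerationSummary(
        generation=generation,
        n_hosts=len(hosts),
        mean_fitness=float(np.mean(fitness)),
        median_fitness=float(np.median(fitness)),
        mean_parasite_load=float(np.mean(loads)) if len(loads) else 0.0,
        n_cleared=outcomes.count(CLEARED),
        n_managed=outcomes.count(MANAGED),
        n_dead=outcomes.count(HOST_DEATH),
        n_uninfected=outcomes.count(UNINFECTED),
        mean_inducibility=float(np.mean(inducibilities)) if inducibilities else float("nan"),
        mean_network_size=float(np.mean([h.network.size for h in hosts])),
        mean_connectivity=float(np.mean([analysis.connectivity(h.network) for h in hosts])),
        n_pleiotropic=sum(1 for h in hosts if h.ptype == PLEIOTROPIC),
        n_non_pleiotropic=sum(1 for h in hosts if h.ptype == NON_PLEIOTROPIC),
    )


def run_generation(hosts, parasites, config: SimulationConfig, streams: Streams, generation: int, next_id: int):
    """Run one full generation cycle.

    Returns (next hosts, next parasites, summary, per-host records,
    per-host fitness, ancestry rows, next_id). The summary and records
    describe the *evaluated* generation (before death/reproduction).
    """
    dyn, fit, evo = config.dynamics, config.fitness, config.evolution
    n = len(hosts)
    n_inf_target = int(round(config.infection_chance * n))

    equilibria = [healthy_equilibrium(h.network, dyn) for h in hosts]

    # infection: random subset of hosts, random bijection with parasites
    k = min(n_inf_target, len(parasites))
    chosen = streams.pairing.choice(n, size=k, replace=False) if k else np.array([], dtype=int)
    order = streams.pairing.permutation(len(parasites)) if parasites else np.array([], dtype=int)

    records = [None] * n
    parasite_outcomes = [None] * len(parasites)
    for slot, host_i in enumerate(chosen):
        parasite = parasites[int(order[slot])]
        host = hosts[int(host_i)]
        sig = host.network.signaling_ids
        if parasite.target not in sig:
            parasite.target = sig[int(streams.pairing.integers(len(sig)))]
        rec = run_infection(host.network, parasite, dyn, fit)
        parasite.cumulative_load = rec.area
        records[int(host_i)] = rec
        parasite_outcomes[int(order[slot])] = rec.outcome
    for slot in range(k, len(parasites)):
        parasites[int(order[slot])].cumulative_load = 0.0

    for i in range(n):
        if records[i] is None:
            records[i] = uninfected_record(equilibria[i].effector_pre)

    fitness = np.array(
        [host_fitness(records[i], hosts[i].network, fit) for i in range(n)]
    )
    dead_flags = np.array([r.outcome == HOST_DEATH for r in records])

    summary = _summarize(generation, hosts, records, fitness, [p.cumulative_load for p in parasites])

    # death
    surv_idx, _ = cull_population(fitness, dead_flags, evo, streams.culling)
    survivors = [hosts[i] for i in surv_idx]
    surv_fitness = fitness[surv_idx]

    par_survivors = parasites
    if parasites:
        par_fitness = [p.cumulative_load for p in parasites]
        par_flags = [
            parasite_outcomes[i] in (CLEARED, HOST_DEATH) for i in range(len(parasites))
        ]
        par_surv_idx, _ = cull_population(par_fitness, par_flags, evo, streams.culling)
        par_survivors = [parasites[i] for i in par_surv_idx]

    # reproduction
    ancestry = []
    n_offspring = n - len(survivors)
    parent_idx = reproduce_hosts(surv_fitness, n_offspring, streams.reproduction)
    offspring = []
    for pi in parent_idx:
        parent = survivors[pi]
        child_net, mtype = mutate_host(parent.network, evo, streams.mutation)
        child = Host(next_id, child_net, parent.ptype)
        next_id += 1
        offspring.append(child)
        ancestry.append(
            {
                "generation": generation,
                "child_id": child.id,
                "parent_id": parent.id,
                "lineage_id": child.lineage_id,
                "mutation_type": mtype or "none",
            }
        )
    next_hosts = survivors + offspring

    next_parasites = par_survivors
    if n_inf_target > 0 and par_survivors:
        pool = sorted({s for h in next_hosts for s in h.network.signaling_ids})
        par_offspring = reproduce_parasites(
            par_survivors, n_inf_target - len(par_survivors), pool, evo, streams.mutation
        )
        next_parasites = par_survivors + par_offspring

    return next_hosts, next_parasites, summary, records, fitness, ancestry, next_id


@dataclass
class RunArchive:
    """Everything the analysis layer needs, without re-simulation."""

    config: SimulationConfig
    summaries: list
    final_hosts: list  # of Host
    final_records: list  # of InfectionRecord, parallel to final_hosts
    final_fitness: list
    final_parasites: list
    ancestry: list

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.summaries])

    def ancestry_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ancestry,
            columns=["generation", "child_id", "parent_id", "lineage_id", "mutation_type"],
        )

    def records_frame(self) -> pd.DataFrame:
        rows = []
        for host, rec, w in zip(self.final_hosts, self.final_records, self.final_fitness):
            rows.append(
                {
                    "host_id": host.id,
                    "lineage_id": host.lineage_id,
                    "ptype": host.ptype or "",
                    "outcome": rec.outcome,
                    "effector_pre": rec.effector_pre,
                    "effector_post": rec.effector_post,
                    "effector_peak": rec.effector_peak,
                    "area": rec.area,
                    "fitness": w,
                }
            )
        return pd.DataFrame(rows)

    def save(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(outdir / "config_echo.yaml")
        self.summary_frame().to_csv(outdir / "summary.tsv", sep="\t", index=False, float_format="%.17g")
        self.ancestry_frame().to_csv(outdir / "ancestry.tsv", sep="\t", index=False)
        self.records_frame().to_csv(outdir / "records_final.tsv", sep="\t", index=False, float_format="%.17g")
        hosts = []
        for host, rec, w in zip(self.final_hosts, self.final_records, self.final_fitness):
            hosts.append(
                {
                    "id": host.id,
                    "ptype": host.ptype,
                    "fitness": w,
                    "network": host.network.to_json_dict(),
                    "record": dataclasses.asdict(rec),
                }
            )
        with open(outdir / "hosts_final.json", "w") as fh:
            json.dump(hosts, fh)
        with open(outdir / "parasites_final.json", "w") as fh:
            json.dump(
                [
                    {"target": p.target, "manipulation": p.manipulation, "cumulative_load": p.cumulative_load}
                    for p in self.final_parasites
                ],
                fh,
            )

    @classmethod
    def load(cls, outdir) -> "RunArchive":
        outdir = Path(outdir)
        config = SimulationConfig.from_yaml(outdir / "config_echo.yaml")
        summary_df = pd.read_csv(outdir / "summary.tsv", sep="\t", float_precision="round_trip")
        summaries = [GenerationSummary(**row) for row in summary_df.to_dict("records")]
        ancestry = pd.read_csv(outdir / "ancestry.tsv", sep="\t").to_dict("records")
        with open(outdir / "hosts_final.json") as fh:
            host_rows = json.load(fh)
        final_hosts, final_records, final_fitness = [], [], []
        for row in host_rows:
            net = RegulatoryNetwork.from_json_dict(row["network"])
            final_hosts.append(Host(row["id"], net, row["ptype"]))
            rec = dict(row["record"])
            rec["effector_trace"] = tuple(rec["effector_trace"])
            rec["parasite_trace"] = tuple(rec["parasite_trace"])
            final_records.append(InfectionRecord(**rec))
            final_fitness.append(row["fitness"])
        with open(outdir / "parasites_final.json") as fh:
            final_parasites = [Parasite(**p) for p in json.load(fh)]
        return cls(config, summaries, final_hosts, final_records, final_fitness, final_parasites, ancestry)


def _init_populations(config: SimulationConfig, streams: Streams, next_id: int, ptype=None):
    hosts = []
    for _ in range(config.n_hosts):
        net = init_random_network(
            streams.init, config.n_signaling, lineage_id=f"L{next_id}"
        )
        net = apply_pleiotropy(net, config.pleiotropy_mode, streams.init)
        hosts.append(Host(next_id, net, ptype))
        next_id += 1
    n_inf = int(round(config.infection_chance * config.n_hosts))
    initial_sig = [f"S{i + 1}" for i in range(config.n_signaling)]
    parasites = [
        Parasite(
            initial_sig[int(streams.init.integers(len(initial_sig)))],
            float(streams.init.uniform(-1.0, 1.0)),
        )
        for _ in range(n_inf)
    ]
    return hosts, parasites, next_id


def run_coevolution(config: SimulationConfig, outdir=None) -> RunArchive:
    """Coevolve one host population with its parasites for
    ``config.n_generations`` generations and archive the outcome."""
    streams = Streams(config.seed)
    ptype = NON_PLEIOTROPIC if config.pleiotropy_mode == "none" else PLEIOTROPIC
    hosts, parasites, next_id = _init_populations(config, streams, 0, ptype)
    summaries, ancestry_all = [], []
    records, fitness = [], []
    final_hosts = hosts
    evaluated_parasites = parasites
    for gen in range(1, config.n_generations + 1):
        final_hosts = hosts
        evaluated_parasites = parasites
        hosts, parasites, summary, records, fitness, ancestry, next_id = run_generation(
            hosts, parasites, config, streams, gen, next_id
        )
        summaries.append(summary)
        ancestry_all.extend(ancestry)
    # snapshot after the last evaluation so cumulative loads are final
    final_parasites = [p.copy() for p in evaluated_parasites]
    archive = RunArchive(
        config=config,
        summaries=summaries,
        final_hosts=final_hosts,
        final_records=list(records),
        final_fitness=list(fitness),
        final_parasites=final_parasites,
        ancestry=ancestry_all,
    )
    if outdir is not None:
        archive.save(outdir)
    return archive


@dataclass
class CompetitionResult:
    winner: str  # pleiotropic | non_pleiotropic | draw
    generations_elapsed: int
    archive: RunArchive

    def to_json_dict(self) -> dict:
        return {"winner": self.winner, "generations_elapsed": self.generations_elapsed}


def run_competition(
    config: SimulationConfig, pre_evolution_generations: int = 0, outdir=None
) -> CompetitionResult:
    """Compete a pleiotropic against a non-pleiotropic host population.

    Each half (``n_hosts // 2`` hosts with its own parasites) optionally
    evolves alone for ``pre_evolution_generations``, then the arenas merge:
    one population, one fitness ranking, offspring inheriting their parent's
    type. The run ends when a type is extinct or at the generation cap (draw).
    """
    if config.pleiotropy_mode == "none":
        raise ValueError("competition requires a pleiotropic mode to compete against 'none'")
    streams = Streams(config.seed)
    half = config.n_hosts // 2
    sub_cfgs = {
        PLEIOTROPIC: dataclasses.replace(config, n_hosts=half),
        NON_PLEIOTROPIC: dataclasses.replace(
            config, n_hosts=half, pleiotropy_mode="none"
        ),
    }
    hosts, parasites = [], []
    next_id = 0
    for ptype, cfg in sub_cfgs.items():
        sub_streams = streams.spawn()
        sub_hosts, sub_parasites, next_id = _init_populations(cfg, sub_streams, next_id, ptype)
        for gen in range(1, pre_evolution_generations + 1):
            sub_hosts, sub_parasites, *_, next_id = run_generation(
                sub_hosts, sub_parasites, cfg, sub_streams, gen, next_id
            )
        hosts.extend(sub_hosts)
        parasites.extend(sub_parasites)

    summaries, ancestry_all = [], []
    records: list = []
    fitness: list = []
    winner = "draw"
    gen = 0
    final_hosts = hosts
    evaluated_parasites = parasites
    for gen in range(1, config.competition_max_generations + 1):
        final_hosts = hosts
        evaluated_parasites = parasites
        hosts, parasites, summary, records, fitness, ancestry, next_id = run_generation(
            hosts, parasites, config, streams, gen, next_id
        )
        summaries.append(summary)
        ancestry_all.extend(ancestry)
        counts = {
            PLEIOTROPIC: sum(1 for h in hosts if h.ptype == PLEIOTROPIC),
            NON_PLEIOTROPIC: sum(1 for h in hosts if h.ptype == NON_PLEIOTROPIC),
        }
        if counts[PLEIOTROPIC] == 0:
            winner = NON_PLEIOTROPIC
            break
        if counts[NON_PLEIOTROPIC] == 0:
            winner = PLEIOTROPIC
            break
    final_parasites = [p.copy() for p in evaluated_parasites]
    archive = RunArchive(
        config=config,
        summaries=summaries,
        final_hosts=final_hosts,
        final_records=list(records),
        final_fitness=list(fitness),
        final_parasites=final_parasites,
        ancestry=ancestry_all,
    )
    result = CompetitionResult(winner, gen, archive)
    if outdir is not None:
        archive.save(outdir)
        with open(Path(outdir) / "result.json", "w") as fh:
            json.dump(result.to_json_dict(), fh)
    return result


def sweep_coevolution(
    modes,
    infection_chances,
    replicates: int,
    base_config: SimulationConfig,
    seed: int,
) -> pd.DataFrame:
    """Run ``replicates`` coevolution simulations per (mode, infection chance)
    cell and tabulate final-generation population statistics."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for mode in modes:
        for chance in infection_chances:
            for rep in range(replicates):
                run_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                cfg = dataclasses.replace(
                    base_config,
                    pleiotropy_mode=mode,
                    infection_chance=chance,
                    seed=run_seed,
                )
                archive = run_coevolution(cfg)
                last = archive.summaries[-1]
                infected = [
                    analysis.inducibility(r)
                    for r in archive.final_records
                    if r.outcome != UNINFECTED
                ]
                rows.append(
                    {
                        "mode": mode,
                        "infection_chance": chance,
                        "replicate": rep,
                        "seed": run_seed,
                        "mean_fitness": last.mean_fitness,
                        "mean_inducibility": float(np.mean(infected)) if infected else float("nan"),
                        "mean_connectivity": last.mean_connectivity,
                        "mean_network_size": last.mean_network_size,
                    }
                )
    return pd.DataFrame(rows)
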