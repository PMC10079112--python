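"""Immune signaling networks and their within-host dynamics.

A host's immune system is a signed, directed protein-interaction graph with
three node roles: a single *detector* (pattern-recognition receptor), a pool
of *signaling* proteins, and a single *effector* (parasite-killing molecule).
Each protein exists in active/inactive form with total concentration 1; the
discrete-time map implemented here moves concentration between the two forms
according to the signed regulatory edges, minus a flat per-step "protein use"
cost proportional to the number of regulatory targets a protein maintains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

DETECTOR = "detector"
SIGNALING = "signaling"
EFFECTOR = "effector"

PLEIOTROPY_MODES = ("none", "fixed-random", "fixed-up", "fixed-down", "slow")


def as_generator(rng) -> np.random.Generator:
    """Coerce a seed / SeedSequence / Generator into a numpy Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class Node:
    id: str
    role: str


@dataclass(frozen=True)
class PleiotropyRecord:
    """One signaling protein carries a developmental side role.

    ``locked`` edges are immutable across evolutionary time; under the
    ``slow`` mode no edge is locked but mutations touching the node's edges
    are rate-reduced.
    """

    node_id: str
    mode: str
    locked: frozenset = frozenset()


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the within-host discrete-time map.

    use_coef
        Per-edge, per-step inactivation cost charged to a protein for each
        regulatory edge it maintains (self-edges included).
    equilibrium_tol
        Healthy-phase convergence test: absolute change of the effector's
        active fraction between consecutive steps.
    max_equilibrium_steps
        Cap on healthy-phase iterations; guarantees termination.
    initial_active
        Active fraction all proteins start from (0.5).
    parasite_initial_active
        Parasite active fraction at infection onset.
    """

    use_coef: float = 0.01
    equilibrium_tol: float = 1e-3
    max_equilibrium_steps: int = 200
    initial_active: float = 0.5
    parasite_initial_active: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.initial_active <= 1.0:
            raise ValueError("initial_active must lie in [0, 1]")
        if self.use_coef < 0 or self.equilibrium_tol < 0:
            raise ValueError("use_coef and equilibrium_tol must be nonnegative")


@dataclass
class NetworkState:
    """Per-protein active fractions, plus the parasite's during infection."""

    active: np.ndarray
    parasite_active: Optional[float] = None

    def __post_init__(self):
        self.active = np.asarray(self.active, dtype=float)
        if np.any(self.active < 0) or np.any(self.active > 1):
            raise ValueError("active fractions must lie in [0, 1]")

    @property
    def inactive(self) -> np.ndarray:
        return 1.0 - self.active


@dataclass(frozen=True)
class CompiledDynamics:
    """Dense-matrix form of a network used by the update kernel.

    ``up[i, j]`` / ``down[i, j]`` hold k_{i,j} / I_{i,j} (weight magnitudes of
    the positive / negative edge j -> i); ``outdeg[j]`` counts edges leaving j.
    """

    up: np.ndarray
    down: np.ndarray
    outdeg: np.ndarray


class RegulatoryNetwork:
    """A host immune signaling network.

    Treated as immutable after construction: mutation operators build new
    instances, and clonal offspring share the parent's object, which lets
    dynamics results be cached per genotype.
    """

    def __init__(
        self,
        nodes: Iterable[Node],
        edges: Mapping[tuple, float],
        pleiotropy: Optional[PleiotropyRecord] = None,
        lineage_id: Optional[str] = None,
    ):
        self.nodes = list(nodes)
        self.edges = dict(edges)
        self.pleiotropy = pleiotropy
        self.lineage_id = lineage_id
        self._index = {n.id: i for i, n in enumerate(self.nodes)}
        self._compiled: Optional[CompiledDynamics] = None
        self._equilibrium_cache: dict = {}
        self._infection_cache: dict = {}
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self):
        roles = [n.role for n in self.nodes]
        if roles.count(DETECTOR) != 1 or roles.count(EFFECTOR) != 1:
            raise ValueError("network must have exactly one detector and one effector")
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node ids")
        det, eff = self.detector_id, self.effector_id
        for (src, dst), w in self.edges.items():
            if src not in self._index or dst not in self._index:
                raise ValueError(f"edge ({src}, {dst}) has a dangling endpoint")
            if src == det and dst == eff:
                raise ValueError("detector cannot connect directly to the effector")
            if not -1.0 <= w <= 1.0:
                raise ValueError("edge weights must lie in [-1, 1]")
        if self.pleiotropy is not None:
            pid = self.pleiotropy.node_id
            if pid not in self._index:
                raise ValueError("pleiotropic node missing from network")
            for src, dst in self.pleiotropy.locked:
                if (src, dst) not in self.edges:
                    raise ValueError("locked edge absent from network")
                if pid not in (src, dst):
                    raise ValueError("locked edge not incident to pleiotropic node")

    @property
    def detector_id(self) -> str:
        return next(n.id for n in self.nodes if n.role == DETECTOR)

    @property
    def effector_id(self) -> str:
        return next(n.id for n in self.nodes if n.role == EFFECTOR)

    @property
    def signaling_ids(self) -> list:
        return [n.id for n in self.nodes if n.role == SIGNALING]

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def locked_edges(self) -> frozenset:
        return self.pleiotropy.locked if self.pleiotropy else frozenset()

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def compiled(self) -> CompiledDynamics:
        if self._compiled is None:
            n = len(self.nodes)
            up = np.zeros((n, n))
            down = np.zeros((n, n))
            outdeg = np.zeros(n)
            for (src, dst), w in self.edges.items():
                s, d = self._index[src], self._index[dst]
                if w >= 0:
                    up[d, s] = w
                else:
                    down[d, s] = -w
                outdeg[s] += 1
            self._compiled = CompiledDynamics(up, down, outdeg)
        return self._compiled

    # -- serialization -----------------------------------------------------

    def to_json_dict(self) -> dict:
        pleio = self.pleiotropy
        locked = pleio.locked if pleio else frozenset()
        return {
            "nodes": [
                {
                    "id": n.id,
                    "role": n.role,
                    "pleiotropic": bool(pleio and n.id == pleio.node_id),
                }
                for n in self.nodes
            ],
            "edges": [
                {"src": src, "dst": dst, "w": w, "locked": (src, dst) in locked}
                for (src, dst), w in sorted(self.edges.items())
            ],
            "pleiotropy_mode": pleio.mode if pleio else None,
            "lineage_id": self.lineage_id,
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "RegulatoryNetwork":
        nodes = [Node(d["id"], d["role"]) for d in data["nodes"]]
        edges = {(e["src"], e["dst"]): e["w"] for e in data["edges"]}
        pleio = None
        mode = data.get("pleiotropy_mode")
        if mode is not None:
            pid = next(d["id"] for d in data["nodes"] if d["pleiotropic"])
            locked = frozenset(
                (e["src"], e["dst"]) for e in data["edges"] if e["locked"]
            )
            pleio = PleiotropyRecord(pid, mode, locked)
        return cls(nodes, edges, pleio, data.get("lineage_id"))

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict())

    @classmethod
    def from_json(cls, text: str) -> "RegulatoryNetwork":
        return cls.from_json_dict(json.loads(text))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        pleio = self.pleiotropy
        for n in self.nodes:
            g.add_node(
                n.id,
                role=n.role,
                pleiotropic=bool(pleio and n.id == pleio.node_id),
            )
        for (src, dst), w in self.edges.items():
            g.add_edge(src, dst, weight=w, locked=(src, dst) in self.locked_edges)
        return g

    def to_graphml(self, path):
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def canonical_key(self) -> tuple:
        """Exact-match key used to count identical genotypes in a population."""
        return (
            tuple(sorted((n.id, n.role) for n in self.nodes)),
            tuple(sorted((s, d, w) for (s, d), w in self.edges.items())),
        )


def init_random_network(rng, n_signaling: int = 3, lineage_id: Optional[str] = None) -> RegulatoryNetwork:
    """Draw a random initial network: one detector, ``n_signaling`` signaling
    proteins, one effector; every ordered pair (self-edges included, the
    direct detector->effector link excluded) is present with probability 0.5
    with weight uniform on [-1, 1]."""
    if n_signaling < 1:
        raise ValueError("need at least one signaling protein")
    rng = as_generator(rng)
    nodes = (
        [Node("D", DETECTOR)]
        + [Node(f"S{i + 1}", SIGNALING) for i in range(n_signaling)]
        + [Node("E", EFFECTOR)]
    )
    ids = [n.id for n in nodes]
    edges = {}
    for src in ids:
        for dst in ids:
            if src == "D" and dst == "E":
                continue
            if rng.random() < 0.5:
                edges[(src, dst)] = rng.uniform(-1.0, 1.0)
    return RegulatoryNetwork(nodes, edges, None, lineage_id)


def _kernel(active: np.ndarray, comp: CompiledDynamics, use_coef: float) -> np.ndarray:
    gain = (1.0 - active) * (comp.up @ active)
    loss = active * (comp.down @ active)
    return np.clip(active + gain - loss - use_coef * comp.outdeg, 0.0, 1.0)


def step_dynamics(
    net: RegulatoryNetwork,
    state: NetworkState,
    params: DynamicsParams,
    parasite=None,
) -> NetworkState:
    """Advance the network one time step.

    With ``parasite`` given, the parasite is treated as one extra protein
    wired per the infection rules and updated by the same kernel.
    """
    if parasite is not None:
        from .infection import attach_parasite

        aug = attach_parasite(net, parasite)
        p0 = state.parasite_active
        if p0 is None:
            raise ValueError("infected step requires state.parasite_active")
        x = np.append(state.active, p0)
        x = _kernel(x, aug.compiled, params.use_coef)
        return NetworkState(x[:-1], float(x[-1]))
    new = _kernel(state.active, net.compiled(), params.use_coef)
    return NetworkState(new, None)


@dataclass(frozen=True)
class EquilibriumResult:
    state: NetworkState
    effector_pre: float
    steps: int
    converged: bool


def healthy_equilibrium(net: RegulatoryNetwork, params: DynamicsParams) -> EquilibriumResult:
    """Iterate the uninfected map from uniform initial activity until the
    effector's active fraction settles (|change| < tol) or the step cap hits.

    Results are cached on the network object; clonal hosts sharing a genotype
    therefore share one computation.
    """
    cached = net._equilibrium_cache.get(params)
    if cached is not None:
        return cached
    comp = net.compiled()
    eff = net.index_of(net.effector_id)
    x = np.full(len(net.nodes), params.initial_active)
    converged = False
    steps = 0
    for steps in range(1, params.max_equilibrium_steps + 1):
        prev_eff = x[eff]
        x = _kernel(x, comp, params.use_coef)
        if abs(x[eff] - prev_eff) < params.equilibrium_tol:
            converged = True
            break
    result = EquilibriumResult(NetworkState(x), float(x[eff]), steps, converged)
    net._equilibrium_cache[params] = result
    return result
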