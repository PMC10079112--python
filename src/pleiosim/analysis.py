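"""Population-level analyses of evolved immune networks.

Covers the constitutive/inducible response spectrum (per-host inducibility
and its kernel-density profile), comparisons between populations (Pearson
correlation of densities, 2D magnitude-vs-inducibility densities), network
robustness (knockout divergence with t-test contrasts), structural features
(connectivity, vertex-disjoint detector->effector paths), modal genotypes,
and lineage splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .infection import (
    FitnessParams,
    InfectionRecord,
    Parasite,
    UNINFECTED,
    run_infection,
)
from .network import DynamicsParams, RegulatoryNetwork, SIGNALING

DEFAULT_GRID = 201


def inducibility(rec: InfectionRecord) -> float:
    """Fraction of the host's maximal response that was induced by infection:
    (peak - pre) / peak, clamped to [0, 1]; zero when no response exists."""
    if rec.effector_peak <= 0.0:
        return 0.0
    return float(np.clip((rec.effector_peak - rec.effector_pre) / rec.effector_peak, 0.0, 1.0))


@dataclass(frozen=True)
class DensityEstimate:
    """Peak-normalized KDE on a fixed grid over [0, 1]."""

    grid: np.ndarray
    density: np.ndarray

    def peak_location(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])


_DEGENERATE_BW = 0.02  # bandwidth fallback for zero-variance samples


def _kde_1d(values: np.ndarray, grid: np.ndarray, bandwidth) -> np.ndarray:
    """Gaussian KDE with boundary reflection at 0 and 1."""
    values = np.asarray(values, dtype=float)
    if values.std() == 0.0:
        bw = _DEGENERATE_BW
        raw = np.exp(-0.5 * ((grid[:, None] - values[None, :]) / bw) ** 2).sum(axis=1)
        refl_lo = np.exp(-0.5 * ((grid[:, None] + values[None, :]) / bw) ** 2).sum(axis=1)
        refl_hi = np.exp(-0.5 * ((grid[:, None] - (2 - values[None, :])) / bw) ** 2).sum(axis=1)
        total = raw + refl_lo + refl_hi
        return total / (bw * np.sqrt(2 * np.pi) * len(values))
    kde = stats.gaussian_kde(values, bw_method=bandwidth)
    return kde(grid) + kde(-grid) + kde(2.0 - grid)


def response_density(
    values,
    bandwidth="silverman",
    grid_points: int = DEFAULT_GRID,
) -> DensityEstimate:
    """Immune response probability density: Gaussian KDE of per-host
    inducibilities on [0, 1], boundary-reflected and peak-normalized to 1."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot estimate a density from an empty sample")
    grid = np.linspace(0.0, 1.0, grid_points)
    dens = _kde_1d(values, grid, bandwidth)
    return DensityEstimate(grid, dens / dens.max())


def density_correlation(a: DensityEstimate, b: DensityEstimate) -> float:
    """Pearson r between two densities on the same grid; |r| <= 0.2 flags a
    substantive difference between the underlying response distributions."""
    if len(a.grid) != len(b.grid) or not np.allclose(a.grid, b.grid):
        raise ValueError("densities must share a grid")
    if a.density.std() == 0.0 or b.density.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a.density, b.density)[0, 1])


@dataclass(frozen=True)
class Density2D:
    """2D density over (inducibility, peak magnitude) in [0, 1]^2."""

    x_grid: np.ndarray
    y_grid: np.ndarray
    density: np.ndarray  # shape (len(y_grid), len(x_grid))


def magnitude_inducibility_density(
    profiles,
    bandwidth="silverman",
    grid_points: int = 51,
) -> Density2D:
    """2D KDE of (inducibility, effector peak) pairs, boundary-reflected on
    both axes; integrates to ~1 over the unit square.

    ``profiles`` is a sequence of (inducibility, effector_peak) pairs.
    Densities from replicate runs are summed by :func:`pool_densities`.
    """
    pts = np.asarray(list(profiles), dtype=float)
    if pts.size == 0:
        raise ValueError("cannot estimate a density from an empty sample")
    x = np.linspace(0.0, 1.0, grid_points)
    y = np.linspace(0.0, 1.0, grid_points)
    xx, yy = np.meshgrid(x, y)
    degenerate = pts.shape[0] < 3
    if not degenerate:
        cov = np.cov(pts.T)
        degenerate = not np.all(np.isfinite(cov)) or np.linalg.matrix_rank(cov) < 2
    dens = np.zeros_like(xx)
    if degenerate:
        # collinear / tiny cloud: isotropic kernel with a fixed bandwidth
        bw = _DEGENERATE_BW
        for px, py in pts:
            for rx in (px, -px, 2 - px):
                for ry in (py, -py, 2 - py):
                    dens += np.exp(-0.5 * (((xx - rx) ** 2 + (yy - ry) ** 2) / bw**2))
        dens /= 2 * np.pi * bw**2 * len(pts)
    else:
        kde = stats.gaussian_kde(pts.T, bw_method=bandwidth)
        for gx in (xx, -xx, 2.0 - xx):
            for gy in (yy, -yy, 2.0 - yy):
                dens += kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(xx.shape)
    return Density2D(x, y, dens)


def pool_densities(densities) -> Density2D:
    """Sum replicate 2D densities on a shared grid (mass per run preserved)."""
    densities = list(densities)
    base = densities[0]
    total = np.zeros_like(base.density)
    for d in densities:
        if d.density.shape != base.density.shape:
            raise ValueError("densities must share a grid")
        total += d.density
    return Density2D(base.x_grid, base.y_grid, total)


def knockout_network(net: RegulatoryNetwork, protein: str) -> RegulatoryNetwork:
    roles = {n.id: n.role for n in net.nodes}
    if roles.get(protein) != SIGNALING:
        raise ValueError("can only knock out a signaling protein")
    nodes = [n for n in net.nodes if n.id != protein]
    edges = {(s, d): w for (s, d), w in net.edges.items() if protein not in (s, d)}
    pleio = net.pleiotropy
    if pleio is not None:
        if pleio.node_id == protein:
            pleio = None
        else:
            locked = frozenset(e for e in pleio.locked if protein not in e)
            pleio = type(pleio)(pleio.node_id, pleio.mode, locked)
    return RegulatoryNetwork(nodes, edges, pleio, net.lineage_id)


def knockout_divergence(
    net: RegulatoryNetwork,
    protein: str,
    dyn: DynamicsParams = DynamicsParams(),
    fit: FitnessParams = FitnessParams(),
) -> float:
    """Mean absolute effector difference between the intact network and the
    network with ``protein`` knocked out, both infected for the full lifespan
    by a non-manipulating parasite (manipulation weight 0), each starting
    from its own healthy equilibrium."""
    ko = knockout_network(net, protein)
    traces = []
    for candidate in (net, ko):
        sig = candidate.signaling_ids
        if not sig:
            raise ValueError("knockout leaves no signaling protein to target")
        parasite = Parasite(sig[0], 0.0)
        rec = run_infection(candidate, parasite, dyn, fit, fixed_horizon=True)
        traces.append(np.asarray(rec.effector_trace))
    return float(np.mean(np.abs(traces[0] - traces[1])))


def knockout_contrast(pleiotropic_divs, other_divs, n_comparisons: int = 1) -> dict:
    """Equal-variance two-sample t-test with Bonferroni correction."""
    a = np.asarray(list(pleiotropic_divs), dtype=float)
    b = np.asarray(list(other_divs), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if a.std() == 0.0 and b.std() == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return {"t": 0.0, "p_raw": 1.0, "p_bonferroni": 1.0, "significant": False, "degenerate": True}
        return {"t": float("inf"), "p_raw": 0.0, "p_bonferroni": 0.0, "significant": True, "degenerate": True}
    t, p = stats.ttest_ind(a, b, equal_var=True)
    p_bonf = min(1.0, float(p) * n_comparisons)
    return {
        "t": float(t),
        "p_raw": float(p),
        "p_bonferroni": p_bonf,
        "significant": p_bonf < 0.05,
        "degenerate": False,
    }


def connectivity(net: RegulatoryNetwork) -> float:
    """Edges divided by possible edges: n^2 ordered pairs (self-edges legal)
    minus the forbidden detector->effector link."""
    n = net.size
    return len(net.edges) / (n * n - 1)


def distinct_paths(net: RegulatoryNetwork) -> int:
    """Maximum number of detector->effector paths sharing no signaling
    protein (internally vertex-disjoint), via unit-vertex-capacity max flow
    on the node-split graph. Edge signs and weights are ignored."""
    import networkx as nx

    det, eff = net.detector_id, net.effector_id
    g = nx.DiGraph()
    inf = len(net.nodes) + 1

    def out_node(v):
        return (v, "out") if v not in (det, eff) else v

    def in_node(v):
        return (v, "in") if v not in (det, eff) else v

    for n in net.nodes:
        if n.role == SIGNALING:
            g.add_edge((n.id, "in"), (n.id, "out"), capacity=1)
    for (s, d) in net.edges:
        if s == d:
            continue
        g.add_edge(out_node(s), in_node(d), capacity=inf)
    if det not in g or eff not in g:
        return 0
    return int(nx.maximum_flow_value(g, det, eff))


def most_common_network(population) -> tuple:
    """Modal genotype under exact-match equality (node roles + edge list at
    full float precision); ties break toward the lowest host id.

    ``population`` is a sequence of Host-like objects with .id and .network.
    Returns (network, count).
    """
    population = list(population)
    if not population:
        raise ValueError("empty population")
    groups: dict = {}
    for host in population:
        key = host.network.canonical_key()
        entry = groups.setdefault(key, [0, host.id, host.network])
        entry[0] += 1
        if host.id < entry[1]:
            entry[1], entry[2] = host.id, host.network
    best = max(groups.values(), key=lambda e: (e[0], -e[1]))
    return best[2], best[0]


def lineage_split(inducibilities_by_lineage, threshold: float = 0.5) -> bool:
    """True iff some generation-0 lineage contains both a predominantly
    inducible host (>= threshold) and a predominantly constitutive one.

    ``inducibilities_by_lineage`` maps lineage_id -> iterable of per-host
    inducibility values in the final generation.
    """
    for values in inducibilities_by_lineage.values():
        values = list(values)
        if any(v >= threshold for v in values) and any(v < threshold for v in values):
            return True
    return False


def archive_inducibilities(archive, infected_only: bool = True):
    """Per-host inducibilities from a RunArchive's final generation."""
    out = []
    for rec in archive.final_records:
        if infected_only and rec.outcome == UNINFECTED:
            continue
        out.append(inducibility(rec))
    return out


def archive_lineage_inducibilities(archive) -> dict:
    by_lineage: dict = {}
    for host, rec in zip(archive.final_hosts, archive.final_records):
        if rec.outcome == UNINFECTED:
            continue
        by_lineage.setdefault(host.lineage_id, []).append(inducibility(rec))
    return by_lineage
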