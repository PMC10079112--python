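# Methods

## Within-host dynamics

Proteins are two-state (active/inactive, total concentration 1). The update
is an explicit discrete-time map, not an ODE: at each step every protein
gains activity from its upregulators in proportion to its inactive pool,
loses activity to its downregulators in proportion to its active pool, and
pays a flat `use_coef` per regulatory edge it maintains (self-edges count;
during infection the effector's −1 edge onto the parasite counts too).
Values are clamped to [0, 1] after every step — the raw map can leave the
interval, and clamping is what keeps the active/inactive decomposition
meaningful. The per-edge cost is charged on *outgoing* edges (the cost of
acting on others) and is independent of the protein's current activity; a
fully inactive protein with many targets therefore simply stays pinned at 0.

Healthy equilibrium starts all proteins at 0.5 and iterates until the
effector's active fraction changes by less than `equilibrium_tol` (10⁻³)
between consecutive steps, capped at 200 steps. Only the effector is
monitored — that is the quantity fitness reads — so other proteins may still
be drifting when iteration stops; the infection then starts from exactly
that state. Both tolerance and cap are configurable; non-convergence at the
cap is flagged, not an error.

Infection termination is evaluated after every step in the order clearance
(parasite < 10⁻²), death (running normalized area > 0.9), lifespan (20
steps → "managed"). Clearance is checked before death so a simultaneous
trigger resolves in the host's favor; death is checked at the final step
too, so "managed" genuinely means the infection ended below the lethal
area. An inoculum already below the clearance threshold clears immediately
with area 0. The area is always normalized by the full 20-step lifespan,
also for early-terminated infections — fast clearance therefore earns a
small damage term, and parasite fitness (the same area) rewards persistence.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `use_coef` | 0.01 | per-edge, per-step inactivation cost; small enough that a five-target protein (0.05/step) can still sustain signaling |
| `equilibrium_tol` / cap | 10⁻³ / 200 | healthy-phase stopping rule |
| `initial_active`, `parasite_initial_active` | 0.5 / 0.5 | uniform start; parasite inoculum symmetric with protein initialization |
| `virulence` V | 1.0 | weight of parasite area in host fitness |
| clearance / death thresholds | 10⁻² / 0.9 | infection end states |
| size cost | 1.1·(N−10) for N>10 | genome-size penalty |
| host / parasite mutation rate | 5·10⁻³ / 10⁻² | per offspring |
| host mutation menu | .25/.25/.3/.1/.1 | add edge / delete edge / re-weight / delete protein / duplicate protein |
| `death_cap` | 0.3 | max fraction of either population dying per generation |
| `slow_factor` | 100 | mutation-rate divisor for the slow pleiotropic node |

`use_coef`, V and the inoculum size are load-bearing and worth sensitivity
analysis: the parasite pays `3·use_coef` per step for its three outgoing
edges, which sets its unopposed plateau (≈0.96 at the default) and hence
whether a host that mounts no response at all survives the 20-step lifespan
(at the defaults it does not — its area crosses 0.9 at the last step).
That knife-edge decides whether "ignore the parasite" is a viable strategy
at low infection risk, and through it how often populations settle on
constitutive versus induced architectures.

## Selection

Death: infection-killed hosts die first; if they exceed the 30% cap a
random excess is restored. Remaining deaths visit survivors in random
order, each dying with probability 1 − percentile, where percentile is the
fraction of the *rest* of the comparison group with strictly lower fitness
(ties share a value): the top of a strictly ordered population never dies,
a 75th-percentile individual dies with probability 0.25. In a fully clonal
population every member shares the bottom percentile, so turnover runs at
the cap — neutral among clones. Parasites are culled by the same rule on
cumulative load, with cleared and host-killing parasites prioritized.

Reproduction: survivors persist, and the dead slots are refilled by
drawing parents with probability proportional to fitness W (roulette
selection; a parent can be drawn repeatedly). We deliberately did not
mirror the percentile death rule here: rank-proportional reproduction
degenerates to truncation selection (only the top rank can ever reproduce)
and has no well-defined behavior in a clonal population, whereas
fitness-proportional sampling reduces smoothly to uniform draws among
clones. Parasite reproduction is quota-based on absolute load (1/2/3
offspring for loads in [0,.33]/(.33,.66]/(.66,1]), parents taken
highest-load first and cycled until the population is replenished.

Mutation specifics: added edges avoid existing pairs and the forbidden
detector→effector link; deletion targets signaling proteins only and never
the pleiotropic protein or any node touching a locked edge (locks are
absolute); duplication copies all incident edges, mapping a self-edge to a
self-edge on the copy, and a duplicated pleiotropic protein's paralog is
fully mutable. Under the `slow` constraint a drawn mutation that would
touch an edge of the slow node is accepted with probability
1/`slow_factor` and otherwise the offspring is an unmutated copy.
If a drawn mutation type has no legal move the type is resampled
(bounded; a pathological network yields an unmutated copy).

## Simulation orchestration

One master seed feeds named substreams (init, pairing, mutation, culling,
reproduction), so runs are byte-reproducible and a logic change in one
phase does not scramble the draws of another. Parasites are re-paired with
hosts uniformly at random each generation (population size = number of
infections); a parasite whose target no longer exists in its host is
retargeted uniformly. Competition halves the population into a pleiotropic
and a non-pleiotropic arena (each with its own parasites), optionally
pre-evolves them separately, then merges hosts *and* parasites into one
population with a single fitness ranking — required for one type to be
driven extinct; a 1000-generation cap declares a draw.

Networks are treated as immutable genotypes: clonal offspring share the
parent's object, and healthy equilibria and infection episodes (keyed by
the parasite's target and manipulation) are cached per genotype. Dynamics
are deterministic, so caching changes nothing observable; it is what makes
population-scale runs fast, since a generation typically contains only a
handful of distinct genotypes.

## Analysis choices

Inducibility is (peak − pre)/peak, defined as 0 when the peak is 0 (no
response means nothing was induced). Response densities use a Gaussian KDE
(Silverman bandwidth) evaluated on a 201-point grid over [0, 1] with
boundary reflection at both ends — without reflection, mass leaks outside
the unit interval and boundary peaks are flattened — then peak-normalized
to 1. Zero-variance samples fall back to a fixed 0.02 bandwidth. The 2D
magnitude-vs-inducibility density reflects in both axes and integrates to
≈1 per run before replicate densities are summed. Pearson correlation
between two densities on the shared grid flags |r| ≤ 0.2 as a substantive
difference; a zero-variance density yields NaN.

Knockout divergence removes one signaling protein (with its edges), infects
both the intact and the perturbed network with a non-manipulating probe
parasite (manipulation weight 0) for a *fixed* 20 steps — no early
termination, so the two effector traces are always the same length — each
from its own healthy equilibrium, and averages the absolute effector
difference. Contrasts use equal-variance two-sample t-tests with Bonferroni
correction.

Connectivity divides the edge count by n² − 1 (all ordered pairs including
self-edges, minus the forbidden detector→effector pair). Distinct
detector→effector paths (paths sharing no signaling protein) are counted as
unit-vertex-capacity max flow on the node-split graph, which the tests
verify against exhaustive path-set search on all graphs up to 8 nodes.
"Most common network" uses exact-match equality (sorted roles and edge
lists at full float precision) — a single re-weighted edge makes a new
genotype — with ties broken toward the lowest host id.

## What the simulations do and do not show

All stochastic acceptance checks run at a reduced scale — 100 hosts for
150 generations, 5–10 replicates per condition — rather than the 500×500
×100 of a publication-scale sweep; the package happily runs the larger
configuration. At the reduced scale the qualitative outcomes are coarser:
populations usually fix a single strategy, so per-run inducibility is
near-binary (fully constitutive or fully induced) and cross-condition
contrasts show up in the *fraction of runs* adopting each strategy rather
than in smooth density shifts. Under the default `use_coef`/V the
zero-response strategy is lethal (see above), which pushes populations at
every infection risk toward whichever of the two viable strategies a
lineage discovers first; the association between fixed downregulatory
pleiotropy and inducible outcomes is directionally present in replicate
means but not in every paired comparison.

The model is clonal (no recombination), has exactly one detector and one
effector, uses perfectly effective and instantaneous effector killing, and
its generator emulates no environmental heterogeneity, spatial structure,
or multi-parasite infection — passing tests say nothing about systems where
those matter. Duplicated pleiotropic proteins lose their constraint
(no subfunctionalization model), and parasites are re-assorted across hosts
every generation, so no host–parasite genotype associations persist.
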