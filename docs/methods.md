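# Methods

## The model

`netham` simulates a system of aggregating protein molecules as a simple
undirected graph on N labeled nodes: one node per molecule, one edge per
noncovalent bond.  The model is an exponential-family random graph model
(ERGM) whose energy — the *network Hamiltonian* — is linear in a chosen
set of sufficient statistics t(g):

    H(g) = Σ_X φ_X t_X(g),        P(g) ∝ h(g) · exp(−H(g) / k_B T),

with h(g) fixed to the uniform counting measure and k_B T = 1 by default.
Negative φ_X means forming motif X is exothermic (favored); positive means
an energetic cost.  Sampling uses the statistically oriented form
θ = −φ/(k_B T), under which P(g) ∝ exp(θᵀ t(g)).

Supported statistics: edge count; 2-stars (Σ_v C(deg v, 2)); null and
edgewise shared-partner counts NSP1, NSP2, ESP0, ESP1 (non-adjacent /
adjacent dyads with *exactly* k common neighbors — plain counts, not
geometrically weighted variants); and simple-cycle counts of length 3, 5,
6, and 7, each cycle counted once.  Graphs are purely topological: no
coordinates, weights, or node attributes.

### Size offsets

Transferring a model between system sizes uses a Krivitsky-style log-size
offset on the edge coefficient: `rescale_edge_phi(φ_e, n_from, n_to)`
returns φ_e + ln(n_from) − ln(n_to).  The φ→θ conversion at size N applies
θ_e = −(φ_e + c − ln N) with offset constant c = 1 by default (the form
used with the shipped presets), and θ_X = −φ_X for every other statistic.
The conversion with the "+1" constant and the plain pairwise offset are
both implemented exactly as published; the package does not attempt to
reconcile their origins, and the constant is configurable (set
`edge_offset=False` for the plain θ = −φ conversion).

## Sampling

`simulate_draw` runs Metropolis-Hastings over edge toggles: a uniformly
random dyad is proposed, and the toggle is accepted with probability
min(1, exp(θᵀ Δt)), where the change statistics Δt are computed from the
local neighborhood of the dyad only (shared-partner reclassification from
common-neighbor counts; cycle changes from simple-path counts between the
dyad's endpoints).  The proposal is symmetric, so detailed balance holds
by construction.  Running statistics are maintained incrementally and are
exactly equal to a full recount of the final graph (integer arithmetic
throughout; a property test enforces it).

Defaults, all configurable:

| parameter          | default        | rationale |
|--------------------|----------------|-----------|
| initialization     | empty graph    | a fully disaggregated monomer system; makes lag-phase behavior observable |
| burn-in            | 50 · C(N, 2) proposals | several expected toggles per dyad |
| degeneracy guard   | 8 · N edges    | aborts 2-star-driven runaway densification so parameter searches survive bad regions |

The hot loop is compiled with numba; the identical source runs uncompiled
when numba is unavailable, and proposal streams are pre-generated with
numpy's PCG64 generator, so results are bitwise identical across the two
modes and fully determined by the seed.  Ensemble draws derive per-rep
seeds from the master seed keyed by rep index, so results do not depend on
evaluation order.

Two numerical notes.  First, a uniform-toggle chain of *fixed* length has
a parity artifact in the dyad-independent limit: at θ = 0 every proposal
is accepted, so the edge-count parity equals the burn-in parity.  The
distributional tests mix even- and odd-length chains to recover the full
equilibrium law.  Second, deeply ordered models mix slowly: see
"Known limitations" below.

## The fibril-fraction assay

The five experimentally observed amyloid fibril topologies (1-ribbon,
2-ribbon, 1,2 2-ribbon — the steric zipper —, double 1,2 2-ribbon,
3-prism) are encoded as periodic templates: `strands` nodes per repeat
unit and offset rules ((strand a, strand b), Δi ∈ {0, 1}) placing an edge
between (a, i) and (b, i + Δi).  Templates are data, not code; users can
override the offsets in configuration.  The shipped reconstructions are:

| template              | strands | rules |
|-----------------------|---------|-------|
| 1-ribbon              | 1 | chain (0,0,Δ1) |
| 2-ribbon              | 2 | rails (s,s,Δ1), rungs (0,1,Δ0) |
| 1,2 2-ribbon          | 2 | 2-ribbon + diagonals (0,1,Δ1) |
| double 1,2 2-ribbon   | 4 | two 1,2 2-ribbons joined by rungs (1,2,Δ0) |
| 3-prism               | 3 | rails (s,s,Δ1), triangle rungs at Δ0 |

The *fibril fraction* of a graph is |fibrillar nodes| / N.  A node is
fibrillar iff (a) it lies in an embedded template segment spanning at
least `min_units` = 3 repeat units (wrap-around allowed — cyclic fibrils
are valid, and common, since the metric discourages free ends), (b) its
complete interior template neighborhood is present, and (c) it has no
edges outside the matched pattern.  This strict interior-only rule rewards
long defect-free fibrils and undercounts ends by design.  Overlapping
segments contribute the union of their interior nodes.  Matching
enumerates unit embeddings anchored at each candidate node (pre-filtered
by interior degree) and extends them axially; with min_units = 3 a
node qualifies exactly when a predecessor and successor unit exist and its
neighborhood equals the pattern.

Because the strictness applies per node, a structure containing a perfect
sub-motif partially matches that motif's template: e.g. the outer strands
of a double 1,2 2-ribbon score 0.5 under the 1,2 2-ribbon template.  The
exact edge patterns of the 1,2 and double 1,2 topologies are
reconstructions from their names, interior degrees, and the steric-zipper
description; the original definitions live in earlier work and its
released scripts, so exact parity with those scripts is not guaranteed
(see "Known limitations").

## The genetic algorithm

Fitness of a parameter point is the mean fibril fraction of `reps`
independent equilibrium draws (degenerate draws score 0 rather than
aborting the search).  Hyperparameters follow the method's vocabulary with
these typical values: reps 16, noiseVarInit 1.0, topFraction 0.25,
maxSurvivors 20, fixEdge/fixEdgeValue on/100, smartVar on, smartPts on,
useLineDensity/minLineDensity on/1.2, childMax 100.

One generation:

1. **Line breeding.** Every survivor pair at Euclidean distance d (over
   the free dimensions) produces ⌊minLineDensity · d⌋ *linear children*
   evenly spaced strictly between the parents; pairs implying fewer than
   one child are deemed too closely related to breed (inbreeding
   avoidance).  Each linear child gets `current_mutants_per_child`
   *mutant* copies with isotropic Gaussian noise of variance
   `current_noise_var` per free dimension (a distribution choice; the
   method only requires "noise").  Broods larger than childMax are
   subsampled uniformly.
2. **Evaluation and acceptance.** If no child strictly outperforms the
   best parent, the entire brood leaves the gene pool and the parents
   rebreed with the noise variance doubled (smartVar; the multiplier is a
   design choice) and one more mutant per linear child (smartPts), up to
   `max_retries_per_generation` = 5 times (a bound on compute; the
   original procedure implies unbounded retry).  Exhaustion ends the run
   with a reported stall.
3. **Selection.** Copies of all breeding parents join the accepted
   generation — a consistently top parameter can become immortal — and the
   top `topFraction` by mean fitness survive (ties to the lower id;
   a uniform random subset if the fraction exceeds maxSurvivors).

Generation 0 comes from `seed_sphere` (uniform in a ball over the free
dimensions) or user-supplied points, and its members are the initial
breeding stock directly: top-fraction selection starts with the first bred
generation, since a user-chosen starting population (e.g. four hand-picked
low-yield points) is meant to breed in full.

With `fixEdge` on, the edge coordinate is excluded from breeding,
mutation, and sphere sampling; it is stored as `fixEdgeValue` in every
individual and used *directly as θ_e* during fitness simulation (the
value is in θ form, matching the convention of holding θ_e = 100
constant), while all other coordinates are φ and simulate with
θ_X = −φ_X.  Per-individual rep seeds are keyed by
(master seed, individual id, rep), so fitness values are reproducible and
independent of evaluation schedule; full runs are reproducible bit for
bit under a fixed master seed.

## Problem sizes used by the test suite and acceptance script

The worked-example statistics run on the printed four-node graph.
Property suites use ≥1000 random 8-node graphs for change statistics,
exhaustive cycle enumeration for n ≤ 8, and closed forms for complete
graphs and dyad-independent samplers.  Published-model reproduction draws
50 equilibrated 256-node samples of the 1-ribbon preset (the assay's
maximum is compared against the printed 1.0).  The end-to-end GA check
runs the 2-ribbon search at 48 nodes with reduced population sizes
(maxSurvivors 6, childMax 20, reps 8) from a frozen generation 0 of four
sphere-sampled points whose single-draw yields were 0.02–0.04; these
scales are the package's own desk-scale study conditions, chosen so the
full suite completes in minutes while exercising every mechanism at the
sizes the published experiments describe (48- and 256-node systems).

## Known limitations

* **Mixing, not statics, limits fibril yield reproduction.**  Under the
  published 2-ribbon and 1,2 2-ribbon coefficients the perfect cyclic
  fibril is a deep equilibrium state — chains started on it stay on it —
  but empty-graph starts at 256 nodes freeze into a degree-correct glass
  (every node at its target degree, no long-range order) and uniform-toggle
  burn-in does not anneal past the barrier at feasible lengths.  Draws
  therefore reproduce the printed maximum fibril fraction for the 1-ribbon
  model (1.0) but not for those two presets.  The original study sampled
  with an external ERGM engine (tie/no-tie proposals, unreported
  schedule), which evidently mixes differently.  A TNT proposal is a
  documented extension point.
* **The double 1,2 2-ribbon template reconstruction is suspect.**  Under
  the published double-ribbon coefficients the reconstructed perfect
  fibril is not even metastable (it decays to a lower-energy state), which
  indicates the original topology's joining pattern differs from the
  reconstruction shipped here.  Template overrides in configuration are
  the escape hatch.
* The GA's evaluated populations are simulated serially; the seed scheme
  already supports parallel evaluation (seeds are keyed by individual),
  but no parallel executor is shipped.
* Shared-partner statistics above NSP2/ESP1 and cycles other than
  3, 5, 6, 7 are not implemented; directed, weighted, and
  covariate-bearing graphs are out of scope.
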