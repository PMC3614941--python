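# Methods

## Model estimation

The input is a set of discrete trajectories: sequences of integer
microstate indices sampled at a fixed time step. Transition counts
`C_ij` are taken with a sliding window at lag `τ` (every ordered pair
`(t, t+τ)` within one trajectory; a strided mode is available), and the
transition matrix is the plain row-normalized estimate `T_ij = C_ij / Σ_k
C_ik`. No pseudocounts are added and no reversibility is enforced by
default, so the estimate is exactly reproducible from the counts; an
optional uniform prior and a count-symmetrization switch exist for users
who want them. Lag is expressed in trajectory steps and all derived times
in lag units — the package is unit-agnostic.

Before any further computation the chain is restricted to the largest
strongly connected component of the directed count graph (ties between
equally large components broken by total population). This is mandatory:
stationary probabilities and commute times are finite only on an ergodic
chain. Removed states are reported by a warning and recorded in
`state_map`, never silently dropped.

The stationary distribution solves `πT = π, Σπ = 1` via least squares on
the stacked system `(Tᵀ − I; 1ᵀ)` after an explicit irreducibility check;
the result is validated as a fixed point to 1e-8 (and cross-checked against
power iteration in the tests). The free-energy proxy is `E_i = −ln π_i`,
dimensionless (units of kT): low `E` means a deep, highly populated basin.

## Commute-time distance

The hitting time `h(i→j)` solves the linear system `h_i = 1 + Σ_k T_ik
h_k` with `h_j = 0`; the commute time `D_ij = h(i→j) + h(j→i)` is
symmetric even for non-reversible chains and is used as the kinetic
distance. Two implementations exist on purpose: per-target linear solves
(simple, O(n⁴) for the full matrix — the independent oracle used in tests
and in the acceptance script) and the fundamental-matrix route `Z = (I − T
+ 1πᵀ)⁻¹`, `h(i→j) = (Z_jj − Z_ij)/π_j` (production, O(n³)). If the
fundamental matrix is ill-conditioned (condition number above 1e12) the
code warns and falls back to the per-target solves. `D` is symmetrized
against floating-point round-off and its diagonal zeroed.

`D` is not a metric (no triangle inequality — commute time behaves like a
squared distance) and nothing in the package assumes it is.

Scale bounds: `d_min` is the smallest off-diagonal entry (below it every
cluster is a singleton) and `D_star` the largest edge of a minimum spanning
tree of `D` (at or above it the neighborhood graph is connected), so all
informative scales lie in `[d_min, D_star]`.

## The density × scale grid

Density thresholds `θ_1 < … < θ_m` are even quantiles of the observed `E`
values, covering `[min E, max E]`, so every level adds a comparable number
of microstates. The scale axis spans `[d_min, D_star]` with **geometric
spacing by default**: commute times in metastable systems span several
orders of magnitude — intra-basin diffusion times at the bottom,
barrier-crossing times at the top — and a log grid resolves cluster
structure at every scale. Even-quantile spacing of the off-diagonal
distances is available but is a poor default here: the pairwise-distance
pool is dominated by pairs involving rarely visited states, which
concentrates the grid in the large-distance tail and skips the scales where
basins separate. Linear spacing is also available. Tied grid values (e.g.
from heavily tied `E`) are nudged apart by 1e-12-scale offsets to keep the
axes strictly increasing.

At each cell `(j, l)` the members `{i : E_i ≤ θ_j}` are clustered as
connected components of the ε-neighborhood graph (`D_ab ≤ ε_l`), which
equals a single-linkage cut — the tests enforce this equivalence against
`scipy`'s single-linkage implementation. Each component is labeled by its
minimum-`E` member, ties broken by lowest index. Component sizes are
reported in conformations (summed microstate populations).

A label's persistence region is the set of cells where it still labels its
own component. Because components only coarsen when either parameter
grows, each row and each column of a region is a contiguous run anchored at
the small-ε / birth-level edge, so the region is a staircase and hence
4-connected; the extractor verifies this and raises on violation (it would
indicate a bug, not a data property). Merge events are recorded
explicitly along both axes (`absorbs` / `merged_by` with the labels
involved); rendering gaps in diagrams is a view concern, not state.
Persistence lengths are measured in grid indices (max run length per row →
scale persistence; per column → density persistence).

## Selecting clusters

Three principles, with defaults expressed relative to the grid and the
data:

1. scale persistence ≥ ⌈q/3⌉ — the cluster is kinetically separated;
2. density persistence ≥ ⌈m/3⌉ — measured from birth (the region cannot
   start earlier), so a late-appearing cluster qualifies by persisting
   after it appears; this threshold is deliberately *not* relaxed for
   late-born labels, which is what keeps last-level noise singletons out;
3. maximum size ≥ 1% of all frames.

Labels passing 1–2 but not 3 are *rare-state candidates* — possibly
genuine small metastable states, possibly under-sampling — provided they
also (a) hold at least 0.1% of frames and (b) have scale persistence
≥ 0.8·q. Both extra conditions resolve the borderline between "valid but
small cluster" and "outlier": states with very few observed transitions
get inflated commute distances and therefore misleading scale persistence,
so a tiny cluster deserves the rare-state flag only if it is both
non-negligibly sampled and separated from *everything* almost up to the
full-connectivity scale `D_star`. Everything else remains visible in the
summary table; thresholds are user-overridable and the CLI always emits
the full summary.

Versions: candidates are processed in descending `E` of their label; each
takes the cell of its region whose component has the most conformations
subject to containing no other candidate's label and no already-claimed
member (fallback: its birth cell, trimmed). This guarantees pairwise
disjoint cores. A full partition assigns every remaining microstate to the
candidate minimizing the single-linkage commute distance to its version,
ties to the lower-`E` label; core mode leaves them unassigned.

The hierarchy scans density levels at one reference scale column and joins
candidates at the first level where their labels share a component; leaves
sit at birth levels, never-merging candidates attach to a virtual root one
level above the top, and the tree serializes to Newick with level-index
branch lengths. The default reference column is the largest scale at which
at least two candidates are still distinct at the most permissive level —
the coarsest informative view; the median column (or any other) can be
requested, but on landscapes whose basins merge only at large scales the
median column sees no merges at all and the tree degenerates.

## Synthetic data

A Metropolis walker on a landscape of inverted generalized-Gaussian wells
(`U = −Σ depth·exp(−½ (r²/w²)^(p/2))`, minimum-image distances on periodic
domains) stands in for molecular dynamics: the analysis consumes only
discrete trajectories, so any Markovian sampler with metastability
exercises every stage, and the planted wells give ground truth (basin of
attraction by steepest descent on the bin-center potential). Positions are
binned on a uniform per-axis grid (row-major indices; periodic domains bin
modulo the period).

Two reference landscapes are provided. The 1-D three-basin fixture (50
bins, 100 trajectories × 2,000 steps by default) has deep plateau basins A
(depth ≈ 5 kT) and B (4.8 kT) and a shallow single-bin basin C (3 kT)
placed inside a broad depression shared with A, so the A–C saddle
(≈ −1.8 kT) lies far below the flat background and C merges into A at
intermediate commute-time scales while B stays separate almost to
`D_star`. The 2-D periodic fixture (20×20 bins, 200 trajectories × 5,000
steps) has four prominent plateau wells a–d with graded depths 6.0 / 5.4 /
4.8 / 4.2 kT, overlapping tails that put the a–b barrier (≈ 3.7 kT from b)
below the core depth of c and d, and two narrow shallow wells e, f
(3.6 kT, holding ≈ 0.3% of frames each) far from the main wells.

Flat-bottomed (exponent-6) wells are deliberate: on a sloped (plain
Gaussian) well, uniform spatial binning manufactures rings of
intermediate-population microstates along the walls, each kinetically
separated from its neighbors in proportion to the local population drop —
an artifact of grid discretization that data-adaptive microstate
construction (e.g. k-center on real trajectories) does not produce, and
which pollutes the diagram with spurious medium-persistence clusters.
Plateau wells concentrate each basin's population at a common level, which
is also closer to real torsion free-energy maps than isolated quadratic
minima. What passing these fixtures shows is that the machinery recovers
planted kinetic structure through the whole pipeline; it does not show
robustness to the heterogeneous microstate sizes, projection noise and
non-Markovianity of real MD data.

Default problem sizes (400 microstates, 10⁶ frames, 25×25 grid) keep a
full pipeline run at a few seconds on one CPU; all randomness flows from a
single integer seed and reruns are byte-identical.

## Numerical choices and limitations

- Label ties in `E` break to the lowest microstate index, deterministically.
- Level-set membership uses `E_i ≤ θ_j` exactly; grid axes are forced
  strictly increasing as described above.
- The ergodic trim keeps one SCC; analyses of systems with genuinely
  disconnected sub-ensembles must be run per component.
- Commute times from low-count states are noisy and inflated; the
  rare-state size floor mitigates but cannot remove this (more sampling
  does).
- The hierarchy is a one-column view; basins whose merge scales differ
  wildly may warrant inspecting several reference columns.
- `mpcluster` does not construct microstates from coordinates, estimate
  reversible/Bayesian transition matrices, or compute spectral (PCCA-type)
  lumpings.
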