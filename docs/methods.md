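# Methods

This note documents the model as implemented: its assumptions, the parameter
conventions, the numerical choices, and what the test suite does and does not
establish.

## Model structure and schedule

One Monte Carlo time step (MCTS) executes, in order: phenotype
classification → branching attempts → proliferation selection/division →
one VEGF step → Notch signaling integration → elasticity refresh → the CPM
sweep → anastomosis resolution → gap filling → metrics.  All stochastic
choices (copy attempts, Metropolis draws, proliferating-cell selection,
division initialization, anastomosis coin flips) consume one seeded
generator, so a (config, seed) pair reproduces its outputs bit-identically;
the only floating-point-sensitive pieces are the two cached sparse
factorizations, which are deterministic on a given platform.

One MCTS is a full sweep of `(M−1)²` copy attempts.  Copy targets are drawn
from the von Neumann neighborhood; adhesion energies sum over Moore pairs
(both neighborhood orders are config knobs).  The sweep's attempt loop is
compiled with numba; the pure-Python loop in `angiocpm.lattice` is the
reference implementation, consumes the identical random stream, and is
cross-checked by an exact enumerated-Markov-chain test.

## Units

Lengths are micrometres, times hours.  Substrate mechanics is solved in SI
(metres, pascals, N/m of nodal force per unit substrate thickness) so the
printed values E = 10 kPa, ν = 0.45, μ_force = 1 N/m² are used directly;
the resulting strains near a contracting cell are a few 10⁻³–10⁻², which
the strain-stiffening law (ε_st = 0.1) converts into a modest but directed
durotaxis bias.

The VEGF field is stored nondimensionally, c = C/S ∈ [0, ~1].  The
chemotaxis term consumes c directly: with ρ⁰_chem = 6·10⁴ and a domain-scale
gradient of ~1/(M−1) per pixel this yields per-flip energies of order 10²,
the dominant drive for tip cells, while α_chem = 0.3 damps fluctuations near
the hypoxic boundary.  For signaling, c converts to molecules as
V_ext = χ_V · S_molec · c with S_molec = 7200: the external-VEGF scale of
the Notch system is 6·V₀ = 1200 molecules and cells near the hypoxic edge
see about six such units, so the boundary concentration S corresponds to
~7200 molecules.  With this scale, NICD in contact-inhibited cells crosses
its activation number I₀ = 200 and the pathway patterns; a substantially
smaller scale leaves the Notch gates unengaged.

## Parameters

All Potts couplings, elasticity/durotaxis constants, VEGF constants and
signaling rates default to the published table values (ρ_area = 9000,
ρ_perimeter = 250, ρ_length = 7200, ρ_durot = 25, ρ⁰_chem = 60000,
ρ_adh = 8.25 cell–cell / 16.50 cell–ECM; r_N = 1200, r_D = r_J = r_VR =
1000 molecules/h, k_C = 5·10⁻⁴, k_T = 2.5·10⁻⁵ (h·molecule)⁻¹, γ = 0.1,
γ_S = 0.5 h⁻¹; Hill fold-changes/exponents/thresholds as tabulated).  Shape
targets are 78.5 µm² / 31.4 µm / 49.5 µm, doubled area, tripled perimeter
and 70 µm length for proliferating cells.  One MCTS is 0.044 h in case (A)
and 0.03 h in case (B), from matching simulated to observed sprout
elongation speeds (`mcts_calibration`).

Values the source model leaves open, fixed here once:

* lattice resolution M = 199 (h = 2.5 µm) at full scale; the test domain is
  100×100 pixels (0.25 mm) with ~33 initial cells;
* the proliferation VEGF threshold ψ_p = 10⁻³ in c-units;
* persistent motion of an incubating tip is a directional energy bonus
  −ρ_persist·cos∠(move, θ) with ρ_persist = 0.1·ρ⁰_chem;
* a node belongs to a cell for traction/consumption purposes if it touches
  one of the cell's pixels (shared nodes accumulate each cell's pull);
* V_ext is read at the bottom-left node of the cell's hypoxia-facing pixel
  (maximal x, ties broken by minimal y);
* hybrid cells behave tip-like for motility, branching and collisions.

## Event rules

**Branching** is a one-shot decision at phenotype acquisition: when a stalk
cell becomes tip or hybrid, the strain vectors (largest principal strain ×
eigenvector, sign-canonicalized into the VEGF-gradient half-plane to prevent
±π cancellation) are averaged over its ECM-bordering pixels; if the mean
direction θ points into the ECM and lies within ±π/2 of the gradient angle
Θ, a new vessel is created with a 400-MCTS incubation, persistent motion
along θ and one permitted tip division.  If θ points at another cell, the
two cells exchange positions and the decision repeats in later MCTS — the
2D surrogate of a tip climbing over the vessel.  An ECM-facing angle veto
consumes the attempt; with retry-until-success semantics the reduced domain
produced ~80 branches per 1000 MCTS and a space-filling cell mass instead of
discrete sprouts.

**Proliferation.**  Each active, non-incubating sprout keeps exactly one
proliferating stalk cell chosen among those touching a tip-like member; it
divides by a balanced 2-means split (alternating equal-size assignment and
centroid correction, initialized from scikit-learn's KMeans) once it reaches
double area, provided local VEGF exceeds ψ_p, the vessel is active, and the
cell still touches ECM.  Daughters split the parent's molecule counts
equally.  Disconnected splits are retried with fresh initializations and
otherwise rejected; a failed division re-arms after a 5-MCTS pause.

**Anastomosis.**  Tip–tip contact between two distinct, active,
non-incubating sprouts inactivates one at random; tip–stalk contact
inactivates the tip's vessel.  Incubating vessels are exempt (a branching
vessel follows ordinary sprout rules only after incubation); a sprout is
also exempt against its parent until it has been observed out of contact
with it once.  Inactive vessels keep their cells and signaling but no longer
proliferate or branch.

**Gap filling.**  A sprout whose closest approach to its parent exceeds one
cell diameter (10 µm) receives a new zero-state stalk cell carved from the
ECM at the midpoint of the closest pixel pair; this is the mechanism by
which the primary vessel acts as a cell source behind a fast-advancing tip.

## Numerics

* CPM: incremental per-cell caches (pixel count, raw coordinate moments,
  exposed edges) give O(1) flip energies; the increments match a
  from-scratch Hamiltonian to 10⁻⁹ relative in the tests.  Flips that would
  annihilate a cell are rejected, as are flips that locally disconnect the
  losing cell (Moore-ring check, configurable).
* FEM: bilinear square elements, 2×2 Gauss integration, clamped boundary;
  the stiffness factorization (SuperLU) is computed once per run.  Strain is
  evaluated once per pixel at the element center.
* VEGF: backward Euler with a cached factorization (the explicit-scheme CFL
  limit at h = 2.5 µm is ~4·10⁻⁵ h, far below one MCTS); consumption is
  treated explicitly.  An explicit FTCS scheme with automatic sub-stepping
  is available.
* Signaling: explicit Euler with 20 sub-steps per MCTS; undershoots below
  zero are clamped (they are integration artifacts near fast cis terms).
* Division: 2-means balance is exact to ±1 pixel by construction.

## What the synthetic conditions do and do not show

The test domain (100×100 pixels, 1000 MCTS, three seeds per condition)
reproduces the model's verified laws exactly (Metropolis acceptance,
analytic VEGF limits, FEM patch tests, signaling fixed points, lateral
inhibition) and the qualitative morphodynamics: monotone front advance,
branching, anastomosis, gap filling, and the strong increase of the hybrid
tip/stalk census with Jagged production.  Raising Delta production at high
Jagged lowers the tip census, as expected from lateral inhibition.

Two caveats.  First, the domain is a quarter of the full-scale system, so
vessel networks are denser and faster (the hypoxic column is often reached
within ~700 MCTS) and absolute counts are not comparable to full-scale
figures.  Second, at this scale the strict tip census (V above all touching
neighbors and above half the population maximum) is partly geometry-bound:
the effect of raising Jagged production on the *strict* tip count is within
seed noise and can come out reversed, even though the binary tip-like
census (tip + hybrid) and the hybrid census order robustly with Jagged
production.  The corresponding check in `tests/test_acceptance.py` uses the
strict census and is expected to be the suite's one fragile assertion.

The stationary distribution of the CPM kinetics is verified against an
exact enumerated Markov chain on a tiny two-cell fixture; its area marginal
is close to, but not exactly, Boltzmann — the annihilation-rejection rule
and the asymmetric proposal distribution break detailed balance at the few-
pixel scale, a known property of this class of kinetics, documented rather
than hidden by the test tolerances.

## Known limitations

2D only; no lumen formation, perfusion or vessel regression; homogeneous
substrate without matrix degradation; a single VEGF isoform; phenotypes are
recomputed memorylessly each MCTS (no hysteresis); Fringe enters only
through its fold-change constants; the balanced 2-means split can fail on
highly non-convex cells, in which case division is deferred.
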