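# angiocpm

A hybrid multiscale simulator of early-stage sprouting angiogenesis — the
process by which new blood vessels sprout from an existing vessel toward a
hypoxic, VEGF-rich region.  It is aimed at computational biologists studying
how chemical (VEGF), mechanical (substrate strain) and cellular (Notch
signaling) cues jointly shape vascular morphology: tip-cell selection,
branching, stalk-cell proliferation and anastomosis.

## The model

Four coupled layers advance together, one Monte Carlo time step (MCTS) at a
time:

* **Cellular Potts model (CPM).**  Endothelial cells are pixel domains on a
  square lattice evolving by Metropolis-accepted pixel-copy attempts,
  `P = exp(-ΔH/T)` for `ΔH > 0` and 1 otherwise, with `T = 4`.  The
  Hamiltonian penalizes deviations of each cell's area, perimeter and
  inertia-tensor length from targets,

  `H = Σ ρ_area((a−A)/A)² + Σ ρ_per((p−P)/P)² + Σ ρ_len((l−L)/L)² + Σ ρ_adh(τ,τ′)(1−δ_σσ′) + H_durot + H_chem`,

  where the cell length is `l = 2a` with `a = 2√λ_max` of the per-unit-area
  inertia tensor.  Chemotaxis contributes
  `ΔH_chem = −ρ_chem (C(x′)−C(x)) / (1 + α_chem C(x))` per flip.
* **Substrate mechanics and durotaxis.**  Cells pull their lattice nodes
  toward their node centroid (`f_k = μ_force Σ_j (X_j − X_k)`); the clamped
  plane-stress Navier equations `Ku = f` (E = 10 kPa, ν = 0.45) are solved by
  finite elements, yielding per-pixel principal strains `ε₁, ε₂` and
  directions `v₁, v₂`.  Extensions along strain-stiffened directions are
  rewarded: `ΔH_durot = −ρ_durot g [h(E(ε₁))(v₁·d̂)² + h(E(ε₂))(v₂·d̂)²]`
  with the sigmoid `h(E) = 1/(1+e^{−ω(E−E_θ)})` and
  `E(ε) = E₀(1 + (ε/ε_st)·1_{ε≥0})`.
* **VEGF reaction–diffusion.**  `∂C/∂t = D_f ∇²C − νC − G(C)` with `C = 0` on
  the vessel side, `C = S` on the hypoxic side, a linear ramp on the
  transverse edges, and Michaelis-style cellular uptake
  `G = min(υC, Γ)` inside cells.
* **Notch–Delta-4–Jagged-1 signaling.**  Each cell integrates six ODEs for
  Notch, Delta-4, Jagged-1, NICD, VEGFR2 and internalized VEGF with shifted
  Hill gates `H^S = H⁻ + λ H⁺`, cis-inhibition (k_C) and perimeter-weighted
  trans-activation (k_T, `X_ext(i) = Σ_j P_ij X_j / P_i`).  A cell whose
  internal VEGF exceeds all touching neighbors' and half the population
  maximum becomes a **tip** cell (motile, leads sprouts); cells between 0.2
  and 0.5 of the maximum are **hybrid** tip/stalk; the rest are **stalk**.

Tip and hybrid cells can seed new vessels along the average principal-strain
direction of the bordering matrix when it roughly aligns with the VEGF
gradient; new branches incubate for 400 MCTS with persistent motion.  One
stalk cell per active sprout grows to double area and divides by a balanced
2-means split of its pixels; colliding sprouts anastomose (one vessel is
inactivated); sprouts that detach from their parent vessel by more than a
cell diameter are reconnected with a fresh stalk cell.  Case (A) dynamics
makes stalk cells non-motile; case (B) gives every cell durotaxis and a
Delta-weighted chemotactic coupling `ρ_chem = ρ⁰_chem D_i / max_k D_k`.

## Worked example

```bash
angiocpm run --seed 7 --mcts 300 --out demo_out
# finished 300 MCTS: 94 cells, 15 tips, 29 sprouts, phi=0.0%
```

This runs case (A) dynamics on the reduced 100×100-pixel domain (0.25 mm,
h = 2.5 µm, 33 initial cells in a one-cell-wide primary vessel at x = 0).
After 300 MCTS (13.2 simulated hours at the calibrated 0.044 h/MCTS) the
population has grown to 94 cells, 15 of which are tip cells, with 29 sprout
vessels active; `phi`, the percentage of the hypoxic column at x = L already
occupied by vessels, is still zero because the front (mean tip abscissa
129 µm in `demo_out/metrics.csv`) has covered about half the domain.
`demo_out/` also holds the per-MCTS metrics table, the branching / division /
anastomosis event log (TSV) and periodic lattice snapshots (`.npz` + per-cell
CSV).

The library surface mirrors the model: `angiocpm.lattice` (CPM energies and
sweeps), `angiocpm.mechanics` (FEM, strains, durotaxis), `angiocpm.vegf`,
`angiocpm.signaling`, `angiocpm.events` and `angiocpm.orchestrator`
(`Simulation`, `mcts_calibration`, metrics).

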