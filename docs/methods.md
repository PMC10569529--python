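# Methods

## Model

`cdc42polarity` simulates the yeast mating-polarity machinery as point
particles undergoing Brownian dynamics and stochastic reactions, in two
geometries:

* **plane2d** — a periodic square of side L = 8.8623 um whose area equals
  the membrane area of the cell (A_m = 78.540 um^2).  Membrane and
  "cytosolic" species share the plane and differ only in diffusion
  coefficient (D_m = 0.0025 um^2/s for membrane proteins, 0.0001 um^2/s
  for receptors, D_c = 15 um^2/s for cytosolic pools).
* **sphere3d** — a sphere of radius R = 2.5 um; membrane species diffuse
  on the surface, cytosolic species inside the ball (reflecting at the
  membrane), pheromone outside (reflecting at cell membranes, absorbed at
  a 7-um shell).

Positions advance by the Euler–Maruyama rule with per-axis increments of
standard deviation sqrt(2 D dt), dt = 1e-4 s.  First-order reactions fire
with probability 1 − exp(−k dt); second-order reactions fire with
probability 1 − exp(−λ dt) when the partners lie within the reactive
radius ρ = 0.05 um (minimum-image distance on the torus, Euclidean chord
on the sphere).  Dissociation products are separated by ρ + 1e-5 um to
avoid immediate re-association.  Within one step the order is: diffusion,
then first-order channels, then bimolecular channels; each particle
participates in at most one reaction per step, and bimolecular candidates
are visited in list (storage) order.

Four circuit variants are assembled from the shipped YAML tables
(`cdc42polarity/tables/`), which are the single source of truth for all
rate constants:

* **core** — Cdc42 membrane/cytosol cycling (k_5a/k_5b), Bem1-GEF
  cycling (k_1a/k_1b), GEF-mediated activation (λ_2a, λ_3), complex
  formation (λ_4a, λ_7, k_4b) and GTP hydrolysis (k_2b).  Mutual
  recruitment of active Cdc42 and Bem1-GEF is the fast positive feedback.
* **receptor_far1** — constitutively active surface receptors recruit
  cytosolic Far1-GEF (λ_8a/k_8b); the receptor–GEF complex activates
  Cdc42 (λ_2c); active Cdc42 recruits cytosolic receptors to the membrane
  (λ_9, an abstraction of actin-cable delivery); endocytosis removes
  surface receptors and receptor–GEF complexes at the shared rate k_10 =
  0.002 s^-1 (membrane residence ≈ 8.3 min).  This is the slow positive
  feedback.
* **combined** — the union of the two.
* **combined_pheromone** (3D only) — receptors must bind an explicit (or
  frozen-field) pheromone molecule to become active (λ_11, k_13, k_14,
  k_15, λ_12); λ_11 = 1.8 s^-1 within ρ gives an equilibrium dissociation
  constant K_D = k_13 / (λ_11 · (2/3)πρ^3 · N_A) ≈ 7 nM.

Both rate columns (2D and 3D) are stored verbatim.  The 2D→3D conversion
rules — k_3D = (V_c/A_m) k_2D for cytosol→membrane association and
λ_3D = (V_c/A_m)(πρ²)/((2/3)πρ³) λ_2D for cytosol/membrane pairs (the
half-sphere reaction volume reflects the membrane-bound partner) — are
used to validate the tables, not to populate them, because the
membrane–membrane binding rate λ_4a (9.6 s^-1 in 2D, 40 s^-1 in 3D) was
tuned rather than derived.

The shared internalization rate k_10 is interpreted as two first-order
channels sharing k_10: free active receptor → cytosolic receptor, and
receptor–GEF complex → cytosolic receptor + cytosolic Far1-GEF.

**3D surface association.**  The 3D association rates are given in um/s.
Because the cytosol (D_c = 15 um^2/s) mixes across the cell in ~1 s —
fast compared with every association timescale — association is
implemented as a first-order conversion at the equivalent well-mixed rate
k_3D·A_m/V_c with the product projected radially onto the sphere.  This
reproduces the correct well-mixed association flux by construction and
makes the 2D and 3D circuits agree species-by-species (verified in the
calibration test).

## Numerical scheme and performance choices

* **Block updates for slow species.**  Species with D ≤ 0.0025 um^2/s
  move every M steps with exact Gaussian increments of variance 2 D M dt,
  with M chosen so the rms move per update is at most ρ/10 = 5 nm
  (M = 50 for membrane proteins, capped at 100 for receptors).  The
  marginal displacement law is exact; the only approximation is freezing
  sub-5-nm jiggle between updates, small against the 50-nm reaction
  radius and against the relative motion contributed by fast partners.
  Cytosolic and extracellular species move every step (their single-step
  displacement already exceeds ρ).
* **Aggregated first-order sampling.**  The number of firings of a
  first-order channel per step is drawn as Binomial(n, p) (geometric-skip
  sampler); firing molecules are drawn uniformly from the species list.
  This is distribution-identical to per-particle Bernoulli trials.
* **Candidate thinning with compound firing for bimolecular channels.**
  For channels with small per-step pair probability p, each candidate on
  the iterated side is tested with probability α = min(1, 20p); a tested
  candidate with k partners inside ρ fires with probability
  (1 − (1−p)^k)/α and the partner is drawn uniformly among the k.  The
  per-candidate compound firing probability — and hence the reaction flux
  at any local density — is preserved exactly (the compensated
  probability saturates only beyond ~25 simultaneous in-range partners).
  Naive per-pair thinning is *not* used: it deflates compound rates at
  high local density, which measurably brakes cluster nucleation.
* **Neighbor search.**  Membrane-bound species live in an incrementally
  updated uniform cell grid (cell ≥ ρ; ~2ρ on the sphere to keep the grid
  cache-resident).  Every bimolecular channel in these circuits has at
  least one membrane reactant, so reactions iterate the non-membrane (or
  rarer) side and look partners up in the grid; the ±1-cell neighbourhood
  covers the reaction radius exactly.
* **Random numbers.**  Gaussian increments come from a pregenerated
  PCG64 float32 buffer; discrete decisions use the kernel's own generator,
  seeded once per run from the user seed.  Runs are reproducible for a
  fixed seed on a given platform.
* **Conservation checks.**  Totals of the Cdc42, Bem1-GEF, Far1-GEF and
  receptor conservation groups are asserted at every recorded snapshot.

## Quantification

* **Polarity (normalized Ripley K).**  From the cumulative distribution
  CDF(r) of pairwise distances (ordered pairs, 1/(N(N−1)) normalization):
  on the plane K(r) = sqrt(A/π · CDF(r)) − r; on the sphere (geodesic
  distances) K(r) = 4πR²·CDF(r) − 2πR²(1 − cos(r/R)).  The scalar K is
  the maximum over r (grid: 200 bins up to L/2, respectively πR).  The
  plane formula is sometimes written without the square root; applied
  literally that form gives r² − r, not 0, for a uniform pattern, so the
  square-root normalization — which does vanish for uniform patterns and
  gives the point-mass limit sqrt(A/π) = 5.0 — is the default, with the
  literal form available behind `literal_2d_form`.  Thresholds: 2D
  K ≥ 1.5 polarized, K ≥ 3 stable; 3D K ≥ 30 polarized, K ≥ 50 stable.
* **Regimes.**  Per run, Δ = F(K ≥ 1.5) − F(K < 1.5) over recorded
  samples; a condition is transient when |Δ/N| ≤ α = 0.85.  Δ(x) along a
  Bem1-GEF abundance scan is fitted with 2N/(1+e^{−b(x−c)}) − N; regime
  boundaries sit at x = c ± ln((1+α)/(1−α))/b.
* **Clusters.**  Voronoi polygons of active-Cdc42 positions (periodic
  tessellation via ghost-point tiling in 2D, spherical Voronoi in 3D);
  the polygon-size threshold is the intersection of the polygon-size
  densities of the data and of 50 matched uniform controls; adjacent
  below-threshold polygons form candidate clusters, filtered by total
  area ≤ 0.785 um² (a ~1-um site; the bound's direction is configurable)
  and by a minimum molecule count of 20 — a package default chosen to
  suppress singleton noise, not a published value.  Cluster-count series
  yield 0/1/2+ state occupancies, transition matrices and dwell times,
  with optional resampling to the 120-s experimental scoring interval.
* **Pheromone.**  Point-source emission is Poisson at the stated rate
  from the emitter-cell surface point facing the receiver (emitter:
  5-um-diameter sphere, 0.05-um gap); uniform baths keep a fixed molecule
  number (c·N_A·V) with re-injection on consumption.  Ring profiles
  average concentrations in a 0.1-um sampling shell over 36 equal-width
  polar-angle rings (ring geometry is configurable; these defaults
  resolve the steep near-pole part of the gradient while keeping counting
  error acceptable).  A measured profile can be frozen into a per-ring
  receptor-activation rate λ_11·(2/3)πρ³·c(θ), replacing explicit
  pheromone in scaled-down runs (flagged as an approximation).

## Desk-scale protocol

The full study protocol (4000-s trajectories, 5–30 replicates per
condition, 50-min 3D gradient runs) is available through
`experiments.preset(...)`; the package's default tests and the acceptance
script run a desk-scale protocol chosen once as:

* core-circuit regimes: 160–180-s runs, dual initial conditions (uniform
  and a pre-polarized σ = 0.2 cluster) at 70/102/120 Bem1-GEF, Δ computed
  over each run's late window.  At this scale the unpolarized condition
  shows dissipation of a pre-formed cluster within ~80 s and the transient
  condition keeps both states alive through the window.  In the polarized
  condition the pre-formed site is held without interruption (Δ/N = +1);
  spontaneous nucleation from uniform initial conditions has a measured
  waiting time of roughly 500 s at 120 Bem1-GEF and is therefore part of
  the full-scale protocol (4000-s presets), not of the desk-scale suite.
* combined circuit: 150-s runs for dissipation (pre-polarized Cdc42 +
  uniform receptors), stabilization (clustered receptors) and coexisting
  transient clusters (uniform).
* gradient stabilization: ring profiles measured from 25-s two-cell
  pheromone simulations; frozen-field 100-s receiver runs with receptors
  initialized at their local binding equilibrium k_on(θ)/(k_on(θ)+k_off)
  — emulating a cell already exposed to the gradient for several binding
  relaxation times (τ ≈ 250 s, which a 100-s run cannot traverse) — and
  stabilization scored as the first K ≥ 30 crossing.  Under the
  low-background gradient the site forms at the source-facing pole within
  ~1 min; under the 1.5-nM-background gradient distributed receptor
  activation keeps seeding competing clusters and stabilization does not
  occur within the window, reproducing the background-competition
  mechanism at reduced scale.
* receptor affinity: equilibrium occupancy measured with λ_11 and k_13
  jointly scaled ×100 (their ratio, hence K_D, is invariant) so that
  equilibration fits in seconds of simulated time.

## What the synthetic fixtures do and do not emulate

The fixture generators produce uniform and Gaussian-clustered patterns,
immobile Far1-GEF seed layouts and Markov cluster-count series with the
experimental 120-s scoring structure.  They emulate molecule counts and
spatial statistics of simulation snapshots, not microscopy: no pixel
noise, no projection artifacts, no detection threshold of the
experimental scoring.  Tests passing on fixtures therefore validate the
statistics pipeline and the simulator's point patterns, not image
analysis of real movies.

## Known limitations

* No excluded volume, actin cables, vesicle traffic, or explicit G
  proteins (the receptor→Far1 coupling is abstracted, as in the model's
  design).
* Desk-scale runs are far shorter than the relaxation time of receptor
  trafficking (~8 min), so receptor distributions are not at steady state
  in the regime tests; conclusions drawn there are about the fast
  polarity machinery under the stated initial conditions.
* The frozen-field gradient mode removes pheromone-number fluctuations
  and the feedback of receptor binding on the local pheromone field.
* Bimolecular kinetics follow the within-ρ probabilistic rule of the
  underlying scheme; effective rates are validated against a well-mixed
  mass-action oracle (λπρ²/A per pair) at the few-percent level, not
  against diffusion-influenced rate theory.
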