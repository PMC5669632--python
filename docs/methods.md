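# Methods

This note records the models implemented in `permeon`, the defaults and
why, what the synthetic machinery does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Reaction coordinates and landscapes

Permeation through a K⁺ selectivity filter is reduced to the pore-axis
coordinates Z₁₂ (center of mass of the two outermost ions, relative to the
filter's center of mass) and Z₃ (the innermost ion). All free energies are
in kcal/mol, lengths in Å, times in ps; kB is fixed at 0.0019872041
kcal·mol⁻¹·K⁻¹ and the reference temperature is 323.25 K (kT ≈ 0.642).

The sampling targets are analytic surfaces rather than molecular systems:

* `harmonic` — separable quadratic (k = 0 gives a flat landscape);
* `double_well` — `U = h((z−c)²/a² − 1)²`, wells at c ± a, barrier exactly
  h. The 6 kcal/mol default is the closed-filter regime (deep wells, no
  conduction); 2–3 kcal/mol is the open regime;
* `permeation_map` — a 2D chain of wells along a valley direction joined by
  C¹ cosine saddles whose peaks sit exactly `barrier` above the higher
  adjacent well, plus transverse confinement (harmonic, or a flat-bottomed
  cosine channel with a plateau); the default three-well chain mimics the
  topology of a two-saddle occupancy cycle (e.g. S1-S3-Cav → S0-S2-S4 →
  release) without pretending atomic realism;
* `gated_ridge` — a cosine ridge across the domain, optionally fading out
  along the other axis, giving maps whose sub-threshold region is split or
  connected through a gap.

Exact barrier heights are by construction: the transverse term vanishes on
the valley line and is non-negative elsewhere, so the minimax path between
wells runs along the valley and its maximum is the designed peak. The
exact gridded reference `boltzmann_pmf` is `U(bin center) − min U`; on
these reaction-coordinate-space surfaces no marginalization is involved.

## Brownian sampler

The MD engine is replaced by overdamped Euler–Maruyama dynamics

    z ← z − (D/kT)·∇(U+w)·dt + sqrt(2·D·dt)·ξ,

with reflecting walls at the domain edge. Only the stationary distribution
matters for free-energy recovery, so inertia is dropped. Defaults: D = 0.5
Å²/ps (a toy value of the order of an aqueous ion's diffusivity), dt =
0.002 ps, sampling every 0.1 ps — one to two relaxation times of a
coordinate held by the default 20 kcal·mol⁻¹·Å⁻² bias, so recorded samples
are approximately independent, which is what the downstream histogram
estimators assume. A domain scan refuses timesteps whose drift step would
exceed 0.5 Å anywhere. Trajectories are bit-reproducible for a fixed seed,
and a batch of windows integrated together is bit-identical to the same
windows integrated singly (each window owns its RNG stream).

Unadjusted Euler–Maruyama carries an O(a·dt) stationary-density error,
with a = D·U''/kT the local relaxation rate. On soft 1D landscapes (a·dt ≈
0.03) this is ~1% of kT and invisible; against the stiff confining walls
of the 2D maps (U'' up to ≈ 80 kcal·mol⁻¹·Å⁻², a·dt ≈ 0.3) it flattens
wall bins by several tenths of kcal/mol at any affordable timestep. The
sampler therefore has a `metropolis` option — a Metropolis-adjusted
Langevin step (accept/reject with the Boltzmann × proposal-density ratio;
proposals outside the domain are rejected) that makes the sampled
distribution exactly Boltzmann at any timestep for roughly twice the cost
per step. The 2D studies in the test suite enable it; the plain integrator
remains the default.

Sample timestamps start at t = 0 with the starting configuration, so a
600 ps window sampled every 1 ps holds 600 rows, retains exactly 500 after
the 100 ps equilibration discard, and splits into exactly five 100 ps
error-analysis slices.

## WHAM

Windows are histogrammed on a shared grid (0.1 Å default spacing,
half-open bins, edge samples to the upper bin) and unbiased by the
standard self-consistent equations with the bias evaluated at bin centers
(its variation within a 0.1 Å bin is negligible). All exponentials live in
log space. Bins with zero total counts never enter any normalization and
are reported as NaN with a false mask; the solution is referenced to zero
at the sampled minimum and anchored at f₀ = 0. Window sets whose
histograms split into non-overlapping groups raise a disconnected-sampling
error listing the groups.

Convergence is declared when the largest offset change in one
self-consistent sweep falls below 10⁻⁷ kcal/mol (well under thermal
noise); the plain iteration can need thousands of O(W×B) sweeps on 2D
problems, so the default solver first minimizes the equivalent convex
likelihood Φ(g) = Σ_b M_b ln Σ_i N_i e^{g_i − w_i(b)/kT} − Σ_i N_i g_i
with L-BFGS (analytic gradient; Φ's stationary point is exactly the WHAM
fixed point and Φ is invariant under a uniform shift of g) and then
polishes with the self-consistent iteration, so convergence is always
certified by the fixed-point residual itself. `method="iteration"` gives
the plain fixed point.

Accuracy expectations, measured against the exact surface: thirteen
600 ps-scale windows spanning a k = 1.2 harmonic well, or twenty-one
windows across the 6 kcal/mol double well, with 5×10⁴ retained samples
each, reproduce the profile with RMS ≈ 0.03 kcal/mol over bins below
6 kcal/mol. Window centers must span the region being compared: bins
beyond the outermost centers are reached only by >3σ bias tails and their
statistical noise alone can exceed 0.1 kcal/mol.

## Adaptive window placement

Windows live on a lattice (0.5 Å default) anchored at the seed. Each round
simulates the newly proposed windows (new windows start from the retained
sample, over all completed neighbor windows, closest to the new center;
ties resolve to the lowest window index, then the earliest sample),
re-solves WHAM over all windows warm-started from the previous offsets,
and proposes the not-yet-simulated lattice neighbors (8-connected by
default, so diagonal valleys are followed without staircase artifacts)
whose estimated free energy is below the creation limit (12 kcal/mol
default). The estimate is multilinear interpolation of the current PMF at
the candidate center; where that is undefined, the minimum defined free
energy among bins lying within half a lattice spacing of the candidate —
counting a bin as "within" if any point of its cell is, since lattice
nodes sit on bin corners and a center-to-center metric would exclude the
entire ring of adjacent bins. A candidate with no defined bin that close
is deferred: the frontier only steps onto nodes it has evidence about,
which is what keeps the explored set equal to the sub-limit region
reachable through sub-limit corridors. The loop terminates when a round
proposes nothing (window count strictly grows per round and the lattice is
finite), and the whole run is reproducible from one master seed.

## PMF post-processing

* **Combination** of independent runs is one WHAM solve over the pooled
  windows — the same logic that merges forward and backward perturbation
  runs — never an average of per-run PMFs; re-splitting a run reproduces
  the unsplit PMF bit for bit. Error bars are reported per run only; a
  statistical error for the combined map is not defined here.
* **Interval error**: the post-equilibration sampling of every window is
  cut into disjoint consecutive 100 ps slices (600 ps windows minus 100 ps
  equilibration give exactly five); each slice is re-solved, offset onto
  the final PMF by the closed-form least-squares constant c* =
  mean_mask(F_final − F_int) over bins with final F < 6 kcal/mol, and the
  per-bin standard deviation over the last five aligned interval PMFs is
  the error map. Slices are per-window and re-solved jointly. An interval
  that leaves mask bins unsampled is an error naming the interval.
* **States** are strict minima over the 8-neighborhood among defined bins
  below a threshold, merged within a radius to the lower minimum; labels
  are free text (occupancy names like "S0-S2-S4" are supplied by the
  analyst, not inferred).
* **Barriers** are read as minimax (widest) paths: modified Dijkstra over
  the 8-connected defined bins minimizing the maximum bin value; the
  barrier is that maximum minus F at the start. This matches reading a
  single saddle height off a map, not an integrated action.
* **Occupancy/permeation**: explicit site cutoffs (strictly decreasing
  along the pore axis) classify each ion per frame; a permeation event
  requires the full crossing, in order, of the cavity's intracellular
  cutoff and S0's extracellular cutoff (hysteresis), so oscillations
  across internal boundaries count nothing.

## Gating models and fits

The Hill equation and the two-sensor concerted (MWC-type) model are as in
the README; the subunit exponent is fixed at 4 (homotetramer), and an
absent sensor contributes a factor of exactly 1 (numerically exact,
matching how sensor-deletion mutants are tabulated). Both curves are
evaluated via log1p/logaddexp identities; agreement with an
extended-precision direct evaluation is at the 10⁻¹² relative level across
pH 0–14 and L₀ from 10⁻¹⁵ to 10³.

Fits are unweighted nonlinear least squares on the per-pH mean open
probabilities (sem is stored, and available as weights, but the reference
fits are reported at per-point level of detail only), with asymptotic
standard errors from the Jacobian at the optimum, reported only for free
parameters. L₀ is optimized as log₁₀L₀ (it spans twelve decades across
constructs) with the linear-scale error recovered by the delta method —
the convention in which such equilibrium constants are tabulated. The
physical ordering pKa_closed ≤ pKa_open is a bound: when only pKa_closed
is free it is a simple upper bound; when both pKas of a sensor are free
the fit parametrizes closed = open − δ with δ ≥ 0 and propagates the
closed-state error through the covariance. Bounds that end active are
reported, and the two-stage workflow mirrors the analysis of
sensor-uncoupling mutants: stage 1 frees L₀ and pKa_closed; if the bound
binds, stage 2 pins pKa_closed = pKa_open and refits L₀ alone.

The Hill summary of a concerted curve evaluates it on pH 4.0–6.5 in 0.05
steps — the experimental dose-response range plus its upper shoulder — and
fits with Pomax free. Two caveats, both visible in the test suite and left
uncosmeticized:

* the *ideal* two-sensor control-channel curve is intrinsically steeper
  (local logit slope ≈ 5.3 at the midpoint) than the Hill coefficient
  fitted to the noisy recordings (~4.4–4.5); Hill summaries of ideal
  curves therefore reproduce every half-activation point to ≲0.05 pH
  units, but overestimate n_H by ~0.3–0.9 relative to the published
  experimental Hill fits;
* three-parameter recovery fits (L₀ plus both pKas of a sensor) have a
  curved likelihood ridge coupling L₀ and pKa_open along which linearized
  standard errors undercover: a 200-dataset Monte-Carlo study at bilayer
  noise (5 replicates, sd 0.05) measures ~89–90% coverage at the nominal
  3σ level for L₀ in that scenario, against ≥98% for every single-free-
  parameter scenario.

## Synthetic data: what it does and does not emulate

The Brownian sampler emulates biased Boltzmann sampling on known surfaces —
it validates the estimators (WHAM, adaptive placement, error maps, barrier
reading), not force fields, solvation or kinetics; passing tests say
nothing about the realism of any molecular model. The Po generator draws
replicate "bilayers" as truncated-normal noise (sd 0.05, clipped to [0,1],
5 replicates per pH on pH 4.0–6.5 every 0.25) around a concerted-model
curve; real bilayer scatter is neither Gaussian nor pH-independent, so the
coverage study calibrates the fitting machinery, not the recordings. Test
problem sizes (5×10³–5×10⁴ retained samples per window, 305–600 ps nominal
windows, three 2D map topologies × three seeds) were chosen as the
smallest at which the estimators' statistical error sits comfortably below
the quantities being asserted.

## Known limitations

No autocorrelation-based decorrelation or binless estimator (an
independent MBAR implementation is used as a cross-check in the tests
only); grids are limited to 1D/2D; no kinetic (rate or dwell-time)
modeling on either side of the package; the adaptive frontier assumes the
creation limit separates cleanly from node free energies — maps whose
nodes sit within the sampling noise of the limit will explore
non-deterministically near the boundary.
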