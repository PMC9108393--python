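# Methods

## The model

`chemofit` models immune-cell infiltration across the top two channels of a
three-lane microfluidic chip as a one-dimensional Keller–Segel-type system.
Space is nondimensionalised so the basal (seeding) interface sits at x = 0,
the matrix/epithelium interface at x = x_t, and the far side of the
epithelial channel at x = 1; time is in hours. Two fields evolve: the PBMC
density ρ(x,t) (cells per unit nondimensional length, so ∫ρ dx is a cell
count) and a generic chemoattractant concentration α(x,t):

    ∂ρ/∂t = ∂x(D_ρ ∂x ρ) − ∂x(χ(x,α) ρ ∂x α) − ξρ
    ∂α/∂t = ∂x(D_α ∂x α) + η₁·1{x≤x_t} + η₂ρ·1{x≥x_t} − κρα − να

Model assumptions, in the package's reading of the assay:

* Resident macrophages are not modelled explicitly; their pro-inflammatory
  stimulus is a uniform cytokine production η₁ throughout the matrix
  channel. Likewise epithelial cells are not modelled; drug–target
  engagement by infiltrated cells releases cytokine at rate η₂ per unit
  PBMC density in the epithelial channel (η₂ = 0 for a non-targeting
  control compound).
* Chemotactic sensitivity follows the receptor law
  χ(x,α) = χ̃(x)·k/(k+α)²: at concentrations well above k, cells can no
  longer resolve the gradient and the response shuts down.
* Cells move and cytokines diffuse more freely through the matrix than the
  epithelium: D_ρ, D_α and χ̃ are piecewise constant, divided by μ_ρ
  (cells/chemotaxis) and μ_α (cytokine) beyond x_t.
* A linear sink ξρ accounts for cells drifting sideways out of the imaged
  region; it acts on the whole domain (the governing equation carries no
  channel indicator).
* Boundary conditions: no flux of either species at x = 1. At x = 0 the
  cytokine obeys a Robin outflux ∂x α = ζα, and the PBMC influx is the
  chemotactic flux drawn from a constant reservoir density ρ̃ in the basal
  channel, which with the Robin condition collapses to
  influx = χ(0,α₀)·ζ·α₀·ρ̃ — so count data constrain (approximately) only
  the product ζρ̃.
* Initial state: ρ = 0 and α at the steady profile maintained by
  macrophage production before any cells have entered.

## Discretisation

Uniform cell-centred finite volumes (default n = 200) with x_t snapped onto
the nearest interior face, so no cell straddles the coefficient jump.
Diffusive face fluxes use the harmonic mean of the adjacent cell
coefficients (exact for a piecewise-constant discontinuity at a face).
Chemotaxis is treated as advection with face velocity χ·∂x α (central
difference of α, face values of χ̃ by harmonic mean) and first-order
upwinding of ρ, which keeps both fields nonnegative. The Robin boundary
value is reconstructed one-sidedly, α_face = α_cell/(1 + ζh/2), preserving
second-order convergence; the observed order against the closed-form
cytokine steady state is ≈ 1.98.

Production supports are assigned by cell centre (η₁ for centres < x_t, η₂ρ
for centres > x_t); the closed/closed overlap of the two indicators at
exactly x_t has measure zero in the continuum and no ambiguous cell in the
discretisation.

Time integration is method-of-lines with LSODA (adaptive, stiff-capable),
rtol 10⁻⁶ / atol 10⁻⁹, on an interleaved state vector so the Jacobian is
banded (bandwidth 3). Undershoots below zero are floored at 0 up to 10⁻⁶
(beyond that the run is declared failed). The cytokine steady state used as
the initial condition is solved as a banded linear system on the same
stencil, so its discrete time derivative vanishes identically; the
combination ν = ζ = 0 with η₁ > 0 has no steady state and is rejected.

## Quantification

Watershed segmentation occasionally merges touching cells, so a region of
area A μm² counts as max(1, round_half_up(A/50)) cells — 50 μm² being a
generous single-PBMC area (diameter < 10 μm), which forces any region above
75 μm² to count as at least two. Half-up rounding makes the 75 μm² boundary
itself round up. Spatial distributions are summarised on 20 equal-width
bins over the region of interest, half-open [a, b) with the last bin
closed. Distance travelled is the recorded position coordinate, and
multi-cell regions enter distance statistics weighted by their declumped
count.

The region-of-interest length is a required configuration value (it is set
by the imaging crop, not by the assay); the default is 700 μm, placing the
350 μm interface at x_t = 0.5 — equal-width matrix and epithelial
channels, plausible for the three-lane chip, and on a grid face for any
even cell count.

## Calibration

The expected count in data bin b at time t is the raw integral of ρ over
the bin (partial finite-volume cells weighted by overlap); no separate
amplitude parameter is introduced, since ρ̃ already carries the overall
scale. The objective is the unweighted sum of squared differences between
observed and expected counts over all time points and bins. Scale
parameters (motilities, rates, k, ρ̃, μ's) are fitted in log₁₀ space;
x_t and ζ linearly. Failed simulations return a large finite penalty
(10³ × the objective of the all-zero prediction) so the surrogate
optimiser keeps a finite, pessimistic picture of infeasible regions.
Experiments are fitted one at a time; there is no joint multi-experiment
likelihood.

## Surrogate optimiser

An efficient-global-optimisation workflow for the expensive PDE objective:
Latin-hypercube initial design (10·d points), an anisotropic Matérn-5/2
Gaussian process with constant trend fitted to log₁₀ objective values
(marginal-likelihood maximisation, 5 restarts, automatic nugget escalation
on ill-conditioning), and batches of q = 4 proposals per iteration from
distinct criteria: maximum expected improvement (maximised by differential
evolution: rand/1/bin, population 15·d, F = 0.8, CR = 0.9, ≤ 100
generations), minimum predictive mean, maximum predictive standard
deviation, then constant-liar EI repeats. Candidates within 10⁻³ of an
existing point are replaced by a random draw. After 5 consecutive batches
with relative improvement < 10⁻³ the search box is recentred on the
incumbent and shrunk by half (at most 4 times); termination on budget
exhaustion or max EI < 10⁻⁶·|incumbent|. All randomness derives from one
seed, making runs bit-reproducible.

On benchmarks, the optimiser reaches ≤ 10⁻⁴ on a 4-D convex quadratic
within 120 evaluations for 10/10 seeds and locates the deeper of two 2-D
Gaussian wells within 0.02 for 9/10 seeds at budget 80.

## Synthetic studies

The generator emulates the assay's exported particle tables: 8 control +
8 cytotoxic experiments, imaged every 2 h to 48 h. Per (time, bin) a count
is drawn Poisson around the model's expected bin count at the condition's
ground-truth parameters (or the rounded mean in noise-free mode), positions
are uniform within the bin, and region areas come from a lognormal
singleton distribution (median 40 μm², σ_log 0.25) with cells merging into
clumps with probability 0.1. Areas are made *count-consistent*: singleton
draws are truncated below 75 μm² and clump areas (sums of member draws) are
resampled until they declump back to the member count, so declumping
exactly inverts clumping and binned counts are unbiased. Counts are drawn
independently across frames — real cells persist between images, so the
generator reproduces frame-wise count statistics but not track-level
statistics; this is adequate because only binned counts enter the fitting
objective. Passing tests on this data therefore validate the counting,
fitting and analysis machinery, not the image segmentation upstream or
temporal correlations in real recordings.

### Ground-truth parameters

The default fixture was chosen once to reproduce the qualitative phases
observed on chip, and exploring the model made three structural trade-offs
explicit:

* **Interface accumulation requires a non-degrading attractant.** For any
  ν > 0 the epithelial channel is a perpetual cytokine sink, which pulls
  the α maximum into the matrix interior and with it the cell pile. With
  ν = 0 (removal by boundary outflux and uptake only) the steady profile
  is a parabola peaking exactly at x_t, the gradient stays nonnegative up
  to the interface, and cells accumulate against it.
* **A near-impermeable epithelium.** Because the sink ξ acts everywhere,
  the epithelial channel steadily drains the interface pile by diffusion;
  a strict density maximum in the last matrix cell requires μ_ρ ~ 10³ —
  consistent with the observation that cells cluster at the interface and
  do not measurably penetrate the epithelial barrier.
* **Receptor-law headroom for the cytotoxic contrast.** The boundary influx
  scale k·α₀/(k+α₀)² peaks at α₀ = k. The cytotoxic condition amplifies
  infiltration through extra cytokine raising α₀, so the control must
  operate well below saturation (α₀/k ≈ 0.1 here, giving a ≈ 2.5×
  amplification); conversely, the strong reciprocal ρ̃–ζ invariance is a
  saturated-boundary phenomenon (α₀ ≈ k), where the influx is stationary
  along ζρ̃ = const. The two regimes cannot coexist at one operating
  point, so the default fixture takes the unsaturated regime — the
  best-fitting ζ per ρ̃ row is still monotonically nonincreasing there —
  and the strong-invariance property is demonstrated at a small-ζ
  (saturated) operating point.

The fixture (`control_params()`): D̄_ρ = 2·10⁻³, D̄_α = 0.05, χ̄ = 2,
μ_ρ = 1000, μ_α = 2, ξ = 0.08 h⁻¹, η₁ = 0.05, κ = 0, ν = 0, k = 10,
ζ = 0.5, ρ̃ = 100, x_t = 0.5; the cytotoxic condition adds η₂ = 0.02.
This yields ≈ 101 infiltrated cells at 48 h in control (counts of order
10² per experiment), saturation (< 0.4 % change per 2 h frame at 48 h),
the leading 0.1 % of cell mass crossing the interface at ≈ 12 h, a strict
late-time density maximum in the interface-adjacent cell, and a cytotoxic
amplification of ≈ 2.5× that emerges only after interface arrival.

## Numerical and design notes

* Objective scans store raw sums of squares; log₁₀ with a 10⁻¹² floor is
  applied only for display. Row-wise ridge minimisers break ties toward
  the largest value (the upper envelope of a flat minimising set), which
  makes degenerate rows (e.g. ρ̃ = 0, where ζ has no effect) behave
  continuously with their neighbours.
* Residual maps use the convention data − model (negative = model
  overestimates) and aggregate across experiments by raw summation, as do
  condition-difference surfaces.
* Problem sizes in the test-suite and the acceptance script (grids of
  100–200 cells, fit budgets of 120–200 evaluations, 10-seed benchmark
  repeats, Monte-Carlo checks at 200–500 replicates) were chosen as the
  smallest sizes at which each property is comfortably resolved.

## Limitations

* One spatial dimension; no explicit epithelial-cell or apoptosis
  dynamics, so the cytotoxic condition's feedback is a lumped η₂ρ source.
* The synthetic generator cannot emulate cell-track statistics or
  segmentation artefacts beyond area clumping.
* With count data alone, ζ and ρ̃ (and more broadly the cytokine-side
  parameters) are practically unidentifiable; fits should be read through
  identifiable combinations such as ζρ̃.
* The Kriging surrogate assumes a deterministic objective; counting noise
  enters the fit only through the data, and no noisy-Kriging
  (re-interpolation) variant is provided.
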