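# Methods

## Models

Cell density C(x, t) (cells/µm) on a closed 1-D chamber [0, l] follows an
advection–diffusion–reaction PDE; the attractant concentration A(x, t) is
depleted by the cells in proportion to local density and remaining
attractant, and diffuses with constant D_A. The six candidate models share
this skeleton and differ only in the advection coefficient (see README for
the table). Two algebraic placements were genuinely open and were fixed as
package design choices:

- The density-interaction term is damped multiplicatively,
  η(t)/(1 + λC) ∂C/∂x. The damping grows with C and disappears at λ = 0 or
  C → 0, mimicking saturation of the receptors for the cell-released
  interaction chemical.
- In the full model the volume-filling factor (1 − C/C_max) multiplies the
  attractant-response term only, not the interaction term: crowding is
  modelled as slowing advection up the occupancy gradient. Every nesting
  relation among the six candidates holds under either choice.

Time-varying parameters α, D_C, γ, η are polynomials in t (hours); α, D_C
and γ are exponentiated so that positivity is automatic and their
coefficients can be optimized unconstrained. η is signed (negative =
repulsion) and stays a plain polynomial.

Units are µm and hours throughout; attractant diffusion coefficients
quoted in µm²/s convert with ×3600 at the configuration boundary.

## Numerics

Space is discretized with a cell-centred, uniform finite-volume grid.
Diffusive interface fluxes are central; advective fluxes are first-order
upwind on the sign of the interface velocity. Upwinding buys robustness in
the advection-dominated regime (grid Péclet |a|dx/D_C > 1, which the
solver reports as a diagnostic) at the price of some numerical diffusion;
the grid-convergence and heat-kernel tests bound that bias. The attractant
gradient entering the velocity is evaluated directly at interfaces
((g(A_i) − g(A_{i−1}))/dx with g the identity or the receptor occupancy
A/(K_d + A)), so the advection operator and the diagnostic
`advection_coefficient` share their stencils.

Boundaries: zero flux everywhere, except an optional prescribed cell
influx across the left boundary (derived from the observed total counts:
flux = dN/dt − νN on a piecewise-linear interpolant of N) deposited into
the first box. The attractant is closed at both ends.

Time integration is LSODA (adaptive, stiff-capable) on the interleaved
state (C_0, A_0, C_1, A_1, ...), which keeps the Jacobian banded
(bandwidth 3) and makes stiff attractant diffusion (D_A up to ~7×10⁵
µm²/h) affordable. Default tolerances are rtol 10⁻⁶ / atol 10⁻⁹; the
desk-scale experiment harnesses use rtol 10⁻⁵ / atol 10⁻⁸, which changes
the weighted log-likelihood by far less than one unit. Integration
failures (step-size collapse, non-finite states) surface as a structured
`SolverFailure` that the inference layer treats as a discarded replicate,
never as a crash. Tiny negative undershoots in C are clipped to zero only
where C enters the likelihood and the depletion term, never in the state
itself, so instability is not masked.

## Likelihood

Each observed coordinate contributes the normalized model density
C(y, t_j)/∫C dx, with linear interpolation between box centres, constant
extrapolation to the domain edges, trapezoid quadrature, and a 10⁻³⁰⁰
floor so a degenerate parameter set yields −∞ log-likelihood rather than
an exception. Because observed cell numbers grow strongly over an assay,
the weighted form ℓ_w = (n/T) Σ_j ℓ_j/n_j gives every time point equal
voice; it equals the plain log-likelihood exactly when counts are
balanced.

## Inference

Free parameters are mapped to unconstrained coordinates (shifted log for
one-sided bounds, scaled logit for two-sided), so bound violations are
impossible by construction; float underflow at extreme coordinates is
clamped to stay strictly inside the open interval. Default bounds follow
the biology: K_d, λ ≥ 0 (unbounded above), C_max bounded below by the
maximum observed density estimate, D_A ≥ 0 or a literature window where
one exists.

The maximum weighted-likelihood fit uses Nelder–Mead by default (BFGS is
available); objective evaluations that fail to solve return a large
penalty so the simplex simply avoids unstable regions. For model
comparison the centre fit is multi-started from dispersed points on the
unconstrained scale (4 starts by default, spread 1.5, best kept and
polished): the surface is multi-modal, and a richer model trapped on the
mode where it merely mimics a poorer nested model (e.g. receptor
saturation with K_d driven large, which collapses to the raw-gradient
model) would spuriously tie the comparison. The bootstrap
pseudo-posterior refits on datasets resampled with replacement within each
time point. Each bootstrap fit starts from the full-data optimum jittered
by 5% multiplicative noise on the unconstrained scale — a cheap,
documented stand-in for a full multi-start protocol that keeps the trap
rate on local optima low. Replicates are keyed by index (seed =
(root_seed, index)), so results are reproducible and independent of
scheduling; failed fits are discarded and fresh replicates drawn up to a
3× budget.

Because the optimizer can still be trapped, the pseudo-posterior may be
multi-modal in achieved likelihood. Pruning operates on the 1-D
distribution of achieved weighted log-likelihoods: a Gaussian KDE is cut
at antimodes whose density falls below 0.8× the smaller neighbouring
peak, and only the cluster containing the global maximum is retained.
Samples whose spread is below one log-likelihood unit pass through
untouched, which also makes pruning idempotent in practice. This
likelihood-space rule is a substitution for an unavailable
parameter-space protocol and is flagged in run metadata.

## Model comparison

WAIC is computed from the pointwise log-likelihood matrix of the pruned
pseudo-posterior evaluated on the *original* data, with the variance-form
penalty (unbiased sample variance) and a numerically stable
log-mean-exp. Its standard error is the standard pointwise form
√(n·var_i w_i) over per-observation contributions w_i = −2(lppd_i − p_i) —
a documented substitution for an unspecified formula, flagged in output.
AICc and BIC use the maximum weighted log-likelihood with n equal to the
total cell count (the likelihood is a sum over cells) and k the number of
free parameters.

Degree selection fits the model at ascending shared polynomial degrees,
warm-starting each degree from the previous optimum and polishing with
simplex restarts until the per-round gain is negligible — without this,
a higher degree can "win" purely through extra optimizer progress. The
search continues only while the richer degree improves *both* AICc and
BIC; requiring both guards against the ~χ²/2 spurious likelihood gain
that extra coefficients always buy, which would otherwise make AICc
improvement a near coin flip under a constant-parameter truth.

The WAIC validation harness cross-checks the bootstrap route on a problem
with an exact answer: polynomial regression with known noise variance,
where the flat-prior posterior of the coefficients is exactly normal.
WAIC per candidate order is computed from (a) bootstrap-refit parameter
sets and (b) exact posterior draws; agreement of selected order and <5%
relative difference per order is the operational definition of "the
pseudo-posterior behaves like the posterior".

## Synthetic assays

The generator forward-solves a chosen truth and draws cell positions at
each observation time by inverse-CDF sampling from the normalized model
density (piecewise-linear on a refined grid), then adds truncated-normal
localization noise reflected at the chamber walls. Observed counts grow
over time — exactly the imbalance the weighted likelihood exists to
correct. Observations contain coordinates only; the attractant stays
latent, as in the real assays.

Preset scenarios:

- `dictyostelium_like` — 2500 µm, 12 panels every 0.5 h, cells seeded at
  the left edge plus left-boundary influx, sigmoidal initial attractant
  scaled to 10 µM, D_A = 150 µm²/s × 3600, no division; generating model
  receptor saturation; localization noise 2 µm; 400 boxes.
- `melanoma_like` — 400 µm, panels every 10 h to 50 h, empty at t = 0
  with all cells entering through the left boundary, uniform A(x,0) = 1,
  ν = 0.02 h⁻¹ fixed; generating model overcrowding; noise 1 µm; 200
  boxes.
- `recovery` — 1000 µm, 6 panels, counts 50→400 (geometric), basic-model
  truth (α = 5×10⁴ µm²/h, D_C = 600 µm²/h, γ = 0.6 h⁻¹, D_A = 100 µm²/h
  fixed), used for parameter-recovery scoring; 60 boxes.
- `saturation` — as `recovery` but receptor-saturation truth deep in the
  saturated regime (K_d = 0.05 ≪ A₀ = 1, α = 4×10⁴, γ = 1.2) with counts
  100→800, used for model-selection consistency.

Per-time-point counts for the real assays are not published; the preset
schedules are plausible, explicitly synthetic, and must not be read as
the original data. Likewise the initial-condition density estimator is a
boundary-corrected (reflection) Gaussian-kernel estimate scaled to the
observed count — a smooth substitution for spline-based log-density
estimation, adequate because downstream results depend only on a smooth,
mass-preserving C(x, 0).

What passing synthetic tests does *not* show: robustness to coordinate-
extraction error beyond small localization noise, to model
misspecification (the generator and the fitted model share the same
solver), or to 2-D effects collapsed into 1-D.

## Problem sizes used in the shipped experiments

Recovery: 20 replicate experiments, m = 100 bootstrap fits each, 50
boxes, Nelder–Mead with 300 (centre) / 100 (bootstrap) evaluations.
Model selection: 5 seeds, m = 50, three candidates. Degree selection: 10
seeds per truth, restart-polished fits. These sizes make the full suite a
desk-scale run while keeping every statistical claim at the stated
replication level; m is configurable up to the thousands for
production-scale pseudo-posteriors.

## Known limitations

- First-order upwinding introduces numerical diffusion of order a·dx/2;
  on coarse grids this can rival the physical D_C, and occasionally the
  likelihood then prefers a degenerate near-zero-D_C mode in which the
  scheme's own diffusion stands in for the physical one. This is the main
  source of the few percent of recovery-interval misses at the shipped
  50-box resolution; a finer grid removes the mode at proportional
  compute cost.
- The pseudo-posterior inherits the caveats of bootstrap-optimization:
  regions where solves fail are under-represented, and pruning keeps only
  the dominant likelihood mode.
- AICc/BIC sample-size convention (total cell count) is a convention;
  cells are not strictly independent draws when the same field is
  observed repeatedly.
- The weighted likelihood is not a true likelihood; information criteria
  computed from it are comparative, not absolute.
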