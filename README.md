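# cellmotion

Inference of the drivers of collective cell movement from one-dimensional
movement-assay data.

Collectively migrating cells — *Dictyostelium* amoebae moving under agarose,
melanoma cells crossing a visualization chamber — spread along the assay
axis through a mix of random motility, chemotaxis up attractant gradients
they generate themselves by depleting the medium, mutual attraction or
repulsion, and crowding effects. `cellmotion` formalizes these hypotheses
as six nested advection–diffusion–reaction PDE models for the cell density
C(x, t),

    ∂C/∂t = −∂/∂x [ a(x,t) C ] + ∂/∂x [ D_C(t) ∂C/∂x ] + ν C,

coupled to a depletable attractant A(x, t),

    ∂A/∂t = D_A ∂²A/∂x² − γ(t) C A,

and differing only in the advection coefficient a(x, t):

| model               | a(x, t)                                                 |
|---------------------|---------------------------------------------------------|
| diffusion           | 0                                                       |
| basic               | α(t) ∂A/∂x                                              |
| receptor saturation | α(t) ∂/∂x [ A / (K_d + A) ]                             |
| interaction         | saturation term + η(t)/(1 + λC) ∂C/∂x                   |
| overcrowding        | (1 − C/C_max) × saturation term                         |
| full                | (1 − C/C_max) × saturation term + interaction term      |

α, D_C, γ and η may vary in time as (exponentiated, for the positive ones)
polynomials. The package is aimed at quantitative cell biologists and
biostatisticians who have per-cell coordinates at a handful of time points
and want to ask *which* movement mechanism the data support.

Fitting uses a time-point-weighted log-likelihood
ℓ_w = (n/T) Σ_j ℓ_j / n_j built from the normalized model density at each
observed cell position, which stops late (cell-rich) time points from
dominating. Uncertainty comes from a bootstrap pseudo-posterior: the data
are resampled with replacement within each time point and the weighted
likelihood re-maximized many times; the resulting cloud of optimized
parameter sets stands in for a posterior sample and feeds the widely
applicable information criterion (WAIC) alongside AICc and BIC.

## Worked example

Simulate an assay with a known "basic" (raw-gradient chemotaxis) truth,
then fit the generating model with a 50-replicate bootstrap
pseudo-posterior:

```python
from cellmotion import CellMigrationModel
from cellmotion.simulate import recovery_scenario, simulate_assay
from cellmotion.model import default_start

scenario = recovery_scenario(seed=0)   # basic-model truth, counts 50 -> 400
obs, truth = simulate_assay(scenario, seed=0)

start = default_start(obs, None, scenario.grid).replace(
    D_A=scenario.params.D_A)           # attractant diffusion is a known constant
model = CellMigrationModel(obs, "basic", grid=scenario.grid, start=start,
                           initial_cells=scenario.initial_cells)
res = model.fit_pseudo_posterior(m=50, seed=0, maxfev=150, maxfev_center=400)
print(res.summary())
```

prints:

```
Collective cell movement model fit
======================================================
model:            basic (polynomial degree 0)
observations:     1079 cells over 6 time points
domain:           1000 um, 60 boxes
free parameters:  3
weighted loglik:  -6944.354
AICc: 13894.73   BIC: 13909.66
WAIC: 14136.81 (SE 31.84)  [pseudo-posterior m=49]
max grid Peclet:  2.404  (instability risk)
------------------------------------------------------
alpha[0]                  10.7516   [10.5937, 10.9954]
D_C[0]                    6.48302   [5.76329, 6.85375]
gamma[0]                -0.372839   [-0.707304, -0.197843]
```

`alpha[0]`, `D_C[0]`, `gamma[0]` are the degree-0 polynomial coefficients
on the optimizer scale — the natural log of the positive parameters. Here
exp(10.75) ≈ 4.7×10⁴ µm²/h chemotactic responsiveness against a generating
value of 5.0×10⁴ (ln = 10.82), exp(6.48) ≈ 650 µm²/h cell diffusion
against 600 (ln = 6.40), and exp(−0.37) ≈ 0.69 h⁻¹ depletion against 0.6
(ln = −0.51): all three bracketed 95-percentile pseudo-posterior intervals
cover the truth. One of the 50 bootstrap fits was pruned as a trapped
low-likelihood mode (m=49). The grid Péclet diagnostic above 1 flags
advection-dominated solves where the first-order upwind scheme is doing
the stabilizing.

Model comparison across candidates and the command-line interface:

```bash
cellmotion simulate --scenario melanoma_like --seed 7 --out run/
cellmotion compare --data run/coordinates.csv --models all --m 50 --out run/
cellmotion recover --seed 0 --n-seeds 5 --m 100 --out run/
```

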