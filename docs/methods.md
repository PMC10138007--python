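# Methods

## Model

`nanotherm` simulates magnetic-nanoparticle hyperthermia on an idealized
tissue phantom: a cube `[0, L]³` of homogeneous healthy tissue containing
one or more spherical tumors, each tissue type with its own constant
thermal conductivity `k`, blood perfusion rate `ω_b`, and metabolic heat
`Q_m`. Temperature follows the modified Pennes bioheat equation

    ρc ∂T/∂t = ∇·(k ∇T) + ω_b ρ_b c_b (T_a − T) + Q_m + Q_r,

with insulated (zero-flux) boundaries and a uniform 37 °C initial state.
The Pennes perfusion term treats blood as arriving at arterial temperature
`T_a` and equilibrating in the capillaries; perfusion is isotropic and
temperature-independent. Each nanoparticle injection deposits heat as a
fixed isotropic Gaussian, `Q_r(x) = Σ_i A·exp(−‖x−x0_i‖²/r0²)`, evaluated
once per injection set: the sources neither move nor decay during a
session.

Default parameters (all SI, configurable per scenario file):

| parameter | healthy | tumor | unit |
|---|---|---|---|
| `k` | 0.51 | 0.64 | W/(m·°C) |
| `ω_b` | 5.0·10⁻⁴ | 1.25·10⁻³ | 1/s |
| `ρ`, `ρ_b` | 1000 | 1000 | kg/m³ |
| `c`, `c_b` | 4200 | 4200 | J/(kg·°C) |
| `Q_m` | 420 | 4200 | W/m³ |

SAR peak `A = 0.08·10⁶ W/m³` and radius `r0 = 1.9·10⁻² m`; session length
`t_end = 3000 s` with step `ht = 0.1 s`; domain `L = 0.1 m` with `N = 128`
intervals; tumor radius 0.01 m; ablation threshold 43 °C. The arterial
temperature `T_a` is taken equal to the 37 °C initial/core temperature,
consistent with the Pennes equilibration assumption. With these values the
healthy tissue relaxes toward `T_a + Q_m/(ω_b ρ_b c_b) = 37.2 °C` with time
constant `ρc/(ω_b ρ_b c_b) = 2000 s` (tumor-valued tissue: 37.8 °C, 800 s)
— closed forms the test suite checks directly.

## Discretization

Space is discretized node-centred: `(N+1)³` nodes at coordinates `i·h`,
`h = L/N`. A node is tumor iff it lies inside or exactly on a tumor sphere
(ties inclusive, with a 10⁻¹² relative slack so exact surface ties survive
floating-point rounding; erring toward tumor is the conservative choice for
full-ablation checks). Time integration is explicit FTCS. Face
conductivities are harmonic means `2k₁k₂/(k₁+k₂)`, which keeps the flux
continuous across the tumor interface. Boundary nodes use mirror ghosts
(the missing neighbour is replaced by the first interior node in that
direction), the standard second-order realization of the zero-flux
condition; corner and edge nodes mirror each missing direction
independently.

The explicit step must satisfy the diffusion-plus-decay bound

    ht ≤ h²·ρc / (6·k_max + h²·(ω_b ρ_b c_b)_max),

about 0.667 s at N = 128 — so the 0.1 s session step has a 6.7× margin.
`simulate` enforces the bound (`force=True` overrides it, and a runtime
monitor aborts with a diagnostic if the field diverges). All state is
float64.

Two step implementations exist. The *general* path stores per-node `k`,
`ω_b`, `Q_m`, `ρc` fields and computes harmonic means on the fly — the
literal heterogeneous-medium update, kept as the reference and used for
arbitrary media. The *production* path exploits the piecewise-two-material
structure: a constant-coefficient 7-point stencil with the healthy-tissue
coefficients sweeps the whole grid, and the nodes inside the
one-node-inflated bounding boxes of the tumor regions — the only nodes
whose update involves any tumor value — are then recomputed with a
two-material kernel using a precomputed 2×2 face-conductivity table. Both
paths are numba-compiled; the test suite verifies they agree to round-off,
including tumors touching the boundary, and that a single step matches a
literal triple-loop transcription of the update on random heterogeneous
5³ media. A full N = 128, 30 000-step session runs in roughly two minutes
on one CPU core.

## Damage metrics and objective

Damage is evaluated on the final field only (no thermal-dose integration):
a node is damaged iff `T ≥ 43 °C` at `t = t_end`, threshold inclusive.
`Nt` and `Nh` are damaged-node percentages within the tumor and healthy
masks respectively, and `β = 1` iff every tumor node is damaged. The
objective `O(p) = 300 − Nt − (100 − Nh) − 100·β` rewards tumor kill and the
full-ablation bonus and penalizes healthy damage; under full ablation it
reduces exactly to `Nh`, so reported objectives are directly interpretable
as collateral-damage percentages. (`Nh` here is the percentage of healthy
tissue *damaged*; defining it as the percentage *below* threshold would
make the objective inconsistent with its own reduction to the
healthy-damage percentage.) Percentages are node counts; a cell-volume
convention would differ by well under 0.2 percentage points at N = 128.

## Differential evolution

The planner optimizes the `3·Np` injection coordinates with best/1/bin DE:

- population `pop_multiplier × 3·Np` individuals (default multiplier 35),
  initialized uniformly in the search box, which defaults to the full
  domain cube per coordinate;
- mutation `V = X_best + F·(X_a − X_b)` with `a, b` sampled distinct and
  different from both the best and the target individual; `F` is dithered
  uniformly in [0.5, 1.0) each generation by default;
- binomial crossover with rate `C = 0.7`; one uniformly chosen coordinate
  is always taken from the mutant so the trial cannot collapse onto the
  target (set `force_crossover=False` for the literal textbook rule);
- out-of-box trial coordinates are clipped to the bounds, keeping
  injections inside the tissue;
- greedy selection with ties favouring the trial;
- stop when `std(O) ≤ atol + tol·|mean(O)|` over the population (defaults
  `atol = 0`, `tol = 0.01`) or after `max_generations` (default 10 000);
  hitting the cap flags the run unconverged instead of raising.

`F`, `C`, `atol`, `tol` have no published reference values for this
problem; the defaults are standard best/1/bin practice and are exposed in
the settings and the config file. The objective is a pure function of the
coordinates and costs a full bioheat simulation, so evaluations are cached
by coordinate bytes and identical individuals are never re-simulated.
Elitism (the population minimum never increases) follows from greedy
selection and is asserted in tests. Runs are exactly reproducible per
seed.

## Randomized scenario generator

`random_scenario` draws pairwise-disjoint tumor spheres with radii uniform
in (0.005, 0.015) m — bracketing the 0.01 m benchmark radius — kept at
least 0.005 m from the domain faces, with the standard tissue and
treatment parameters. It emulates the geometric variability of multi-focal
disease on the same phantom; it does *not* emulate irregular tumor shapes,
heterogeneous intratumoral properties, or anatomically realistic
boundaries, so tests passing on these fixtures validate the numerics and
the planning machinery, not clinical realism.

## Validation and reproduction status

Beyond unit oracles (hand-evaluated single steps, closed-form uniform
relaxation, steady states, cube symmetry, second-order spatial / first-
order temporal convergence on a damped cosine eigenmode), the suite
cross-validates the full 3D pipeline against an independent 1D radial
bioheat solver for the spherically-symmetric central-tumor case — a
conservative finite-volume radial operator, direct steady solve, and
sparse-matrix-exponential transient, sharing no code with the production
stencil. Peak temperature agrees to < 0.05 °C and the 43 °C ablation
radius to < 2%.

Against the published benchmark values for these scenarios, this
implementation reproduces all structural results — complete tumor ablation
for the naive plans, optimized plans matching or beating naive ones, the
near-degeneracy of scenario 1's optimum — but computes systematically
larger damage extents: the healthy-damage percentages exceed the reference
values by ≈0.5–1.3 percentage points (e.g. scenario 1 naive: 2.14% vs
1.53%), equivalent to a 43 °C ball about 1.4 mm larger in radius per
isolated injection. The radial cross-check shows this is a property of the
stated model and parameters, not of the discretization. No re-scaling of
parameters consistent across all three scenarios was found that removes
the offset, so the published damage levels could not be traced to the
stated model; the acceptance tests record this disagreement openly rather
than absorbing it into tolerances. `scripts/acceptance.py` recomputes all
benchmark quantities from scratch so the comparison is reproducible.

## Problem sizes used by the test suite

Full-fidelity checks (N = 128, ht = 0.1 s, 3000 s) run once per benchmark
configuration as shared session fixtures (~2 min each). The grid-
independence test uses N = 64/96/128 with the same ht; the N = 256 tier
lives in `scripts/grid_independence.py`. Optimizer end-to-end tests use
N = 32 with ht = 5 s (stability limit ≈ 10.7 s there) and a reduced
population — sizes chosen to exercise the same landscape at desk scale.

## Known limitations

- Damage is thresholded at 43 °C on the final field; no Arrhenius or
  CEM43 dose models, no time-delayed necrosis.
- Perfusion is constant: no temperature dependence, vascular shutdown, or
  damage feedback.
- Geometry is idealized (cube + spheres); no image-derived anatomy,
  anisotropy, or temperature-dependent properties.
- The SAR Gaussian is an empirical stand-in for nanoparticle dispersal;
  transport/diffusion of particles is not modelled.
- Single-session planning only; the session length is fixed, not part of
  the optimization.
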