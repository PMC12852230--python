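# Methods

`bcsheal` simulates the four-week healing of a breast-conserving-surgery
(lumpectomy) cavity with a coupled mechanobiological finite-element model,
and learns fast outcome surrogates from those simulations with multi-fidelity
Gaussian-process (GP) regression. This note records the model, the numerical
choices, and the limits of what the synthetic study design can show.

## Synthetic cohort and geometry

Each synthetic patient is described by four characteristics — breast density
(fibroglandular volume fraction), cavity (tumor) volume, breast volume, and
cavity depth — sampled by Latin hypercube design over the ranges observed in
a processed-MRI lumpectomy population (density 0.0439–0.7113, cavity volume
33.41–35,096.57 mm³, breast volume 90,191–3,208,695 mm³, depth 6.96–54.58 mm),
plus a uniform 0–5 mm surgical margin added to the tumor-sphere radius. The
hypercube is stratified one-sample-per-bin per dimension; rows whose stratum
combination cannot hold a feasible cavity (we require a 2 mm tissue shell
between the cavity sphere and both the skin and the chest wall) are redrawn
within their strata and dropped with a diagnostic if no feasible draw exists.
Because the four characteristics are sampled independently and uniformly,
corner combinations (a deep, large cavity in a small breast) are rejected;
the effective cohort is the feasible subset of the design.

Geometries are hemispherical breasts on the chest-wall plane with a
spherical cavity centered on the apex axis at the prescribed depth. The
hemisphere is convex, so a Delaunay tessellation of boundary + interior
points meshes it exactly: the dome is sampled by latitude rings (with a
sub-surface witness layer and slight inward jitter to suppress boundary
slivers), the interior by a body-centered-cubic lattice, and the cavity by a
point sphere with one graded tissue shell outside it. Boundary-flat sliver
tets (all four vertices on the outer surface, quality < 1e-3) are discarded;
a single corrective rebuild rescales the polyhedral surfaces so meshed
breast and cavity volumes land within a fraction of a percent of their
targets. Two refinement levels are generated; the low-fidelity mesh carries
~70 % fewer elements. The high-fidelity geometry additionally applies a
seeded, volume-preserving ellipsoidal perturbation of the outer surface
(blended to zero near the cavity), so the two fidelity levels are correlated
but not identical — the property the multi-fidelity surrogate exploits.
Synthetic geometries are defined directly in the upright configuration; the
prone-to-upright unloading machinery (below) exists for externally supplied,
gravity-loaded meshes.

## Tissue model

Kinematics use the multiplicative split `F = Fe Fp` with the plastic part
diagonal in an orthonormal microstructural basis `{a0, s0, n0}` (`a0` the
preferred collagen direction; the basis is completed by Gram–Schmidt against
the global z axis with a deterministic tie-break). The passive response is a
compressible neo-Hookean matrix plus a Gasser–Ogden–Holzapfel dispersed-fiber
term, the whole energy scaled by the collagen volume fraction `phi`:

    Psi = phi [ k0 (I1e − 3) + k1/2 (Je − 1)² − 2 k0 log Je
                + kf/(2 k2) (exp(k2 E²) − 1) ],
    E = kappa (I1e − 3) + (1 − 3 kappa)(I4e − 1).

The fiber strain `E` is the stress-free GOH form (zero stress at `Fe = I`);
the fiber term is active only in tension, gated on `E > 0`, where the energy
is C1 — gating on `I4e > 1` instead makes the stress discontinuous at the
switch and we found it to be a major source of Newton failures. `k0, k1`
come from the patient's rule-of-mixtures Young's modulus (10/40 kPa
adipose/fibroglandular in the healing stage; 1.5/6 kPa in gravity staging)
with `mu = 2 k0` and `k1` the first Lamé parameter, so the linearized
response reproduces `(E, nu)` exactly. We use `nu = 0.35`: wounded tissue
drains interstitial fluid under sustained load, and a stiffer volumetric
penalty makes the deep cavity collapse a numerically violent snap-through
without changing the healed-state picture.

The active stress is a cell traction aligned with the dispersion-weighted
deformed fiber structure tensor `Ahat = A/tr(A)`, `A = I + (1 − 3 kappa) a⊗a`:

    sigma_act = rho (t_rho + t_rho_c c/(K_tc + c)) (phi/(K_t² + phi²)) Ahat.

With `K_t = 0.1`, traction peaks on compliant provisional matrix
(`phi ≈ 0.1`) and saturates out in dense scar — this localizes contraction
to the healing cavity rather than the cytokine-tinged surrounding tissue.
The magnitude passes through a smooth ceiling `sigma_max tanh(m/sigma_max)`
with `sigma_max = 100 kPa`: cells cannot exert unbounded stress, and the
ceiling removes a runaway crush instability in large, low-density cavities
where `rho`, `c` and the `phi`-peak coincide. Mechanosensing
`H(Je) = 1/(1 + exp(−gamma_e (Je − theta_e)))` uses `gamma_e = 50`,
`theta_e = 1.10`, so `H ≈ 0` at `Je = 1` and healthy-tissue homeostasis is
exact (all baseline rates balance at `rho = phi = 1`, `c = 0`).

The fresh cavity starts at `phi = 1e-3` (a seroma-filled void with a
provisional fibrin matrix that lacks mechanical integrity); in the
*mechanical solve only*, the stiffness is floored at `phi = 0.25` — the
clot and fluid retain some volumetric and shear resistance, and without a
floor the crushed seroma elements shear chaotically (the biochemical fields
and the active-stress `phi` always use the true collagen fraction). In
gravity staging the cavity instead uses the fluid law: (regularized) zero
shear with a 300 kPa bulk modulus.

## Healing kinetics

Fibroblasts `rho` and cytokine `c` obey reaction–diffusion equations on the
reference domain; collagen `phi`, plastic stretches `lambda_p`, fiber
direction `a0`, and dispersion `kappa` evolve by local ODEs at one
quadrature point per element. The full parameter set, with units and
one-line meanings, lives in `src/bcsheal/params/default.toml`; the loader
validates completeness and rejects unknown keys. Salient forms:

- fibroblast diffusivity `D_rho = d_rho_phi v(phi)²/6 + d_rho_c c/(K+c) + d_rho_0`
  with a biphasic crawling speed `v(phi) = v_max phi/(K_v² + phi²)` (no
  substrate in the void, steric hindrance in dense matrix);
- logistic fibroblast growth boosted by cytokine and stretch, saturating
  cytokine production by cells, linear clearance;
- collagen deposition `∝ rho/(K_phi_rho + phi)` boosted by cytokine and
  stretch, degradation enhanced by inflammation (`c rho d_phi_c`);
- plastic flow `lambda_p_dot = (phi_dot+ / tau)(⟨lam_e − (1+delta)⟩ −
  ⟨(1−delta) − lam_e⟩)`: remodeling converts elastic stretch beyond a ±5 %
  dead zone into permanent stretch at a rate set by the *new collagen
  deposition rate* `phi_dot+` (the production term). The symmetric dead zone
  is what produces permanent cavity compaction (`Jp < 1`) and the
  surrounding tension halo (`Jp > 1`);
- fiber reorientation toward the maximum-stretch eigenvector and dispersion
  relaxation toward `(1/3)(lam2/lam1)^gamma`.

Parameter values were set by scale reasoning (diffusion lengths of a few mm
over days; front speeds reaching the cavity center within the first two
weeks) and then calibrated once so that an 8-patient generalized-geometry
cohort reproduces the reference trajectory anchors: cohort-mean cavity
volume minimum ≈ 26 % of the excised volume in the first two weeks, partial
rebound, ≈ 49 % at week 4. The anchors' driving structure is: early cytokine
release boosts traction in and around the collagen-poor cavity; invading
fibroblasts contract the provisional matrix while plasticity locks roughly
half the compression in; cytokine clearance and collagen accumulation then
shut the traction down and the elastic share recoils — the rebound. In this
calibration the trajectory minimum falls on day 6–8 rather than day 9; we
did not chase the timing further because the depth, week-4 value, and shape
are reproduced.

## Solution scheme

Linear tetrahedra for displacement and fields; one quadrature point per
element for microstructure. Each step of `Delta t = 0.5 d` over the 28-day
horizon applies an operator split: (i) backward-Euler reaction–diffusion
update (implicit lumped-mass diffusion and linear decay — an M-matrix, so
positivity is preserved up to the obtuse-element exceptions, which are
clipped at a 5 % tolerance; explicit nonnegative production), (ii)
quadrature-point remodeling (implicit scalar Newton for `phi`; exact
exponential relaxation for `kappa`; explicit capped updates for `lambda_p`
— never overshooting the dead zone — and `a0`, renormalized, with
reorientation frozen on near-degenerate stretch spectra), (iii) quasi-static
re-equilibration with `sigma = sigma_pas + sigma_act`.

Equilibrium uses Newton's method with a finite-difference consistent tangent
(12 directional derivatives per element, vectorized over all elements), a
backtracking line search that rejects steps causing element inversion, a
factorized-tangent cache reused across healing steps, and, on line-search
failure, pseudo-transient continuation (adaptive diagonal regularization
that walks through snap-through states while still converging to the exact
equilibrium). The excision shock at t = 0 and stubborn steps fall back to an
active-stress load ramp, warm-started and then cold-started; a failing step
halves `Delta t` down to 0.2 d. Patients whose solve still fails (typically
large, shallow cavities within ~3 mm of the skin, or extreme soft-and-large
combinations — some 10–20 % of a uniform-LHS cohort) are recorded and
skipped; cohort statistics are over the completed subset.

The operator splitting converges at first order: halving `Delta t` from the
default changes the week-4 cavity volume by ≈ 2 %, shrinking further under
refinement. Gravity staging (for externally supplied prone geometries)
applies the body force `rho g = 9.81e-3 kPa/mm` incrementally with automatic
load-step halving, and recovers the unloaded configuration by the fixed-point
iteration that repeatedly subtracts the forward-gravity mismatch until the
loaded surface is reproduced within 0.5 mm.

## Outcome metrics

Cavity contraction is the deformed cavity-element volume as a percentage of
its post-excision value (day 0 = 100 %). %BSD is the area-weighted
percentage of skin facets whose mean vertex displacement between the
pre-excision reference surface and the week-4 surface exceeds 1 mm;
correspondence is by material point and no rigid registration is applied
(the chest wall is fixed). The reference state is the equilibrium of the
intact breast with homeostatic fields, so only surgery-induced deformation
counts. Cavity depth is the exact minimum point-to-triangle distance from
the cavity centroid to the skin. Cohort summaries use per-day means and
empirical 2.5/97.5 percentiles, and the %BSD histogram in <1 %, 1–10 %,
>10 % bins.

A synthetic reviewer consensus stands in for a human visibility panel: five
seeded Bernoulli "reviewers" vote with probability
`logistic(0.15 (pbsd − 10) − 0.05 (depth − 20))`, so simulations with more
than ~10 %BSD are almost always judged visibly deformed, deeper cavities
less so. The consensus score is the fraction voting visible.

## Surrogates

Inputs are scaled to [0, 1] by the cohort ranges; the contraction surrogate
takes normalized time as a fifth input (one GP over the whole trajectory
rather than one per day). GP regression uses a squared-exponential ARD
kernel with learned Gaussian noise, fitted by multi-restart L-BFGS-B on the
marginal log-likelihood with analytic gradients; restarts include a
deterministic lengthscale/noise grid that guards against the all-noise local
optimum, and a jitter ladder handles near-singular covariances. The
multi-fidelity model is the two-level nonlinear autoregressive GP: level 2
regresses the high-fidelity outputs on `(x, mu_1(x))` with the composite
kernel `k_rho(x)·k_f(f) + k_delta(x)`; prediction propagates level-1
posterior samples (default 100–500) through level 2 and moment-matches by
the law of total variance. Validation repeatedly splits the high-fidelity
set in the 150:13 train:test proportion (scaled to the cohort at hand),
scoring held-out MAE for %BSD and RMSE for contraction. The
visible-deformation "classifier" is GP regression on the consensus scores
with predictions clamped to [0, 1]. Outcome maps evaluate a surrogate on a
50×50 grid (2,500 predictions) over a pair of characteristics with the
others at the cohort medians.

## What the synthetic study does and does not show

The generator emulates the study conditions — characteristic ranges,
hemisphere-plus-sphere geometry, two correlated fidelity levels, margin
randomization — but not real anatomy: no MRI-derived breast shapes, no
tissue heterogeneity, no ptosis, no contralateral side, and the cohort is
uniform over the characteristic box rather than distributed like a clinical
population (so large cavities are over-represented and the %BSD histogram
skews high). Passing tests therefore demonstrate that the implemented
mechanobiology reproduces the reference healing dynamics and that the
surrogate machinery meets its accuracy bounds on this emulated cohort; they
do not validate prediction for real patients. Radiation effects,
angiogenesis, and immune cascades are outside the model. Solver-failure
exclusion (above) slightly biases cohort summaries toward less extreme
responders.
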