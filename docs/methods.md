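# Methods

## The model

`tumimm` simulates the interaction between a growing tumor cell population
and two antagonistic arms of the immune response.

**Tumor cells** are structured by size. The density `n(t, z)` obeys a
growth-fragmentation equation

    ∂t n + ∂z( V(z) (1 + β(t)) n ) = Q(n) − ℓ(t) n,      n(t, 0) = 0,

where `V(z)` is the individual growth velocity — constant, or the Gompertz
law `V(z) = r z ln(b/z)` which vanishes at size 0 and at the maximal size
`b` — and `Q` is the binary division operator
`Q(n)(z) = 4 a(2z) n(2z) − a(z) n(z)`: a cell of size `2z` splits into two
daughters of size `z` at frequency `a(·)`, either constant or activated
above a size threshold `z0`. Division conserves the total tumor mass
`μ1 = ∫ z n dz` while increasing the cell count `μ0 = ∫ n dz`. Two scalars
couple the tumor to the immune fields: the kill rate `ℓ = ∫ δ(x) c(t, x) dx`
(the *immune strength*, written `μ̄_c` in outputs) and the growth
enhancement `β = ∫ b1(x) c_r(t, x) dx` exerted by protumor cells.

**Immune cells** live on the two-dimensional unit disc. Antitumor effectors
`c` (CD8⁺ T, NK, N1, M1) and protumor cells `c_r` (Treg, MDSC, N2, M2) both
drift up the gradient of a chemotactic potential `φ` with sensitivity `χ`
and diffuse with coefficient `D`, vanishing on the disc boundary
(non-activated far from the tumor). The potential solves the quasi-static
Neumann problem `−∇·(K∇φ) = f(μ1) σ̃` with the Michaelis–Menten response
`f(μ1) = μ1/(η + μ1)` and a zero-mean source shape `σ̃`. Effectors are
recruited at rate `g(μ1) S` (`g` linear by default, quadratic optionally),
die at rate `γ`, are converted into protumor cells at rate `k_r I θ(x)`
near the tumor (form function `θ`), and are suppressed by protumor cells at
rate `k_c c_r`. Protumor cells are recruited by the cytokine signal from a
distant three-spot source `S_r` and from converted effectors, and die at
rate `γ_r`.

**Cytokines** are lumped into a single well-mixed concentration `I(t)` with
`dI/dt = ψ(μ1) − τ I`, where `ψ(μ1) = ψ̄ (μ1 − m)⁺` activates only above
the critical tumor mass `m`.

Two long-time regimes exist. In the **equilibrium phase** the immune
strength `μ̄_c` settles exactly at the Malthus eigenvalue `λ` of the
growth-fragmentation operator (the eigenpair `(λ, N)` satisfies
`∂z(V N) = Q(N) − λ N`, `∫N dz = 1`), leaving a residual controlled tumor;
in the **escape phase** the protumor response outpaces the effectors and
`μ1` grows without bound. For constant `V` and `a` the eigenvalue is `λ = a`
exactly, and enhancing the growth by `(1+β)` leaves `λ` unchanged while
rescaling the profile to `N(z/(1+β))/(1+β)` — both identities are used as
analytic oracles in the test suite.

**Therapy.** Two pulsed treatments extend the model. *Reactivation*
(checkpoint-inhibitor-like) introduces exhausted cells `c_a`, fed by a
fraction `α` of the suppression loss `k_c c c_r`, and returns them to the
effector pool at rate `T₁(t) c_a`. *Blockade* (cytokine-trap-like) clamps
every cytokine-driven recruitment of protumor cells by `max(0, 1 − T₂(t))`.
Each drug effect obeys `dT/dt = κ(t) − d_T T` with `κ` a pulse train: dose
`q` for a duration of 1 time unit every 7, starting at `t0` (decay rates
0.05 and 0.0105 for the two drugs).

## Reduced ODE model

Neglecting space and taking `V`, `a` constant collapses the system to five
ODEs for `(μ0, μ1, c, c_r, I)`. Three closed-form equilibria organize the
dynamics: the healthy state `H = 0` (always linearly unstable — eigenvalue
`a > 0`); the protumor-free state
`NP = (γa²/(δVS), γa/(δS), a/δ, 0, 0)`, admissible iff its tumor mass is
below the critical mass (`a/δ < mS/γ`) and then always linearly stable with
eigenvalues `{−γ_r, −τ, −a, (−γ ± √(γ(γ−4a)))/2}` — damped for `γ > 4a`,
oscillatory for `γ < 4a`; and a protumor-positive state `P` whose mass obeys
`μ1^P − m = (γa/δ − mS)/(S − Q1 x − Q2 x²)` with `x = a/δ`,
`Q1 = ψ̄ k_r/τ`, `Q2 = ψ̄ k_c k_r/(γ_r τ)`. With `X2` the positive root of
the denominator, the admissibility pattern as `x` grows is
`NP → P → none` when `m < γX2/S` and `NP → NP+P → none` when `m > γX2/S`;
beyond the last threshold the tumor mass necessarily blows up. The printed
formulas correspond to a unit cytokine slope; the implementation carries
`ψ̄` through (replace `Q` by `ψ̄Q`), reducing to the same expressions at
`ψ̄ = 1`. The reduced model defaults keep the documented scenario values
(`V = 0.616`, `δ = 1`, `S = 1.5`, `k_r = 1.25`, `k_c = 0.1`, `m = 2`,
`γ = 0.18`) with unit `ψ̄`, `γ_r`, `τ`.

## Discretization

**Size.** Uniform finite volumes on `[0, z_max]`; `z_max = b` for the
Gompertz law, ten times the support of the initial datum for constant
growth (with the truncation loss through `z_max` monitored and warned
about beyond 10⁻⁶ of the tumor mass). Transport uses first-order upwinding
(the velocity is nonnegative), division evaluates the gain `4a(2z)n(2z)` by
linear interpolation and then applies a nonnegative affine-in-`z`
multiplicative correction making the discretization *exactly* conservative:
the first moment of `Q` vanishes and the gain integral equals twice
`∫ a n dz` at machine precision. Time stepping is Lie splitting — an
explicit upwind transport substep under the CFL constraint
`dt ≤ 0.9 h / max V(1+β)`, then an explicit reaction substep under
`dt ≤ 0.5/(a + ℓ)` — each substep positivity-preserving under its own
constraint (a single unsplit Euler stage would need the stricter combined
bound).

**Eigenpairs.** Power method: iterate the linear stepper from the uniform
density, renormalize to unit mass each step, and estimate
`λ = (mass ratio − 1)/dt`; for the explicit Euler stepper the eigenvector
multiplier is exactly `1 + dt λ`, so this estimator carries no `O(dt)`
bias (a logarithmic estimate would be biased by `≈ dt λ²/2`, several
percent at coarse-grid CFL steps). Iteration stops when successive
estimates change by less than the tolerance (default 10⁻⁸); the discrete
residual of the eigenproblem is reported alongside.

**Space.** Cartesian finite volumes on `[−1, 1]²` with a staircase mask of
the unit disc (cells whose center lies inside). The protumor source breaks
radial symmetry (three spots at angles 90°, 210°, 330° on the circle of
radius 0.7), ruling out a radial reduction. The Neumann Laplacian for `φ`
uses two-point fluxes on interior faces only; solvability is enforced by
projecting the source to zero mean (verified before each solve), the gauge
by pinning one cell during the sparse LU solve and subtracting the mean
afterwards. Cell fields use ghost-value-zero Dirichlet closures at
half-cell distance. Each transport step splits into explicit upwind
advection with face velocities `χ ∂φ/∂n` (zero on the boundary, consistent
with the Neumann condition on `φ`), implicit diffusion (factorized once per
`(dt, D)` pair and reused), and an implicit linear reaction update
`u ← (u + dt·gain)/(1 + dt·loss)`; every substep maps nonnegative states to
nonnegative states. The cytokine and drug ODEs use exact exponential
integrators with steps split at dose-pulse edges.

**Coupling.** One splitting step per time level: moments → elliptic solve at
strength `f(μ1)` → immune fields (gains and losses frozen at the step
start) → cytokine → tumor. The step size is the largest dyadic fraction of
`dt_max = 0.1` below all stability bounds, so implicit-diffusion
factorizations are reused across the run. Integration halts once
`μ1 > 10⁶ × μ1(0)` (a finite proxy for blow-up), and also when the stable
step collapses — below `dt_max/2²⁴` unconditionally, or below
`dt_max/2¹⁰` once the mass already exceeds 10³ times its initial value
(with a growth enhancement `β ∝ c_r` blowing up, the CFL bound shrinks
like `1/(1+β)` and further integration only confirms the escape); the
outcome classifier
labels a run *escape* when `μ1` exceeds 10³ times its initial value while
increasing, *equilibrium* when the relative derivative of `μ1` stays below
10⁻⁵ over the trailing 10% of the run, and *undecided* otherwise. The model
is fully deterministic: identical configurations reproduce series bit for
bit.

**Equilibrium-mass predictor.** With no growth enhancement (`b1 = 0`) the
eigenvalue decouples and the equilibrium must satisfy `∫δC dx = λ`. The
predictor solves the stationary immune equations at frozen tumor mass
(sparse upwind advection–diffusion–reaction solves, damped fixed-point
iteration on the nonlinear suppression and conversion couplings, exact
cytokine balance `I = ψ(μ1)/τ`) and brackets the smallest positive root of
`μ1 ↦ ∫δC_{μ1} dx − λ` from zero. Cross-validating this root against the
long-run simulation is one of the package's structural checks (they agree
to better than 1% at the production resolution; the guaranteed tolerance
is 10%).

## Parameters

Printed simulation values (provenance `paper` in manifests): kill weight
`A = 1`, `ξ² = 0.02`; signal `A_σ = 0.002`, `ξ_σ² = 0.05`; division
`a = 0.8` with threshold `z0 = 1`; growth `V = r = 0.616`, `b = 10`;
`χ = 0.864`; effector source `S = 5`; effector death `γ = 0.18`; initial
tumor `n0 = 1` on `[0.125, 5]` with `c = c_r = 0`, `I = 0`; therapy pulses
of length 1 every 7 time units with decays 0.05 / 0.0105 and exhausted
fraction `α = 0.5`.

All remaining rates are package defaults (provenance `default`), chosen
once so that the printed conditions reproduce every qualitative regime the
model is known for, and documented here:

| parameter | default | role |
|---|---|---|
| `D` | 0.05 | immune cell diffusion on the unit disc |
| `K` | 1.0 | signal diffusion in the potential equation |
| `η` | 1.0 | Michaelis–Menten half-saturation mass |
| `γ_r` | 1.0 | protumor cell death rate |
| `γ_a` | 0.18 | exhausted cell death rate (= `γ`) |
| `τ` | 0.2 | cytokine damping (slow: the protumor response outlives the tumor-mass peak) |
| `ψ̄` | 4.0 | cytokine production slope above the critical mass |
| `m` | 2.0 | critical tumor mass |
| `k_r` | 0.1 | conversion rate of effectors into protumor cells |
| `k_c` | 1.0 | suppression rate of effectors by protumor cells |
| `A_θ`, `ξ_θ²` | 1.0, 0.05 | conversion-site form function |
| `A_b1`, `ξ_b1²` | 0.05, 0.02 | growth-enhancement kernel |
| `S_r` | 3 spots × amplitude 15 × scale 1/5 | protumor source |

The defaults sit deliberately in the *slow-cytokine / strong-suppression*
corner. Because the effector supply `g(μ1)S` ramps within a fraction of a
time unit whereas protumor recruitment requires cytokine accumulation, a
fast cytokine response (`τ ≈ 1`) lets the effectors crush any tumor before
suppression matters, and the only escape route left is direct
cytokine-driven conversion of effectors — a channel that reactivation
therapy structurally cannot counter, since reactivated cells are instantly
re-converted and even feed the protumor pool. With slow damping and a
`c`-independent recruitment (`I S_r`), suppression (`k_c c c_r`) becomes
the escape driver; this is precisely the loss channel whose exhausted
fraction reactivation recycles, and whose recruitment blockade clamps, so
both treatment arms act on the mechanism that causes escape. Under these
defaults: `a = 0.8` reaches equilibrium with `μ̄_c → λ`; `a = 4` escapes;
the reactivation dose `q = 2` controls the escaping tumor when started at
`t0 = 5` but not at `t0 = 15`; blockade below `q2 ≈ 0.18` fails alone at
`t0 = 10`; and the combination `(q, q2) = (2, 0.14)` controls at `t0 = 10`
where both monotherapies fail. The final tumor mass is monotone
non-increasing in the dose.

## Problem sizes

Production runs use a 64×64 bounding grid (≈ 3 200 disc cells) with 256
size cells and horizons of 100–150 time units; the long equilibrium run
takes a few seconds on one core. Unit and property tests use 32×96 (and
the regression-style therapy sweeps 32×96 with horizons 30–100). Eigenvalue
computations use 300–960 size cells. The acceptance script uses 480 size
cells for the eigenvalue identity and 256 for the division-operator moment
check.

## Known limitations

* The staircase disc boundary is first-order; boundary-sensitive
  quantities (e.g. the potential near `|x| = 1`) carry `O(h)` error.
* The interpolation-based division gain is exact in its two enforced
  moments but only first-order accurate pointwise; eigen*profiles* on
  coarse grids are correspondingly diffuse even where the eigen*value* is
  structurally exact.
* The outcome classifier is a finite-horizon proxy: a trajectory that
  transiently exceeds 10³ × `μ1(0)` while increasing is labeled escape even
  if a late treatment subsequently controls it (therapy analyses therefore
  judge control by the final mass, not the label).
* Exact equality of the equilibrium immune strength with the Malthus
  eigenvalue holds for the discretized operators; both converge to the
  continuum values at first order in the grid spacings.
* No toxicity constraints, no spatial tumor resolution (the tumor is a
  point source for chemotaxis), and a single lumped cytokine compartment.
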