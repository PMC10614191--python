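# Methods

## Scope and model

`slospt` treats a monodisperse fluid of charged hard spherocylinders
(cylinder length L, hemispherical caps of diameter D, core volume
v_r = πD²L/4 + πD³/6) in the isotropic phase.  The electrostatics is the
linear (Debye–Hückel) double-layer repulsion between rod axes,

    βU(x, θ) = A' exp(−κ(x − D)) / sin θ,        x ≥ D,

with x the minimum axis–axis distance, θ the crossing angle, κ the inverse
Debye length.  Nonlinear charge renormalisation, density-dependent
screening, orientationally ordered phases and the twisting effect are out
of scope.

## Electrostatic amplitude

The exact amplitude follows from matching the outer potential of a charged
cylinder (line charge density Z, Bjerrum length λ_B) to an effective line
charge:

    A' = 2π Z² λ_B κ⁻¹ e^{−κD} / [(κD/2) K₁(κD/2)]².

Asymptotes: A' → 2πZ²λ_Bκ⁻¹e^{−κD} for thick double layers (κD ≪ 1) and
A' → 8Z²λ_B/(κ²D) for thin ones.  The package's uniform approximation

    A' ≈ 2π Z² λ_B κ⁻¹ / (1 + πκD/4)

interpolates between both limits; its measured maximum deviation from the
exact expression is 4.45% (at κD ≈ 1.1) over κD ∈ [10⁻², 10²], computed on
a 200-point log grid.  Bessel functions are evaluated in exponentially
scaled form (`k1e`) so the thin-double-layer regime does not underflow.

Dimensional analysis note: A' depends on three dimensionless groups
(Zλ_B, κD, λ_B/D).  The reduced API takes all three with λ_B/D defaulting
to 1; relative-error quantities are independent of the charge prefactor.

## Effective diameter

For rods crossing at θ the soft repulsion thickens the contact distance by

    Δ(θ; d_c) = ∫_D^{d_c} [1 − e^{−βU_c(x,θ)}] dx,

where U_c is the **truncated-and-shifted** potential with cutoff d_c (the
form a simulation actually uses; the shift matters — with plain truncation
the threshold cutoffs below come out ≈25% smaller).  Substituting
t = (A'/sinθ)e^{−κ(x−D)} turns Δ into exponential integrals; the
implementation switches between a small-argument identity built on
E(a) = ln a + γ_E + E1(a) and an exponentially scaled large-argument form,
so the kernel is finite and accurate for all crossing angles and cutoffs.

The orientation average weights D + Δ(θ) with the excluded-volume factor
sin θ over isotropic axes:

    D_eff = D + (2/π) ∫₀^π sin²θ Δ(θ) dθ.

Quadrature: Gauss–Legendre on (0, π/2) (doubled by symmetry), 400 nodes by
default; every call verifies that halving the node count moves the result
by < 10⁻⁸ relative.  The sin²θ Jacobian tames the logarithmic growth of Δ
as θ → 0, so no substitution is needed.

For A' ≥ 2 and d_c → ∞ the closed form
D_eff = D + κ⁻¹(ln A' + γ_E + ln 2 − ½) applies; its measured worst-case
deviation from the exact integral over A' ∈ [2, 50] × κD ∈ [0.25, 4] is
1.89%, consistent with the 2.2% validity statement used throughout.

**Threshold cutoff.**  d_c^t is the smallest cutoff for which

    (D_eff(∞) − D_eff(d_c)) / D_eff(d_c) ≤ 2.2%,

with the finite-cutoff exact value in the denominator (the exact integral
is the reference).  The difference is monotone in d_c, so plain bisection
to ~10⁻⁵ relative suffices.  With this convention the nine-cell reference
grid (A ∈ {1, 4, 16} × κD ∈ {0.5, 1, 2}) reproduces to ±0.04 in both
d_c^t/D and D_eff/D; the tabulated effective diameters are the
finite-cutoff values evaluated *at* the threshold (the d_c = ∞ values sit
exactly 2.2% higher and round differently for the strongest amplitudes).

## SPT thermodynamics

Pressure of hard spherocylinders (γ = 1 + L/D, y = φ/(1−φ)):

    Π̃ = y + a y² + b y³,  a = 3γ(γ+1)/(3γ−1),  b = 12γ(2γ−1)/(3γ−1)².

The y² coefficient makes B₂ exact for convex bodies; b has the correct
Onsager scaling (b/a² → 0 as γ → ∞) and reduces to the SPT hard-sphere
value 3 at γ = 1.  The free volume fraction follows from the SPT insertion
work plus the pV term,

    α = (1−φ) exp(−2a y − (3/2) b y² − Π̃),

which is thermodynamically consistent with the pressure through the exact
Widom/Gibbs–Duhem identity

    Π̃(φ) = φ(1 − ln α) + ∫₀^φ ln α dφ'.

`pressure_from_alpha` applies that identity to *tabulated* α(φ) —
analytic or measured — using trapezoidal integration with a linear-in-φ
extension of ln α below the first tabulated point (exact to leading order
in density).  The integral form needs no numerical differentiation, which
keeps it stable on noisy Monte Carlo data.  On a 200-point grid to φ = 0.3
it recovers the SPT pressure to better than 0.1% for γ ∈ {2, 6, 11, 21}.

Charged rods use the identical expressions at γ* = 1 + L/D_eff and the
effective volume fraction φ_eff = ρ v_r(L, D_eff); reduced pressures are
quoted per effective rod volume in that case.

### Accuracy against simulation

The package's own Monte Carlo places the SPT free volume fraction above
the measured one, increasingly so with density: at γ = 11 the deviation is
+8.7% ± 0.8% already at φ = 0.05 (measured α = 0.2152 ± 0.0017 vs SPT
0.2340) and grows to roughly a factor of two by φ = 0.15; at γ = 6,
φ = 0.2 the measured −ln α = 5.66 ± 0.07 vs SPT's 4.94.  This is the
expected signature of SPT's third virial coefficient, which underestimates
the exact value for long rods (exact B₃/B₂², computed here by triple-overlap
Monte Carlo: 0.410 at γ = 6 and 0.305 at γ = 11, vs the SPT forms' 0.26 and
0.16).  Agreement is excellent in the B₂-dominated dilute regime and for
short rods (γ ≲ 3), which is also the regime the effective-diameter mapping
creates (γ* is small when D_eff ≫ D).  The benchmark test asserts a 5%
band and therefore documents this known deviation by failing at γ = 11 for
φ ≥ 0.05; the number triplets it prints are the measured deviations.

## Simulation machinery

*Geometry.*  Minimum segment–segment distance by the clamped closest-point
algorithm: solve the unconstrained 2-parameter problem, then clamp and
re-minimise alternately in both orders and keep the closer pair.  Verified
against dense double-scan sampling to ≤ 10⁻³ D (typical agreement 10⁻⁸).
Periodic boundaries by minimum image on the center separation; validity
requires every box edge ≥ 2(L + reach), enforced before any run.  Neighbor
pruning keeps rods whose *trial-position* center distance is below
reach + L — a superset of true neighbors by the triangle inequality.

*Monte Carlo.*  Metropolis with single-rod translations (uniform cube,
tunable size), small rotations (uniform angle about a random axis, tunable)
and occasional full reorientations (default 20% of rotation trials; a
symmetric proposal that decorrelates orientations much faster than small
steps).  Acceptance is tuned into (0.3, 0.4) during equilibration only;
tuning saturates at configured caps in dilute systems.  The total energy is
cached and updated incrementally; periodic audits recompute it from scratch
and fail the run on > 10⁻⁸ drift or any non-finite value.  The 1/sinθ
divergence of the potential for parallel rods is floored at sinθ = 10⁻⁶
(recorded in run metadata) so aligned states have finite, relaxable energy.

*Initialisation.*  Two protocols: (i) the aligned-expansion protocol —
dense aligned lattice start, relax to isotropic (guarded by a nematic-order
threshold), then stepwise affine box expansion with re-equilibration;
(ii) random sequential insertion (RSA) of rods at the target density
followed by equilibration.  Relaxing global alignment proceeds by slow
rotational diffusion and takes many thousands of sweeps at working
densities, so the benchmark studies use the RSA route and pay the long
orientational equilibration once at the highest density (1200–1500 sweeps
at N = 256; measured insertion probabilities are stationary from ≈600
sweeps over runs four times longer).  Production sampling uses fixed move
sizes with snapshots every 10–25 sweeps.

*Insertion estimators.*  α_eff counts trial rods whose axis keeps distance
≥ D_eff from all system rods; α_ref averages e^{−ΔŨ} with the actual
truncated-shifted energy (hard overlap ⇒ 0).  Both run on the same trial
stream, so the A' = 0, D_eff = D case is identical term by term.  Errors
are between-configuration standard errors of per-snapshot means; the
≥10-successes reliability flag is applied at reporting, not estimation.

## Study problem sizes

Test-scale studies use N = 256 rods for the hard-rod benchmark (γ = 11,
φ ≤ 0.2, ~2·10⁴–10⁵ insertions per snapshot, 10–20 snapshots per density)
and N = 110 rods for the charged-rod accuracy trends (L/D = 5,
(A, κD) = (16, 0.5), cutoffs d_c/D ∈ {4, 8}, effective volume fractions
0.06–0.13 where α ∈ [0.2, 0.6]).  The full-size configuration (N = 1352,
L/D + 1 = 11, all published (A, κD) sets) passes the dry-run geometric
validation and runs through the same code paths.

## What the generator does and does not emulate

The synthetic configurations are equilibrium (or RSA-then-equilibrated)
states of the exact model above: monodisperse, rigid, uniformly charged
rods with pairwise screened repulsion and fixed κ.  Real suspensions add
polydispersity, flexibility, charge regulation and rod-contributed
screening; passing tests therefore validate the theory ↔ simulation loop
for the model, not those extra effects.

## Known limitations

- SPT α is quantitatively reliable only at low density or small effective
  aspect ratio (see accuracy section); the package reports, rather than
  hides, this.
- The effective-diameter mapping is second-virial-level; its error grows
  with density and with D_eff/D, which the trend studies measure.
- Widom insertion loses statistical power when α ≲ 10⁻⁵; estimates below
  ten successes are flagged unreliable.
- The isotropic-phase assumption is not checked against the true
  isotropic–nematic boundary; the nematic order parameter is monitored and
  studies stay well below ordering densities.
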