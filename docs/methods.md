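# Methods

## Proximal 1D model

Each of the 27 proximal vessels (geometry in `pulmuq/data/network_default.csv`)
solves mass conservation and momentum balance for cross-sectional area
A(x,t), flow q(x,t) and transmural pressure p(x,t) in CGS units, with blood
density ρ = 1.055 g/cm³, kinematic viscosity ν = 3.03×10⁻² cm²/s and a
power-law velocity profile of exponent γ = 9 (blunt core, no slip at the
wall; advection prefactor (γ+2)/(γ+1) = 1.1, friction −2πν(γ+2)q/A).  The
wall is thin, homogeneous and linearly elastic,
p = (4/3)K(√(A/A₀) − 1) with K = Eh/r₀ constant per side (K_A for all
arteries, K_V for all veins).  The axial coordinate of every vessel runs in
the direction of mean flow, so venous x = 0 faces the microvascular bed and
venous x = L the left atrium; the structural parent/daughter table columns
are adjacency, not flow direction.

### Discretization

Richtmyer two-step Lax–Wendroff on the conservative flux
F = (q, (γ+2)/(γ+1)q²/A + B(A)/ρ) with B(A) = (f/3)A^{3/2}/√A₀, f = 4K/3,
which makes the pressure-gradient term exactly conservative inside a
uniform vessel; wave speed c² = (2K/3ρ)√(A/A₀).  Each vessel uses
n = max(3, round(L/Δx)+1) nodes with per-vessel Δx so endpoints land on
nodes.  Default Δx = 0.125 cm with Δt ≈ 1.04×10⁻⁴ s; ensemble studies use
Δx = 0.25 cm with Δt ≈ 2.1×10⁻⁴ s (a deliberate problem-size choice for
large ensembles — the dt-halving self-convergence test bounds the
difference at < 0.5 % RMS on the inlet pressure trace).  Δt is rounded so
one cardiac cycle holds a whole multiple of the admittance-kernel sample
count.  The CFL number is monitored every step and the run aborts above 1.

### Boundary closures

All physical and junction boundaries combine the outgoing Riemann
invariant W± = u ± 4c — extrapolated from the characteristic foot and
advanced by the friction source d(W±)/dt = −2πν(γ+2)u/A (omitting the
source biases steady pressure drops at first order in Δx) — with the
constraint of the boundary:

* MPA inlet: prescribed q(t); area from W−.
* Junctions: flow conservation and static-pressure continuity (the model
  equations equate static pressure at junctions; a total-pressure variant
  is not implemented).  A damped 3×3 Newton solves the three end areas;
  the single-vessel side of each junction then balances mass exactly, so
  the junction mass defect is zero to rounding.
* Venous outlets: prescribed left-atrial pressure at x = L; flow from W+.
* Terminal pairs: the convolution of the bed's admittance kernels with the
  pressure histories at the terminal artery outlet and paired vein inlet.
  The zero-lag own-port tap is folded implicitly into the boundary Newton
  (an explicit tap is unconditionally unstable here); the zero-lag
  cross-port tap lags one Δt; all older taps read a ring buffer of the
  last cycle's pressures.

### Initialization and convergence

Veins start at the mean LA pressure and arteries at that plus mean inflow
times the parallel DC resistance of the beds, with q = 0; this initial
state only shortens the transient.  Cycles repeat until the maximum
pressure change at the inlet vessel between consecutive cycles is
≤ 1 dyn/cm² (≈ 0.00075 mmHg); typical counts are 6–70 cycles across the
prior box.

## Structured-tree beds

Radii follow r_ij = αⁱβʲ·r_root from the attached terminal artery's radius;
branching stops when r < r_min, and every terminal arteriole crosses to a
venous mirror tree with identical radii node-for-node and lengths
ℓ_rr^V·r instead of ℓ_rr^A·r.  (The alternative reading — venous radii
regenerated from the proximal venous radius — is not modelled; the
venous root radius is recorded but unused.)  Small-vessel flow is linear
and periodic: per harmonic ω_k = 2πk/T each vessel is a symmetric 2×2
admittance (into-port convention) with Womersley factor
F_J = 2J₁(w₀)/(w₀J₀(w₀)), w₀ = i^{3/2} r₀√(ωρ/μ), compliance
C = (3/2)πr₀²/K_ST and wave speed c = √(πr₀²(1−F_J)/(ρC)); the ω → 0 limit
is the Poiseuille matrix.  The apparent viscosity follows the empirical
in-vitro law η_rel(d) = 220e^{−1.3d} + 3.2 − 2.44e^{−0.06d^{0.645}}
(d in µm) scaled by plasma viscosity 0.01 g/cm/s.

Subtree admittance depends only on (i, j), so condensation is memoized on
index pairs: terminals are artery∘vein series two-ports, siblings add in
full parallel, and a parent wraps the combined load between its artery and
vein segments (interior pressure nodes eliminated exactly).  A projected
node count above 10⁶ raises an error suggesting a larger r_min.  If
sin(ωL/c) vanishes at some harmonic (resonance), that frequency is
perturbed by one part in 10⁹ and the condensation retried.

Kernels are the inverse DFT of the Hermitian-extended grand admittance
(Nyquist forced real); the spectral grid defaults to 512 harmonics
(1024 kernel samples per period).

Distal pathway reconstruction walks the α-only or β-only branch sequences:
at each junction a 2×2 nodal solve gives the interior arterial/venous port
pressures from the parent segment admittances and the condensed daughter
loads, and per-vessel mean pressure/flow, Poiseuille WSS
4μQ̄/(πR̄³) (R̄ pressure-dilated through the linear wall law
R = r₀(1 + 3p/(4K_ST))) and cyclic stretch (from the full reconstructed
p(t), all harmonics) are tabulated.  Ensemble profiles are pooled on a
normalized distance-from-termination coordinate (0 = smallest vessel,
1 = bed root) because r_min — hence pathway length — varies per sample.

## Quantities of interest

At proximal vessel midpoints: WSS(t) = μŪ(γ+2)/R with Ū = q/A and
R = √(A/π); CS = (R_max − R_min)/R_min; wave intensity by characteristic
splitting of successive differences, dP± = (dP ± ρc dU)/2,
dI± = ±(dP±)²/(ρc), classified FCW/FEW/BCW/BEW by the sign of the
pressure increment in each direction.  No smoothing is applied to the
increments, and intensities are per-sample dP·dU products without a dt
normalization — integrated energies are therefore shape-level quantities
meant for relative comparison, not absolute W/cm² values.  The wave speed
comes from the wall law (exact within the model) rather than a PU-loop
estimate.

## Uncertainty quantification

The eight parameters (K_A, K_ST, K_V, α, β, ℓ_rr^A, ℓ_rr^V, r_min) have
independent uniform priors (bounds in `pulmuq.pce.DEFAULT_BOUNDS`) mapped
affinely to [−1,1]⁸.  Surrogates use orthonormal Legendre polynomials of
total degree ≤ K fitted pointwise by ordinary least squares on a plain
pseudo-random uniform design (Latin hypercube available by flag); in the
orthonormal convention all normalization factors γ_j are 1, so the mean is
c₀, the variance Σ_{j≥1}c_j², and Sobol' indices are coefficient
sums-of-squares over the multi-index support sets.  Time-resolved indices
are aggregated as variance-weighted integrals (generalized Sobol' indices)
reported at end-cycle.  The reference study design is K = 4 with 2000
training and 100 validation samples; the test suite and acceptance script
run reduced designs (K ≤ 2, 64–72 samples) sized for a single CPU.
Fits warn when N < 2·#basis and fail on rank deficiency; zero-variance
output points are masked.

## Synthetic boundary waveforms

The reference inflow/LA signals are not distributed, so the generator
emulates them parametrically: a half-sine ejection of stroke volume 70 cm³
over 40 % of a T = 0.85 s cycle with a 2 % backflow lobe (cardiac output
≈ 4.9 L/min), and LA pressure 8 mmHg baseline with 3 mmHg a-wave (0.9 T)
and 2 mmHg v-wave (0.5 T) Gaussian bumps, widths 5 % of T — adult resting
values in the pulmonary-capillary-wedge range.  The pulse is circularly
Gaussian-smoothed (σ = 0.5 % of T), which preserves the stroke volume
exactly.  These stand-ins reproduce the physiological operating point but
not the detailed harmonic content of measured data: in particular the
synthetic ejection carries a smaller pulse amplitude than typical MRI
inflow (no steep upstroke, no notch, no diastolic flow), so
pulse-pressure-derived quantities such as proximal cyclic stretch sit at
the low end of published ranges (≈ 2 % here at the prior midpoint), and
ensemble statistics that depend on absolute flow magnitude should be read
as scaled-down reproductions.  Passing tests establish internal
consistency of the model and pipeline, not agreement with any subject's
recorded waveforms.

## Numerical choices and degenerate inputs

Newton solves use analytic Jacobians, positivity clamps (A ≥ 0.05A₀) and a
bisection fallback at the coupled terminal boundaries; tolerances are
10⁻¹¹–10⁻¹² relative with machine-noise floors where u = W ∓ 4c cancels
catastrophically at near-zero flow.  Junction mass balance is exact by
construction.  Degenerate networks (a single vessel acting as both inlet
and outlet) are supported for verification; trees degenerate to a root
with two terminal daughters when r_min ≥ α·r_root.  Ensemble failures
(CFL, non-convergence) are caught per sample, reported, and excluded from
regression with a warning above 2 %.

## Known limitations

Rigid-wall viscoelasticity, vessel taper, gravity/zone effects, capillary
sheet mechanics and collapsible venous tubes are outside the model.  The
venous mirror tree shares arterial radii (no taper toward the larger
proximal venous radius).  Boundary-condition uncertainty (inflow shape, LA
pressure) is not part of the prior.  Sensitivity conclusions rest on
variance-based indices under independent uniform priors.
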