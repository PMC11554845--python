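# pulmuq

Multiscale hemodynamics of the pulmonary circulation with uncertainty
quantification: a nonlinear 1D pulse-wave model of the proximal pulmonary
arteries and veins, coupled through structured-tree models of the
microvascular beds, with polynomial-chaos emulation and variance-based
(Sobol') sensitivity analysis of pressure, flow, wall shear stress (WSS),
cyclic stretch (CS) and wave-intensity quantities.

The package is aimed at cardiovascular modellers studying pulmonary
hypertension — in particular group II PH, where both the arterial and the
venous side matter — and at experimentalists who need physiologic ranges of
mechanobiological stimuli (WSS, CS) for in-vitro work.

## Model

**Proximal vessels** (15 arteries, 12 veins, strictly bifurcating): 1D mass
and momentum balance with a power-law velocity profile (γ = 9),

    A_t + q_x = 0,
    q_t + (γ+2)/(γ+1) (q²/A)_x + (A/ρ) p_x = −2πν(γ+2) q/A,

closed by a linearly elastic wall law p = (4/3)(Eh/r₀)(√(A/A₀) − 1), with a
single stiffness K_A = Eh/r₀ for all arteries and K_V for all veins.  The
system is advanced by the Richtmyer two-step Lax–Wendroff scheme to a
periodic steady state (beat-to-beat pressure error ≤ 1 dyn/cm²).

**Distal beds**: each terminal artery feeds a self-similar tree with radii
r_ij = αⁱ βʲ r_root, lengths ℓ_rr·r, terminated at r_min, mirrored by a
venous tree that drains into the paired vein.  Small-vessel flow is linear
(Womersley) with the radius-dependent apparent viscosity of blood; each
vessel is a 2×2 frequency-domain admittance and the whole bed condenses
recursively into one "grand" admittance per harmonic.  Its inverse Fourier
transform gives real periodic kernels used as convolution boundary
conditions by the time-domain solver.

**Boundary data**: a periodic MPA inflow and a left-atrial pressure
waveform.  Since the reference signals are not distributed, the package
generates parametric stand-ins (half-sine ejection, a-/v-wave atrial bumps;
defaults give cardiac output ≈ 4.9 L/min and LA pressure ≈ 8 mmHg).

**Uncertainty**: eight parameters θ = (K_A, K_ST, K_V, α, β, ℓ_rr^A,
ℓ_rr^V, r_min) carry independent uniform priors.  Model outputs are expanded
in orthonormal Legendre chaos fitted by ordinary least squares; means,
variances, validation error, first/second/total Sobol' indices and their
variance-weighted (generalized) time aggregates come directly from the
coefficients.

## Worked example

```python
from pulmuq import default_network, mpa_inflow, la_pressure
from pulmuq.structured_tree import SpectralGrid, TreeParameters, \
    generate_tree_index, grand_admittance
from pulmuq.solver import SolverConfig, run_simulation
from pulmuq.qoi import qoi_table

net = default_network()                      # 15 arteries + 12 veins
grid = SpectralGrid(T=0.85, n_modes=512)
beds = {}
for artery, vein in net.terminal_pairs:      # 8 two-sided beds
    p = TreeParameters(root_radius=net[artery].radius)
    beds[artery] = grand_admittance(generate_tree_index(p), p, grid)

field = run_simulation(net, beds, mpa_inflow(0.85), la_pressure(0.85),
                       SolverConfig(dx=0.25, dt_target=2.05e-4))
print(field.n_cycles)                        # 14  (cycles to periodicity)
print(qoi_table(field).set_index("vessel").loc["MPA"].round(2))
```

prints (prior-midpoint parameters, coarse grid):

```
mean_p_mmHg      18.48
sys_p_mmHg       28.19
dia_p_mmHg       10.18
mean_q           80.71
cs                0.02
mean_wss          3.35
peak_wss         13.35
FCW            1839.40
FEW            1947.91
BCW             275.98
BEW             321.74
```

i.e. MPA pressure 28/10 (mean 18.5) mmHg at a mean flow of 80.7 cm³/s —
normal adult pulmonary hemodynamics — with a cyclic stretch of 2 %, mean
midpoint wall shear of 3.4 dyn/cm², and the time-integrated energies of
the four wave types (forward/backward compression/expansion) dominated by
the forward waves, as expected for a normotensive pulmonary tree.

The same pipeline scales to full studies from the shell:

```bash
pulmuq synth --out-dir waves/          # write the boundary waveforms
pulmuq simulate --out run.h5           # one simulation + QoI table
pulmuq ensemble study.yml              # cached prior ensemble
pulmuq sobol study.yml                 # PCE + generalized Sobol' indices
pulmuq report study_out/               # digest of a finished study
```

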