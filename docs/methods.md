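# Methods

`pulmo1d` simulates pulse-wave propagation in a bifurcating pulmonary
arterial tree, calibrates its outflow boundary conditions to sparse
per-subject measurements, and computes wall-shear physiomarkers used to
characterize chronic thromboembolic pulmonary hypertension (CTEPH). This
note records the model, the numerical choices, what the synthetic data
emulate, and the limits of both.

## Governing equations

Each vessel is a straight, impermeable, tapered cylinder carrying
axisymmetric, incompressible, Newtonian, laminar flow. With axial
coordinate x (cm), time t (s), cross-sectional area A(x,t) (cm²),
volumetric flow Q(x,t) (mL/s) and transmural pressure P(x,t), the 1D
mass and momentum balances are

    ∂A/∂t + ∂Q/∂x = 0
    ∂Q/∂t + (γ+2)/(γ+1) ∂/∂x(Q²/A) + (A/ρ) ∂P/∂x = −2πμ(γ+2)/ρ · Q/A

with blood density ρ = 1.03 g/mL and viscosity μ = 0.03 P held constant.
The convective coefficient and the friction term follow from the assumed
power-law axial velocity profile

    u(r) = Ū (γ+2)/γ (1 − (r/R)^γ),   Ū = Q/A,

whose exponent γ controls the bluntness of the core: γ = 2 is Poiseuille
flow, larger γ flattens the profile. γ = 5 is the package default, the
value that best matches sector-averaged radial velocity samples of the
kind extracted from 2D phase-contrast MR images (the `fit_gamma`
routine reproduces that selection on synthetic samples).

The system is closed by a thin-walled, linearly elastic tube law

    P(A) = (4/3) K (√(A/A_dia) − 1) + P_dia,      K = Eh/r₀,

anchored at the measured diastolic state (A_dia, P_dia). K (mmHg) lumps
Young's modulus, wall thickness and reference radius into one stiffness;
given paired systolic/diastolic pressure and area at the main pulmonary
artery (MPA) it follows analytically,
K = (3/4)(P_sys − P_dia)/(√(A_sys/A_dia) − 1), and the package applies
one K network-wide per subject-condition (per-vessel overrides are
possible through the network file). The associated pulse-wave speed is
c(A) = √((2K_cgs/3ρ)·√(A/A_dia)). Pressures below the collapse bound
P_dia − (4/3)K, where the linear law loses a physical area, raise an
error rather than being modeled.

## Boundary conditions

The measured MPA flow waveform drives the inlet. Bifurcations enforce
flow conservation Q_p = Q_d1 + Q_d2 and pressure continuity
P_p = P_d1 = P_d2. Every terminal vessel drains into a three-element
Windkessel (WK3): proximal resistance R_P, distal resistance R_D,
compliance C, discharging toward a reference pressure set to the wedge
pressure P_PCW. Nominal values per terminal i:

* R_T(i) = (P_mean − P_PCW)/Q̄_i with Q̄_i from the Poiseuille split
  Q̄_i = F_i/(F_i+F_j)·Q̄_p, F = πr₀⁴/(8μL) (length-averaged radius);
  initially R_P = R_D = R_T/2;
* C_total = t_decay / (R_T,total · ln((P_sys−P_PCW)/(P_dia−P_PCW))),
  the exponential-decay fit over the diastolic window t_decay (taken as
  the non-systolic fraction of the cycle and carried with the record);
* C_total distributed over terminals ∝ 1/R_T(i), which keeps all
  terminal time constants equal — consistent with the single observed
  decay constant.

Totals obey the parallel-circuit identities. For obstructed (CTEPH)
records the left-lung flow is recomputed as Q̃_LPA(t) = Q_MPA − Q_RPA
(left-side imaging is unreliable under obstruction) and the nominal
left/right split is rebalanced from the measured per-side mean flows.

## Numerical scheme

Richtmyer two-step Lax–Wendroff on the conservative form, in CGS. The
pressure-gradient term is carried as a flux potential
B = (4K/9ρ)·A^{3/2}/√A₀(x) plus a geometric source ∝ dA₀/dx for tapered
vessels; the discrete dA₀/dx are finite differences of the nodal A₀,
which makes the rest state (A = A₀, Q = 0) an exact discrete
equilibrium. Defaults: Δx = 0.125 cm, Δt = 1e-4 s reduced automatically
to satisfy a Courant number of 0.5 (halving down to a floor on observed
violations); coarse analyses use Δx = 0.25 cm, Δt = 2e-4 s. Cycles
repeat until the relative least-square difference between consecutive
pressure cycles falls below 1e-8 (default).

Boundary and junction nodes are closed with half-cell continuity: the
boundary area is updated from the adjacent half-step (midpoint) flux and
the trapezoidal average of the boundary flow, making the boundary area a
linear function of the unknown boundary flow; the remaining relations
are physical (prescribed inlet flow; junction mass + pressure
continuity, solved as a 2×2 Newton on the daughter flows; the WK3 ODE,
integrated with implicit Euler, as a scalar Newton). An earlier
characteristic-compatibility closure was accurate pointwise but leaked
mass at O(Δx) per cycle; the half-cell closure imposes the coupling
conditions on the same trapezoidal fluxes that move mass, so the cyclic
balance between inflow and summed outflow volumes is limited only by how
deeply the periodic state is converged (≈3e-5 relative at the default
tolerance). Newton tolerances are scaled to the natural magnitudes
(pressure level, A·c for flows) — absolute tolerances below the rounding
noise of the invariant products never converge.

The kernel is compiled with numba (cached); a converged coarse solve of
a 15-vessel tree takes O(1 s) on one core, which is what makes
multi-start calibration and the cohort study tractable.

## Calibration

Scarce data cannot identify every Windkessel element, so all terminals
share one scaling triple θ_wk = (r_P, r_D, c) applied to the nominal
set. The cost matches model output to the calibration set
{P_sys, P_dia, A_sys, A_dia, Q_LPA(t), Q_RPA(t)} (Q̃_LPA for CTEPH):

    S(θ) = w_P Σ_j (P_j^c − P_j(θ))² + w_A Σ_j (A_j^c − A_j(θ))²
         + w_Q (1/N) Σ_k Σ_i (Q_k^c(t_i) − Q_k(t_i;θ))²

with scalars read at the MPA midplane (systolic = cycle max, diastolic =
end-diastolic value — robust to the early-diastolic dip under a
reverse-flow notch) and flows at the LPA/RPA inlet planes, just distal
to the bifurcation, where phase-contrast planes are placed; this also
keeps the obstructed-record surrogate Q_MPA − Q_RPA (exact only at the
junction itself) close to the left-side flow it stands in for. The default
weights normalize each block by the squared magnitude of its data; the
literal unit-weight form is available (`weights="unit"`). Optimization:
trust-region least squares in log10 θ (positivity built in) from ten
log-uniform draws in [0.1, 10]³, each start stopping when the parameters
change by less than 1e-6; the finite-difference step is 2% — smaller
steps drown in the noise left by the cycle-periodicity tolerance.
Forward solves warm-start from the previous converged state; a failed
solve returns a large penalty so the optimizer survives infeasible
corners. The result records all starts and whether they agree to 1e-3
relative spread.

## Shear physiomarkers

Signed wall shear τ = sign(Q)·μ(γ+2)|Q/A|/R with R = √(A/π) — the wall
derivative of the power-law profile carrying the flow direction. Per
node over one period: TAWSS = (1/T)∫|τ|dt and
OSI = ½(1 − |∫τ dt| / ∫|τ|dt) ∈ [0, 0.5] (0 unidirectional, 0.5
zero-mean; identically zero shear reports OSI 0 with a warning). Both
are trapezoidal quadratures on the solver grid; per-vessel values are
length averages. τ ∝ (γ+2) at fixed flow, so re-evaluating shear from
one state across γ rescales TAWSS exactly by (γ′+2)/(γ+2) and leaves
OSI unchanged.

The network physiomarker φ is the percentage of in-scope vessels with
both TAWSS < 5 dyne/cm² (literature low-shear cutoff) and OSI > 0.05
(a cohort-average-derived cutoff, fixed as configuration here, not
recomputed). Scope defaults to intralobar vessels, counted per vessel;
length-weighting and whole-network scope are options.

## Synthetic subjects

No measured data ship with the package; a generator emulates the paired
study design at canine scale (≈12 kg animal):

* trees of 2^g − 1 vessels (default g = 4), MPA radius ≈ 0.7 cm, child
  radii shrinking by ≈0.79·taper per generation, length ≈ 5 radii;
  seeded multiplicative radius and length jitter emulate the anatomic
  spread of segmented networks — this spread, not the mean level, is
  what produces the low-flow, low-TAWSS, oscillatory branches that φ
  counts, and because it lives in the observable geometry the calibrated
  model retains it (hidden outflow-bed heterogeneity, available as
  `bed_jitter`, is invisible to a three-parameter calibration and is off
  by default);
* inlet flow: half-sine ejection over 40% of a 0.5 s cycle, 20 mL
  stroke volume (mean ≈ 40 mL/s), optional early-diastolic reverse
  notch; the cohort baseline uses a 5% reverse fraction, consistent
  with mild pulmonary regurgitation seen in MRI flow data;
* baseline design targets: P_sys/P_dia = 20/12 mmHg, P_PCW = 5 mmHg,
  K = 40 mmHg; the truth Windkessels are built from these targets (the
  truth compliance uses the R_D-based decay constant, since the WK3
  capacitor discharges through R_D) and then held fixed while the
  tube-law diastolic reference is anchored to the model's own output by
  fixed-point iteration. At the fixed point the record is exactly
  self-consistent: the calibration pipeline's reconstruction (analytic
  K, diastolic anchoring, nominal Windkessels) reproduces the truth
  model at the implied scaling triple reported as `theta_truth`, which
  is therefore an exact recovery target for noiseless baseline records.
  The CTEPH left/right resistance ratio is not representable by one
  global triple (as in reality), so exact recovery is asserted for
  baseline only;
* the CTEPH transform multiplies R_P ×2.0 and R_D ×4.1 network-wide
  with an extra left-lung R_D factor 1.25, compliance ×0.45, stiffness
  ×1.6, stroke volume ×0.67, and raises the waveform reverse fraction
  to 0.18 — together these land the defining disease physiology (mPAP
  rising from ≈14 to ≈25–28 mmHg, a left-share flow drop, wall
  stiffening, TAWSS falling in extralobar and intralobar vessels, φ
  rising). The global resistance rise and cardiac-output drop are
  essential: a purely left-sided obstruction raises right-lung flow
  enough to *increase* RPA shear, and without the stronger diseased
  notch (backflow fractions of 15–30% are reported in severe pulmonary
  hypertension) distal OSI stays near zero and φ degenerates;
* measurement emulation: scalars at the MPA midplane, branch flows at
  the LPA/RPA midplanes resampled to 32 frames/cycle (the truth model is
  driven by the same 32-frame waveform the record carries); additive
  seeded Gaussian noise (fraction of signal scale) applied last.
* the default cohort draws 5 subjects with seeded between-subject
  variation in size, rate, stroke volume, stiffness and transform
  severity.

What passing the cohort tests shows — and does not show: the pipeline
recovers known generating parameters and reproduces the qualitative
paired disease pattern under its own modeling assumptions (1D,
power-law profile, linear wall, lumped outflow, additive noise). It
does not validate those assumptions against animals or patients, nor
calibrate against image-derived geometry, secondary flows, or
respiratory effects.

## Statistics

Disease effects across the paired cohort use one-sided paired t-tests
(t = d̄/(s_d/√n), n−1 degrees of freedom) with a-priori directions per
output (pressures, resistances, stiffness and φ up; compliance and
TAWSS down); p-values are reported to 4 decimals with no
multiple-testing correction. Zero-variance differences degenerate with
a warning. Progression analysis correlates per-subject relative changes
(CTEPH − baseline)/baseline between outputs (Pearson), flags |r| > 0.8,
and drops near-zero-variance columns (e.g. shear-direction metrics that
are essentially zero everywhere) with a logged note.

## Known limitations

1D axisymmetric flow with a fixed profile exponent: no secondary flows,
separation or recirculation, so OSI is likely biased low; γ fixed at 5
network-wide overestimates shear in small, low-Womersley vessels. The
linear tube law has no collapse behavior and a single stiffness per
condition. Synthetic trees are binary with two-way junctions only; no
anastomoses. Calibration identifiability of the compliance factor is
weak when the diastolic decay nearly completes within the cycle. The
cyclic mass balance is limited by the periodicity tolerance, not by the
scheme.

The global compliance factor c is the most weakly identified calibration
parameter: the two measured branch flows are constrained to sum to the
prescribed inlet flow, so a network-wide compliance change acts on the
data mainly through pulse pressure, and at baseline stiffness the vessel
walls — not the outlet capacitors — dominate the pulse-storage balance.
Noiseless records pin c exactly (the cost has a clean minimum), but
under flow-measurement noise its recovery error varies widely between
noise realizations, while the resistance factors stay within a few
percent. Conclusions that lean on the absolute calibrated compliance
should carry that caveat; the disease-direction statistics do not (the
compliance drop is carried primarily by the nominal re-parameterization
between conditions).
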