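# Methods

This note records the models, estimators and numerical choices behind
`fastwater`, in the order of the processing chain. Units throughout:
g/mol (mass), nm (length), ps/ns (time; integration steps in fs),
kJ/mol (energy), K (temperature); k_B = 0.0083144621 kJ/(mol K).

## Mass repartitioning and rescaling

A 3-site water with site masses (m_O, m_H, m_H), total M_0 = m_O + 2 m_H,
is modified in two steps. Repartitioning moves a mass m_r from oxygen to
the hydrogens symmetrically (m_O − m_r, m_H + m_r/2): this slows the
fastest librational modes and stabilises integration at fixed time step.
Rescaling multiplies all sites by m_tot/M_0 so the molecular mass becomes
m_tot. Classical configuration-space averages are independent of masses,
so every structural and thermodynamic property is preserved exactly;
dynamically, scaling all masses by f² is equivalent to scaling time by f,
so viscosity scales as √(m_tot/M_0) and self-diffusion as √(M_0/m_tot).

**Published rounding.** Site masses are kept at full precision
internally. `WaterModelMasses.published(decimals=3)` rounds the hydrogen
mass and assigns the oxygen the exact remainder m_tot − 2 m_H, so the
published triple still sums to the target total — a topology built from
naively per-site-rounded masses would carry a slightly wrong molecular
mass. For the default fast model (m_r = 4, m_tot = 1.116) this yields
(0.744, 0.186, 0.186).

**Topology editing** operates on GROMACS TOP/ITP text. The water
moleculetype is located by name; atoms are identified positionally
(atom 1 = O) following the rigid-water block convention, not by element
parsing. Only the 8th whitespace-delimited field (mass) of the three
atom lines is rewritten; all other bytes are preserved and the edit is
idempotent. Virtual-site/4-site waters are out of scope: the two-step
algebra above is defined for 3 sites.

## Crash-rate kinetics

Integration failures are modelled as a Poisson process; replica
outcomes form a censored-exponential sample (crash at t_i, or intact end
at t_i). The ML rate is k = n_crash / Σ t_i with the sum over all
replicas. The standard error is the Cramér–Rao bound of this likelihood,
k/√n_crash. With zero crashes the SE is undefined; the estimate reports
k = 0 with the one-sided 95% bound ln(20)/Σ t_i instead. Rates are
optionally normalised to per (ns × 1000 molecules).

The mass dependence ln k = ln A − c·m_tot is fitted by weighted linear
least squares in log space (σ_ln k = se/k = 1/√n_crash); fitting in log
space keeps the problem well conditioned over many decades of rate.
Zero-rate points carry no log-space information and are dropped with a
warning. Inverting the fit at a target rate gives the iso-stability mass
m_tot(k) = (ln A − ln k)/c; a family over m_r traces the contour used to
pick the fastest-diffusing stable model. A fitted |c| below 1e−12 is
treated as flat (no solution).

Note the MLE of a censored-exponential rate carries a genuine positive
O(1/E[n_crash]) bias (≈1.5e−3 at k = 0.1/ns, n = 40, t_end = 5 ns); the
Monte-Carlo calibration tests budget 3 standard errors of the mean for
this.

## Diffusion from wrapped NPT trajectories

**Unwrapping.** Continuous coordinates are rebuilt from displacements:
u_k = u_{k−1} + Δw − L_k·round(Δw/L_k), with Δw the raw frame-to-frame
displacement and L_k the box of the later frame. This is correct under
barostat box fluctuations, where image-counter unwrapping fails. Two
consequences are deliberate: (i) a corrected displacement reaching L/2
is ambiguous and triggers an aliasing warning; (ii) with a fluctuating
box, wrapping the unwrapped path back into the per-frame boxes does not
reproduce the input (the accumulated image offsets are sums of multiples
of *different* box lengths) — the exact inverse property holds only for
a constant box, and is tested there.

**MSD.** Time- and particle-averaged over all overlapping origins,
computed with the FFT + cumulative-sum decomposition (O(F log F) for all
lags). Default maximum lag is a quarter of the trajectory.

**GLS fit.** MSD(τ) = 2·dim·D·τ + b is fitted over lags ≥ t_min
(default 20 ps, at most 40 evenly subsampled lags) by generalized least
squares. The covariance of overlapping-origin MSD values for free
diffusion of independent Gaussian walkers is available in closed form:
with iid increments of variance σ² = 2DΔt, Isserlis' theorem gives
cov(msd_n, msd_m) = 2σ⁴ Σ_{k,l} overlap(k,l)² / (M_n M_m), where
overlap counts shared increments of the two windows; the double sum
collapses over the origin offset j = l−k to an O(F) expression per lag
pair. The covariance scale depends on D, so the fit is iterated (OLS
seed, two GLS reweightings). Q is the upper-tail χ² probability of the
weighted residual with n_lags − 2 degrees of freedom: uniform on [0, 1]
when the data are genuinely Brownian (mean ≈ 0.5), and exactly 1 for
noiseless input. If the covariance Cholesky fails, the fit falls back to
diagonally weighted least squares and flags `method="wls-diagonal"`;
this simplification replaces a bootstrap fallback because the analytic
diagonal is always available and the fallback is exercised only by
degenerate inputs. dim = 3 by default; dim = 2 supports the lateral
(membrane) case where MSD(τ) = 4Dτ.

**Finite-size extrapolation.** D(L) against 1/L is linear for a periodic
cubic box: D(L) = D_∞ − k_B T ξ/(6πηL), ξ = 2.837297. The straight-line
intercept gives D_∞ and the slope the shear viscosity
η = k_B T ξ/(6π|slope|), in kJ ns mol⁻¹ nm⁻³ (× 1.6605e−3 → Pa s).
A slope within 1e−10·max|D| of zero is reported as size-independent
diffusion with infinite viscosity rather than an absurd finite number.

**Equipartition diagnostics.** For rigid 3-site molecules, T_trs comes
from COM velocities (3N translational DOF) and T_rot from projecting
residual site velocities onto rigid-body rotation: angular momentum
about the COM, ω = I⁻¹L, and 2E_rot = ωᵀIω over 3N rotational DOF
(nonlinear rigid body). Collinear geometries make I singular and raise
an error. Divergence of the two temperatures diagnoses integrator
artifacts at effectively long time steps. The Maxwell–Boltzmann sampler
draws uniform orientations, COM velocities N(0, k_BT/m_tot) and
principal-axis angular velocities N(0, k_BT/I_a); the calibration test
uses 10 independent frames of 1e5 molecules (SE ≈ 0.24 K against a
±1 K check band).

## Synthetic generators

**Brownian system.** Independent particles take Gaussian steps of
variance 2DΔt per axis. The box edge follows a bounded AR(1) process
(φ = 0.9, relative amplitude clipped at 3σ) as a stand-in for barostat
volume fluctuations — only the unwrapping contract (correctness under a
fluctuating L) is emulated, not barostat physics, and the box motion is
uncoupled from particle motion. Steps are applied to the *wrapped*
coordinate and re-wrapped into the current box, so the retained
continuous path is exactly what displacement unwrapping must
reconstruct (verified to 1e−9). What this generator does not emulate:
hydrodynamic correlations between particles, momentum conservation,
ballistic short-time motion, and genuine barostat coupling — so passing
tests validate the estimator chain, not any claim about real water.

**Dihedral Langevin generator.** Overdamped dynamics on
U(θ) = Σ_j k_j cos(jθ − δ_j) (default: a symmetric double well,
2 kJ/mol·cos 2θ, minima at ±90°, 4 kJ/mol barrier ≈ 1.6 k_BT at 310 K)
with effective friction γ_eff = γ_floor + γ·√(mass_scale). The
stationary density ∝ exp(−βU) is friction-independent (the discrete
analogue of mass-independent configuration averages) while every
relaxation time is ∝ γ_eff, giving the √mass scaling law, and a
positive γ_floor produces the τ = a + b√m internal-friction shape.
Initial angles are rejection-sampled from the exact stationary density,
so series are stationary from frame one.

Integration uses the Leimkuhler–Matthews discretization (the Gaussian
increment is the average of two consecutive unit normals), which is
second-order accurate in the invariant measure. This matters: with
plain Euler–Maruyama at a common dt, the O(dt) stationary bias differs
across frictions and a large-sample KS test comparing mass scales would
detect the integrator, not the physics; conversely, scaling dt with
√mass under a shared seed makes the chains identical by construction
and the comparison vacuous. A common dt, LM updates and independent
seeds per mass scale keep the invariance test honest. The step must
satisfy dt ≤ 0.1·γ_eff/max|U″| (enforced); max|U″| = Σ|k_j|j².

## Collective-variable statistics

- **Linear ACF**: mean-subtracted, variance-normalized, FFT-based with
  unbiased per-lag normalization; ρ_0 = 1 exactly.
- **Dihedral ACF**: C(t) = ⟨cos(θ(t₀+t) − θ(t₀))⟩ via FFT correlations
  of cos θ and sin θ; decays to the squared circular resultant of the
  stationary distribution. `normalize="fluctuation"` subtracts that
  plateau and rescales to decay 1 → 0 (used for integrated times of
  series with anisotropic stationary distributions).
- **S_D²** is defined as the squared circular resultant
  ⟨cos θ⟩² + ⟨sin θ⟩², the standard circular order parameter: 1 for a
  delta-like distribution, 0 for uniform or antipodal ones. Other
  dihedral order-parameter conventions exist; this choice is flagged
  here because downstream numbers depend on it.
- **τ_int** = Δt·(½ + Σ_{k≤W} ρ_k) with the Sokal automatic window
  (smallest W ≥ c·τ_int(W)/Δt, c = 5 by default; a "first negative ρ"
  rule is selectable). With replicas, τ_int is the mean of per-replica
  estimates and the SE their standard deviation over √n_replicas —
  across-replica errors rather than single-series formulas, since
  replicas are genuinely independent.
- **τ_exp** from linear regression of ln C(t) over a user range, or by
  default the contiguous lags with C ∈ [0.05, 0.5]; SE by the delta
  method from the slope error.
- **Block SEM**: block sizes double while ≥ 32 blocks remain; the SEM
  curve rises to a plateau once blocks exceed the correlation time.
  The estimate averages the curve from the first block size whose
  increment falls below 5%, falling back to the largest block.
- **Free energies**: G_i = −k_BT ln p_i from equal-width histograms,
  shifted so min G = 0 (the histogram normalization constant is
  arbitrary, so only differences are meaningful); empty bins are masked
  NaN, not zero. Defaults: 72 × 5° bins for dihedrals,
  Freedman–Diaconis for distances. A 2D variant supports difference
  maps G_A − G_B on shared bins.
- **KS comparison**: correlated MD samples invalidate nominal KS
  p-values, so the distribution of the two-sample statistic itself is
  built from every unordered within-group replica pair and every
  cross-group pair (no subsampling). The overlap summary is the
  fraction of between-group statistics below the 95th percentile of the
  pooled within-group values: ≈ 1 under the null, ≈ 0 under a clear
  shift.
- **Internal-friction fit**: weighted LS of τ = a + b√m with weights
  1/se²; with stated SEs the covariance is the unscaled
  inverse-information matrix, otherwise residual-scaled.

## Problem sizes and tolerances in the test suite

Monte-Carlo checks use fixed seeds and sizes chosen so statistical
margins are a few times tighter than the asserted tolerances: 1000
censored crash datasets (k = 0.1/ns, n = 40, t_end = 5 ns); 200
Brownian seeds of 100 particles × 5000 frames (Q-mean band [0.4, 0.6],
per-seed 3·se coverage ≥ 99%); dihedral runs of 48 replicas × 3×10⁵
steps at dt = 0.0025 ps per mass scale (τ ratios within 10%, KS
p > 0.01 on ~5·τ_int-strided pools); AR(1) of 10⁶ samples for the
closed-form τ_int (5%). The full suite runs in about two minutes on one
CPU.

## Known limitations

- Only 3-site rigid waters; no solute (protein/lipid) mass
  repartitioning, no force-field parameter changes.
- The crash model implements only the exponential-in-mass
  approximation, not a microscopic collision model; contours are
  validated on synthetic fits.
- Orthorhombic boxes only; no velocity-autocorrelation/Green–Kubo
  viscosity; no membrane-specific finite-size corrections.
- The GLS covariance assumes free diffusion; for strongly subdiffusive
  or confined input the Q diagnostic loses its calibration.
- Synthetic generators validate estimators, not water models: none of
  the MD-derived numbers (diffusion coefficients, hydrogen-bond
  statistics, peptide relaxation times) can be reproduced without
  running MD.
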