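# Methods

## Model

The arm is a two-link planar manipulator moving in the horizontal plane
(shoulder angle θ₁ from the +x axis, elbow angle θ₂ relative to the upper
arm, no gravity term):

    τ = M(θ)·θ̈ + h₁(θ)[θ̇₁θ̇₂] + h₂(θ)[θ̇²] + B·θ̇

with inertia about the joints (M₁₁ = I₁ + I₂ + m₂(L₁² + 2L₁S₂cosθ₂),
M₁₂ = M₂₁ = I₂ + m₂L₁S₂cosθ₂, M₂₂ = I₂), Coriolis/centrifugal coefficient
a = m₂L₁S₂sinθ₂, and a symmetric joint-viscosity matrix B.  Movements are
planned as straight-path minimum-jerk reaches; measured (or simulated)
trajectories are reduced to this form by inverse kinematics.

**Time-normalisation.**  On s = t/D the shape of a reach is duration-free;
the equation of motion factorizes as τ(Ds) = (1/D²)·[inertial + interaction
terms] + (1/D)·B·θ̃′.  Replacing 1/D by λ/D² — λ chosen to minimize the
integrated squared residual over the duration range, λ = ∫D⁻³/∫D⁻⁴
(λ = 0.399 s for 0.30–0.70 s) — collapses the whole right side to
τ̃(s)/D², a duration-free *normalized torque*.  The approximation is exact
at D = λ; the relative residual |1 − λ/D| reaches 0.43 at the range edges,
which is the dominant model error at long durations.

**Signal-dependent noise.**  The executed torque is the commanded torque
plus Gaussian noise with standard deviation proportional to the command:
τᵢ_noise = kᵢ·|τᵢ|·zᵢ, with dimensionless per-joint gains kᵢ.  zᵢ is white
in normalized time, discretized on a fixed 101-point s-grid as
z = N(0,1)·√(s₀/Δs).  The reference step s₀ = 0.004 — one 500 Hz sample at
the centre duration 0.5 s — fixes the noise intensity so that (i) the
distribution of γ is independent of D and of grid resolution, making
W = γ/D exact in distribution, and (ii) gains of order 0.2–0.9 produce
millimetre-to-centimetre endpoint scatter on a 15 cm reach, the
physiological scale.  A per-sample real-time convention (under which
W ∝ D^(−3/2)) exists in the literature; k values are convention-dependent
and only comparable within one convention.

**Propagation to endpoint error.**  Linearizing the forward dynamics
around the noise-free movement, the position response to a torque impulse
is the viscous DC response B⁻¹; the endpoint error components are

    Δx(D) = (1/D)·Σᵢ kᵢ·αᵢˣ,  αᵢˣ = ∫₀¹ (Jˣ(θ̃)B⁻¹)ᵢ·|τ̃ᵢ(s)|·zᵢ(s) ds

(same for y with Jʸ; trapezoid quadrature on the s-grid; the same zᵢ
drives both integrals, producing correlated Δx, Δy), and
W = √(Δx²+Δy²) = γ/D.  The analytic endpoint covariance is
Σ = (s₀/D²)·Σᵢ kᵢ²·∫gᵢgᵢᵀτ̃ᵢ²ds with gᵢ the i-th column of [JˣB⁻¹; JʸB⁻¹].
The inertial row JˣM⁻¹ of the propagation matrix governs the velocity
error and does not enter W.

**Where the linearization is honest and where it is not.**  The B⁻¹
response is the *rest* displacement: after the command ends, the residual
joint velocity decays under Mθ̈ = −Bθ̇, carrying the hand a further
B⁻¹M(θ)θ̇ (the conserved quantity of the free decay).  The full simulation
therefore reports the settled endpoint (integration to D plus that
closed-form displacement), and the synthetic generator and the analysis
pipeline read endpoints after settling for the same reason.  Two residual
approximations remain: the propagation integral evaluates the Jacobian at
the time the noise occurs, whereas the true response maps the accumulated
joint displacement through the *final* posture — this distorts individual
covariance axes by tens of percent (up to ~70% on a near-degenerate minor
axis) while largely cancelling in the radial error W — and the
λ-substitution misweights the viscous share of the noise away from D = λ.
Empirically the full simulation's mean W agrees with γ̄/D within ~3–5% at
D = λ in all four directions, degrading to ~20–40% at D = 0.7; agreement
is flat (~3%) across gains k ∈ [0.1, 1.2] at the study's movement scale,
i.e. plant nonlinearity is subdominant to these two linearization choices.
A corollary worth knowing: at fixed gains the *simulated* mean error falls
more slowly than 1/D (the viscous noise contribution does not scale as
1/D²), so synthetic observed W̄(D) is flatter than the model curve.

**Interaction torques.**  Coriolis/centrifugal terms can be toggled off
(in inverse and forward dynamics together).  The effect on endpoint
scatter at the study's scale is direction-dependent — a few percent for
right/left reaches and up to ~25% for front reaches — because dropping the
interaction terms also removes their velocity-derivative, which acts as
configuration-dependent damping comparable to B/2.

## Parameters

| parameter | default | meaning |
|---|---|---|
| L₁, L₂ | subject-specific (reference means 0.282, 0.331 m) | link lengths |
| Sᵢ, mᵢ, Iᵢ | proportional to L via coefficients fit to the bundled 11-subject table | segment parameters; 0.740 kg air-sled added to m₂ |
| B | per-direction reference means (e.g. front [[0.690, 0.181], [0.181, 0.790]] kg·m²/s) | joint viscosity |
| k₁, k₂ | estimated (reference range ≈ 0.17–0.93) | signal-dependent noise gains |
| λ | 0.399 s (from the 0.30–0.70 s range) | duration-approximation coefficient |
| s₀ | 0.004 | noise reference step (see above) |
| c | harmonic mean of observed W, clamped to ≤ 2·min W | linearization centre; c = 2·min W saturates the validity bound W ≥ c/2 but makes the slope match worst-case (~34% vs ~6% for the harmonic rule) |
| filter | 3rd-order Butterworth, 10 Hz, forward–backward | position preprocessing (gain 0.5 at cut-off) |
| detection | 5% of peak tangential speed | onset/offset; on a minimum-jerk profile the detected duration is 0.8811 of the true one |
| integrator | RK4, dt = 1 ms | forward dynamics (torque supplied on the half-step grid, so RK4 stage times are exact nodes) |

The anthropometric coefficients are fit by relative least squares across
the bundled table; they reproduce each tabulated subject's S and m within
3% and I within 3.5% (the inertia columns are printed to three decimals).

## Noise-gain estimation

(k₁, k₂) are estimated by simulation-based inference: for each grid cell,
100 endpoints per (direction × duration-bin) condition are simulated
through the full nonlinear dynamics from the condition's trial-averaged
desired trajectory, and the 95% confidence ellipses (mean + covariance
eigendecomposition scaled by the χ²₂ quantile) of simulated and observed
endpoints are compared by the Ellipse Difference Index — the summed
distance between the four axis endpoints, pairing major↔major and
minor↔minor with the orientation that minimizes the sum (EDI is a
pseudometric: symmetric, non-negative, zero iff the ellipses coincide).
The total EDI over all conditions is minimized on a coarse grid
(default 0.05–1.20, step 0.05) with an optional 0.01-step refinement pass
around the coarse optimum.  Two implementation choices matter:

- **Common random numbers.** One noise stream per (seed, pass, condition),
  shared across grid cells, so the EDI surface is smooth in k and the
  argmin is not set by cell-to-cell Monte-Carlo jitter.  With independent
  per-cell streams the surface jitter (~0.02 on a total EDI of ~0.28)
  exceeds the curvature between neighbouring cells and recovery degrades
  by several grid steps.
- **Level-consistency.** The confidence level (default 0.95) scales both
  ellipses identically, so the argmin is insensitive to it.

On full-scale synthetic experiments (320 successful trials, 20 per
condition, k_true = (0.5, 0.7)) the grid search recovers both gains within
one 0.05 step for the fixed-seed test condition, and the recovery bias
across five seeds is ≤ 0.03 per component; single-seed excursions of two
steps in k₂ occur (the objective carries a shallow k₁–k₂ trade-off ridge).

## Synthetic experiments

The generator emulates the temporally constrained centre-out task: four
directions (right/front/left/back), 15 cm distance, duration windows
0.30–0.40 … 0.60–0.70 s, 500 Hz recording, start posture (45°, 100°),
20 successes per cell (320 in all), with per-trial attempts judged by the
same criteria the analysis applies (detected duration inside the window,
single-peaked speed profile).  Choices a real dataset would not expose:

- Subjects aim inside the window: target durations are drawn from the
  central half of each bin (full-bin-uniform targets make the window check
  selectively discard large-error trials, truncating the endpoint
  distributions the estimator must match).  Commanded durations are
  corrected for the 0.8811 detection shortening and quantized to the
  recording period.
- Measurement noise is 0.2 mm i.i.d. Gaussian per sample (optical
  digitizer scale); it is negligible against millimetre-scale endpoint
  scatter.
- Failed attempts are kept and flagged so rejection code paths run.
- The recorded series includes a 0.2 s pre-cue hold and a 1.2 s settle
  tail; the ground-truth endpoint error is the fully settled rest
  position (known gains, desired trajectories and true errors ship in a
  ground-truth bundle for recovery tests).

What passing recovery tests on these data do **not** show: robustness to
feedback corrections, trajectory variability beyond noise (the desired
path is exactly minimum-jerk), learning across trials, marker dropout, or
inter-subject variability in the noise gains.  Observed W̄(D) from the
generator is flatter than γ̄/D (see the corollary above), so Fitts'-law
fits of *synthetic observations* have unstable slopes; the Fitts'-law
correspondence is validated on the model curve itself.

## Problem sizes and numerical choices

The test suite and the bundled analyses use: 101-point normalized grids;
RK4 at 1 ms; 10⁵ draws for covariance oracles; 2000 trials for
linear-vs-full comparisons; n_sim = 100 per grid cell with a coarse window
0.30–0.90 at the standard 0.05 step for full-scale recovery; Rayleigh
and KS checks at n = 2000.  Ties in the grid argmin break toward smaller
k₁ then k₂; degenerate (collinear) observation groups are skipped with a
warning, and estimation fails only if every group is degenerate.
Reachability is enforced strictly inside the open workspace
(|L₁−L₂| < r < L₁+L₂); θ₂ = 0/π are kinematic singularities excluded by
construction.

## Known limitations

- The linear model's per-axis covariance is systematically distorted by
  the Jacobian-at-noise-time choice (faithful to the model's derivation);
  only the radial error W should be compared quantitatively.
- W = γ/D is exact for the linear model by construction; the full
  simulation obeys it only near D = λ.
- One (k₁, k₂) pair is assumed per subject across directions; per-direction
  gains are out of scope.
- Stiffness/impedance, feedback control, constant and temporal noise
  components, and 3-D or gravity-loaded dynamics are not modelled.
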