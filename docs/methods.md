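# Methods

## Model

The laminar neural mass model couples five neural populations through
second-order synaptic kernels. Population *i*'s output postsynaptic
potential yᵢ obeys ÿᵢ + 2aᵢẏᵢ + aᵢ²yᵢ = Aᵢaᵢσᵢ(vᵢ), where (Aᵢ, aᵢ) are the
gain (mV) and rate (1/s) of the population's transmitter — AMPA
(3.25, 100), slow GABA (−22, 50), fast GABA (−30, 220) — and
σ(v) = 2φ₀/(1 + e^{r(v₀−v)}) converts the membrane potential to a firing
rate (φ₀ = 2.5 1/s, r = 0.56 1/mV, v₀ = 6 mV except 1 mV for the
superficial pyramidal population, whose low threshold is what lets the
slow rhythm gate its gamma). Membrane potentials are contact-count-weighted
sums of afferent PSPs. The two external drives are presynaptic rates; a
constant rate p settles the AMPA kernel at its DC gain, so drives enter
membrane potentials as (A_A/a_A)·p mV. This convention reproduces the
model's known bifurcation landmarks (SNIC near 104, Hopf points near 363
and 455 at zero superficial drive) and keeps all user-facing drive
parameters in physiological rate units.

The state is 10-dimensional: (y₁…y₅) in mV and their derivatives. The
Jacobian is analytic, using σ′(v) = r·σ·(1 − σ/(2φ₀)), and is verified in
the tests against complex-step differentiation of an independently written
copy of the vector field (machine-precision agreement; plain finite
differences cannot reach the required accuracy at this system's curvature).

## Integration

The default integrator is a compiled fixed-step RK4 with dt = 1e-4 s. The
fastest kernel rate is 220 1/s, so |a·dt| ≈ 0.022 and the local truncation
error is far below every analysis tolerance; fixed stepping also makes
every run bit-deterministic. An adaptive RK45 path (rel_tol 1e-8, abs_tol
1e-10) is available through `SolverSettings(method="adaptive")` and is used
in the tests as an accuracy cross-check. Observables are sampled at
1000 1/s — 25 samples per gamma cycle — after discarding a 10 s transient;
spectral analyses record 50 s.

One caveat found during validation: in the spiky near-SNIC regime at high
superficial drive (φe2 ≳ 250 with φe1 just past the SNIC), the *tangent*
dynamics used for Lyapunov exponents is much stiffer than the flow, and
dt = 1e-4 there can manufacture spurious positive exponents (λ₁ up to ~4)
that vanish at dt = 2e-5. Lyapunov computations in that strip should use
the finer step (the `dt` argument of `benettin_les`); elsewhere 1e-4 agrees
with linear theory and the reference systems.

## Equilibria and continuation

Fixed points are solved by damped Newton (residual < 1e-10; a 10 s
flow relaxation pulls poor guesses into the Newton basin). Branches are
traced by pseudo-arclength continuation: secant predictor, Newton corrector
on the bordered system, steps adapting between 1e-4 and 5 with a trust
region that rejects correction steps landing far from the prediction or
behind the current point — both failure modes occur near folds, where the
orthogonality hyperplane can cut the branch twice. The arclength metric
scales state components by 100 so that the fold region (where the branch is
vertical in the parameter) is resolved; tangent orientation is kept
consistent in the same scaled metric. The equilibrium curve at φe2 = 0 is
S-shaped and closes through a fold at negative drive (φe1 ≈ −65), so
continuation is allowed to overshoot the physical range on the starting
side by up to 250 rate units; only in-window events are reported.

Folds are detected by a sign change of the tangent's parameter component,
bracketed by small-step walking, and polished by damped Newton on the
extended fold system (f = 0, Jv = 0, c·v = 1) — the refined points satisfy
the zero-eigenvalue condition to ~1e-13. Hopf points are detected by a
change in the number of complex eigenvalue pairs in the right half plane
and refined by bisection on that count (bisection on a single "leading"
pair fails when another pair is already unstable, as happens at nonzero
φe2); refinements whose closest-to-axis pair is not actually near the axis
are discarded — these are real-eigenvalue collisions on the middle branch,
not Hopf points. Criticality is decided empirically: a probe simulation on
the unstable-equilibrium side must show a small stable oscillation whose
amplitude shrinks toward the point (square-root scaling), else the point is
labeled subcritical.

A fold is relabeled SNIC when simulation just past it exhibits a
large-amplitude orbit whose period grows as the offset shrinks
(period(δ/4) > period(δ), with δ = 2 rate units). Two-parameter loci are
grids of one-dimensional continuations, with the gamma-Hopf locus selected
by emergent frequency (≥ 25 Hz) and allowed to sit at negative φe1 (gamma
already unstable at zero deep drive).

## Periodic orbits

Orbits solve the single-shooting system Φ_T(x) − x = 0 with a Poincaré
phase condition (hyperplane through the reference point orthogonal to the
flow). The monodromy matrix is integrated with the orbit via the 10×10
variational equations (RK4, step ≤ 2.5e-5 s); its eigenvalues are the
Floquet multipliers, and the trivial multiplier lands within 1e-3 of +1 —
a direct accuracy check. Branches of orbits are continued in
(x, T, θ) by the same pseudo-arclength scheme (state and period scaled by
100), which follows unstable cycles through folds — the only way to reach
them, since they repel simulations. Passing through a supercritical Hopf
point the family shrinks onto the equilibrium and re-emerges mirrored;
continuation stops when the parameter direction reverses at near-zero
amplitude (a true fold of cycles reverses at finite amplitude and is
traversed). Folds of cycles are reported at the branch's geometric
parameter fold; torus and period-doubling points are sign changes of
(max |μ| − 1) over complex and negative-real multipliers respectively,
refined by bisection with re-converged orbits.

## Signal metrics

Spectra are Welch estimates (10 s Hann segments, 50% overlap, DC removed;
0.1 Hz resolution). The dominant frequency is the raw PSD argmax above
0.5 Hz, optionally excluding 12–30 Hz — the model has no significant power
there, and the exclusion separates slow from gamma rhythms; peaks below
1e-6 of total power are treated as "no rhythm" (steady cell). No
aperiodic-background correction is applied anywhere.

Phase–amplitude coupling is the Tort modulation index: zero-phase
(forward–backward) 4th-order Butterworth band-pass, analytic-signal phase
and envelope, 18 phase bins of 20°, MI = KL(P‖uniform)/log 18 ∈ [0, 1]. The
estimator is validated on synthetic amplitude-modulated signals with a
closed-form coupling depth (MI monotone in depth, zero at depth 0).

Lyapunov pairs use the Benettin method: flow plus two tangent vectors
integrated together, Gram–Schmidt renormalization every 0.1 s, 200 s
accumulation after a 20 s transient by default; the convergence error is
the standard deviation of ten block estimates. The zero tolerance for
regime classification is 0.05 1/s, matched to the finite-time bias of the
flow-direction exponent at 200 s (≈ 0.025). Regimes: steady (λ₁ < −tol),
periodic (λ₁ ≈ 0, λ₂ < −tol), quasiperiodic (both ≈ 0), chaotic (λ₁ > tol).
The estimator is validated against three flows with known spectra: a linear
contraction (−1, −3), the limit-cycle normal form ṙ = κr(1−r²) (0, −2κ),
and two uncoupled incommensurate rotations (0, 0).

Maps default to a 48×48 grid; tests and the worked examples use a handful
of representative cells plus short rows, sized so the whole suite runs in
minutes on one core — the map functions accept any grid, and the published
landscape's full resolution (384×384) is available as an explicit large
run via the CLI.

## PV-dysfunction scan

Reducing the PV→P2 contact count C7 from 550 models the synaptic damage
attributed to amyloid-beta oligomer accumulation. For each C7 the scan
recomputes the SNIC, slow-Hopf and gamma-Hopf loci over a φe2 grid and a
scalar coexistence fraction: the fraction of a 48-column φe1 grid per φe2
row lying both inside the slow-cycle region (between SNIC and slow Hopf)
and past the gamma-Hopf locus. The region boundaries come from the same
continuation code path as the equilibrium module, so the baseline row is
identical to a direct branch computation. At C7 = 300 all loci at zero deep
drive shift left (hyperexcitability) and the coexistence fraction grows; by
C7 = 150 no gamma Hopf exists anywhere in the window — gamma extinction.

## Two-column model

Two identical columns are coupled by feedforward (superficial pyramidal of
column 1 → superficial pyramidal of column 2) and feedback (deep pyramidal
of column 2 → deep pyramidal, superficial pyramidal, and slow interneurons
of column 1) projections; all four pyramidal populations share one external
rate φ. Coupled firing rates enter the target membrane potentials through
the steady AMPA gain, the same convention as the external drives, which
keeps the state exactly 20-dimensional and makes the zero-gain limit
decouple the columns *identically* (tested to the last bit, including the
bifurcation set of the continued branch). The canonical coupling constants
of the original formulation are not available to this package; the default
gains (50 feedforward; 30, 30, 10 feedback) are placeholders of the same
order as the long-range intracolumn constants C11–C13 and are explicit
configuration. Quantitative bifurcation values of the coupled system
therefore depend on the user's gains, and only structural properties are
asserted: exact decoupling, the analytic 20×20 Jacobian against a
complex-step oracle, bounded rhythmic dynamics in all four populations with
a superficial gamma component, and Hopf detection on the coupled branch.

## Synthetic validation

The `synth` module carries the ground-truth generators: the PAC test
signal x(t) = sin(2πf_s t) + [1 − d + d(1 + sin(2πf_s t))/2]·sin(2πf_f t)
(+ optional seeded Gaussian noise), the three Lyapunov reference flows
above, and the direct kernel convolution that serves as the oracle for the
ODE form of the synapse (agreement < 1e-4 mV RMS on band-limited random
drives). These validate every estimator against inputs whose answers are
known independently of the neural model; they do not emulate physiological
noise, finite electrodes, or volume conduction, so passing tests certify
the estimators and the model's mathematics, not fidelity to recorded EEG.

## Known limitations

* The printed eigenvalue census of the resting state ("three complex pairs
  and two real eigenvalues") is inconsistent with a 10-dimensional system;
  the actual spectrum has four complex pairs and two real eigenvalues, and
  the package asserts the qualitative content (stability, mixed
  complex/real spectrum).
* Chaotic cells near the high-φe2 fold-of-cycles region could not be
  confirmed at desk scale: with accurate tangent integration (dt = 2e-5)
  every probed cell's λ₁ decays toward zero like finite-time bias, ending
  below the 0.05 1/s threshold. Coarser steps do produce positive
  exponents there, but these are integration artifacts of the
  near-homoclinic spikes. The corresponding regime-map assertion is kept
  faithful to the claimed landscape and documents this discrepancy.
* Codim-2 bifurcations (Bogdanov–Takens, fold-Hopf, the criticality
  exchange where the Hopf loci cross) are not classified; criticality is
  probed pointwise.
* No stochastic input, no conduction delays, no multi-area networks beyond
  the two-column structure.
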