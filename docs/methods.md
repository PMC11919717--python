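# Methods

## Physical model

A micron-scale probe (radius `a`, default 0.5 µm) is held by an optical
trap of total stiffness `k` in a linear viscoelastic medium. Inertia and
thermal fluctuations are neglected (overdamped, athermal regime): the
instantaneous force balance is

    6πa · [material operator](x)(t) = k (x_l(t) − x(t)),

where `x_l` is the position of the (equivalent single) trap and the
material operator is built from *springpots*, fractional elements with
stress–strain law `σ = C_α D_t^α ε`, `0 ≤ α ≤ 1`. Parallel combinations
(Kelvin–Voigt type, viscoelastic solids) add stresses; series combinations
(Maxwell type, viscoelastic liquids) add creep compliances. The classical
spring/dashpot/Maxwell/Kelvin–Voigt models are the integer-exponent limits
and are required (and tested) to agree with the fractional families to
1e-12 relative. The generalized Stokes–Einstein relation `χ = 1/(6πa G*)`
links the probe response to the shear modulus. Units are pN–µm–s, the
complex convention is `e^{+iωt}` with `G = G′ + iG″`, both parts
non-negative for every admissible family.

Time-domain kernels: springpot `G(t) = C_α t^{−α}/Γ(1−α)`,
`J(t) = t^α/(C_α Γ(1+α))`; fractional Kelvin–Voigt creep and fractional
Maxwell relaxation use the two-parameter Mittag-Leffler function
`E_{a,b}(z)`, evaluated by an adaptively truncated power series (terms
below 1e-16 of the partial sum) with an explicit cancellation guard, a
large-argument asymptotic expansion, and a fixed-Talbot Laplace-inversion
fallback. The series/asymptotic/fallback selection is by the estimated
magnitude of the series' peak term, keeping at least ~6 significant
digits; accuracy is verified in the tests against the closed-form
identities `E_{1,2}(−x) = (1−e^{−x})/x` and `E_{1/2,1}(−x) = e^{x²}
erfc(x)` and against an independent Gaver–Stehfest inversion.

## Instrument model

The acousto-optic deflectors alternate the laser between the driving trap
(position commands `x_{1,n} = A sin(ω n/f_t)`, one per sharing cycle) and
the static trap at the origin. Within the linear trap range the optical
force equals that of a single full-stiffness trap moving along a
trapezoid: a linear ramp of 10 µs into the new position, a 30 µs dwell,
and the reverse, for an 80 µs cycle; hence a per-trap rate
`f_t = 12.5 kHz` and a drive Nyquist bound of 6.25 kHz. Note the AOD
*addressing* rate is twice the per-trap rate (25 kHz); the per-trap
sampling rate that bounds the sweep is `1/cycle`.

Detector samples are taken 33 µs after each slot's *acoustic* rising
edge. The acoustic wave needs a finite transit time to fill the beam
cross-section (`fill_delay`, default 8 µs), so the sample lands
`33 − 8 = 25 µs` into the *optical* half-cycle — the centre of the dwell.
This reconciliation matters: the first-harmonic map used here is
algebraically identical to a derivation with samples taken
at the peak phase of the trap-occupancy fundamental, which is the dwell
centre; sampling 33 µs into the optical cycle instead would put the
simulation and the analytic map ~10% apart at `ω_t/10` for springpot-like
media. `fill_delay` is a configuration parameter and the consistency is
enforced by the config invariant `ramp < sample_delay − fill_delay <
ramp + dwell`.

A sine drive at exactly the Nyquist frequency samples to
`A sin(πn) ≡ 0` — no physical drive — and is rejected; simulated sweeps
use the grid points strictly below the bound.

## Trajectory solvers

Stress-additive families (Newtonian, springpot, Kelvin–Voigt, fractional
Kelvin–Voigt): each springpot contributes a Grünwald–Letnikov fractional
derivative, `D^α x(t_n) ≈ dt^{−α} Σ_j w_j x_{n−j}`,
`w_j = w_{j−1}(1−(α+1)/j)`; the implicit dependence on `x_n` is solved
algebraically each step, so the march is direct. Integer orders have
finitely many non-zero weights and cost O(N); fractional memory is O(N²)
with an optional short-memory window.

Compliance-additive families (Newtonian, Maxwell, fractional Maxwell):
the hereditary (Volterra) creep integral `x(t) = (1/6πa)∫ J(t−s) dF(s)`
discretized with midpoint kernel samples and piecewise-constant force
increments, again with the current step solved algebraically. For the
linear kernels `J = J_el + t/η` (Newtonian, Maxwell) the memory sum
telescopes into two running sums, giving an exact O(N) recursion.

The springpot is representable on both routes; the two independent
solvers agree to 0.32% of the trajectory scale over 20 ms (recomputed by
the acceptance script). Default integration step `dt = 0.5 µs` (20 points
per ramp); halving it changes extracted fundamentals by <0.2%. The bead
and medium start from rest with zero pre-history, and the first drive
period of every trace is discarded before spectral analysis to shed the
start-up transient.

## Extraction and first-harmonic compensation

Each slot stream is reduced to its fundamental amplitude at the known
drive frequency using the true, per-slot sample timestamps. The default
estimator is a harmonic least-squares regression on
`{1, cos(hωt), sin(hωt)}`, `h ≤ 4` (harmonics whose aliased frequency
collides with DC or the fundamental are dropped); the plain single-bin
projection is available as `method="projection"`. The regression exists
because the slot signals are periodic but strongly non-sinusoidal — the
drive is a zero-order-hold staircase — and with sample spacing
incommensurate to the drive period the plain projection leaks 1–2% of
harmonic power into the fundamental.

The deviated response follows from the interleaved amplitudes as
`χ_t = −2V̂2/(k(V̂1+V̂2))`, with `V` the force exerted by the trap on the
bead. Truncating the trap occupancy at its first harmonic gives the
closed-form map `χ_t = g(χ, ω_t, k)` quoted in the README; negative
frequencies enter via Hermitian symmetry `χ(−ν) = χ*(ν)`. For an ideal
elastic solid the map vanishes identically, as do the simulator's
static-slot samples.

Compensation inverts the map per frequency. The shifted arguments
`ω_t ± ω` exceed the drive Nyquist, so they are always evaluated from a
model of the assumed material class (viscoelastic solid → fractional
Kelvin–Voigt, viscoelastic liquid → fractional Maxwell, or springpot)
fitted to the current estimate, and the algebraic inversion is iterated
to a fixed point (relative change < 1e-6, at most 50 iterations). The
plain iteration contracts slowly (ratio ≈ 0.96) for strongly deviated
liquids, so every third iterate is extrapolated by Aitken's Δ² rule and
the inner fits are warm-started from the previous model; all tested
materials then converge within ~25 iterations. Re-applying compensation
to an already-compensated spectrum is a stage-tracked no-op, since the
map `χ_t → χ` is not the identity. Frequencies that fail extraction or
inversion are retained with a quality flag; fitting excludes them.

## Fitting and derived parameters

`fit_model` performs nonlinear least squares (via lmfit) on the stacked
relative residuals of `G′` and `G″`, each component normalized by its own
measured value — homoscedastic when measurement noise is relative, which
makes the covariance-based confidence intervals consistent (coverage
≈ 94% at nominal 95% in the 500-seed calibration the acceptance script
reruns). The compensation's internal fit instead normalizes by `1/|G|`,
which tolerates the near-zero storage components of pure liquids. Points
with `G′ ≤ 0` or `G″ ≤ 0` are excluded before fitting (the standard
negative-data-point exclusion rule for measured spectra), quasi-moduli
are fitted in log10 space, exponents are bounded to [0, 1] (boundary hits
flagged), and a deterministic multi-start over an exponent grid with
data-driven modulus guesses handles the multi-modality of fractional
fits; ties resolve to the first-found optimum. For the two-springpot
families the elements are exchangeable and the result is canonicalized to
`α ≤ β`.

Derived quantities: crossover `ω_c` solves `G′(ω) = G″(ω)` (closed form
`E/η` for Maxwell/Kelvin–Voigt, bracketed root-finding on
`[1e-6, 1e9] rad/s` otherwise, "absent" when no sign change);
`τ = η/E` for the classical families and `1/ω_c` otherwise; the loss-slope
viscosity is the zero-intercept regression of `G″` on `ω` minimizing
relative residuals.

## Auxiliary estimators

*Creep compliance*: under a force clamp `F0`, `J(t) = 6πa·x_bead/F0` with
`x_bead = x_trap − F/k`; samples where the measured force leaves a ±5%
band around the set-point are flagged (the tolerance is a package choice;
only the set-point itself is physically specified). *Creep → modulus*:
Evans-type discrete transform of the piecewise-linear interpolant of
`J(t)`, with the short-time intercept `J(0⁺)` and the steady-flow
viscosity taken from fitted local power laws over the first and last
decades. The frequency grid spans `[1/t_max, 1/(2·max(Δt_min, t_0))]` —
capped at the inverse of the first sample time, because higher
frequencies depend on the unobserved early response. Accuracy against the
Maxwell closed form is ~0.01% over the two interior decades; edge decades
are less reliable and should be trimmed before fitting. *Jeffrey model*:
`x/f_FC = (1/κ)(1−e^{−κt/γ₁}) + t/γ₂`, initialized from the slope
relations (initial slope `1/γ₁+1/γ₂`, late slope `1/γ₂`, late intercept
`1/κ`); monotonicity of the input is checked on coarse bin means so that
sample-level noise does not trip the guard. *Stokes drag*:
`η = slope/(6πR)` from a zero-intercept fit of plateau force versus trap
velocity. *Trap stiffness*: linear fit of the force scan within ±200 nm
of the force zero-crossing, with an RMS-residual diagnostic.
*Probe radius*: half the distance between the force extrema of a scan
across the particle — a heuristic (so labelled), calibrated only by the
synthetic scans in the test suite.

## Synthetic data

The fixture generator simulates sweeps at the instrument timing above
(25 kHz sharing, 10 µs ramps, 30 µs dwells, 33 µs sampling delay,
defaults `k = 50 pN/µm`, `a = 0.5 µm`, `A = 100 nm`, within the ±200 nm
linear range) and optionally adds seeded additive Gaussian detector noise
with standard deviation expressed relative to the RMS of the driving-slot
stream. All randomness flows from the single seed in `SweepConfig`;
fixture files are byte-stable given the seed. What it does *not* emulate:
thermally consistent Brownian motion (only additive detector noise),
trap-force nonlinearity beyond the linear-range bound, 3D and rotational
degrees of freedom, wall/hydrodynamic corrections, drift, and detector
crosstalk. Passing tests therefore demonstrate correctness of the
deterministic measurement model and estimators, not robustness to every
artefact of real recordings.

Default sweep sizes keep the whole suite light: per frequency, one
discarded transient period plus a measurement window of at least two
periods and at least 4 ms.

## Known limitations

* The first-harmonic map ignores the zero-order-hold image spectrum of
  the staircase drive and all higher occupancy harmonics; its mismatch
  with the full simulation grows roughly as `(ω/ω_t)²` — ~0.4% at 1 kHz,
  ~7% at 4 kHz — so compensated values in the top half-decade below
  Nyquist carry a systematic residual. Higher-harmonic corrections are
  out of scope.
* For ideal viscoelastic liquids in a stiff trap (`k|χ| ≳ 1` at the
  sharing frequency) the real part of the response is poorly determined;
  the workflow's advisory stage warns when the trap is not softer than
  the material at the top measured frequency.
* Fractional-memory simulation is O(N²) in the step count; sub-10 Hz
  drives of fractional materials are expensive unless the short-memory
  window is enabled.
* Confidence intervals are covariance-based (delta method for log-fitted
  parameters) and symmetric; they are calibrated by simulation, not
  profile likelihood.
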