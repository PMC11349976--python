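# Methods

This note records the models the package integrates, the conventions and
calibrations behind them, and what the shipped defaults do and do not
represent.

## Single oscillators

All single-unit models are integrated with fixed-step classical
Runge–Kutta (RK4). A fixed step gives bit-reproducible runs and doubles as
the history buffer for the delayed model; the default step matches the
5 µs-equivalent used for the box models (200 steps per cycle for a
unit-frequency oscillator). An optional external drive is sampled on the
half-step grid so RK4 stages never interpolate.

* **Van der Pol** — `ẍ + ω(−α + βx²)ẋ + ω²x = F(t)`. For 0 < α ≪ 1 the
  limit cycle has amplitude 2√(α/β) and frequency ω/2π; both are used as
  oracles in the tests. At α = 1 the cycle is visibly non-sinusoidal (odd
  harmonics) and its amplitude exceeds the weakly nonlinear estimate by
  ≈ 0.4%.
* **Van der Pol–Duffing** — stiffness `ω²(λ + μx²)x`. The sign conventions
  of α are kept exactly as each model family states them, even where the
  two families disagree; sign choices are data, not code.
* **Delayed stiffness** — `ω²(x(t) + κx(t−Δt))` with constant pre-history.
  The delayed value is linearly interpolated into the stored trajectory;
  Δt = 0 reduces exactly to stiffness ω²(1+κ), and 0 < Δt < dt is rejected
  (refine the grid instead). Small-amplitude stability is decided by the
  rightmost root of the quasipolynomial `s² + ω(−α)s + ω²(1 + κe^(−sΔt))`,
  found by Newton iteration from a grid of starting points; simulation and
  oracle agree on the active/passive flip locations to within one step.
* **Anti-damped** — damping `ω(α + βx² − γ/⟨x²⟩)`. ⟨x²⟩ is a first-order
  low-pass of x² with time constant `tau_avg` (default 10 cycles; the
  averaging scale is only qualitatively specified by the model family, so
  it is a parameter). The γ/⟨x²⟩ term is singular at zero, so the initial
  average must be positive and a configurable floor (10⁻¹² model units)
  clamps cold starts with a warning rather than aborting.
* **Hopf** — `ż = (iω₀ + ε)z − |z|²z`. The radial part has the closed form
  `r(t)² = ε r₀² e^{2εt}/(ε + r₀²(e^{2εt} − 1))`, which every Hopf
  integration is tested against.

Divergence guard: any state exceeding 10⁶ × max(1, initial amplitude)
aborts with the step, time and (for arrays) element identified. Unstable
regimes are legitimate outputs of several models and must fail loudly.

Amplitude readout is half the peak-to-peak excursion over the final window
(default 20%) rather than RMS·√2, so strongly non-sinusoidal steady states
are still summarised correctly. Growth/decay classification fits the
per-cycle peak envelope in log space over the last half; per-cycle peaks
are exact for exponential envelopes and immune to the spectral leakage
that an FFT analytic signal suffers when amplitude spans orders of
magnitude.

## Coupled Hopf pair

`ż_bm = z_bm(α_bm + i2πf) + c₁₂z_oc`,
`ż_oc = z_oc(α_oc + i2πf + β|z_oc|²) + c₂₁z_bm`. With both α < 0 and real
symmetric coupling c, the linearised eigenvalues are
(α_bm+α_oc)/2 + i2πf ± √(((α_bm−α_oc)/2)² + c²); the real part first
touches zero at c\* = √(α_bm·α_oc). The simulated growth/decay boundary
(bisection on the late-half log-envelope slope of |z_bm|) reproduces c\*
to better than 10⁻³. The regime classifier uses a ±10⁻⁴ dead band on the
slope; the shipped default sweep {0.05, 0.16, 0.30} spans below/near/above
the threshold for the standard parameters (α_bm = −0.5, α_oc = −0.05,
β = −0.5, f = 0.5).

## Chains (lizard ear)

The complex chain adds `(d_R + i d_I)(z_{j+1} − 2z_j + z_{j−1})` to each
Hopf unit, implemented as the standard second difference. Boundaries are free ends by default (one-sided
stencil, so the coupling term sums to zero over the chain — no net energy
injection by coupling); periodic is available.

The Van der Pol chain integrates the Liénard form
`ẋ_n = μ_n(y_n − x_n³/3 + α_n x_n + γ_el·Δ²x)`,
`ẏ_n = −(2πf_n)²x_n/μ_n + γ_vis·Δ²ẋ/μ_n`, which eliminates to
`ẍ_n + μ_n(−α_n + x_n²)ẋ_n + (2πf_n)²x_n = 0` per unit. Elastic coupling
enters the ẋ bracket (a displacement stencil); viscous coupling applies
the same stencil to velocities in the acceleration equation. Note that
after elimination both routes act on ẋ with different scalings (μγ_el vs
γ_vis); the original studies' contrast between the two modes depends on
their unpublished coupling placement, so this package asserts clustering
only for the elastic route.

Plateau detection measures each unit's dominant frequency on the late-time
window (spectral peak with quadratic interpolation) and greedily merges
adjacent units agreeing within `rel_tol` (default 1%) with the running
plateau mean. Silent units get NaN and break plateau adjacency.

## The fluid-filled-box cochlea

Element 1 is a damped harmonic oscillator for the middle ear
(`ẍ₁ + d₁ω₁ẋ₁ + ω₁²x₁ = p₁`, d₁ = 0.1, resonance 1 kHz); elements 2…n are
partition sections with natural frequencies decreasing exponentially from
10 kHz to 0.14 kHz (element 200 of 351 sits at 0.888 kHz). The fluid maps
instantaneous accelerations to pressures, `p = a·F⁻¹·ẍ` with a = 0.2.

**The operator F.** F is the second-difference operator of a
one-dimensional duct: interior rows `(1, −2, 1)/h²`, a basal row tying the
one-sided pressure gradient to the middle-ear acceleration, and a
Dirichlet ghost (pressure release) beyond the apex. Two conventions are
fixed here:

* *Sign.* With `p = a·F⁻¹·ẍ` and a > 0, the interior stencil must be
  `(1, −2, 1)` (negative-definite): the fluid then loads the partition
  inertially (pressure opposes acceleration). The opposite sign feeds
  energy into a fully passive box, which is unphysical; the passive-decay
  test pins this down.
* *Duct length.* h = `duct_length`/(n−1), with all other physical
  constants folded into a. The duct length controls how much
  travelling-wave phase accumulates between the stapes and a given place,
  hence whether the box can hold a standing wave with several nodes. The
  default, 100 (folded units), was calibrated against the published
  single-active-oscillator behaviour: at that value the 0.9 kHz wave
  accumulates ≈ 2 cycles of phase from stapes to place, the 40–50 ms
  displacement profile shows sharp interference minima (elements 124 and
  165) basal of the active element and essentially no wave apical of it,
  and the amplitude ratio between the active element and the basal side
  is ≈ 25. Shorter ducts (≲ 60) leave the basal response quasi-static and
  nodeless.

**Implicit pressure coupling.** Pressure depends on accelerations and vice
versa; each RK4 stage solves the linear system exactly through the cached
operator `S = (I − a·M⁻¹·K·F⁻¹)⁻¹` (state-independent; state-dependent
coefficients enter only the local force vector). Lagging the pressure by a
step would be cheaper but shifts stability boundaries.

**Van der Pol elements** (`simulate_vdp_box`):
`ẍ_j + ω_jγ(t)ẋ_j + ω_j²x_j = κp_j`, γ(t) = −α_j + β_jx². Defaults
β_j = 20, α_j = −0.1 (passive), α₂₀₀ = +0.1 (one active element), initial
kick ẋ₂₀₀(0) = 0.01, dt = 5 µs, 50 ms, millisecond/kHz units.

**Two-mass elements** (`simulate_nk_box`): per element, a
basilar-membrane mass m₁ = 0.044 and tectorial-membrane mass m₂ = 0.0073
(SI surface densities) joined by four spring/damper pairs, with an active
feedback force γ₀·γ[x−y, ẋ−ẏ]·(c₄(ẋ−ẏ) + k₄(x−y)) on m₁, where
`γ[α, β] = 1 − tanh((α/α_sat)² + (β/β_sat)²)` (α_sat = 2·10⁻⁵,
β_sat = 0.1) saturates the gain at large excursions. Larger γ₀ means
less damping.

**The element parameter table.** The per-element stiffness and damping
values of the original two-mass studies come from an external table that
is not reproduced; this package ships its own smooth exponential
place-map family (`nk_place_maps`), built from dimensionless shape
constants: every spring/damper scales with the local place frequency
(k₁ = m₁ω², c₁ = 2ζ₁m₁ω, …), the TM branch resonates at r₂·ω (default
0.5 — detuning the second mass below the local characteristic frequency
is what lets an isolated-stable element amplify travelling waves), and
the feedback-force scale is rolled off smoothly (C² smoothstep) near both
duct ends, because the stapes and pressure-release boundaries otherwise
support spurious edge modes that destabilise before any physical
standing-wave mode. With the defaults:

* every element in isolation is stable up to γ₀ ≈ 1.12 (base elements to
  ≈ 2.2 due to the roll-off) and strongly unstable at γ₀ = 2;
* the single-active-element configuration (uniform γ₀ = 0.5,
  γ₀,₂₀₀ = 2.0) produces a sinusoidal emission at ≈ 650 Hz with a
  four-node standing wave;
* a −0.15 notch at element 200 in a uniform array destabilises the
  ≈ 674 Hz standing-wave mode between the notch and the stapes in the
  window γ₀ ∈ [≈1.005, ≈1.03], in which the notch-free array is still
  stable and every element in isolation rings down — the irregularity
  alone turns the box into a global oscillator. Moving the notch basally
  (elements 120/150/200) raises the emission frequency monotonically
  (1803/1250/674 Hz).

All numerical thresholds of the two-mass box (where non-sinusoidality
begins, where instability begins, amplification factors) are properties
of the parameter table; with a different table they move. Only their
existence and ordering are asserted.

`nk_box_growth_rate` builds the full linearised state matrix (≈1400×1400
with fluid coupling folded in) and returns the rightmost eigenvalue real
part — collective stability without a time-domain run; the time-domain
emissions match its mode frequencies to ≲ 1 Hz.

## Stochastic inputs

* Narrow-band noise: white Gaussian noise through a 4th-order Butterworth
  band-pass applied forward–backward (zero phase), rescaled so the stated
  amplitude is the delivered RMS. Default bandwidth 0.5·f₀.
* Ornstein–Uhlenbeck fields use the exact Gaussian transition kernel
  (x_{k+1} = x_k e^(−θΔ) + √(σ²(1−e^(−2θΔ))/(2θ))·ξ), so stationary
  variance σ²/(2θ) and lag autocorrelation e^(−θΔ) hold on any grid. σ is
  a free parameter (default 1); only mean-reversion speeds are prescribed
  by the source models (0.008, 0.04).
* Multiplicative roughness: base·(1 + ε·N(0,1)) or base·(1 + OU field).
  Sign-flipping perturbations warn and can be clamped at a configurable
  floor; the originating models do not state the intended behaviour.

Every generator is a pure function of (spec, seed) — bitwise repeatable.

## Signal statistics

* Spectra: Hann taper, single segment, normalised to maximum 1.
* The noise-driven-oscillator pipeline (`fig2` preset) drives the α = 1,
  β = 4 Van der Pol with narrow-band noise centred on its own measured
  fundamental (self-calibrated from a short undriven run), adds white
  noise to the *output*, then band-passes around the emission peak and
  around the strongest noise peak inside the driven band but away from
  the emission line (a naive peak search lands on the oscillator's third
  harmonic, which is a sine, not noise). Drive RMS 0.1 and white noise
  std 0.05 are repository conventions chosen to keep the emission
  ≥ 20 dB above the noise floor; the source material prints no levels.
* Histogram modes: Gaussian-kernel smoothed histogram (Silverman
  bandwidth, floored at 1.5 histogram bins); modes are local maxima above
  5% of the global maximum **with prominence ≥ 10%** of it. The
  prominence requirement exists because quasi-periodic phase sampling of
  a near-sine puts a shallow comb (and the drive a slight centre fill) on
  the arcsine histogram; bare local-maximum counting then reports a
  spurious central mode. The emission band yields two modes at ±(limit
  cycle amplitude) with a minimum near zero; a noise-only band yields one
  zero-centred mode.
* Sinusoidality: 1 − (envelope CV + non-fundamental power fraction)/2,
  clipped to [0,1], on the raw analytic envelope (smoothing would hide
  the variability being measured).
* Entrainment: locked = dominant frequency within one spectral bin of the
  probe and envelope modulation < 5%; beating = envelope modulation at
  ≈ the detuning; partial otherwise.

## Problem sizes and run lengths

The box runs use the full n = 351 at dt = 5 µs throughout. Time spans per
purpose: 50 ms for the standard single-active-oscillator window; 150 ms to
classify the emission as steady (the standing wave needs ~100 ms to
equilibrate); 0.12 s per point for two-mass gain sweeps; 0.6 s for the
irregularity-driven emission (its growth rate just above threshold is
≈ 10 s⁻¹, so saturation takes a few hundred ms). The histogram pipeline
uses 2·10⁵ samples (2000 cycles), which is ample for stable mode
detection.

## Known limitations

* The fluid operator is the canonical 1-D long-wave discretisation; the
  original state-space formulation may differ in boundary details. The
  duct length is calibrated (see above), not derived from anatomy.
* The two-mass element table is this package's own calibrated family; its
  numeric thresholds are not those of the unpublished original table.
* The synthetic noise drives are Gaussian and stationary; real ear-canal
  noise is neither, so passing histogram tests show the mechanism
  (limit cycle vs noise), not measurement realism.
* Entrainment classification assumes a single probe tone and a single
  dominant oscillator; multi-tone or multi-emission interactions are out
  of scope.
* The anti-damped model's averaging time constant and the ⟨x²⟩ floor are
  conventions; behaviour at cold starts (⟨x²⟩ → 0) is a regularisation,
  not part of the original model.
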