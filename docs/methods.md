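# Methods

This note documents the models, numerical choices and design decisions
behind `eiwaves`, in the spirit of a methods appendix.  Units throughout:
mV, ms, Hz; synaptic strengths in mV·s; the oscillation phase carries time
units (period T), so phase gradients are in ms and phase-coupling constants
in 1/ms.

## 1. EIF single-neuron numerics

The membrane potential obeys `tau_m dV/dt = E_L - V + Delta_T
exp((V-V_T)/Delta_T) + I + sigma sqrt(tau_m) xi`, with a spike registered
at the numerical cutoff `V_thresh = -30 mV`, reset to `V_reset = -68 mV`
and a refractory hold of `tau_ref = 1.7 ms` (defaults: `tau_m = 10 ms`,
`E_L = -65 mV`, `V_T = -59.9 mV`, `Delta_T = 3.5 mV`, `sigma = 10 mV`).

**Stationary rate.**  Threshold integration of the Fokker–Planck equation:
with unit emitted flux, the flux is 1 between reset and threshold and 0
below, and the density is integrated downward from `V_thresh` to
`E_L - 10 sigma` with a per-step integrating-factor (exponential) update on
a uniform grid (`dV = 0.01 mV` at reference resolution; halving the grid
changes rates by < 0.1%).  The free rate is the inverse of the density
mass and the refractory period is folded in as
`r = 1/(tau_ref + 1/r_free)`.

**Linear response.**  For a sinusoidal modulation of the mean current at
frequency f the first-order Fokker–Planck problem is solved by two backward
sweeps — one carrying unit emitted flux with delayed re-injection
`exp(-i omega tau_ref)` at the reset, one driven by the stationary density —
combined so the flux vanishes at the lower bound.  The zero-frequency
limit reproduces the f-I slope to better than 1% (tested).

**Fitted adaptive timescale.**  The modulus of the response over 1 Hz–1 kHz
in 1 Hz steps (default) is fitted per grid current by
`A / sqrt(1 + (2 pi f tau)^2)` (unweighted least squares; the amplitude is
concentrated out and the profile objective minimized in log tau).  The
resulting `tau^(FAT)(I)` at the excitatory operating point is ~8.8 ms.

**Transfer table.**  Phi, its central-difference derivatives, tau^(FAT) and
its derivative are tabulated on a uniform current grid (reference:
`dI = 0.1 mV` over (-28, 20) mV) and interpolated linearly (cubic
available).  The current range covers the limit-cycle excursion plus the
heavy-tailed inhibitory-current excursions of long stochastic runs; a
query outside the range is an error, never an extrapolation.  A "desk"
profile (`dI = 0.2 mV`, 2 Hz frequency steps, `dV = 0.02 mV`) builds ~20x
faster and reproduces all derived constants within a few percent; the test
suite uses it with a wider range (-60, 45) mV for the long stochastic runs
at small N.

## 2. Rate model

Module dynamics: `tau(I_E) dI_E/dt = -I_E + I_E_ext + w_EE r_E - w_EI r_I`
and `tau(I_I) dI_I/dt = -I_I + I_I_ext + w_IE r_E`, with `r = Phi(I)` and
both populations sharing the same `Phi_sigma` and `tau^(FAT)` (the noise
strength is fixed at sigma_tot = 10 mV, not state-dependent).  There is no
I→I coupling.  External currents are calibrated to impose the fixed-point
rates (5 and 10 Hz): `I_E_ext = Phi^{-1}(r_E_s) - w_EE r_E_s + w_EI
r_I_s`, `I_I_ext = Phi^{-1}(r_I_s) - w_IE r_E_s`.

Reference synaptic cases (mV·s): A — w_EE 1.6, w_IE 2.0, w_EI 0.32;
B — 1.6/1.6/0.8; C — 1.76/3.2/0.4.  Case A is the default operating point
(alpha = 2.33, beta = 2.15, oscillatory-unstable fixed point, T = 63.7 ms).

Integration is forward Euler at dt = 0.01 ms (higher-order schemes are out
of scope; halving dt changes the period by < 0.1%).  Stochastic mode draws
per-step Poisson spike counts with mean `N Phi(I) dt` and sets
`r = n/(N dt)` — rates are non-negative by construction and the scheme has
no free noise parameter.  Draws are consumed in a fixed order (E
populations module 0..L-1, then I), so runs are bit-reproducible at fixed
seed.  Default initial state: the fixed point plus a 0.1 mV kick on the
excitatory currents (uniform, or Gaussian per module when a seed for
initial noise is given).  Default transient discard is 250 ms; analyses of
weak-noise runs (N >= 1e5) discard 2-2.5 s because the deterministic
approach to the cycle is slow compared to the noise level.

Coupling: two modules exchange a fraction `f_lr` of their excitatory drive;
chains use the periodized exponential profile `C(l) ~ exp(-lambda |l|)`
normalized to unit sum, optionally mixed with a purely local component
`(1-alpha) delta_l0 + alpha exp(-lambda|l|)`.  "E→E" applies the long-range
mixing only to the E equation, "E→E,I" to both.

## 3. Spiking network

Euler–Maruyama at dt = 0.01 ms; all-to-all within-module delta synapses
applied as population-count increments `J_XY n_Y` at the end of the step
after the presynaptic spike (one-step effective delay avoids within-step
ordering ambiguity).  Per-synapse weights `J_XY = w_XY/(N_Y tau_m)`;
external noise calibrated from the budget `sigma_X^2 = sigma_tot^2 - sum_Y
J_XY^2 N_Y tau_m r_Y^s`.  During the refractory hold the potential is
clamped at reset and synaptic input is discarded (the source description is
silent on this; the choice is documented, not load-bearing at these
rates).  Membrane potentials start at `E_L` plus 5 mV Gaussian spread.

Cross-module connectivity has two schemes: `sampled` (two modules; each
targeted neuron receives `C_lr = round(f_lr N_E)` synapses from randomly
drawn neurons of the other module at full weight, within-module weights
rescaled by `1 - f_lr` — keeps cross-module shot noise) and `mixed`
(all-to-all with profile-scaled weights — the large-N variant; chains use
this scheme, since per-neuron sampled wiring for chains is out of desk
scale).  `build_long_range_connections` generates per-neuron source
assignments for the distance-profile statistics (exact in-degree N_E,
profile-distributed offsets).

Validation sizes are deliberately small (N of a few thousand, seconds):
they confirm the uncoupled operating point (5/10 Hz), the agreement of the
spiking module with the stochastic FAT model at equal N (identical
spectral peaks — both shifted below the deterministic 1/T by the
finite-size frequency shift at small N — and matching autocorrelation
shapes), and the coupling-strength ordering of two-module synchrony.  They
do not probe the N ~ 1e6 regime.

## 4. Oscillation theory

**Limit cycle.**  After a 2 s transient, upward crossings of r_E through
its time mean define the Poincare section; the period is the mean crossing
interval over the detection window (successive intervals must agree to
1e-4 relative) and one period is resampled by cubic interpolation onto a
uniform grid of ~dt spacing.  The phase origin (t = 0 at the section) is
arbitrary; all derived constants are origin-invariant (tested).  The
on-model derivative `dI0/dt` is evaluated from the right-hand side, not by
finite differences.

**Floquet analysis.**  `dM/dt = L(t) M` is integrated over one period with
the same explicit Euler scheme; `L(t)` contains the `tau'(I) I0'` terms
from the state-dependent timescale (which drop out at the fixed point but
not on the cycle).  For the single module the neutral mode is set to the
exact cycle tangent (the numerical eigenvector agrees to ~1e-3);
biorthogonal adjoints come from pointwise inversion of the basis matrix,
so `g_i . e_j = delta_ij` holds at every sample by construction.  For the
coupled (antisymmetric/per-wavenumber) problems the recurrent excitatory
gain is rescaled by `1 - 2 f_lr` (E→E: the E→E term only) or by `C~(q)`,
and the true eigenvectors of the monodromy matrix are used — substituting
the tangent is only correct at f_lr = 0 and noticeably biases the
fluctuation formulas at moderate coupling.

**Phase diffusion and coupling constants.**  D_E, D_I, the synchronization
functions S(dphi) and the constants D_phi^E (negative) and D_phi^EI
(positive) are quadratures of phase-response-weighted noise or coupling
terms along the cycle (rectangle rule on the periodic grid, which is
spectrally accurate for periodic integrands).  The identity
`S'(0) = -2 D_phi` and the small-coupling multiplier slope `mu1 - 1 =
-2 f_lr D_phi T` close to within 1-2%; the multiplier slope carries a
genuine O(f_lr) curvature (~10% at f_lr = 1e-3 for E→E), so the three-way
consistency is asserted after Richardson extrapolation in f_lr.

**Two-mode fluctuation theory.**  The variance of activity differences
between two coupled modules (and per-wavenumber chain spectra) comes from
integrating the projected Poisson-noise covariance along the cycle with
the per-mode contraction factors `mu_j mu_k/(1 - mu_j mu_k)`.  Complex
multiplier pairs are handled in complex arithmetic; the two-module result
is asserted real to 1e-8 relative, and chain spectra use Hermitian
products (the correct `<|.|^2>` for complex Fourier modes; identical to
the non-conjugated form when multipliers are real).  The Poisson sampling
floor `mean(r)/(N_E bin)` is reported separately since it depends on the
observation bin.  Accuracy: at f_lr = 0.1, N = 1e5 the prediction matches
stochastic simulations to < 10%; at f_lr = 0.02 phase excursions reach a
sizable fraction of the period and the linear calculation overestimates by
~20% (the periodicity-aware phase approximation brackets from below) — the
tests encode these bands.

**Chain dispersion.**  Critical and fastest-growing wavenumbers are found
by bisection/minimization over the effective coupling and mapped to q
through the exact inversion of `C~(q) = 1 - 2 f_lr` (the small-lambda
approximation `q = lambda sqrt(2 f/(1-2f))` is also reported; they differ
by < 1% at lambda = 1/3).  The E→E,I long-wavelength relaxation rate
`sigma_q = D_phi^EI [1 - C~(q)]` is the first-order expansion of the exact
per-q Floquet rate `-ln mu_1(q)/T`; at L = 64 (effective coupling 0.04)
they differ by ~18%, so simulation tests compare against the exact rate
(agreement ~1% using per-period envelope fitting of the spatial-mode
amplitude, which is insensitive to the periodic modulation of the decaying
eigenfunction).

## 5. Signal analysis

Correlograms follow the deviatory-product definition with the zero-lag
Poisson correction `mean(r)/(N bin)` for autocorrelations.  The
autocorrelation decay time is fitted with the dephasing form
`2 sum_n p_n cos(2 pi n tau/T) exp(-n^2 tau/tau_D)` (shared tau_D, n^2
harmonic scaling, non-negative powers).  At moderate N (~1e4) the measured
decay is slower than the pure-dephasing prediction — fluctuations distort
the cycle itself and the phase description degrades, exactly the regime
where the reduction is expected to lose accuracy; at N >= 4e4 prediction
and fit agree within ~20%.

Hilbert phases: rates are averaged into 1 ms bins, band-passed at
15-40 Hz with a fifth-order Butterworth filter applied forward-backward
(zero phase), and the analytic-signal angle is unwrapped in time.  The
mean period T_bar comes from the peak of the per-module-averaged
periodogram.  The time-valued phase is the *peak-time delay* (the negative
of the analytic-signal angle times T/2pi), so a wave travelling toward
increasing module index has a positive gradient and velocity `1/grad`
(modules/ms), matching `v = d/grad` in physical units.  Nearest-neighbour
gradients are mapped into (-T_bar/2, T_bar/2].

A caution established while validating: the *global* drift of the
band-passed Hilbert phase is a biased estimator of the oscillator phase —
broadband in-band noise pulls the unwrapping rate toward the band's
spectral centroid, inflating apparent frequency and diffusion.  Oscillator
phase diffusion is therefore measured from Poincare crossing times of the
low-pass-filtered rate (tests) or from the autocorrelation decay; phase
*differences* between modules are unaffected (the bias is common mode).

Propagation events: local gradients are averaged over five neighbouring
pairs and retained when the absolute average exceeds the standard
deviation of the contributing differences (with a 1e-6 ms floor so that
numerically synchronized noiseless chains yield no events).  On
spatially-independent noise the retention rate is ~12% (regression-pinned
in the tests).  Velocities come from the lateral shift minimizing the
squared wrapped phase-profile distance at frame lags 1-5 (ties to the
smallest shift, sub-module parabolic refinement, least-squares slope over
lags).  The per-event velocity is noisy (shift quantization); the
systematic agreement with `1/grad` is tight on decile-binned averages
(r > 0.95 at desk scale).

Spatial spectra use the unitary convention `P(q) = <|L^{-1/2} sum_n dr_n
exp(-iqn)|^2>` (Parseval: `sum_q P = sum_n dr_n^2` per frame), matching
the theory's mode normalization.

## 6. Synthetic fixtures and what passing means

The workbench fixtures plant known structure: pure and lagged sinusoids,
traveling waves `cos(2 pi (t/T - x/Lambda))`, spatially independent white
noise, correlograms drawn exactly from the dephasing family, and Poisson
spike-count sampling.  They validate the analysis pipeline's kinematic
identities and calibration, not the network model; conversely the
stochastic-simulation tests validate the theory under the model's own
assumptions (white Poisson noise, instantaneous synapses, no delays,
identical modules).  Passing therefore demonstrates internal quantitative
consistency of model, theory and analysis at desk scale — not that real
cortex satisfies the assumptions (no synaptic delays or conduction times,
no heterogeneity, no correlated external input, 1-D chains only).

## 7. Problem sizes

Default desk-scale sizes used by tests and the acceptance script: transfer
tables at the resolutions above; chains of L = 64 modules (up to 128 for
relaxation-rate checks, 1024 for pure-theory spectra); module sizes N =
5e3-1e5 for rate-model runs (2e4-s single-module runs for decay-time
fits); spiking networks of N = 2e3-5e3 for seconds.  The theory
quadratures use the full cycle resolution (~6400 samples).  Full-scale
settings (N up to 1.6e6, L = 256-512 chains, hundreds of seconds) are
reachable through the same APIs; recipes encode desk-scale defaults.
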