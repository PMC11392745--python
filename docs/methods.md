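# Methods

## The model

The package simulates a two-population network of N_E excitatory and N_I
inhibitory quadratic integrate-and-fire (QIF) neurons.  Each membrane
potential obeys

    tau_m dv_j/dt = v_j^2 + I_j + xi_j(t) + tau_m S(t) + I_theta(t),

where `I_j` is a quenched excitability drawn once from a Cauchy
(Lorentzian) distribution centred at `I0` with half-width at half-maximum
(HWHM) `Delta`, `xi_j` is independent zero-centred Cauchy white noise of
HWHM `Gamma`, `S(t)` is the delta-pulse population coupling and
`I_theta(t) = A sin(2 pi f_theta t)` an optional 10 Hz sinusoidal drive to
the excitatory population.  Neurons crossing `v_peak = 100` are reset to
`v_reset = -100` and clamped for `2 tau_m / 100` ms (the time the exact
model spends on the excursion to +/- infinity); the spike is recorded
halfway through the clamp and each spike increments every connected
postsynaptic voltage by `J_eff / N_pre` at the recorded time.  In sparse
networks each directed edge is kept with probability `1 - P_C` and weights
are divided by `1 - P_C`, preserving the mean interaction strength.

Because the disorder is Cauchy, the N -> infinity dynamics closes exactly
on four collective variables per the Lorentzian-ansatz reduction: the
population rates R_E, R_I (internally 1/ms) and mean voltages V_E, V_I,

    dR_X/dt = 2 R_X V_X / tau + Delta_eff_X / (pi tau^2),
    dV_X/dt = (V_X^2 + I0_X [+ I_theta]) / tau - tau (pi R_X)^2
              + J_XE R_E - J_XI R_I,

with `Delta_eff_X = Delta_X + Gamma_X`: quenched heterogeneity and Cauchy
noise are exactly interchangeable at the collective level (a property the
test suite asserts bitwise), while their microscopic spike statistics
differ sharply — the basis of the bursting-subgroup analysis below.

### Coupling-term convention

Printed forms of the network equation sometimes carry an ambiguous factor
of 2 on the synaptic term.  We fix the convention by requiring the
network's mean-field limit to equal the mass equations above exactly: a
per-spike voltage kick of `J_eff / N_pre`, with the coupling entering the
voltage equation as `+[J_XE R_E - J_XI R_I]` (no factor 2).  Under this
convention the mass model's chaos onset at `Delta_eff_E = 0.4` computes to
I0_E = 0.475, matching the reference value 0.47; the doubled convention
destroys the chaotic pocket entirely (the attractor stays a limit cycle),
which rules it out.

### Finite-size closure

Finite-N fluctuations are modelled by augmenting each population's drive
with one Gaussian white-noise term per synaptic channel, of amplitude
`J_ab sqrt(R_b / (N_b dt))` in the voltage equation, integrated with
Euler-Maruyama (rates clamped at zero inside the amplitude).  The ζ
variables are standard unit-variance Gaussians, satisfying the white-noise
correlator `<ζζ'> = δ(t - t')`; a bounded-support reading of the noise
would violate that normalisation, so it is not used.  The closure
reproduces the `Sigma_V ~ N^(-1/2)` scaling of the asynchronous regime
(log-log slope -0.50 in the tests) and noise-induced gamma bursts near
the Hopf bifurcation.

## Units

Internal time is milliseconds and internal rates 1/ms throughout; every
user-facing frequency (spectra, bands, burst statistics) is converted to
Hz at the I/O boundary.  Voltages, drives and weights are in the
dimensionless QIF units of the model.  One published bifurcation diagram
labels peak rates in "Hz" with values of order 1; our Feigenbaum scan
reports peak R_E in 1/ms and we flag, rather than guess at, that
discrepancy.

## Stability toolbox

* **Fixed points** — damped Newton with the analytic Jacobian, step-
  limited to keep both rates positive, multi-started from a coarse grid
  of rates placed on the R-nullcline `V = -Delta_eff / (2 pi tau R)`.
  Roots are accepted at sup-norm residual < 1e-10.
* **Hopf detection** — natural continuation in I0_E (previous root seeds
  the next solve), watching the leading complex-conjugate eigenvalue
  pair; the sign change is bisected to 1e-3 in drive.
* **Lyapunov spectra** — Benettin's method: base RK4 (dt = 0.01 ms) plus
  tangent vectors integrated with the Jacobian evaluated at the base RK4
  stage points, QR-reorthonormalised every 1 ms.  Diagnostics: the sum of
  the four exponents matches the time-averaged Jacobian trace to < 0.1%
  in practice (asserted at 5%), and at a stable fixed point the spectrum
  reproduces the eigenvalue real parts to ~2e-4 /ms over a 20 s run.
* **Chaos onset** — smallest drive with lambda_1 > 1e-3 /ms on an upward
  scan (the transition is discontinuous and direction matters; the upward
  scan from the asynchronous side is the reported convention), bisection-
  refined to 5e-3.
* **Classification** — stable fixed point + decayed probe trajectory ->
  asynchronous; stable fixed point + sustained oscillation -> bistable;
  unstable fixed point + |lambda_1| < 1e-3 /ms -> PING; lambda_1 > 1e-3
  /ms -> IBG.  Probes start from the fixed point plus (0.01, 0.01, 0, 0).
  Conflicting evidence yields "unclassified" with diagnostics.

## Signal metrics

Spectrograms use SciPy's STFT with 0.05 s windows and 90% overlap,
max-normalised and log10-floored (1e-1 or 1e-5 by figure convention).
Envelope and phase extraction uses a 4th-order zero-phase Butterworth
band-pass (theta 8-12 Hz, gamma 30-100 Hz by default — the bands bracket
the 10 Hz drive and the 50-70 Hz bursts; the reference text states no
bands) followed by the Hilbert transform, with 0.5 s trimmed per edge
before any statistic.  PAC is the raw mean vector length
`|mean(A_gamma e^{i phi_theta})|`, in units of the amplitude signal (no
surrogate normalisation).  Bursts are maximal intervals with gamma
envelope above mean + k SD (k = 1) lasting >= 20 ms after bridging gaps
< 10 ms.  The E->I delay is the parabolic-refined cross-correlation peak
lag of R_E leading R_I; for sweeps across coupling strengths the lag
window must stay below half an oscillation period to avoid locking onto
the neighbouring cycle.

## Scaled-down study conditions

Reference-scale numerics (N = 16,000 neurons, network dt = 0.00015 ms,
~100 s windows) are config-reachable (`scale="paper"`), but all tests and
the acceptance script run desk-scale equivalents chosen once:

* network: N = 1000-4000 per population, Euler dt = 0.005 ms (a free
  neuron at threshold then moves 10 << v_peak per step), 10-20 s windows
  after 1-2 s transients;
* mass model: RK4 dt = 0.01 ms, 10-100 s windows; Lyapunov scans 20 s per
  point after 2 s transients;
* rate bins 0.1 ms (the ~2 ms PING delay needs sub-ms resolution), 1 ms
  for spectra.

Two desk-scale effects are worth recording.  First, with pure Cauchy
noise the network tracks the mass model closely already at N = 1000; with
quenched heterogeneity the effective chaos onset of the sampled network
sits ~0.05-0.1 drive units above the mass-level 0.475 at N = 2000-4000
(finite-sample corrections to the Lorentzian; the effect shrinks with N).
The bursting-subgroup analysis therefore probes the drive upward from the
mass-level pocket and measures just inside the network's own bursting
regime, mirroring the reference placement just above the mass-level
onset.  Because that onset is discontinuous, the burst sparsity reached
just above it — and with it the exact location of the bursting
subgroup's CV mode (~1.2-2.4 across quenched realizations, around the
reference cv ~ 2) — varies from realization to realization at desk
scale.  Second, the mean membrane potential of the network carries a
constant negative offset relative to the mass V (reset clamps at -100 and
truncated Lorentzian tails); all metrics are offset-invariant, and
waveform agreement is assessed on cycle-averaged, band-limited (< 200 Hz)
traces, where network and mass agree to a few percent — the high
harmonics of the voltage spike differ systematically because the network
has a finite threshold at 100 where the exact reduction assumes infinity.

## What the generator does and does not emulate

The spiking simulator is the package's synthetic-data source.  It
reproduces the collective phenomenology the mass model predicts —
asynchronous irregular activity, PING cycles with an E->I delay of ~2 ms,
deterministic chaotic gamma bursts, noise-induced bursts near the Hopf,
theta-gamma PAC — and the microscopic signatures the reduction cannot see
(bimodal CV with a bursting subgroup near cv ~ 2 under quenched
heterogeneity; unimodal high CV under Cauchy noise).  It does not include
synaptic kinetics, conduction delays, conductance-based synapses, or
non-Cauchy heterogeneity; passing tests therefore say nothing about
models with those features.

## Known limitations and open numbers

* The Hopf critical drive at `Delta_eff_E = 6.0` computes to -2.822 under
  the printed parameter set (confirmed independently by finite-difference
  Jacobians and by direct integration of the onset), against a reference
  value of -2.88; the chaos onset at 0.4 verifies exactly.  A ~5%
  perturbation of a single coupling (e.g. J_IE) moves the Hopf by more
  than this gap, so the difference is consistent with a small parameter
  or method difference upstream; we report what the stated equations and
  parameters give.
* Mean gamma-burst duration is strongly detector-dependent: the declared
  detector (Hilbert envelope, mean + 1 SD, >= 20 ms, gaps < 10 ms merged)
  yields ~35 ms at the chaotic operating point because the chaotic
  attractor alternates large and small cycles and the envelope dips
  inside a visually continuous ~100-300 ms burst; smoothed-envelope or
  dual-threshold variants yield 45-95 ms.  The in-burst dominant
  frequency (~67 Hz) is robust across detectors.
* No continuation of unstable limit cycles or two-parameter bifurcation
  curves: codimension-1 points are located numerically and the bistable
  window is mapped by adiabatic hysteresis sweeps instead.
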