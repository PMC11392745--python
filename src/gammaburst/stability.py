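"""Stability and bifurcation analysis of the neural mass model.

Implements the tools used to map the (I0_E, Delta_eff_E) plane: damped-
Newton fixed-point location with natural continuation, eigenvalue-based
Hopf detection, the Benettin Lyapunov spectrum via tangent-space RK4 with
periodic QR reorthonormalization, peak-value (Feigenbaum) scans across the
period-doubling cascade, adiabatic hysteresis sweeps, and a decision-rule
regime classifier (asynchronous / PING / bistable / IBG).

Thresholds used by the classifier (all configurable):

* ``LAMBDA_TOL`` = 1e-3 / ms separates "zero" from "positive" largest
  Lyapunov exponents: |lambda_1| < tol is treated as a limit cycle,
  lambda_1 > tol as chaos.
* ``OSC_SIGMA_TOL`` = 1e-3 on the standard deviation of V_E separates a
  decayed trajectory from a sustained oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model_core import ModelParams, SimulationConfig
from .neural_mass import (MassState, pack_params, _rhs, _jac, _rk4_step,
                          integrate_mass)

__all__ = [
    "LyapunovResult",
    "RegimeLabel",
    "PhaseDiagram",
    "find_fixed_point",
    "jacobian_at",
    "detect_hopf",
    "lyapunov_spectrum",
    "feigenbaum_scan",
    "detect_chaos_onset",
    "hysteresis_sweep",
    "classify_regime",
    "phase_diagram_scan",
]

LAMBDA_TOL = 1e-3       # 1/ms: |lambda_1| below -> limit cycle, above -> chaos
OSC_SIGMA_TOL = 1e-3    # sigma_V below -> trajectory decayed to fixed point
# Oscillation probes start from the fixed point plus this perturbation
PROBE_PERTURBATION = np.array([0.01, 0.01, 0.0, 0.0])


class FixedPointNotFound(RuntimeError):
    pass


class BranchLost(RuntimeError):
    def __init__(self, msg, last_good_drive=None):
        super().__init__(msg)
        self.last_good_drive = last_good_drive


# ----------------------------------------------------------------- fixed points

def _newton(p, y0, tol=1e-12, max_iter=200):
    """Damped Newton on the mass vector field, keeping both rates positive."""
    y = np.asarray(y0, float).copy()
    for _ in range(max_iter):
        f = _rhs(y, p, 0.0)
        if np.max(np.abs(f)) < tol:
            return y
        try:
            step = np.linalg.solve(_jac(y, p), f)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        while lam > 1e-9:
            yn = y - lam * step
            if yn[0] > 0 and yn[2] > 0:
                break
            lam *= 0.5
        y = y - lam * step
    return y if np.max(np.abs(_rhs(y, p, 0.0))) < 1e-10 else None


def find_fixed_point(params: ModelParams, guess: MassState | None = None,
                     residual_tol: float = 1e-10):
    """Locate an equilibrium of the mass model (R_E, R_I > 0 branch).

    Damped Newton iteration with the analytic Jacobian, falling back to a
    multi-start over a coarse grid of rates (with V on the R-nullcline
    V = -Delta_eff / (2 pi tau R)) when the supplied guess fails.

    Returns ``(state, residual)``; raises :class:`FixedPointNotFound` if no
    root with positive rates is found.
    """
    p = pack_params(params)
    starts = []
    if guess is not None:
        starts.append(guess.as_array())
    for re in (0.001, 0.005, 0.02, 0.05, 0.1, 0.3):
        for ri in (0.001, 0.02, 0.1, 0.3):
            ve = -p[4] / (2 * np.pi * p[0] * re) if p[4] > 0 else -1.0
            vi = -p[5] / (2 * np.pi * p[1] * ri) if p[5] > 0 else -1.0
            starts.append(np.array([re, ve, ri, vi]))
    for y0 in starts:
        y = _newton(p, y0)
        if y is None or not (y[0] > 0 and y[2] > 0):
            continue
        res = float(np.max(np.abs(_rhs(y, p, 0.0))))
        if res < residual_tol:
            return MassState.from_array(y), res
    raise FixedPointNotFound(
        f"no equilibrium with positive rates at I0_E={params.I0_E}, "
        f"Delta_eff_E={params.Delta_eff_E}")


def jacobian_at(params: ModelParams, state: MassState) -> np.ndarray:
    """4x4 Jacobian of the mass vector field at ``state``."""
    return np.asarray(_jac(state.as_array(), pack_params(params)))


def _max_real_eig(params, state):
    return float(np.linalg.eigvals(jacobian_at(params, state)).real.max())


# ------------------------------------------------------------------------ Hopf

def detect_hopf(params: ModelParams, drive_range=(-5.0, 0.0), d_step=0.02,
                refine_tol=1e-3):
    """Critical drive where the fixed point loses stability to a complex pair.

    Tracks the positive-rate equilibrium by natural continuation in I0_E
    (previous root as next guess), watching the largest real part among the
    Jacobian's complex-conjugate eigenvalue pairs; the detected sign change
    is refined by bisection to ``refine_tol``.  Returns ``None`` when no
    crossing occurs in range.
    """
    lo, hi = drive_range
    if hi <= lo:
        raise ValueError("drive_range must be increasing")

    def complex_max_re(pp, st):
        ev = np.linalg.eigvals(jacobian_at(pp, st))
        pairs = ev[np.abs(ev.imag) > 1e-12]
        return float(pairs.real.max()) if len(pairs) else None

    guess = None
    prev = None
    last_good = None
    for drive in np.arange(lo, hi + 0.5 * d_step, d_step):
        pp = params.replace(I0_E=float(drive))
        try:
            st, _ = find_fixed_point(pp, guess)
        except FixedPointNotFound:
            raise BranchLost(f"fixed-point branch lost at I0_E={drive:.4f}",
                             last_good_drive=last_good)
        guess = st
        last_good = float(drive)
        m = complex_max_re(pp, st)
        if m is None:
            prev = None
            continue
        if prev is not None and prev[1] < 0 <= m:
            a, b = prev[0], float(drive)
            ga = prev[2]
            while b - a > refine_tol:
                c = 0.5 * (a + b)
                stc, _ = find_fixed_point(params.replace(I0_E=c), ga)
                if complex_max_re(params.replace(I0_E=c), stc) < 0:
                    a, ga = c, stc
                else:
                    b = c
            return 0.5 * (a + b)
        prev = (float(drive), m, st)
    return None


# -------------------------------------------------------------------- Lyapunov

@njit(cache=True)
def _benettin(y0, p, dt, n_transient, n_steps, renorm_every, n_exp, v_bound):
    y = y0.copy()
    t = 0.0
    for _ in range(n_transient):
        y = _rk4_step(y, p, t, dt)
        t += dt
    Q = np.eye(4)[:, :n_exp].copy()
    logs = np.zeros(n_exp)
    n_blocks = n_steps // renorm_every
    trace_len = min(n_blocks, 2000)
    conv = np.zeros((trace_len, n_exp))
    tr_sum = 0.0
    b = 0
    for i in range(n_steps):
        # tangent RK4 uses the Jacobian frozen at the base RK4 stage points
        J1 = _jac(y, p)
        y1 = y + 0.5 * dt * _rhs(y, p, t)
        J2 = _jac(y1, p)
        y2 = y + 0.5 * dt * (_rhs(y1, p, t + 0.5 * dt))
        J3 = _jac(y2, p)
        y3 = y + dt * (_rhs(y2, p, t + 0.5 * dt))
        J4 = _jac(y3, p)
        for j in range(n_exp):
            d = Q[:, j].copy()
            k1 = J1 @ d
            k2 = J2 @ (d + 0.5 * dt * k1)
            k3 = J3 @ (d + 0.5 * dt * k2)
            k4 = J4 @ (d + dt * k3)
            Q[:, j] = d + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        tr_sum += (J1[0, 0] + J1[1, 1] + J1[2, 2] + J1[3, 3]) * dt
        y = _rk4_step(y, p, t, dt)
        t += dt
        if not np.isfinite(y[1]) or abs(y[1]) > v_bound:
            return logs, conv[:0], t, tr_sum, 1
        if (i + 1) % renorm_every == 0:
            q, r = np.linalg.qr(Q)
            for j in range(n_exp):
                d = abs(r[j, j])
                logs[j] += np.log(d)
                # keep orientation deterministic
                if r[j, j] < 0:
                    q[:, j] = -q[:, j]
            Q = q[:, :n_exp].copy()
            if b < trace_len:
                conv[b] = logs / ((i + 1) * dt)
                b += 1
    return logs, conv[:b], t, tr_sum, 0


@dataclass
class LyapunovResult:
    """Sorted Lyapunov exponents (1/ms) with their convergence trace."""

    exponents: np.ndarray
    integration_time_ms: float
    renorm_interval_ms: float
    convergence: np.ndarray = field(repr=False, default=None)
    mean_jacobian_trace: float = 0.0

    @property
    def lambda_max(self) -> float:
        return float(self.exponents[0])


def lyapunov_spectrum(params: ModelParams, config: SimulationConfig | None = None,
                      n_exp: int = 4, initial: MassState | None = None,
                      renorm_ms: float = 1.0) -> LyapunovResult:
    """Benettin-style Lyapunov spectrum of the mass model.

    The base trajectory and ``n_exp`` tangent vectors are integrated
    jointly with RK4 (tangent stages use the Jacobian at the base-stage
    points) and reorthonormalized by QR every ``renorm_ms``.  Exponents are
    the time-averaged log stretch factors, returned sorted descending.
    """
    config = config or SimulationConfig(dt=0.01, transient_s=2.0, duration_s=20.0)
    if initial is None:
        try:
            st, _ = find_fixed_point(params)
            y0 = st.as_array() + PROBE_PERTURBATION
        except FixedPointNotFound:
            y0 = np.array([0.05, -1.0, 0.05, -1.0])
    else:
        y0 = initial.as_array()
    dt = config.dt
    n_tr = int(round(config.transient_s * 1000.0 / dt))
    n_st = int(round(config.duration_s * 1000.0 / dt))
    renorm = max(1, int(round(renorm_ms / dt)))
    logs, conv, t_end, tr_sum, failed = _benettin(
        y0, pack_params(params), dt, n_tr, n_st, renorm, n_exp, 1e4)
    if failed:
        raise FloatingPointError(f"divergence during Lyapunov integration "
                                 f"at t = {t_end:.2f} ms")
    T = n_st * dt
    lam = np.sort(logs / T)[::-1]
    return LyapunovResult(lam, T, renorm * dt, conv, tr_sum / T)


# ------------------------------------------------------- Feigenbaum / chaos onset

def feigenbaum_scan(params: ModelParams, drive_values,
                    config: SimulationConfig | None = None,
                    prominence: float = 1e-4):
    """Local maxima of R_E(t) per drive (the attractor's peak set).

    One distinct peak value = period-1 cycle, two = period-2, a broad set =
    chaos candidate.  The state is carried from one drive to the next
    (adiabatic continuation of the attractor).
    """
    from scipy.signal import find_peaks
    config = config or SimulationConfig(dt=0.01, transient_s=2.0, duration_s=4.0)
    state = None
    out = {}
    for drive in np.asarray(drive_values, float):
        pp = params.replace(I0_E=float(drive))
        traj = integrate_mass(pp, config, initial=state, sample_dt=0.05)
        state = traj.final_state()
        idx, _ = find_peaks(traj.R_E, prominence=prominence)
        out[float(drive)] = traj.R_E[idx]
    return out


def detect_chaos_onset(params: ModelParams, drive_range, d_step=0.01,
                       config: SimulationConfig | None = None,
                       lambda_tol: float = LAMBDA_TOL,
                       refine_tol: float = 5e-3):
    """Smallest drive with a positive largest Lyapunov exponent.

    Scans I0_E upward (from the asynchronous, stable-fixed-point side) and
    bisection-refines the first crossing of ``lambda_tol``.  The transition
    is discontinuous, so the reported onset is tied to this upward scan
    direction.  Returns ``None`` if lambda_1 never exceeds the tolerance.
    """
    config = config or SimulationConfig(dt=0.01, transient_s=2.0, duration_s=20.0)
    lo, hi = drive_range

    def lam1(drive):
        return lyapunov_spectrum(params.replace(I0_E=float(drive)),
                                 config, n_exp=1).lambda_max

    prev = None
    for drive in np.arange(lo, hi + 0.5 * d_step, d_step):
        m = lam1(drive)
        if m > lambda_tol:
            if prev is None:
                return float(drive)
            a, b = prev, float(drive)
            while b - a > refine_tol:
                c = 0.5 * (a + b)
                if lam1(c) > lambda_tol:
                    b = c
                else:
                    a = c
            return b
        prev = float(drive)
    return None


# ------------------------------------------------------------------- hysteresis

def hysteresis_sweep(params: ModelParams, control_values, direction="up",
                     level="mass", config: SimulationConfig | None = None,
                     fs=None, sample_dt: float = 0.1):
    """Adiabatic sweep of Gamma_E recording the oscillation amplitude Sigma_V.

    The state at the end of one control value seeds the next (adiabatic
    protocol); sweeping ``up`` then ``down`` and comparing the two curves
    exposes the bistable window bounded by the saddle-node of limit
    cycles.  ``level`` selects the deterministic mass model ("mass"), the
    finite-size stochastic mass model ("mass-finite", requires ``fs``), or
    the spiking network ("network").
    """
    from .oscillation_metrics import sigma_v
    control = np.asarray(control_values, float)
    if direction == "down":
        control = control[::-1]
    elif direction != "up":
        raise ValueError("direction must be 'up' or 'down'")
    config = config or SimulationConfig(dt=0.01, transient_s=1.0, duration_s=4.0)

    out = np.empty(len(control))
    state = None
    net_state = None
    for i, g in enumerate(control):
        pp = params.replace(Gamma_E=float(g), Delta_E=0.0)
        if level == "mass":
            traj = integrate_mass(pp, config, initial=state, sample_dt=sample_dt)
            state = traj.final_state()
            out[i] = sigma_v(traj.V_E)
        elif level == "mass-finite":
            from .neural_mass import integrate_mass_finite_size
            traj = integrate_mass_finite_size(pp, config, fs, initial=state,
                                              sample_dt=sample_dt)
            state = traj.final_state()
            out[i] = sigma_v(traj.V_E)
        elif level == "network":
            from .qif_network import build_connectivity, simulate_network
            conn = build_connectivity(pp, seed=config.seed)
            _, series, net_state = simulate_network(
                pp, config, conn, initial_state=net_state, return_state=True)
            out[i] = sigma_v(series.V_E)
        else:
            raise ValueError(f"unknown level {level!r}")
    return control, out


# --------------------------------------------------------------- classification

@dataclass
class RegimeLabel:
    """Classification of one parameter point with its supporting evidence."""

    label: str                   # asynchronous | PING | bistable | IBG | unclassified
    lambda_max: float
    fixed_point_stable: bool | None
    sigma_v: float
    diagnostics: dict = field(default_factory=dict)


def classify_regime(params: ModelParams, config: SimulationConfig | None = None,
                    lambda_tol: float = LAMBDA_TOL,
                    sigma_tol: float = OSC_SIGMA_TOL) -> RegimeLabel:
    """Decision-rule regime label for one (I0_E, Delta_eff_E) point.

    1. locate the fixed point and test its linear stability;
    2. integrate a trajectory from the perturbed fixed point, measure the
       oscillation amplitude Sigma_V and the largest Lyapunov exponent;
    3. label: stable FP + decayed trajectory -> asynchronous; stable FP +
       sustained oscillation -> bistable; unstable FP + |lambda_1| small ->
       PING; lambda_1 > tol -> IBG (collective chaos).

    Conflicting evidence yields ``unclassified`` with diagnostics rather
    than a silent guess.
    """
    from .oscillation_metrics import sigma_v
    config = config or SimulationConfig(dt=0.01, transient_s=2.0, duration_s=10.0)
    diag = {}
    fp_stable = None
    init = None
    try:
        st, res = find_fixed_point(params)
        fp_stable = _max_real_eig(params, st) < 0
        diag["fixed_point"] = st
        diag["fp_residual"] = res
        init = MassState.from_array(st.as_array() + PROBE_PERTURBATION)
    except FixedPointNotFound:
        diag["fixed_point"] = None

    traj = integrate_mass(params, config, initial=init)
    sv = float(sigma_v(traj.V_E[len(traj.V_E) // 2:]))
    lam = lyapunov_spectrum(params, config, n_exp=1, initial=init).lambda_max
    diag["lambda_max"] = lam

    if lam > lambda_tol:
        label = "IBG"
    elif fp_stable is True and sv < sigma_tol:
        label = "asynchronous"
    elif fp_stable is True and sv >= sigma_tol:
        label = "bistable"
    elif fp_stable is False and abs(lam) <= lambda_tol and sv >= sigma_tol:
        label = "PING"
    elif fp_stable is False and lam < -lambda_tol and sv < sigma_tol:
        # trajectory decayed although the FP is linearly unstable: conflict
        label = "unclassified"
    elif fp_stable is None:
        label = "unclassified"
    else:
        label = "unclassified"
    return RegimeLabel(label, lam, fp_stable, sv, diag)


@dataclass
class PhaseDiagram:
    """Rectangular grid of regime labels over (I0_E, Delta_eff_E)."""

    drives: np.ndarray
    delta_effs: np.ndarray
    labels: np.ndarray          # object array of str, shape (len(delta), len(drive))
    lambda_max: np.ndarray
    sigma_v: np.ndarray
    mean_freq_hz: np.ndarray

    def to_dataframe(self):
        import pandas as pd
        rows = []
        for i, d in enumerate(self.delta_effs):
            for j, g in enumerate(self.drives):
                rows.append((g, d, self.labels[i, j], self.lambda_max[i, j],
                             self.sigma_v[i, j], self.mean_freq_hz[i, j]))
        return pd.DataFrame(rows, columns=[
            "I0_E", "Delta_eff", "label", "lambda1", "sigma_V", "mean_freq_Hz"])

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def phase_diagram_scan(params: ModelParams, drives, delta_effs,
                       config: SimulationConfig | None = None) -> PhaseDiagram:
    """classify_regime + lambda_1 + Sigma_V + mean frequency per grid cell.

    Cells are independent (order never affects results); per-cell failures
    are recorded as ``failed`` labels and the scan continues.
    """
    from .oscillation_metrics import mean_frequency
    drives = np.asarray(drives, float)
    delta_effs = np.asarray(delta_effs, float)
    config = config or SimulationConfig(dt=0.01, transient_s=2.0, duration_s=10.0)
    shape = (len(delta_effs), len(drives))
    labels = np.empty(shape, object)
    lam = np.full(shape, np.nan)
    sv = np.full(shape, np.nan)
    freq = np.full(shape, np.nan)
    for i, d in enumerate(delta_effs):
        for j, g in enumerate(drives):
            pp = params.replace(I0_E=float(g), Delta_E=float(d), Gamma_E=0.0)
            try:
                r = classify_regime(pp, config)
                labels[i, j] = r.label
                lam[i, j] = r.lambda_max
                sv[i, j] = r.sigma_v
                if r.sigma_v >= OSC_SIGMA_TOL:
                    traj = integrate_mass(pp, config)
                    freq[i, j] = mean_frequency(traj.V_E, traj.fs_hz)
            except Exception as e:  # per-cell failure: record, continue
                labels[i, j] = "failed"
    return PhaseDiagram(drives, delta_effs, labels, lam, sv, freq)
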