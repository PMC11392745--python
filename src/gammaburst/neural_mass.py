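"""Exact four-variable neural mass model of the E-I QIF network.

For Cauchy-distributed excitabilities (and/or Cauchy membrane noise) the
N -> infinity dynamics of the spiking network closes exactly on four
collective variables: the population rates R_E, R_I (1/ms) and the mean
membrane potentials V_E, V_I.  The disorder enters only through the
effective half-widths Delta_eff_X = Delta_X + Gamma_X; quenched
heterogeneity and Cauchy noise are interchangeable at this level.

The module provides the vector field, its exact linearization (the tangent
/ variational system used for Lyapunov analysis), a fixed-step RK4
integrator, and an Euler-Maruyama integrator with the finite-size
rate-fluctuation closure: each synaptic channel alpha<-beta contributes a
Gaussian white-noise term of amplitude J_ab * sqrt(R_beta / (N_beta dt))
to the drive of population alpha, vanishing as N -> infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model_core import ModelParams, SimulationConfig, RngStreams

__all__ = [
    "MassState",
    "FiniteSizeConfig",
    "pack_params",
    "mass_derivatives",
    "tangent_derivatives",
    "integrate_mass",
    "integrate_mass_finite_size",
    "MassTrajectory",
]

# Index layout of the packed parameter vector handed to numba kernels.
# [tauE, tauI, I0E, I0I, dEeff, dIeff, JEE, JEI, JIE, JII, A, f_theta_Hz]
_NP = 12


@dataclass
class MassState:
    """The four collective variables (R in 1/ms, V in model units)."""

    R_E: float
    V_E: float
    R_I: float
    V_I: float
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.R_E, self.V_E, self.R_I, self.V_I], float)

    @classmethod
    def from_array(cls, y, t=0.0) -> "MassState":
        return cls(float(y[0]), float(y[1]), float(y[2]), float(y[3]), t)


@dataclass
class FiniteSizeConfig:
    """Effective population sizes for the stochastic rate closure."""

    N_E: int = 8000
    N_I: int = 8000
    seed: int = 0

    def __post_init__(self):
        if self.N_E < 1 or self.N_I < 1:
            raise ValueError("population sizes must be >= 1")


def pack_params(params: ModelParams) -> np.ndarray:
    return np.array([
        params.tau_m_E, params.tau_m_I, params.I0_E, params.I0_I,
        params.Delta_eff_E, params.Delta_eff_I,
        params.J_EE, params.J_EI, params.J_IE, params.J_II,
        params.theta_amplitude, params.theta_frequency,
    ])


@njit(cache=True)
def _rhs(y, p, t):
    tauE, tauI = p[0], p[1]
    theta = p[10] * np.sin(2.0 * np.pi * p[11] * t / 1000.0)
    RE, VE, RI, VI = y[0], y[1], y[2], y[3]
    out = np.empty(4)
    out[0] = 2.0 * RE * VE / tauE + p[4] / (tauE * tauE * np.pi)
    out[1] = ((VE * VE + p[2] + theta) / tauE
              - tauE * (np.pi * RE) ** 2 + p[6] * RE - p[7] * RI)
    out[2] = 2.0 * RI * VI / tauI + p[5] / (tauI * tauI * np.pi)
    out[3] = ((VI * VI + p[3]) / tauI
              - tauI * (np.pi * RI) ** 2 + p[8] * RE - p[9] * RI)
    return out


@njit(cache=True)
def _jac(y, p):
    """4x4 Jacobian of the vector field (theta drive is additive: no entry)."""
    tauE, tauI = p[0], p[1]
    RE, VE, RI, VI = y[0], y[1], y[2], y[3]
    J = np.zeros((4, 4))
    J[0, 0] = 2.0 * VE / tauE
    J[0, 1] = 2.0 * RE / tauE
    J[1, 0] = -2.0 * np.pi ** 2 * tauE * RE + p[6]
    J[1, 1] = 2.0 * VE / tauE
    J[1, 2] = -p[7]
    J[2, 2] = 2.0 * VI / tauI
    J[2, 3] = 2.0 * RI / tauI
    J[3, 0] = p[8]
    J[3, 2] = -2.0 * np.pi ** 2 * tauI * RI - p[9]
    J[3, 3] = 2.0 * VI / tauI
    return J


@njit(cache=True)
def _rk4_step(y, p, t, dt):
    k1 = _rhs(y, p, t)
    k2 = _rhs(y + 0.5 * dt * k1, p, t + 0.5 * dt)
    k3 = _rhs(y + 0.5 * dt * k2, p, t + 0.5 * dt)
    k4 = _rhs(y + dt * k3, p, t + dt)
    return y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@njit(cache=True)
def _integrate(y0, p, dt, n_transient, n_steps, stride, v_bound):
    y = y0.copy()
    t = 0.0
    for _ in range(n_transient):
        y = _rk4_step(y, p, t, dt)
        t += dt
    m = n_steps // stride
    out = np.empty((m, 4))
    k = 0
    for i in range(n_steps):
        y = _rk4_step(y, p, t, dt)
        t += dt
        if abs(y[1]) > v_bound or abs(y[3]) > v_bound or not np.isfinite(y[1]):
            return out[:k], t, 1
        if (i + 1) % stride == 0 and k < m:
            out[k] = y
            k += 1
    return out[:k], t, 0


@njit(cache=True)
def _integrate_finite_size(y0, p, dt, n_transient, n_steps, stride,
                           NE, NI, seed, v_bound):
    np.random.seed(seed)
    y = y0.copy()
    t = 0.0
    m = n_steps // stride
    out = np.empty((m, 4))
    k = 0
    for i in range(n_transient + n_steps):
        d = _rhs(y, p, t)
        RE = y[0] if y[0] > 0.0 else 0.0
        RI = y[2] if y[2] > 0.0 else 0.0
        # channel noise amplitudes sqrt(R_beta / (N_beta dt)), weight J_ab
        aEE = p[6] * np.sqrt(RE / (NE * dt))
        aEI = p[7] * np.sqrt(RI / (NI * dt))
        aIE = p[8] * np.sqrt(RE / (NE * dt))
        aII = p[9] * np.sqrt(RI / (NI * dt))
        y = y + dt * d
        y[1] += dt * (aEE * np.random.randn() + aEI * np.random.randn())
        y[3] += dt * (aIE * np.random.randn() + aII * np.random.randn())
        t += dt
        if abs(y[1]) > v_bound or not np.isfinite(y[1]):
            return out[:k], t, 1
        if i >= n_transient and (i - n_transient + 1) % stride == 0 and k < m:
            out[k] = y
            k += 1
    return out[:k], t, 0


@dataclass
class MassTrajectory:
    """Strided trajectory of the mass model (t in ms, R in 1/ms)."""

    t: np.ndarray
    R_E: np.ndarray
    V_E: np.ndarray
    R_I: np.ndarray
    V_I: np.ndarray
    sample_dt: float

    @property
    def fs_hz(self) -> float:
        """Sampling frequency in Hz."""
        return 1000.0 / self.sample_dt

    def final_state(self) -> MassState:
        return MassState(self.R_E[-1], self.V_E[-1], self.R_I[-1],
                         self.V_I[-1], self.t[-1])

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "t_ms": self.t, "R_E": self.R_E, "V_E": self.V_E,
            "R_I": self.R_I, "V_I": self.V_I,
        }).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "MassTrajectory":
        import pandas as pd
        df = pd.read_csv(path, float_precision="round_trip")
        expected = ["t_ms", "R_E", "V_E", "R_I", "V_I"]
        if list(df.columns) != expected:
            raise ValueError(f"malformed trajectory CSV: columns {list(df.columns)}"
                             f" != {expected}")
        dt = float(df.t_ms.iloc[1] - df.t_ms.iloc[0]) if len(df) > 1 else 0.0
        return cls(df.t_ms.to_numpy(), df.R_E.to_numpy(), df.V_E.to_numpy(),
                   df.R_I.to_numpy(), df.V_I.to_numpy(), dt)


def mass_derivatives(state: MassState, params: ModelParams, t: float | None = None):
    """Time derivative of the four collective variables (pure function)."""
    y = state.as_array()
    tt = state.t if t is None else t
    return MassState.from_array(_rhs(y, pack_params(params), tt), tt)


def tangent_derivatives(base: MassState, pert, params: ModelParams):
    """Exact linearization of the vector field applied to a perturbation.

    ``pert`` may be a length-4 array (dR_E, dV_E, dR_I, dV_I) or a
    MassState; returns an array of the same four components.
    """
    d = pert.as_array() if isinstance(pert, MassState) else np.asarray(pert, float)
    return _jac(base.as_array(), pack_params(params)) @ d


def _default_initial(params: ModelParams) -> MassState:
    return MassState(0.05, -1.0, 0.05, -1.0)


def integrate_mass(params: ModelParams, config: SimulationConfig,
                   initial: MassState | None = None,
                   sample_dt: float = 0.1, v_bound: float = 1e4) -> MassTrajectory:
    """Fixed-step RK4 trajectory of the deterministic mass model.

    The transient window is integrated and discarded; the measurement
    window is stored every ``sample_dt`` ms (decoupling the integration
    step from the analysis sampling).
    """
    y0 = (initial or _default_initial(params)).as_array()
    dt = config.dt
    stride = max(1, int(round(sample_dt / dt)))
    n_tr = int(round(config.transient_s * 1000.0 / dt))
    n_st = int(round(config.duration_s * 1000.0 / dt))
    out, t_end, failed = _integrate(y0, pack_params(params), dt, n_tr, n_st,
                                    stride, v_bound)
    if failed:
        raise FloatingPointError(
            f"mass-model divergence (|V| > {v_bound}) at t = {t_end:.3f} ms")
    tgrid = config.transient_s * 1000.0 + stride * dt * np.arange(1, len(out) + 1)
    return MassTrajectory(tgrid, out[:, 0], out[:, 1], out[:, 2], out[:, 3],
                          stride * dt)


def integrate_mass_finite_size(params: ModelParams, config: SimulationConfig,
                               fs: FiniteSizeConfig,
                               initial: MassState | None = None,
                               sample_dt: float = 0.1,
                               v_bound: float = 1e4) -> MassTrajectory:
    """Euler-Maruyama trajectory with the finite-size noise closure."""
    y0 = (initial or _default_initial(params)).as_array()
    dt = config.dt
    stride = max(1, int(round(sample_dt / dt)))
    n_tr = int(round(config.transient_s * 1000.0 / dt))
    n_st = int(round(config.duration_s * 1000.0 / dt))
    seed = RngStreams(fs.seed).kernel_seed("finite_size")
    out, t_end, failed = _integrate_finite_size(
        y0, pack_params(params), dt, n_tr, n_st, stride,
        fs.N_E, fs.N_I, seed, v_bound)
    if failed:
        raise FloatingPointError(
            f"finite-size mass divergence at t = {t_end:.3f} ms")
    tgrid = config.transient_s * 1000.0 + stride * dt * np.arange(1, len(out) + 1)
    return MassTrajectory(tgrid, out[:, 0], out[:, 1], out[:, 2], out[:, 3],
                          stride * dt)
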