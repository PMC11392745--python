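"""Shared parameter types, Cauchy sampling, theta drive and the RNG contract.

Unit conventions used throughout the package
--------------------------------------------
* Internal time unit is the millisecond; membrane time constants, delays,
  integration steps and spike times are all in ms.
* Internal population rates are in 1/ms.  Every user-facing frequency is
  reported in Hz (conversion factor 1000 at the I/O boundary).
* Voltages, drives and synaptic weights are in the dimensionless units of
  the quadratic integrate-and-fire (QIF) model.

RNG contract
------------
A single root seed spawns independent, named streams (quenched
excitabilities, membrane noise, connectivity, finite-size noise, initial
conditions) via :class:`numpy.random.SeedSequence`, so changing one
stochastic component never perturbs the draws of another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import numpy as np

__all__ = [
    "ModelParams",
    "SimulationConfig",
    "RngStreams",
    "sample_cauchy",
    "theta_drive",
]

# Named purposes for the per-purpose RNG streams (fixed order = fixed spawn).
_STREAM_NAMES = ("excitability", "noise", "connectivity", "finite_size", "init")


@dataclass
class ModelParams:
    """Static model constants of the two-population QIF network.

    Defaults are the reference parameter set of the study: an
    excitatory-inhibitory network with strong recurrent excitation
    (J_EE=10.8), cross couplings J_IE=2.0 and J_EI=9.6286, recurrent
    inhibition J_II=9.53939, identical 5 ms membrane time constants, fixed
    inhibitory drive I0_I=2.0 and inhibitory heterogeneity Delta_I=0.10.
    The excitatory drive I0_E and the excitatory disorder (Delta_E and/or
    Gamma_E) are the control parameters scanned in all analyses.
    """

    tau_m_E: float = 5.0      # ms
    tau_m_I: float = 5.0      # ms
    I0_E: float = 0.0         # mean excitatory drive (model units)
    I0_I: float = 2.0         # mean inhibitory drive
    Delta_E: float = 0.0      # quenched-heterogeneity HWHM, E population
    Delta_I: float = 0.10     # quenched-heterogeneity HWHM, I population
    Gamma_E: float = 0.0      # Cauchy-noise HWHM, E population
    Gamma_I: float = 0.0      # Cauchy-noise HWHM, I population
    J_EE: float = 10.8
    J_IE: float = 2.0
    J_EI: float = 9.6286
    J_II: float = 9.53939
    N_E: int = 8000
    N_I: int = 8000
    P_C: float = 0.0          # fraction of cut connections, 0 = all-to-all
    v_peak: float = 100.0
    v_reset: float = -100.0
    theta_amplitude: float = 0.0   # A
    theta_frequency: float = 10.0  # f_theta, Hz

    def __post_init__(self) -> None:
        if self.tau_m_E <= 0 or self.tau_m_I <= 0:
            raise ValueError("membrane time constants must be positive")
        if min(self.Delta_E, self.Delta_I, self.Gamma_E, self.Gamma_I) < 0:
            raise ValueError("heterogeneity/noise HWHM must be nonnegative")
        if min(self.J_EE, self.J_IE, self.J_EI, self.J_II) < 0:
            raise ValueError("synaptic strengths must be nonnegative")
        if not (0 <= self.P_C < 1):
            raise ValueError("P_C must lie in [0, 1)")
        if self.N_E < 1 or self.N_I < 1:
            raise ValueError("population sizes must be >= 1")
        if self.v_peak != -self.v_reset:
            raise ValueError("threshold/reset must satisfy v_peak = -v_reset")
        if self.theta_frequency <= 0:
            raise ValueError("theta_frequency must be positive")

    # Effective disorder is derived, never stored: Delta_eff = Delta + Gamma.
    @property
    def Delta_eff_E(self) -> float:
        return self.Delta_E + self.Gamma_E

    @property
    def Delta_eff_I(self) -> float:
        return self.Delta_I + self.Gamma_I

    def replace(self, **kwargs) -> "ModelParams":
        d = asdict(self)
        d.update(kwargs)
        return ModelParams(**d)

    def to_json(self, path=None) -> str:
        doc = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc_or_path) -> "ModelParams":
        return cls(**_load_doc(cls, doc_or_path))


@dataclass
class SimulationConfig:
    """Numerical configuration shared by the network and mass integrators.

    ``dt`` is the integration step of the simulator it is handed to (the
    spiking network uses Euler; the deterministic mass model uses RK4, the
    finite-size mass model Euler-Maruyama).  ``transient_s`` is discarded
    before the ``duration_s`` measurement window.  ``rate_bin_ms`` sets
    both the raster rate-binning and the stride at which trajectories are
    stored.
    """

    dt: float = 0.001          # ms
    transient_s: float = 2.0
    duration_s: float = 10.0
    seed: int = 0
    rate_bin_ms: float = 0.1
    scheme: str = "euler"      # "euler" | "rk4"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.transient_s < 0 or self.duration_s < 0:
            raise ValueError("durations must be nonnegative")
        if self.rate_bin_ms <= 0:
            raise ValueError("rate_bin_ms must be positive")
        if self.scheme not in ("euler", "rk4"):
            raise ValueError("scheme must be 'euler' or 'rk4'")

    def replace(self, **kwargs) -> "SimulationConfig":
        d = asdict(self)
        d.update(kwargs)
        return SimulationConfig(**d)

    def to_json(self, path=None) -> str:
        doc = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc_or_path) -> "SimulationConfig":
        return cls(**_load_doc(cls, doc_or_path))


def _load_doc(cls, doc_or_path) -> dict:
    """Parse a JSON document (string or path) and reject unknown keys."""
    text = str(doc_or_path)
    if not text.lstrip().startswith("{"):
        text = Path(doc_or_path).read_text()
    d = json.loads(text)
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return d


class RngStreams:
    """Independent per-purpose random generators spawned from one root seed."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAM_NAMES))
        self._gens = {
            name: np.random.default_rng(ss)
            for name, ss in zip(_STREAM_NAMES, children)
        }
        # Scalar sub-seeds (< 2**31) for numba kernels that seed internally.
        self._ints = {
            name: int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1)) + 1
            for name, ss in zip(_STREAM_NAMES, children)
        }

    def generator(self, purpose: str) -> np.random.Generator:
        return self._gens[purpose]

    def kernel_seed(self, purpose: str) -> int:
        return self._ints[purpose]


def sample_cauchy(n, center, hwhm, seed=None, rng=None, clip=None):
    """Draw i.i.d. Cauchy(center, hwhm) samples via the inverse quantile map.

    The quantile map is ``center + hwhm * tan(pi * (u - 1/2))`` with u
    uniform in (0, 1).  ``hwhm = 0`` returns ``n`` copies of ``center``
    (heavy tails are part of the model and are *not* truncated unless a
    finite ``clip`` is passed, in which case samples are clamped to
    ``center +/- clip`` for numerical safety).
    """
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    if hwhm < 0:
        raise ValueError("hwhm must be nonnegative")
    if hwhm == 0:
        return np.full(n, float(center))
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random(n)
    x = center + hwhm * np.tan(np.pi * (u - 0.5))
    if clip is not None:
        x = np.clip(x, center - clip, center + clip)
    return x


def theta_drive(t_ms, amplitude, f_theta_hz=10.0):
    """External sinusoidal theta input A*sin(2*pi*f*t), t in ms, f in Hz."""
    if f_theta_hz <= 0:
        raise ValueError("f_theta must be positive")
    return amplitude * np.sin(2.0 * np.pi * f_theta_hz * np.asarray(t_ms) / 1000.0)
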