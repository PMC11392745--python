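"""Shared fixtures: a handful of expensive simulations computed once.

The operating points mirror the reference analyses: the "star" point
(I0_E=2.0, Delta_eff=2.0) sits on the PING limit cycle; the IBG point
(I0_E=0.5, Delta_eff=0.4) is inside the collective-chaos pocket.
"""

import numpy as np
import pytest

import gammaburst as gb


STAR = dict(I0_E=2.0, Delta_E=2.0)
IBG = dict(I0_E=0.5, Delta_E=0.4)


@pytest.fixture(scope="session")
def star_mass():
    """Deterministic mass trajectory on the PING limit cycle, 0.1 ms samples."""
    cfg = gb.SimulationConfig(dt=0.01, transient_s=1.0, duration_s=3.0,
                              scheme="rk4")
    return gb.integrate_mass(gb.ModelParams(**STAR), cfg)


@pytest.fixture(scope="session")
def star_net():
    """Spiking network at the star point (N=2000/pop, 3 s measurement)."""
    p = gb.ModelParams(N_E=2000, N_I=2000, **STAR)
    cfg = gb.SimulationConfig(dt=0.005, transient_s=1.0, duration_s=3.0, seed=7)
    raster, series = gb.simulate_network(p, cfg)
    return raster, series


@pytest.fixture(scope="session")
def ibg_mass():
    """Chaotic mass trajectory at the IBG point (30 s measurement)."""
    cfg = gb.SimulationConfig(dt=0.01, transient_s=2.0, duration_s=30.0,
                              scheme="rk4")
    return gb.integrate_mass(gb.ModelParams(**IBG), cfg)


def mean_cycle(x, fs_hz, n_res=200, f_lowpass=200.0):
    """Cycle-averaged waveform of an oscillatory trace.

    The trace is band-limited to the oscillation's first harmonics
    (low-pass at ``f_lowpass``), split at successive peaks, each cycle
    resampled to ``n_res`` points and averaged.  Robust to small frequency
    mismatches that dephase a direct long-window comparison.
    """
    from scipy.signal import butter, sosfiltfilt, find_peaks
    sos = butter(4, f_lowpass, "lowpass", fs=fs_hz, output="sos")
    z = sosfiltfilt(sos, np.asarray(x, float) - np.mean(x))
    pk, _ = find_peaks(z, prominence=z.std(), distance=int(fs_hz / 200))
    cycles = []
    for a, b in zip(pk[:-1], pk[1:]):
        seg = z[a:b]
        if len(seg) >= 5:
            cycles.append(np.interp(np.linspace(0, 1, n_res),
                                    np.linspace(0, 1, len(seg)), seg))
    return np.mean(cycles, axis=0)


def rel_rms(a, b):
    return float(np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(b ** 2)))
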