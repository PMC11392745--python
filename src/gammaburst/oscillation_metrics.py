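"""Measures of network and mass-model dynamics.

Spike irregularity (per-neuron coefficient of variation of inter-spike
intervals and its population mean), collective oscillation amplitude
(Sigma_V, the SD of the mean membrane potential), STFT spectrograms,
power-weighted mean frequency, band-limited analytic-signal envelopes and
phases, theta-gamma phase-amplitude coupling via the mean vector length

    PAC = MVL = | (1/M) * sum_t A_gamma(t) * exp(i * phi_theta(t)) |,

gamma-burst detection by envelope thresholding, and the E->I delay D from
the cross-correlation of the two population rates.

Filtering defaults (declared, since such choices are seldom printed):
4th-order Butterworth band-pass applied forward-backward (zero phase),
theta band 8-12 Hz, gamma band 30-100 Hz; 0.5 s trimmed from each edge
after filtering before any statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "THETA_BAND", "GAMMA_BAND",
    "CvResult", "SpectrogramResult", "PacResult", "BurstStatistics",
    "isi_cv", "sigma_v", "spectrogram_stft", "mean_frequency",
    "envelope_and_phase", "mvl", "pac_mvl", "detect_bursts", "ei_delay",
]

THETA_BAND = (8.0, 12.0)    # Hz
GAMMA_BAND = (30.0, 100.0)  # Hz
EDGE_TRIM_S = 0.5           # trimmed per edge after zero-phase filtering


class UndefinedResult(RuntimeError):
    """Raised when a metric has no defined value on the given input."""


# -------------------------------------------------------------- irregularity

@dataclass
class CvResult:
    cv: float                     # population mean over included neurons
    cv_i: np.ndarray              # per-neuron values (NaN if < 3 spikes)
    n_included: int
    n_excluded: int

    def histogram(self, bins=40, range=(0.0, 4.0)):
        vals = self.cv_i[np.isfinite(self.cv_i)]
        return np.histogram(vals, bins=bins, range=range)


def isi_cv(raster, min_spikes: int = 3) -> CvResult:
    """Per-neuron ISI coefficient of variation cv_i = SD/mean, and its mean.

    Neurons with fewer than ``min_spikes`` spikes carry no ISI statistics
    and are excluded from the population mean (their cv_i is NaN).  The
    full cv_i vector is returned for bimodality analyses of the bursting-
    subgroup signature.
    """
    trains = raster.spike_trains()
    cv_i = np.full(len(trains), np.nan)
    for k, st in enumerate(trains):
        if len(st) >= min_spikes:
            isi = np.diff(st)
            mu = isi.mean()
            if mu > 0:
                cv_i[k] = isi.std() / mu
    ok = np.isfinite(cv_i)
    if not ok.any():
        raise UndefinedResult("no neuron has enough spikes for a CV")
    return CvResult(float(cv_i[ok].mean()), cv_i, int(ok.sum()),
                    int((~ok).sum()))


def sigma_v(series) -> float:
    """SD of the population-mean voltage — the oscillation-amplitude proxy."""
    x = np.asarray(series, float)
    if len(x) < 2:
        raise ValueError("series must have length >= 2")
    return float(x.std())


# ---------------------------------------------------------------- spectrogram

@dataclass
class SpectrogramResult:
    t_s: np.ndarray               # window centers, s
    f_hz: np.ndarray
    log_power: np.ndarray         # log10(S / max S), floored
    floor: float
    window_s: float
    overlap: float

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("t_s", data=self.t_s)
            f.create_dataset("f_hz", data=self.f_hz)
            f.create_dataset("log_power", data=self.log_power)
            f.attrs.update({"floor": self.floor, "window_s": self.window_s,
                            "overlap": self.overlap})


def spectrogram_stft(series, fs_hz, window_s=0.05, overlap=0.9,
                     floor=1e-1) -> SpectrogramResult:
    """Short-time Fourier power of a population signal, max-normalized.

    Power is S(t, f) = |X(t, f)|^2 from windows of length ``window_s``
    with fractional ``overlap``, divided by its global maximum, floored at
    ``floor`` and returned as log10.
    """
    x = np.asarray(series, float)
    nper = int(round(window_s * fs_hz))
    if len(x) < nper:
        raise ValueError("series shorter than one STFT window")
    f, t, Z = sps.stft(x - x.mean(), fs=fs_hz, nperseg=nper,
                       noverlap=int(round(overlap * nper)), padded=False,
                       boundary=None)
    S = np.abs(Z) ** 2
    S /= S.max()
    return SpectrogramResult(t, f, np.log10(np.maximum(S, floor)),
                             floor, window_s, overlap)


def mean_frequency(series, fs_hz, band=(1.0, 200.0)) -> float:
    """Power-weighted mean frequency of the (mean-subtracted) signal."""
    x = np.asarray(series, float)
    f, P = sps.periodogram(x - x.mean(), fs=fs_hz)
    sel = (f >= band[0]) & (f <= band[1])
    tot = P[sel].sum()
    if tot <= 0:
        raise UndefinedResult(f"no power in band {band}")
    return float((f[sel] * P[sel]).sum() / tot)


# -------------------------------------------------------- envelope and phase

def _bandpass(x, fs_hz, band, order=4):
    lo, hi = band
    if not (0 < lo < hi < fs_hz / 2):
        raise ValueError(f"band {band} outside (0, fs/2) = (0, {fs_hz / 2})")
    sos = sps.butter(order, band, btype="bandpass", fs=fs_hz, output="sos")
    if len(x) < 50:
        raise ValueError("series too short for zero-phase band-pass filtering")
    return sps.sosfiltfilt(sos, x)


def envelope_and_phase(series, fs_hz, band, role="amplitude", order=4):
    """Band-limited analytic-signal magnitude or phase.

    Zero-phase Butterworth band-pass followed by the Hilbert transform;
    ``role`` selects the envelope ("amplitude") or the instantaneous
    phase in radians ("phase").  No edge trimming is applied here — the
    PAC routine trims.
    """
    x = np.asarray(series, float)
    analytic = sps.hilbert(_bandpass(x - x.mean(), fs_hz, band, order))
    if role == "amplitude":
        return np.abs(analytic)
    if role == "phase":
        return np.angle(analytic)
    raise ValueError("role must be 'amplitude' or 'phase'")


# ------------------------------------------------------------------------ PAC

def mvl(amplitude, phase) -> complex:
    """Mean vector of an amplitude series against a phase series.

    Returns the complex mean (1/M) * sum A(t) exp(i phi(t)); its modulus
    is the PAC value, its argument the preferred coupling phase.
    """
    amplitude = np.asarray(amplitude, float)
    phase = np.asarray(phase, float)
    if amplitude.shape != phase.shape:
        raise ValueError("amplitude and phase must have the same shape")
    return complex(np.mean(amplitude * np.exp(1j * phase)))


@dataclass
class PacResult:
    mvl: float                    # units of the amplitude signal
    theta_band: tuple
    gamma_band: tuple
    n_samples: int
    preferred_phase: float = 0.0  # radians, argument of the mean vector


def pac_mvl(series, fs_hz, theta_band=THETA_BAND, gamma_band=GAMMA_BAND,
            edge_trim_s=EDGE_TRIM_S, min_theta_cycles=10) -> PacResult:
    """Mean-vector-length phase-amplitude coupling of one signal.

    The gamma-band envelope A(t) is paired with the theta-band phase
    phi(t); PAC = |mean(A * exp(i phi))| over the edge-trimmed series.
    Requires at least ``min_theta_cycles`` theta cycles after trimming.
    """
    x = np.asarray(series, float)
    n_trim = int(round(edge_trim_s * fs_hz))
    amp = envelope_and_phase(x, fs_hz, gamma_band, "amplitude")
    ph = envelope_and_phase(x, fs_hz, theta_band, "phase")
    if n_trim > 0:
        if 2 * n_trim >= len(x):
            raise ValueError("series shorter than twice the edge trim")
        amp, ph = amp[n_trim:-n_trim], ph[n_trim:-n_trim]
    n_cycles = len(amp) / fs_hz * np.mean(theta_band)
    if n_cycles < min_theta_cycles:
        raise ValueError(f"only {n_cycles:.1f} theta cycles after trimming; "
                         f"need >= {min_theta_cycles}")
    vec = mvl(amp, ph)
    return PacResult(abs(vec), tuple(theta_band), tuple(gamma_band),
                     len(amp), float(np.angle(vec)))


# --------------------------------------------------------------------- bursts

@dataclass
class BurstStatistics:
    intervals_ms: np.ndarray      # (n, 2) start/end in ms
    mean_duration_ms: float
    median_duration_ms: float
    burst_rate_hz: float          # bursts per second of signal
    dominant_freq_hz: float       # power-weighted, in-burst, gamma band
    threshold: float
    k_threshold: float

    @property
    def n_bursts(self) -> int:
        return len(self.intervals_ms)


def detect_bursts(series, fs_hz, gamma_band=GAMMA_BAND, k_threshold=1.0,
                  min_duration_ms=20.0, merge_gap_ms=10.0,
                  edge_trim_s=EDGE_TRIM_S) -> BurstStatistics:
    """Threshold the gamma envelope to segment oscillatory bursts.

    Bursts are maximal intervals where the envelope exceeds
    mean + k * SD for at least ``min_duration_ms``; sub-threshold gaps
    shorter than ``merge_gap_ms`` are bridged first.  Zero bursts is a
    valid result (all statistics NaN).  The dominant in-burst frequency is
    the power-weighted mean of the band-passed signal's periodogram
    restricted to in-burst samples.
    """
    x = np.asarray(series, float)
    g = _bandpass(x - x.mean(), fs_hz, gamma_band)
    env = np.abs(sps.hilbert(g))
    n_trim = int(round(edge_trim_s * fs_hz))
    if n_trim > 0 and 2 * n_trim < len(x):
        g = g[n_trim:-n_trim]
        env = env[n_trim:-n_trim]
    thr = env.mean() + k_threshold * env.std()
    above = env > thr

    d = np.diff(above.astype(np.int8))
    starts = np.where(d == 1)[0] + 1
    ends = np.where(d == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above)]

    gap = int(round(merge_gap_ms * fs_hz / 1000.0))
    merged = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_n = int(round(min_duration_ms * fs_hz / 1000.0))
    keep = [(s, e) for s, e in merged if e - s >= min_n]

    if not keep:
        return BurstStatistics(np.empty((0, 2)), np.nan, np.nan, 0.0,
                               np.nan, thr, k_threshold)
    iv = np.array(keep, float) * 1000.0 / fs_hz
    durs = iv[:, 1] - iv[:, 0]
    in_burst = np.zeros(len(g), bool)
    for s, e in keep:
        in_burst[s:e] = True
    f, P = sps.periodogram(np.where(in_burst, g, 0.0), fs=fs_hz)
    sel = (f >= gamma_band[0]) & (f <= gamma_band[1])
    dom = float((f[sel] * P[sel]).sum() / P[sel].sum()) if P[sel].sum() > 0 else np.nan
    return BurstStatistics(iv, float(durs.mean()), float(np.median(durs)),
                           len(keep) / (len(g) / fs_hz), dom, thr, k_threshold)


# ---------------------------------------------------------------------- delay

def ei_delay(r_e, r_i, fs_hz, max_lag_ms=None):
    """Lag (ms) maximizing the cross-correlation of R_E leading R_I.

    Positive D means the excitatory volley precedes the inhibitory one (the
    PING signature).  The integer-bin argmax is refined by a parabolic fit
    through the three samples around the peak.  A peak sitting on the lag
    boundary raises a warning flag in the returned tuple's second element.

    ``max_lag_ms`` defaults to half the dominant oscillation period of
    ``r_e`` — on a periodic signal the cross-correlation repeats every
    cycle, so a wider window can lock onto the neighbouring cycle's peak.
    """
    x = np.asarray(r_e, float)
    y = np.asarray(r_i, float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if max_lag_ms is None:
        f, P = sps.periodogram(x - x.mean(), fs=fs_hz)
        f_dom = f[1:][np.argmax(P[1:])]
        max_lag_ms = 500.0 / f_dom if f_dom > 0 else 10.0
    x = x - x.mean()
    y = y - y.mean()
    cc = sps.correlate(y, x, mode="full")
    lags = sps.correlation_lags(len(y), len(x), mode="full") * 1000.0 / fs_hz
    sel = np.abs(lags) <= max_lag_ms
    cc, lags = cc[sel], lags[sel]
    i = int(np.argmax(cc))
    boundary = i == 0 or i == len(cc) - 1
    if not boundary:
        # parabolic sub-bin refinement
        y0, y1, y2 = cc[i - 1], cc[i], cc[i + 1]
        denom = y0 - 2 * y1 + y2
        frac = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        lag = lags[i] + frac * (lags[1] - lags[0])
    else:
        lag = lags[i]
    return float(lag), boundary
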