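"""Spiking E-I network of quadratic integrate-and-fire neurons.

This is the package's synthetic-data generator: every downstream metric
can be exercised on its output with no external data.  Each neuron obeys

    tau_m dv/dt = v^2 + I_j + xi(t) + tau_m * S(t) + theta(t)

with quenched Cauchy-distributed excitabilities I_j, optional zero-
centered Cauchy membrane noise xi of HWHM Gamma, instantaneous delta-pulse
coupling S (each presynaptic spike kicks every connected postsynaptic
voltage by J_eff/N_pre), and an optional sinusoidal theta drive to the E
population.  Integration is explicit Euler.

Threshold handling follows the finite-threshold QIF convention: when v
crosses v_peak (= 100) at the end of a step the neuron is reset to v_reset
(= -100) and clamped there for 2*tau_m/100 ms — the time the exact model
spends traveling v_peak -> +inf and -inf -> v_reset — with the spike time
recorded halfway through the clamp (reset time + tau_m/100).  Delta-pulse
kicks are delivered at the recorded spike time.

In the all-to-all case the N -> infinity limit of this scheme is exactly
the neural mass model of :mod:`gammaburst.neural_mass`; network-vs-mass
trace agreement is part of the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model_core import ModelParams, SimulationConfig, RngStreams, sample_cauchy

__all__ = [
    "Connectivity",
    "SpikeRaster",
    "PopulationSeries",
    "build_connectivity",
    "cauchy_noise_increment",
    "simulate_network",
    "population_series_from_raster",
]


# ---------------------------------------------------------------- connectivity

@dataclass
class Connectivity:
    """All-to-all or random sparse wiring with rescaled weights.

    For sparse wiring (P_C > 0) each directed edge of each projection is
    kept independently with probability 1 - P_C and every weight is
    divided by 1 - P_C, keeping the mean interaction strength equal to the
    all-to-all network.  ``csr[proj] = (indptr, indices)`` lists the
    postsynaptic targets of each presynaptic neuron; projections are keyed
    "EE", "IE" (presyn E) and "EI", "II" (presyn I), first index = postsyn.
    """

    dense: bool
    J_eff: dict
    P_C: float = 0.0
    csr: dict | None = None

    def in_degree(self, proj: str) -> np.ndarray:
        """Empirical in-degree of each postsynaptic neuron for one projection."""
        if self.dense:
            raise ValueError("dense connectivity has full in-degree")
        _, indices = self.csr[proj]
        minlen = int(indices.max()) + 1 if len(indices) else 0
        return np.bincount(indices, minlength=minlen)


def build_connectivity(params: ModelParams, seed: int = 0) -> Connectivity:
    """Sample the network wiring (dense if P_C = 0)."""
    if not (0 <= params.P_C < 1):
        raise ValueError("P_C must lie in [0, 1)")
    J = {"EE": params.J_EE, "IE": params.J_IE, "EI": params.J_EI, "II": params.J_II}
    if params.P_C == 0:
        return Connectivity(dense=True, J_eff=J, P_C=0.0)
    keep = 1.0 - params.P_C
    J_eff = {k: v / keep for k, v in J.items()}
    rng = RngStreams(seed).generator("connectivity")
    sizes = {"E": params.N_E, "I": params.N_I}
    csr = {}
    for proj, (post, pre) in {"EE": ("E", "E"), "IE": ("I", "E"),
                              "EI": ("E", "I"), "II": ("I", "I")}.items():
        n_pre, n_post = sizes[pre], sizes[post]
        indptr = np.zeros(n_pre + 1, np.int64)
        chunks = []
        for j in range(n_pre):
            targets = np.nonzero(rng.random(n_post) < keep)[0].astype(np.int32)
            chunks.append(targets)
            indptr[j + 1] = indptr[j] + len(targets)
        csr[proj] = (indptr, np.concatenate(chunks) if chunks else
                     np.empty(0, np.int32))
    return Connectivity(dense=False, J_eff=J_eff, P_C=params.P_C, csr=csr)


def cauchy_noise_increment(gamma, dt, n, seed=None, rng=None):
    """Cauchy(0, Gamma*dt) increments: the integral of xi over one step.

    The simulator adds these to the voltage as increment / tau_m (Levy-
    process convention: the HWHM of the integrated noise grows linearly
    with the step).
    """
    if gamma < 0:
        raise ValueError("Gamma must be nonnegative")
    if gamma == 0:
        return np.zeros(n)
    return sample_cauchy(n, 0.0, gamma * dt, seed=seed, rng=rng)


# -------------------------------------------------------------------- rasters

@dataclass
class SpikeRaster:
    """Spike times (ms) with 0-based neuron ids; E neurons 0..N_E-1 first."""

    times: np.ndarray
    ids: np.ndarray
    N_E: int
    N_I: int
    t_start: float
    t_stop: float

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def population(self, pop: str) -> "SpikeRaster":
        mask = self.ids < self.N_E if pop == "E" else self.ids >= self.N_E
        return SpikeRaster(self.times[mask], self.ids[mask], self.N_E,
                           self.N_I, self.t_start, self.t_stop)

    def spike_trains(self):
        """Per-neuron sorted spike-time arrays (list of length N_E + N_I)."""
        order = np.lexsort((self.times, self.ids))
        ids, times = self.ids[order], self.times[order]
        N = self.N_E + self.N_I
        bounds = np.searchsorted(ids, np.arange(N + 1))
        return [times[bounds[k]:bounds[k + 1]] for k in range(N)]

    def to_text(self, path) -> None:
        order = np.argsort(self.times, kind="stable")
        with open(path, "w") as fh:
            fh.write(f"# N_E={self.N_E} N_I={self.N_I} "
                     f"t_start={self.t_start!r} t_stop={self.t_stop!r}\n")
            for t, j in zip(self.times[order], self.ids[order]):
                fh.write(f"{float(t)!r}\t{int(j)}\n")

    @classmethod
    def from_text(cls, path) -> "SpikeRaster":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# N_E="):
                raise ValueError(f"malformed raster file {path}: bad header")
            meta = dict(kv.split("=") for kv in header[2:].split())
            times, ids = [], []
            for ln, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ValueError(f"malformed raster file {path}, line {ln}")
                times.append(float(parts[0]))
                ids.append(int(parts[1]))
        return cls(np.array(times), np.array(ids, np.int64),
                   int(meta["N_E"]), int(meta["N_I"]),
                   float(meta["t_start"]), float(meta["t_stop"]))

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("ids", data=self.ids)
            f.attrs.update({"N_E": self.N_E, "N_I": self.N_I,
                            "t_start": self.t_start, "t_stop": self.t_stop})

    @classmethod
    def from_hdf5(cls, path) -> "SpikeRaster":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(f["times"][:], f["ids"][:], int(f.attrs["N_E"]),
                       int(f.attrs["N_I"]), float(f.attrs["t_start"]),
                       float(f.attrs["t_stop"]))


@dataclass
class PopulationSeries:
    """Uniformly sampled mean voltages and population rates (R in 1/ms)."""

    t: np.ndarray
    V_E: np.ndarray
    V_I: np.ndarray
    R_E: np.ndarray
    R_I: np.ndarray
    bin_ms: float

    @property
    def fs_hz(self) -> float:
        return 1000.0 / self.bin_ms

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"t_ms": self.t, "V_E": self.V_E, "V_I": self.V_I,
                      "R_E": self.R_E, "R_I": self.R_I}
                     ).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "PopulationSeries":
        import pandas as pd
        df = pd.read_csv(path, float_precision="round_trip")
        expected = ["t_ms", "V_E", "V_I", "R_E", "R_I"]
        if list(df.columns) != expected:
            raise ValueError(f"malformed series CSV: columns {list(df.columns)}"
                             f" != {expected}")
        bin_ms = float(df.t_ms.iloc[1] - df.t_ms.iloc[0]) if len(df) > 1 else 0.0
        return cls(df.t_ms.to_numpy(), df.V_E.to_numpy(), df.V_I.to_numpy(),
                   df.R_E.to_numpy(), df.R_I.to_numpy(), bin_ms)


# ------------------------------------------------------------------ simulation

@njit(cache=True)
def _run_network(v, hold, Iq, NE, NI, dt, n_transient, n_steps,
                 tauE, tauI, gamE, gamI, vpeak, vreset,
                 kEE, kEI, kIE, kII,
                 dense, indptrEE, indEE, indptrIE, indIE,
                 indptrEI, indEI, indptrII, indII, wEE, wEI, wIE, wII,
                 holdE, holdI, delayE, delayI,
                 A, f_theta, bin_steps, seed, noise_clip, record_raster):
    np.random.seed(seed)
    N = NE + NI
    L = max(delayE, delayI) + 2
    # dense: per-population spike counters per future slot
    cntE = np.zeros(L)
    cntI = np.zeros(L)
    # sparse: per-neuron pending kicks per future slot
    if dense:
        pend = np.zeros((1, 1))
    else:
        pend = np.zeros((N, L))

    n_total = n_transient + n_steps
    nbins = n_steps // bin_steps
    VE = np.zeros(nbins)
    VI = np.zeros(nbins)
    sE = np.zeros(nbins)
    sI = np.zeros(nbins)

    cap = 1024
    sp_t = np.empty(cap)
    sp_id = np.empty(cap, np.int64)
    nsp = 0

    cE = dt / tauE
    cI = dt / tauI
    gEdt = gamE * dt / tauE
    gIdt = gamI * dt / tauI
    err_t = -1.0
    err_j = -1

    for i in range(n_total):
        slot = i % L
        t = i * dt
        if dense:
            kickE = kEE * cntE[slot] - kEI * cntI[slot]
            kickI = kIE * cntE[slot] - kII * cntI[slot]
            cntE[slot] = 0.0
            cntI[slot] = 0.0
        else:
            kickE = 0.0
            kickI = 0.0
        theta = A * np.sin(2.0 * np.pi * f_theta * t / 1000.0) if A != 0.0 else 0.0

        for j in range(N):
            isE = j < NE
            if hold[j] > 0:
                hold[j] -= 1
                if not dense:
                    pend[j, slot] = 0.0
                continue
            vj = v[j]
            if isE:
                vj += cE * (vj * vj + Iq[j] + theta) + kickE
                if gamE > 0.0:
                    inc = gEdt * np.tan(np.pi * (np.random.random() - 0.5))
                    if noise_clip > 0.0:
                        if inc > noise_clip:
                            inc = noise_clip
                        elif inc < -noise_clip:
                            inc = -noise_clip
                    vj += inc
            else:
                vj += cI * (vj * vj + Iq[j]) + kickI
                if gamI > 0.0:
                    inc = gIdt * np.tan(np.pi * (np.random.random() - 0.5))
                    if noise_clip > 0.0:
                        if inc > noise_clip:
                            inc = noise_clip
                        elif inc < -noise_clip:
                            inc = -noise_clip
                    vj += inc
            if not dense:
                vj += pend[j, slot]
                pend[j, slot] = 0.0
            if not np.isfinite(vj):
                err_t = t
                err_j = j
                return (sp_t[:nsp], sp_id[:nsp], VE, VI, sE, sI, v, hold,
                        err_t, err_j)
            if vj >= vpeak:
                v[j] = vreset
                if isE:
                    hold[j] = holdE
                    rec = i + 1 + delayE
                else:
                    hold[j] = holdI
                    rec = i + 1 + delayI
                rslot = rec % L
                if dense:
                    if isE:
                        cntE[rslot] += 1.0
                    else:
                        cntI[rslot] += 1.0
                else:
                    if isE:
                        for a in range(indptrEE[j], indptrEE[j + 1]):
                            pend[indEE[a], rslot] += wEE
                        for a in range(indptrIE[j], indptrIE[j + 1]):
                            pend[NE + indIE[a], rslot] += wIE
                    else:
                        jj = j - NE
                        for a in range(indptrEI[jj], indptrEI[jj + 1]):
                            pend[indEI[a], rslot] -= wEI
                        for a in range(indptrII[jj], indptrII[jj + 1]):
                            pend[NE + indII[a], rslot] -= wII
                # spike time = reset time + tau/100; bin on the recorded step
                tspk = (i + 1) * dt + (tauE if isE else tauI) / 100.0
                idx = rec - n_transient - 1
                in_window = 0 <= idx < nbins * bin_steps
                if in_window:
                    b = idx // bin_steps
                    if isE:
                        sE[b] += 1.0
                    else:
                        sI[b] += 1.0
                if record_raster and in_window:
                    if nsp >= cap:
                        cap2 = cap * 2
                        nt = np.empty(cap2)
                        ni = np.empty(cap2, np.int64)
                        nt[:nsp] = sp_t[:nsp]
                        ni[:nsp] = sp_id[:nsp]
                        sp_t = nt
                        sp_id = ni
                        cap = cap2
                    sp_t[nsp] = tspk
                    sp_id[nsp] = j
                    nsp += 1
            else:
                v[j] = vj

        # sample population-mean voltages at bin centers
        if i >= n_transient:
            k = i - n_transient
            if k % bin_steps == bin_steps // 2:
                b = k // bin_steps
                if b < nbins:
                    aE = 0.0
                    for j in range(NE):
                        aE += v[j]
                    aI = 0.0
                    for j in range(NE, N):
                        aI += v[j]
                    VE[b] = aE / NE
                    VI[b] = aI / NI
    return sp_t[:nsp], sp_id[:nsp], VE, VI, sE, sI, v, hold, err_t, err_j


def simulate_network(params: ModelParams, config: SimulationConfig,
                     connectivity: Connectivity | None = None,
                     initial_state=None, return_state: bool = False,
                     noise_clip: float = 0.0, record_raster: bool = True):
    """Euler integration of the spiking network.

    Returns ``(SpikeRaster, PopulationSeries)`` for the measurement window
    (the transient is discarded).  ``initial_state`` may be a ``(v, hold)``
    tuple from a previous call (adiabatic protocols); ``noise_clip`` > 0
    clamps single-step Cauchy increments at that value (off by default —
    heavy tails are part of the model).
    """
    if connectivity is None:
        connectivity = build_connectivity(params, seed=config.seed)
    NE, NI = params.N_E, params.N_I
    N = NE + NI
    dt = config.dt
    # guard: a free neuron at v_peak must move by less than v_peak per step
    if dt * (params.v_peak ** 2 + abs(params.I0_E)) / min(params.tau_m_E, params.tau_m_I) >= params.v_peak:
        raise ValueError(f"dt={dt} too coarse for v_peak={params.v_peak}: "
                         "per-step voltage change at threshold exceeds v_peak")

    streams = RngStreams(config.seed)
    Iq = np.empty(N)
    Iq[:NE] = sample_cauchy(NE, params.I0_E, params.Delta_E,
                            rng=streams.generator("excitability"))
    Iq[NE:] = sample_cauchy(NI, params.I0_I, params.Delta_I,
                            rng=streams.generator("excitability"))

    if initial_state is not None:
        v = np.asarray(initial_state[0], float).copy()
        hold = np.asarray(initial_state[1], np.int64).copy()
    else:
        v = streams.generator("init").uniform(-2.0, 2.0, N)
        hold = np.zeros(N, np.int64)

    if connectivity.dense:
        kEE = connectivity.J_eff["EE"] / NE
        kIE = connectivity.J_eff["IE"] / NE
        kEI = connectivity.J_eff["EI"] / NI
        kII = connectivity.J_eff["II"] / NI
        empty_ptr = np.zeros(1, np.int64)
        empty_idx = np.empty(0, np.int32)
        csr_args = (empty_ptr, empty_idx) * 4
        w = (0.0, 0.0, 0.0, 0.0)
    else:
        kEE = kIE = kEI = kII = 0.0
        c = connectivity.csr
        csr_args = (c["EE"][0], c["EE"][1], c["IE"][0], c["IE"][1],
                    c["EI"][0], c["EI"][1], c["II"][0], c["II"][1])
        w = (connectivity.J_eff["EE"] / NE, connectivity.J_eff["EI"] / NI,
             connectivity.J_eff["IE"] / NE, connectivity.J_eff["II"] / NI)

    holdE = max(1, int(round(2.0 * params.tau_m_E / 100.0 / dt)))
    holdI = max(1, int(round(2.0 * params.tau_m_I / 100.0 / dt)))
    delayE = max(0, int(round(params.tau_m_E / 100.0 / dt)))
    delayI = max(0, int(round(params.tau_m_I / 100.0 / dt)))
    bin_steps = max(1, int(round(config.rate_bin_ms / dt)))
    n_tr = int(round(config.transient_s * 1000.0 / dt))
    n_st = int(round(config.duration_s * 1000.0 / dt))

    (sp_t, sp_id, VE, VI, sE, sI, v_out, hold_out, err_t, err_j) = _run_network(
        v, hold, Iq, NE, NI, dt, n_tr, n_st,
        params.tau_m_E, params.tau_m_I, params.Gamma_E, params.Gamma_I,
        params.v_peak, params.v_reset,
        kEE, kEI, kIE, kII, connectivity.dense, *csr_args, *w,
        holdE, holdI, delayE, delayI,
        params.theta_amplitude, params.theta_frequency,
        bin_steps, streams.kernel_seed("noise"), noise_clip,
        record_raster)
    if err_j >= 0:
        raise FloatingPointError(
            f"non-finite voltage of neuron {err_j} at t = {err_t:.4f} ms")

    order = np.argsort(sp_t, kind="stable")
    t0 = n_tr * dt
    raster = SpikeRaster(sp_t[order], sp_id[order], NE, NI,
                         t0, t0 + n_st * dt)
    nbins = n_st // bin_steps
    bin_ms = bin_steps * dt
    tgrid = t0 + bin_ms * (np.arange(nbins) + 0.5)
    series = PopulationSeries(tgrid, VE, VI,
                              sE / (NE * bin_ms), sI / (NI * bin_ms), bin_ms)
    if return_state:
        return raster, series, (v_out, hold_out)
    return raster, series


def population_series_from_raster(raster: SpikeRaster, voltages=None,
                                  bin_width: float = 1.0) -> PopulationSeries:
    """Re-bin a raster into population rates R = spikes / (N * bin).

    ``voltages`` may be an existing :class:`PopulationSeries` whose mean-
    voltage traces are carried over (subsampled at the new bin centers);
    otherwise the voltage channels are NaN.  An empty raster gives all-zero
    rates.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(raster.t_start, raster.t_stop + 0.5 * bin_width, bin_width)
    if len(edges) < 2:
        raise ValueError("bin_width larger than the raster span")
    e_mask = raster.ids < raster.N_E
    cE, _ = np.histogram(raster.times[e_mask], edges)
    cI, _ = np.histogram(raster.times[~e_mask], edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if voltages is not None:
        VE = np.interp(centers, voltages.t, voltages.V_E)
        VI = np.interp(centers, voltages.t, voltages.V_I)
    else:
        VE = np.full(len(centers), np.nan)
        VI = np.full(len(centers), np.nan)
    return PopulationSeries(centers, VE, VI,
                            cE / (raster.N_E * bin_width),
                            cI / (raster.N_I * bin_width), bin_width)
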