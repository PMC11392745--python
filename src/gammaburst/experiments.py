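"""Config-driven experiment recipes and result-bundle I/O.

Each recipe reproduces one figure-level analysis end to end at a chosen
scale preset and writes every intermediate series, a flat metrics JSON and
a manifest (parameters, seeds, package version) sufficient to regenerate
the bundle.  The "desk" preset runs each recipe on a single CPU in
minutes; "paper" uses the full-scale reference numerics (N = 16,000
neurons, dt = 0.00015 ms network steps, ~100 s windows) and is intended
for cluster use — selecting it emits a RuntimeWarning.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .model_core import ModelParams, SimulationConfig
from .neural_mass import (FiniteSizeConfig, integrate_mass,
                          integrate_mass_finite_size)
from .qif_network import build_connectivity, simulate_network
from . import oscillation_metrics as om
from . import stability

log = logging.getLogger("gammaburst")

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS"]

# Reference operating points used across recipes
STAR_POINT = dict(I0_E=2.0, Delta_E=2.0)          # PING limit cycle
IBG_POINT = dict(I0_E=0.5, Delta_E=0.4)           # collective chaos
NIBG_POINT = dict(I0_E=-3.0, Gamma_E=3.0)         # near-Hopf asynchronous

_PRESETS = {
    "desk": dict(net_N=2000, net_dt=0.005, net_T=10.0, net_Tt=2.0,
                 mass_T=20.0, mass_Tt=2.0),
    "paper": dict(net_N=8000, net_dt=0.00015, net_T=100.0, net_Tt=10.0,
                  mass_T=100.0, mass_Tt=10.0),
}


@dataclass
class ExperimentConfig:
    """Named recipe + parameter overrides + numerical scale."""

    experiment: str
    out_dir: str = "results"
    scale: str = "desk"
    seed: int = 0
    params: dict = field(default_factory=dict)       # ModelParams overrides
    sim: dict = field(default_factory=dict)          # SimulationConfig overrides

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"choose from {sorted(EXPERIMENTS)}")
        if self.scale not in _PRESETS:
            raise ValueError(f"scale must be one of {sorted(_PRESETS)}")
        if self.scale == "paper":
            warnings.warn("the 'paper' preset uses cluster-scale numerics",
                          RuntimeWarning)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml
        return cls(**yaml.safe_load(Path(path).read_text()))


def _stage(name, t0):
    log.info("stage %-22s done in %6.1f s", name, time.time() - t0)


def _mass_config(cfg: ExperimentConfig) -> SimulationConfig:
    pre = _PRESETS[cfg.scale]
    d = dict(dt=0.01, transient_s=pre["mass_Tt"], duration_s=pre["mass_T"],
             seed=cfg.seed, rate_bin_ms=0.1, scheme="rk4")
    d.update(cfg.sim)
    return SimulationConfig(**d)


def _net_config(cfg: ExperimentConfig) -> SimulationConfig:
    pre = _PRESETS[cfg.scale]
    d = dict(dt=pre["net_dt"], transient_s=pre["net_Tt"],
             duration_s=pre["net_T"], seed=cfg.seed, rate_bin_ms=0.1)
    d.update(cfg.sim)
    return SimulationConfig(**d)


def _net_params(cfg: ExperimentConfig, **point) -> ModelParams:
    pre = _PRESETS[cfg.scale]
    d = dict(N_E=pre["net_N"], N_I=pre["net_N"])
    d.update(point)
    d.update(cfg.params)
    return ModelParams(**d)


# -------------------------------------------------------------------- recipes

def _ibg_portrait(cfg: ExperimentConfig, out: Path) -> dict:
    """Chaotic bursting-gamma portrait: mass trajectory, lambda_1, burst
    statistics, and the network's bursting-subgroup CV signature under
    quenched heterogeneity vs Cauchy noise."""
    metrics = {}
    mc = _mass_config(cfg)
    params = _net_params(cfg, **IBG_POINT)
    t0 = time.time()
    traj = integrate_mass(params, mc)
    traj.to_csv(out / "mass_trajectory.csv")
    lam = stability.lyapunov_spectrum(params, mc, n_exp=1)
    metrics["lambda_max_per_ms"] = lam.lambda_max
    bs = om.detect_bursts(traj.V_E, traj.fs_hz)
    metrics["burst_mean_duration_ms"] = bs.mean_duration_ms
    metrics["burst_dominant_freq_hz"] = bs.dominant_freq_hz
    _stage("mass portrait", t0)

    for tag, overrides in (("quenched", dict(Delta_E=0.4, Gamma_E=0.0)),
                           ("noise", dict(Delta_E=0.0, Gamma_E=0.4))):
        t0 = time.time()
        pp = params.replace(**overrides)
        nc = _net_config(cfg)
        raster, series = simulate_network(pp, nc, build_connectivity(pp, nc.seed))
        raster.to_text(out / f"raster_{tag}.tsv")
        series.to_csv(out / f"series_{tag}.csv")
        cv = om.isi_cv(raster.population("E"))
        metrics[f"cv_{tag}"] = cv.cv
        hist, edges = cv.histogram()
        np.savetxt(out / f"cv_hist_{tag}.csv",
                   np.c_[edges[:-1], hist], delimiter=",",
                   header="cv_bin_left,count", comments="")
        _stage(f"network {tag}", t0)
    return metrics


def _nibg_portrait(cfg: ExperimentConfig, out: Path) -> dict:
    """Noise-induced bursts near the Hopf: finite-size mass model vs
    network at the same near-critical point."""
    metrics = {}
    params = _net_params(cfg, **NIBG_POINT)
    mc = _mass_config(cfg)
    t0 = time.time()
    fs = FiniteSizeConfig(params.N_E, params.N_I, cfg.seed)
    mcfs = mc.replace(scheme="euler", dt=min(mc.dt, 0.01))
    traj = integrate_mass_finite_size(params, mcfs, fs)
    traj.to_csv(out / "mass_finite_size.csv")
    sp = om.spectrogram_stft(traj.V_E, traj.fs_hz, floor=1e-5)
    sp.to_hdf5(out / "mass_spectrogram.h5")
    bs = om.detect_bursts(traj.V_E, traj.fs_hz)
    metrics["mass_burst_rate_hz"] = bs.burst_rate_hz
    metrics["mass_sigma_v"] = om.sigma_v(traj.V_E)
    _stage("finite-size mass", t0)

    t0 = time.time()
    nc = _net_config(cfg)
    raster, series = simulate_network(params, nc)
    series.to_csv(out / "series_network.csv")
    metrics["network_sigma_v"] = om.sigma_v(series.V_E)
    bsn = om.detect_bursts(series.V_E, 1000.0 / series.bin_ms)
    metrics["network_burst_rate_hz"] = bsn.burst_rate_hz
    _stage("network", t0)
    return metrics


def _phase_diagram(cfg: ExperimentConfig, out: Path) -> dict:
    """Coarse regime map over (I0_E, Delta_eff_E)."""
    t0 = time.time()
    drives = cfg.params.pop("drives", np.linspace(-5, 6, 12))
    deltas = cfg.params.pop("delta_effs", np.linspace(0.2, 7.0, 8))
    params = _net_params(cfg)
    pd_ = stability.phase_diagram_scan(params, drives, deltas, _mass_config(cfg))
    pd_.to_csv(out / "phase_diagram.csv")
    _stage("phase diagram", t0)
    labels, counts = np.unique(pd_.labels.astype(str), return_counts=True)
    return {f"n_{l}": int(c) for l, c in zip(labels, counts)}


def _hysteresis(cfg: ExperimentConfig, out: Path) -> dict:
    """Adiabatic up/down sweeps of Gamma_E at fixed drive: bistability."""
    t0 = time.time()
    control = cfg.params.pop("control", np.linspace(1.0, 5.0, 17))
    params = _net_params(cfg, I0_E=5.0, Delta_E=0.0)
    nc = _net_config(cfg).replace(transient_s=0.5,
                                  duration_s=min(2.0, _PRESETS[cfg.scale]["net_T"]))
    up_x, up = stability.hysteresis_sweep(params, control, "up", "network", nc)
    dn_x, dn = stability.hysteresis_sweep(params, control, "down", "network", nc)
    np.savetxt(out / "hysteresis.csv",
               np.c_[up_x, up, dn_x[::-1], dn[::-1]], delimiter=",",
               header="gamma_up,sigma_v_up,gamma_down,sigma_v_down",
               comments="")
    _stage("hysteresis", t0)
    window = np.abs(up - dn[::-1])
    return {"max_branch_separation": float(window.max())}


def _pac_scan(cfg: ExperimentConfig, out: Path) -> dict:
    """PAC vs distance to criticality near the chaotic (IBG) transition
    and near the Hopf (NiBG side), theta amplitude A = 0.2."""
    t0 = time.time()
    mc = _mass_config(cfg)
    base = _net_params(cfg)
    rows = []
    crit = {}
    for delta in (0.4, 6.0):
        pp = base.replace(Delta_E=delta, Gamma_E=0.0)
        if delta < 1.5:
            c = stability.detect_chaos_onset(pp, (0.3, 0.7), 0.02, mc)
        else:
            c = stability.detect_hopf(pp, (-5.0, 0.0))
        crit[delta] = c
        for dist in np.linspace(-0.3, 0.3, 7):
            ppd = pp.replace(I0_E=c + dist, theta_amplitude=0.2)
            traj = integrate_mass(ppd, mc)
            pac = om.pac_mvl(traj.V_E, traj.fs_hz)
            rows.append((delta, dist, c, pac.mvl))
    np.savetxt(out / "pac_scan.csv", np.array(rows), delimiter=",",
               header="delta_eff,distance,critical_drive,pac", comments="")
    _stage("pac scan", t0)
    arr = np.array(rows)
    return {
        "critical_drive_chaos": crit[0.4],
        "critical_drive_hopf": crit[6.0],
        "pac_max_ibg": float(arr[arr[:, 0] == 0.4, 3].max()),
        "pac_max_nibg": float(arr[arr[:, 0] == 6.0, 3].max()),
    }


def _sparse_pac(cfg: ExperimentConfig, out: Path) -> dict:
    """Network PAC at the IBG fringe for decreasing in-degree K."""
    t0 = time.time()
    Ks = cfg.params.pop("in_degrees", (4, 40, 400))
    params = _net_params(cfg, I0_E=0.35, Delta_E=0.0, Gamma_E=0.4,
                         theta_amplitude=0.2)
    nc = _net_config(cfg)
    rows = []
    for K in Ks:
        pc = 1.0 - K / params.N_E
        if not 0 <= pc < 1:
            raise ValueError(f"in-degree {K} incompatible with N={params.N_E}")
        pp = params.replace(P_C=pc)
        raster, series = simulate_network(pp, nc)
        pac = om.pac_mvl(series.V_E, series.fs_hz)
        rows.append((K, pc, pac.mvl))
    dense_raster, dense_series = simulate_network(params.replace(P_C=0.0), nc)
    pac_dense = om.pac_mvl(dense_series.V_E, dense_series.fs_hz)
    rows.append((params.N_E, 0.0, pac_dense.mvl))
    np.savetxt(out / "sparse_pac.csv", np.array(rows), delimiter=",",
               header="K,P_C,pac", comments="")
    _stage("sparse pac", t0)
    return {f"pac_K{int(k)}": float(p) for k, _, p in rows}


def _freq_maps(cfg: ExperimentConfig, out: Path) -> dict:
    """Mean oscillation frequency vs drive (gamma-range confinement)."""
    t0 = time.time()
    mc = _mass_config(cfg)
    base = _net_params(cfg)
    rows = []
    for delta in (0.4, 2.0, 6.0):
        for drive in np.linspace(0.0, 6.0, 7):
            pp = base.replace(Delta_E=delta, I0_E=drive)
            traj = integrate_mass(pp, mc)
            if om.sigma_v(traj.V_E) < stability.OSC_SIGMA_TOL:
                continue
            rows.append((delta, drive, om.mean_frequency(traj.V_E, traj.fs_hz)))
    np.savetxt(out / "freq_map.csv", np.array(rows), delimiter=",",
               header="delta_eff,I0_E,mean_freq_hz", comments="")
    _stage("freq maps", t0)
    freqs = np.array(rows)[:, 2]
    return {"freq_min_hz": float(freqs.min()), "freq_max_hz": float(freqs.max())}


EXPERIMENTS = {
    "phase_diagram": _phase_diagram,
    "hysteresis": _hysteresis,
    "ibg_portrait": _ibg_portrait,
    "nibg_portrait": _nibg_portrait,
    "pac_scan": _pac_scan,
    "sparse_pac": _sparse_pac,
    "freq_maps": _freq_maps,
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one named recipe end to end; idempotent given config + seed.

    Writes all intermediate series, a ``metrics.json`` and a
    ``manifest.json`` under ``config.out_dir/<experiment>``; returns the
    metrics dict.  A stage failure aborts with the stage name; partial
    outputs are preserved.
    """
    out = Path(config.out_dir) / config.experiment
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "experiment": config.experiment,
        "scale": config.scale,
        "seed": config.seed,
        "params_overrides": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                             for k, v in config.params.items()},
        "sim_overrides": dict(config.sim),
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    t0 = time.time()
    try:
        metrics = EXPERIMENTS[config.experiment](config, out)
    except Exception as e:
        raise RuntimeError(f"experiment {config.experiment!r} failed: {e}") from e
    metrics = {k: (None if v is None or (isinstance(v, float) and not np.isfinite(v))
                   else v) for k, v in metrics.items()}
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
    log.info("experiment %s finished in %.1f s", config.experiment,
             time.time() - t0)
    return metrics
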