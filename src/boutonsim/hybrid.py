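"""Fast "hybrid" calcium mode: stochastic channel gating mapped onto a
calibrated local calcium template driving the sensor CTMC.

Local calcium at a vesicle is decomposed as

    [Ca](t) = resting + microdomain(t) + residual(t)

* The microdomain term is the quasi-steady nanodomain of the open
  channel cluster: a first-order-filtered copy (relaxation time ~ the
  buffer capture time) of the instantaneous open-channel count weighted
  by the voltage-dependent driving force, scaled by a distance kernel
  exp(-r/lambda)/r.  Its amplitude and screening length are calibrated
  once against spatial-engine runs and then frozen.
* The residual term is the deterministic bulk excess from the same
  influx, solved by 1-D buffered reaction-diffusion along the axon axis
  (clamped ends, mobile buffer, pumps).  It is computed once per
  configuration/protocol and shared across trials (trial-to-trial
  variability of the bulk excess is small compared to channel noise).

Channel gating remains stochastic per trial - the dominant noise
source - so the hybrid mode reproduces the release statistics of the
spatial mode at a small fraction of its cost.
"""
from __future__ import annotations

import hashlib
import json

import numpy as np

from . import _kernels
from .config import (IONS_PER_UM3_PER_UM, PER_M_S_TO_PER_UM_MS,
                     PER_S_TO_PER_MS, SimConfig)
from .spatial import CalciumTrace, pump_leak_per_pump_ms
from .stimulus import StimulusProtocol, generate_ap_waveform

_residual_cache: dict = {}


def mean_open_weighted(cfg: SimConfig, t_grid: np.ndarray,
                       onsets_ms) -> np.ndarray:
    """Deterministic mean of (open channels x driving force) on a grid."""
    from .channels import driving_force, master_equation
    dt = float(t_grid[1] - t_grid[0])
    out = np.zeros_like(t_grid)
    window = 15.0
    tw = np.arange(0.0, window, dt)
    v = generate_ap_waveform(cfg.ap, tw)
    occ = master_equation(v, dt, cfg.channels)
    template = occ[:, 4] * driving_force(v, cfg.channels) * cfg.channels.n_channels
    for onset in onsets_ms:
        k0 = int(round(onset / dt))
        k1 = min(k0 + len(tw), len(out))
        if k0 < len(out):
            out[k0:k1] += template[:k1 - k0]
    return out


def open_counts_weighted(cfg: SimConfig, t_grid: np.ndarray, onsets_ms,
                         seed: int) -> np.ndarray:
    """Stochastic open-channel count times driving force, per sample."""
    from .channels import driving_force, rate_arrays
    dt = float(t_grid[1] - t_grid[0])
    v = generate_ap_waveform(cfg.ap, t_grid, onsets_ms=onsets_ms)
    a, b = rate_arrays(v, cfg.channels)
    nopen = _kernels.channel_ensemble_open(a, b, dt, cfg.channels.n_channels,
                                           seed % (2 ** 31))
    return nopen * driving_force(v, cfg.channels)


def _residual_key(cfg: SimConfig, onsets_ms, duration_ms, dt) -> str:
    payload = dict(
        flux=cfg.channels.flux_open, nch=cfg.channels.n_channels,
        ap=(cfg.ap.foot_ms, cfg.ap.rise_ms, cfg.ap.fall_ms,
            cfg.ap.peak_mv, cfg.ap.baseline_mv),
        buf=(cfg.buffer.concentration_um, cfg.buffer.kh_plus, cfg.buffer.kh_minus,
             cfg.buffer.km_plus, cfg.buffer.km_minus, cfg.buffer.d_cb,
             cfg.buffer.sites_high, cfg.buffer.sites_medium),
        pump=(cfg.pumps.density_per_um2, cfg.pumps.kpm1, cfg.pumps.kpm2,
              cfg.pumps.kpm3, cfg.pumps.kpm4),
        geom=cfg.geometry.box_um, dca=cfg.diffusion.d_ca,
        c0=cfg.diffusion.resting_ca_um,
        pde=(cfg.hybrid.pde_nx, cfg.hybrid.source_sigma_um),
        onsets=tuple(round(float(o), 6) for o in onsets_ms),
        dur=duration_ms, dt=dt, if_drive=cfg.channels.ghk_flux,
    )
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _md_filter(x, dt, hyb):
    """Microdomain relaxation: two-pole kernel (unit steady-state gain)
    calibrated against the spatial engine's impulse response."""
    y1 = _kernels.one_pole_filter(x, dt, hyb.tau_md_ms)
    y2 = _kernels.one_pole_filter(x, dt, hyb.tau_md2_ms)
    return hyb.w_md_fast * y1 + (1.0 - hyb.w_md_fast) * y2


def _capture_partition_high(cfg: SimConfig) -> float:
    """Fraction of entering calcium first captured by high-affinity
    calbindin sites (capture-flux ratio at resting occupancy)."""
    buf = cfg.buffer
    c0 = cfg.diffusion.resting_ca_um
    free_h = buf.total_high_sites_um * (1 - c0 / (c0 + buf.kd_high_um))
    free_m = buf.total_medium_sites_um * (1 - c0 / (c0 + buf.kd_medium_um))
    rate_h = buf.kh_plus * free_h
    rate_m = buf.km_plus * free_m
    return rate_h / (rate_h + rate_m)


def residual_trace(cfg: SimConfig, onsets_ms, duration_ms: float,
                   dt_out: float) -> np.ndarray:
    """Deterministic bulk residual free calcium at the active zone (µM
    above zero; includes the resting level).  Cached per configuration."""
    key = _residual_key(cfg, onsets_ms, duration_ms, dt_out)
    if key in _residual_cache:
        return _residual_cache[key]
    hyb = cfg.hybrid
    nx = hyb.pde_nx
    box = cfg.geometry.box_um
    dx = box[0] / (nx - 1)
    area = box[1] * box[2]
    d_ca = cfg.diffusion.d_ca * 1e-3  # µm^2/ms
    # explicit-Euler stability for the stiffest (free calcium) field
    dt_pde = min(0.4 * dx * dx / d_ca, dt_out)
    stride = max(int(round(dt_out / dt_pde)), 1)
    dt_pde = dt_out / stride
    n_out = int(round(duration_ms / dt_out))
    nt = n_out * stride
    tg = np.arange(nt) * dt_pde
    src = mean_open_weighted(cfg, tg, onsets_ms) * cfg.channels.flux_open
    xg = np.linspace(-box[0] / 2, box[0] / 2, nx)
    shape = np.exp(-xg ** 2 / (2 * hyb.source_sigma_um ** 2))
    shape /= shape.sum() * dx * area * IONS_PER_UM3_PER_UM  # -> µM/ms per (ion/ms)
    buf = cfg.buffer
    pump = cfg.pumps
    n_pumps = pump.density_per_um2 * 2 * (box[0] * box[1] + box[0] * box[2]
                                          + box[1] * box[2])
    out = _kernels.residual_pde(
        src, dt_pde, nx, dx, area,
        d_ca, buf.d_cb * 1e-3, cfg.diffusion.resting_ca_um,
        buf.kh_plus * PER_M_S_TO_PER_UM_MS, buf.kh_minus * PER_S_TO_PER_MS,
        buf.km_plus * PER_M_S_TO_PER_UM_MS, buf.km_minus * PER_S_TO_PER_MS,
        buf.total_high_sites_um, buf.total_medium_sites_um,
        pump.kpm1 * PER_M_S_TO_PER_UM_MS,
        (pump.kpm2 + pump.kpm3) * PER_S_TO_PER_MS,
        pump.kpm3 * PER_S_TO_PER_MS, pump.kpm4 * PER_S_TO_PER_MS,
        n_pumps / (box[0] * area),
        pump_leak_per_pump_ms(pump, cfg.diffusion.resting_ca_um),
        shape, _capture_partition_high(cfg), n_out, stride)
    _residual_cache[key] = out
    return out


def vesicle_distances_nm(cfg: SimConfig) -> np.ndarray:
    """Distance of each vesicle sensor from the VDCC cluster centre."""
    ves = cfg.geometry.vesicle_positions_um()
    clus = np.array(cfg.geometry.cluster_center_um)
    return np.linalg.norm(ves - clus, axis=1) * 1e3


def hybrid_ca_trace(cfg: SimConfig, protocol: StimulusProtocol, seed: int,
                    per_vesicle: bool = True,
                    flux_scale: float = 1.0) -> tuple:
    """Per-vesicle local calcium traces for one trial.

    Returns (t_grid, ca) with ca of shape (n_vesicles, nt) (or (1, nt)
    when ``per_vesicle`` is false).  ``flux_scale`` scales the calcium
    entry per open channel (extracellular-calcium manipulations).
    """
    hyb = cfg.hybrid
    if hyb.amp_um_per_channel < 0:
        raise ValueError("microdomain amplitude must be nonnegative")
    dt = hyb.grid_dt_ms
    nt = int(round(protocol.duration_ms / dt))
    t = np.arange(nt) * dt
    c0 = cfg.diffusion.resting_ca_um
    if not protocol.onsets_ms:
        ca = np.full((1 if not per_vesicle else 7, nt), c0)
        return t, ca
    now = open_counts_weighted(cfg, t, protocol.onsets_ms, seed)
    md = _md_filter(now.astype(np.float64), dt, hyb)
    scaled = cfg.copy()
    scaled.channels.flux_open = cfg.channels.flux_open * flux_scale
    res = residual_trace(scaled, protocol.onsets_ms, protocol.duration_ms, dt)
    if per_vesicle:
        dists = vesicle_distances_nm(cfg)
    else:
        dists = np.array([cfg.geometry.l_c_nm])
    amps = np.array([hyb.amp_at(r) for r in dists]) * flux_scale
    # the residual already contains the resting level
    ca = res[None, :] + amps[:, None] * md[None, :]
    return t, ca


def hybrid_probe_trace(cfg: SimConfig, protocol: StimulusProtocol,
                       seed: int, flux_scale: float = 1.0) -> CalciumTrace:
    """Hybrid-mode calcium trace at the active-zone probe position."""
    t, ca = hybrid_ca_trace(cfg, protocol, seed, per_vesicle=False,
                            flux_scale=flux_scale)
    return CalciumTrace(t, ca[0], probe="active-zone (hybrid)")


def calibrate_hybrid_amplitude(cfg: SimConfig, target_peak_um: float = 12.0) -> float:
    """Set the microdomain amplitude so that the deterministic-mean
    single-AP template peaks at ``target_peak_um`` at the reference
    distance.  Returns amp (µM per weighted open channel)."""
    if target_peak_um < 0:
        raise ValueError("negative peak target")
    dt = cfg.hybrid.grid_dt_ms
    nt = int(round(40.0 / dt))
    t = np.arange(nt) * dt
    now = mean_open_weighted(cfg, t, [0.0])
    md = _md_filter(now, dt, cfg.hybrid)
    res = residual_trace(cfg, [0.0], 40.0, dt)
    k = int(np.argmax(md))
    base = res[k] + 0.0
    amp = (target_peak_um - base) / md[k]
    return float(amp)
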