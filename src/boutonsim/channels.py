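"""Stochastic P/Q-type VDCC gating and open-channel calcium influx.

The channel is a 5-state linear chain C1=C2=C3=C4=O with voltage
dependent rates a_i(v) = a_i0 exp(v/v_i), b_i(v) = b_i0 exp(-v/v_i);
only the open state conducts.  The single-channel flux while open is a
calibration parameter (ions/ms at resting driving force), modulated by
the instantaneous electrodiffusive driving force: by default the
normalized GHK flux factor for a divalent ion with negligible
intracellular concentration.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from . import _kernels
from .config import SimConfig, VDCCParams
from .stimulus import generate_ap_waveform

# RT/(zF) for Ca2+ near physiological temperature, in mV
_VGHK_MV = 13.27


@dataclass
class ChannelTrajectory:
    """Jump path of a single channel: state codes 0..4 (C1..C4, O)."""
    jump_times_ms: np.ndarray
    jump_states: np.ndarray
    t_end_ms: float
    start_state: int = 0

    def open_intervals(self) -> list:
        """Disjoint (t_open, t_close) intervals of the open state."""
        out = []
        t_open = 0.0 if self.start_state == 4 else None
        for t, s in zip(self.jump_times_ms, self.jump_states):
            if s == 4 and t_open is None:
                t_open = t
            elif s != 4 and t_open is not None:
                out.append((t_open, t))
                t_open = None
        if t_open is not None:
            out.append((t_open, self.t_end_ms))
        return out

    def states_at(self, t_grid) -> np.ndarray:
        """Piecewise-constant state evaluated on a time grid."""
        t_grid = np.asarray(t_grid)
        idx = np.searchsorted(self.jump_times_ms, t_grid, side="right")
        states = np.concatenate(([self.start_state], self.jump_states))
        return states[idx]


def vdcc_rates(v_mv: float, params: VDCCParams):
    """Forward/backward gating rates a_i(v), b_i(v) in ms^-1."""
    a0 = np.asarray(params.a0)
    b0 = np.asarray(params.b0)
    vi = np.asarray(params.v)
    a = a0 * np.exp(v_mv / vi)
    b = b0 * np.exp(-v_mv / vi)
    return a, b


def rate_arrays(voltage_mv: np.ndarray, params: VDCCParams):
    """Vectorized (nt, 4) rate arrays for a voltage trace."""
    v = np.asarray(voltage_mv, dtype=float)[:, None]
    a0 = np.asarray(params.a0)[None, :]
    b0 = np.asarray(params.b0)[None, :]
    vi = np.asarray(params.v)[None, :]
    return a0 * np.exp(v / vi), b0 * np.exp(-v / vi)


def generator_matrix(v_mv: float, params: VDCCParams) -> np.ndarray:
    """CTMC generator (5x5) of the gating chain at fixed voltage."""
    a, b = vdcc_rates(v_mv, params)
    Q = np.zeros((5, 5))
    for i in range(4):
        Q[i, i + 1] = a[i]
        Q[i + 1, i] = b[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(v_mv: float, params: VDCCParams) -> np.ndarray:
    """Stationary state occupancy at fixed voltage (detailed balance)."""
    a, b = vdcc_rates(v_mv, params)
    w = np.ones(5)
    for i in range(4):
        w[i + 1] = w[i] * a[i] / b[i]
    return w / w.sum()


def master_equation(voltage_mv, dt_ms, params: VDCCParams,
                    p0=None) -> np.ndarray:
    """Deterministic occupancy evolution (matrix exponential per sample).

    Independent oracle for the stochastic simulators; returns (nt, 5).
    """
    v = np.asarray(voltage_mv, dtype=float)
    p = stationary_distribution(v[0], params) if p0 is None else np.asarray(p0, float)
    out = np.zeros((len(v), 5))
    cache: dict = {}
    for k, vk in enumerate(v):
        out[k] = p
        key = round(float(vk), 6)
        if key not in cache:
            cache[key] = expm(generator_matrix(vk, params).T * dt_ms)
        p = cache[key] @ p
    return out


def driving_force(voltage_mv, params: VDCCParams) -> np.ndarray:
    """Normalized single-channel flux factor w(V), w(baseline) = 1.

    GHK mode: w ~ u / (exp(u) - 1), u = V / (RT/zF), for inward Ca flux
    with negligible intracellular calcium.  Linear mode: (V_rev - V)
    clipped at zero.  Normalization is at -70 mV.
    """
    v = np.atleast_1d(np.asarray(voltage_mv, dtype=float))
    if params.ghk_flux:
        u = v / _VGHK_MV
        w = np.where(np.abs(u) < 1e-9, 1.0, u / np.expm1(u))
        u0 = -70.0 / _VGHK_MV
        w0 = u0 / np.expm1(u0)
    else:
        w = np.clip(params.v_rev_mv - v, 0.0, None)
        w0 = params.v_rev_mv + 70.0
    return w / w0


def simulate_channel(voltage_mv, dt_ms: float, params: VDCCParams,
                     seed: int, start_state: int | None = None) -> ChannelTrajectory:
    """Exact-jump stochastic path of one channel along a voltage trace
    (piecewise-constant voltage per sample)."""
    v = np.asarray(voltage_mv, dtype=float)
    if v.size == 0:
        raise ValueError("empty voltage trace")
    if start_state is None:
        rng = np.random.default_rng(seed)
        start_state = int(rng.choice(5, p=stationary_distribution(v[0], params)))
    a, b = rate_arrays(v, params)
    max_jumps = int(50 * len(v) * dt_ms) + 1000
    times, states, _ = _kernels.channel_single_path(
        a, b, dt_ms, seed % (2 ** 31), start_state, max_jumps)
    return ChannelTrajectory(times, states, t_end_ms=len(v) * dt_ms,
                             start_state=start_state)


def simulate_open_counts(voltage_mv, dt_ms: float, params: VDCCParams,
                         seed: int) -> np.ndarray:
    """Open-channel count per sample for the whole cluster (aggregated
    exact-jump simulation of n_channels iid chains)."""
    a, b = rate_arrays(np.asarray(voltage_mv, float), params)
    return _kernels.channel_ensemble_open(a, b, dt_ms, params.n_channels,
                                          seed % (2 ** 31))


def channel_flux_events(trajectory: ChannelTrajectory, flux_open: float,
                        dt_ms: float, seed: int = 0) -> np.ndarray:
    """Poisson ion-injection schedule from a trajectory's open intervals.

    Returns the number of ions injected in each dt bin over the
    trajectory's duration; expected total = flux_open * total open time.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    if flux_open < 0:
        raise ValueError("flux must be nonnegative")
    nt = int(np.ceil(trajectory.t_end_ms / dt_ms))
    open_time = np.zeros(nt)
    for t0, t1 in trajectory.open_intervals():
        k0 = int(t0 / dt_ms)
        k1 = min(int(np.ceil(t1 / dt_ms)), nt)
        for k in range(k0, k1):
            lo = max(t0, k * dt_ms)
            hi = min(t1, (k + 1) * dt_ms)
            if hi > lo:
                open_time[k] += hi - lo
    rng = np.random.default_rng(seed)
    return rng.poisson(flux_open * open_time)


def open_probability_trace(cfg: SimConfig, window_ms: float = 15.0,
                           dt_ms: float = 0.005) -> tuple:
    """Deterministic open probability and flux weight over one AP window.

    Returns (t, p_open, w_flux) starting at the AP onset.
    """
    t = np.arange(0.0, window_ms, dt_ms)
    v = generate_ap_waveform(cfg.ap, t)
    occ = master_equation(v, dt_ms, cfg.channels)
    return t, occ[:, 4], driving_force(v, cfg.channels)


def calibrate_channel_flux(target_peak_um: float, cfg: SimConfig,
                           n_trials: int = 24, seed: int = 1234,
                           rel_tol: float = 0.05, max_iter: int = 8) -> float:
    """Calibrate the single-channel flux against the local calcium peak.

    Runs spatial-mode single-AP trials and adjusts ``flux_open`` by a
    secant-type iteration until the mean across-trial peak of the probe
    trace matches ``target_peak_um``.  The local peak responds nearly
    linearly to the flux at these concentrations, so convergence is fast.
    Returns the calibrated flux (ions/ms at resting driving force).
    """
    from .spatial import measure_peak_local_ca
    if target_peak_um < 0:
        raise ValueError("target peak must be nonnegative")
    if target_peak_um == 0.0:
        return 0.0
    flux = cfg.channels.flux_open if cfg.channels.flux_open > 0 else 500.0
    for it in range(max_iter):
        c = cfg.copy()
        c.channels.flux_open = flux
        peak = measure_peak_local_ca(c, n_trials=n_trials, seed=seed + it)
        if abs(peak - target_peak_um) <= rel_tol * target_peak_um:
            break
        ratio = target_peak_um / max(peak, 1e-9)
        ratio = min(max(ratio, 0.25), 4.0)
        flux *= ratio
    return flux
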