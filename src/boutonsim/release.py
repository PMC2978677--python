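"""Dual calcium-sensor release machinery of the active zone.

Each docked vesicle carries two independent calcium sensors: a
five-site synchronous sensor fusing at rate gamma from full occupancy
and a two-site asynchronous sensor fusing at a*gamma; spontaneous
fusion at rate delta proceeds from the fully unbound sensor.  Unbinding
steps are slowed by the cooperativity factor b (rate n k_off b^(n-1)
from occupancy n).  A release closes a zone-wide gate (refractory
period) that re-opens after an exponentially distributed delay with
mean epsilon; while closed, fusion is disabled but calcium binding
continues.  The readily releasable pool holds 7 vesicles and is
decremented by each release unless the zone is depletion-free.

A phenomenological single-gate variant treats the whole active zone as
one sensor state machine with its own published rate set, equal fusion
rates on both pathways and no vesicle limit.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .config import SensorParams, ZoneConfig

PATHWAYS = ("synchronous", "asynchronous", "spontaneous")


@dataclass
class ReleaseEvent:
    trial: int
    time_ms: float
    vesicle: int
    pathway: str


def _state_index(ns: int, na: int) -> int:
    return ns * 3 + na


def sensor_rate_matrix(params: SensorParams, ca_um: float,
                       with_fusion_sink: bool = True) -> np.ndarray:
    """CTMC generator over the 18 (ns, na) occupancy states.

    With ``with_fusion_sink`` the matrix is 19x19 with an absorbing
    fused state appended; otherwise fusion transitions recycle to
    (0, 0) (instant vesicle replacement), which is the relevant object
    for stationary release-flux computations.
    """
    if ca_um < 0:
        raise ValueError("calcium concentration must be nonnegative")
    ksp = params.ks_plus_um_ms
    ksm = params.ks_minus_ms
    kap = params.ka_plus_um_ms
    kam = params.ka_minus_ms
    b_s = params.b
    b_a = params.b if params.b_on_async else 1.0
    n = 19 if with_fusion_sink else 18
    Q = np.zeros((n, n))
    for ns in range(6):
        for na in range(3):
            i = _state_index(ns, na)
            if ns < 5:
                Q[i, _state_index(ns + 1, na)] += (5 - ns) * ksp * ca_um
            if ns > 0:
                Q[i, _state_index(ns - 1, na)] += ns * ksm * b_s ** (ns - 1)
            if na < 2:
                Q[i, _state_index(ns, na + 1)] += (2 - na) * kap * ca_um
            if na > 0:
                Q[i, _state_index(ns, na - 1)] += na * kam * b_a ** (na - 1)
            f = fusion_rate(params, ns, na)
            if f > 0:
                Q[i, 18 if with_fusion_sink else _state_index(0, 0)] += f
    d = np.einsum("ii->i", Q)
    d[:] = 0.0
    d[:] = -Q.sum(axis=1)
    return Q


def fusion_rate(params: SensorParams, ns: int, na: int) -> float:
    """Instantaneous fusion hazard (1/ms) of a vesicle in state (ns, na)."""
    f = 0.0
    if ns == 5:
        f += params.gamma_ms
    if na == 2:
        f += params.a * params.gamma_ms
    if params.delta_from_any_state or (ns == 0 and na == 0):
        f += params.delta_ms
    return f


def stationary_state(params: SensorParams, ca_um: float) -> np.ndarray:
    """Stationary law over (ns, na) with fusion recycling to (0, 0)."""
    Q = sensor_rate_matrix(params, ca_um, with_fusion_sink=False)
    A = np.vstack([Q.T, np.ones(18)])
    rhs = np.zeros(19)
    rhs[18] = 1.0
    pi, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def spontaneous_release_rate(params: SensorParams, ca_um: float = 0.1,
                             n_vesicles: int = 7) -> float:
    """Steady-state fusion flux (releases per ms) of the whole zone at
    clamped calcium: deterministic linear-algebra computation."""
    pi = stationary_state(params, ca_um)
    flux = sum(pi[_state_index(ns, na)] * fusion_rate(params, ns, na)
               for ns in range(6) for na in range(3))
    return n_vesicles * flux


def apply_variant(zone: ZoneConfig, variant: str) -> ZoneConfig:
    """Return a zone configuration with a sensor variant applied.

    sync-KO removes the synchronous pathway (states and gamma fusion),
    SAKO removes the asynchronous pathway, and 'phenomenological' swaps
    in the single-gate active-zone model (infinite RRP).
    """
    if variant not in ZoneConfig.VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    import copy
    out = copy.deepcopy(zone)
    out.variant = variant
    if variant == "phenomenological":
        out.sensor = out.phenomenological_params.as_sensor_params()
        out.depletion_free = True
    return out


def refractory_gate(release_times_ms, epsilon_ms: float, rng) -> list:
    """Closed intervals of the zone gate given a stream of releases.

    Each release closes the gate for an exponentially distributed
    duration with mean epsilon; overlapping closures merge.
    """
    if epsilon_ms <= 0:
        raise ValueError("epsilon must be positive")
    intervals = []
    for t in sorted(release_times_ms):
        dur = rng.exponential(epsilon_ms)
        if intervals and t <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], t + dur))
        else:
            intervals.append((t, t + dur))
    return intervals


def _kernel_args(zone: ZoneConfig):
    p = zone.sensor
    sync_on = zone.variant != "sync-KO"
    async_on = zone.variant != "SAKO"
    refractory_mode = 0
    if zone.refractory:
        refractory_mode = 2 if zone.deterministic_refractory else 1
    phenom = zone.variant == "phenomenological"
    return dict(
        ksp=p.ks_plus_um_ms, ksm=p.ks_minus_ms,
        kap=p.ka_plus_um_ms, kam=p.ka_minus_ms,
        b_s=p.b, b_a=p.b if p.b_on_async else 1.0,
        gamma=p.gamma_ms, agamma=p.a * p.gamma_ms, delta=p.delta_ms,
        delta_any=p.delta_from_any_state,
        eps_ms=p.epsilon_ms, refractory_mode=refractory_mode,
        dead_ms=zone.refractory_dead_time_ms,
        depletion_free=zone.depletion_free or phenom,
        reset_on_release=not phenom,
        sync_on=sync_on, async_on=async_on,
    )


def equilibrium_initial_states(zone: ZoneConfig, ca_um: float,
                               n_vesicles: int, rng) -> tuple:
    """Sample initial (ns, na) occupancies from the stationary law."""
    pi = stationary_state(zone.sensor, ca_um)
    idx = rng.choice(18, size=n_vesicles, p=pi)
    return (idx // 3).astype(np.int64), (idx % 3).astype(np.int64)


def simulate_active_zone(ca_traces, dt_ms: float, zone: ZoneConfig,
                         seed: int, trial: int = 0,
                         equilibrate: bool = True,
                         max_events: int = 100000) -> list:
    """Exact stochastic path of the active zone driven by per-vesicle
    calcium traces (piecewise-constant per sample).

    ``ca_traces`` has shape (n_vesicles, nt); for the per-vesicle model
    the zone holds ``zone.rrp`` vesicles and the trace count must match.
    Returns a list of :class:`ReleaseEvent`.
    """
    ca = np.ascontiguousarray(np.atleast_2d(np.asarray(ca_traces, dtype=np.float64)))
    phenom = zone.variant == "phenomenological"
    n_ves = 1 if phenom else zone.rrp
    if ca.shape[0] == 1 and n_ves > 1:
        ca = np.repeat(ca, n_ves, axis=0)
    if ca.shape[0] != n_ves:
        raise ValueError(f"expected {n_ves} calcium traces, got {ca.shape[0]}")
    rng = np.random.default_rng(seed)
    if equilibrate:
        init_ns, init_na = equilibrium_initial_states(zone, float(ca[0, 0]),
                                                      n_ves, rng)
    else:
        init_ns = np.zeros(n_ves, dtype=np.int64)
        init_na = np.zeros(n_ves, dtype=np.int64)
    kw = _kernel_args(zone)
    n_ev, t, v, p = _kernels.zone_sim(
        ca, dt_ms,
        kw["ksp"], kw["ksm"], kw["kap"], kw["kam"], kw["b_s"], kw["b_a"],
        kw["gamma"], kw["agamma"], kw["delta"], kw["delta_any"],
        kw["eps_ms"], kw["refractory_mode"], kw["dead_ms"],
        kw["depletion_free"], kw["reset_on_release"],
        kw["sync_on"], kw["async_on"],
        init_ns, init_na, int(rng.integers(2 ** 31)), max_events)
    return [ReleaseEvent(trial, float(t[i]), int(v[i]), PATHWAYS[p[i]])
            for i in range(n_ev)]
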