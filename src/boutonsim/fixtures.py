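"""Synthetic fixtures with known generating parameters, for testing the
analysis layer independently of the simulator."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocols import EnsembleResult, events_to_frame
from .release import ReleaseEvent
from .spatial import CalciumTrace


@dataclass
class Fixture:
    kind: str
    params: dict
    data: object


def _multi_exp_events(params: dict, rng) -> EnsembleResult:
    """Release events drawn from a0 e^(-t/tau_f) + a1 e^(-t/tau_s) + a2
    (rates per ms per trial) over a window, independently per trial."""
    n_trials = params.get("n_trials", 10000)
    window = params.get("window_ms", 400.0)
    comps = params.get("components", [(0.025, 6.0), (0.00023, 160.0)])
    const = params.get("constant", 0.00012)
    latency = params.get("latency_ms", 0.0)
    events = []
    for a, tau in comps:
        mean_total = a * tau * (1 - np.exp(-(window - latency) / tau)) * n_trials
        n = rng.poisson(mean_total)
        t = latency + rng.exponential(tau, n)
        t = t[t < window]
        for x in t:
            events.append((rng.integers(n_trials), x))
    n = rng.poisson(const * (window - latency) * n_trials)
    for x in latency + rng.uniform(0, window - latency, n):
        events.append((rng.integers(n_trials), x))
    ev = [ReleaseEvent(int(tr), float(t), 0, "synchronous") for tr, t in events]
    return EnsembleResult(events=events_to_frame(ev), n_trials=n_trials,
                          duration_ms=window, label="multi-exp-fixture")


def _constant_ca_events(params: dict, rng) -> EnsembleResult:
    """Homogeneous Poisson release at a known rate (per ms, whole zone)."""
    rate = params.get("rate_per_ms", 1.2e-4)
    n_trials = params.get("n_trials", 1000)
    window = params.get("window_ms", 400.0)
    events = []
    for trial in range(n_trials):
        n = rng.poisson(rate * window)
        for t in np.sort(rng.uniform(0, window, n)):
            events.append(ReleaseEvent(trial, float(t), int(rng.integers(7)),
                                       "spontaneous"))
    return EnsembleResult(events=events_to_frame(events), n_trials=n_trials,
                          duration_ms=window, label="constant-ca-fixture")


def _ca_transient(params: dict, rng) -> CalciumTrace:
    """Noisy single-AP calcium transient with known peak/rise/decay."""
    dt = params.get("dt_ms", 0.01)
    dur = params.get("duration_ms", 50.0)
    peak = params.get("peak_um", 12.0)
    rise = params.get("rise_ms", 0.3)
    decay = params.get("decay_ms", 0.6)
    onset = params.get("onset_ms", 2.0)
    base = params.get("baseline_um", 0.1)
    noise = params.get("noise_um", 0.0)
    t = np.arange(0.0, dur, dt)
    s = np.clip(t - onset, 0.0, None)
    shape = (1 - np.exp(-s / rise)) * np.exp(-s / decay)
    t_pk = rise * np.log(1 + decay / rise)
    shape /= (1 - np.exp(-t_pk / rise)) * np.exp(-t_pk / decay)
    c = base + (peak - base) * np.where(t > onset, shape, 0.0)
    if noise > 0:
        c = np.clip(c + rng.normal(0, noise, c.shape), 0.0, None)
    return CalciumTrace(t, c, probe="fixture")


def generate_fixture(kind: str, params: dict | None = None,
                     seed: int = 0) -> Fixture:
    """Deterministic synthetic data with stored ground truth.

    Kinds: ``ca_transient`` (noisy calcium pulse),
    ``multi_exp_events`` (events from a known exponential mixture),
    ``constant_ca_events`` (homogeneous Poisson events).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    makers = {
        "ca_transient": _ca_transient,
        "multi_exp_events": _multi_exp_events,
        "constant_ca_events": _constant_ca_events,
    }
    if kind not in makers:
        raise ValueError(f"unknown fixture kind {kind!r}; options {sorted(makers)}")
    data = makers[kind](params, rng)
    params["seed"] = seed
    return Fixture(kind=kind, params=params, data=data)
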