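"""Membrane-voltage stimulation protocols: single APs and trains.

The voltage is spatially uniform over the bouton; the only information
passed from the axon shaft is the membrane potential.  The exact axonal
AP waveform used in the original work is not published, so a parametric
double-exponential template stands in: baseline until ``onset + foot``,
then ``(1 - exp(-s/rise)) * exp(-s/fall)`` normalized to the peak.  The
foot delay is set so that evoked release peaks ~3 ms after stimulus
onset (the observed latency); the template parameters are configuration
fields so a digitized waveform can be substituted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import APParams


@dataclass
class StimulusProtocol:
    """Ordered AP onset times within a simulation window."""
    onsets_ms: list
    duration_ms: float
    frequency_hz: float = 0.0

    def __post_init__(self):
        on = list(self.onsets_ms)
        if any(b <= a for a, b in zip(on, on[1:])):
            raise ValueError("onsets must be strictly increasing")
        if any(o >= self.duration_ms for o in on):
            raise ValueError("all onsets must precede duration_ms")
        self.onsets_ms = on


# APWaveform is the parameter set; alias kept for the domain vocabulary.
APWaveform = APParams


def _template(s: np.ndarray, rise: float, fall: float) -> np.ndarray:
    """Normalized biexponential shape for s >= 0 (peak value 1)."""
    t_peak = rise * math.log(1.0 + fall / rise)
    h_peak = (1.0 - math.exp(-t_peak / rise)) * math.exp(-t_peak / fall)
    h = (1.0 - np.exp(-np.clip(s, 0.0, None) / rise)) * np.exp(-np.clip(s, 0.0, None) / fall)
    return np.where(s > 0.0, h / h_peak, 0.0)


def generate_ap_waveform(ap: APWaveform, t_grid: np.ndarray,
                         onsets_ms=None) -> np.ndarray:
    """Evaluate the membrane potential (mV) on ``t_grid`` (ms).

    ``onsets_ms`` superposes several APs (depolarizations add relative
    to baseline); by default the single onset in ``ap`` is used.
    Deterministic: no randomness enters the waveform.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be one-dimensional and strictly increasing")
    if np.any(t < 0):
        raise ValueError("t_grid must be nonnegative")
    if onsets_ms is None:
        onsets_ms = [ap.onset_ms]
    v = np.full_like(t, ap.baseline_mv)
    amp = ap.peak_mv - ap.baseline_mv
    for onset in onsets_ms:
        s = t - onset - ap.foot_ms
        v = v + amp * _template(s, ap.rise_ms, ap.fall_ms)
    return v


def make_train(frequency_hz: float, duration_ms: float,
               first_onset_ms: float = 0.0) -> StimulusProtocol:
    """Regular AP train: onsets at ``first_onset + k/frequency`` for all
    k with onset < duration.  Zero frequency gives an empty protocol."""
    if frequency_hz < 0:
        raise ValueError("frequency must be nonnegative")
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    onsets: list = []
    if frequency_hz > 0:
        period = 1000.0 / frequency_hz
        k = 0
        while True:
            t = first_onset_ms + k * period
            if t >= duration_ms:
                break
            onsets.append(t)
            k += 1
    return StimulusProtocol(onsets_ms=onsets, duration_ms=duration_ms,
                            frequency_hz=frequency_hz)


def read_voltage_trace(path) -> tuple:
    """Read a two-column plain-text voltage trace (time_ms, voltage_mV)."""
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("voltage trace file must have two columns")
    return data[:, 0], data[:, 1]


def write_voltage_trace(path, t_ms, v_mv) -> None:
    np.savetxt(path, np.column_stack([t_ms, v_mv]),
               header="time_ms voltage_mV")
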