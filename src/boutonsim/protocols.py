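"""Experiment orchestration: trial ensembles for single APs, trains,
refractory on/off comparisons, sensor knockouts and depletion-free zones.

Named release-probability presets (channel count / co-localization
distance combinations):

=========  ===========  =========
preset     n_channels   l_c (nm)
=========  ===========  =========
pr02       48           250
pr06       72           250
pr06_far   128          400
pr095      112          250
=========  ===========  =========
"""
from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .hybrid import hybrid_ca_trace
from .release import ReleaseEvent, apply_variant, simulate_active_zone
from .stimulus import StimulusProtocol, make_train

PRESETS = {
    "pr02": dict(n_channels=48, l_c_nm=250.0),
    "pr06": dict(n_channels=72, l_c_nm=250.0),
    "pr06_far": dict(n_channels=128, l_c_nm=400.0),
    "pr095": dict(n_channels=112, l_c_nm=250.0),
}


def preset_config(name: str, base: SimConfig | None = None) -> SimConfig:
    """A configuration for one of the named release-probability presets."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    cfg = (base or SimConfig()).copy()
    cfg.channels.n_channels = PRESETS[name]["n_channels"]
    cfg.geometry.l_c_nm = PRESETS[name]["l_c_nm"]
    return cfg


@dataclass
class ExperimentSpec:
    """One ensemble experiment: configuration, stimulus, trial count."""
    label: str
    config: SimConfig
    protocol: StimulusProtocol
    n_trials: int = 2000
    engine: str = "hybrid"
    seed: int = 0
    flux_scale: float = 1.0
    spatial_duration_ms: float | None = None  # spatial-mode window override

    def validate(self) -> "ExperimentSpec":
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.engine not in ("hybrid", "spatial"):
            raise ValueError("engine must be 'hybrid' or 'spatial'")
        return self


@dataclass
class EnsembleResult:
    """Release events across an ensemble of independent trials."""
    events: pd.DataFrame          # columns: trial, time_ms, vesicle, pathway
    n_trials: int
    duration_ms: float
    label: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def per_trial_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_trials, dtype=int)
        if len(self.events):
            vc = self.events["trial"].value_counts()
            counts[vc.index.to_numpy()] = vc.to_numpy()
        return counts

    def times(self, pathway: str | None = None) -> np.ndarray:
        ev = self.events
        if pathway is not None:
            ev = ev[ev["pathway"] == pathway]
        return ev["time_ms"].to_numpy()


def events_to_frame(events: list) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.trial, e.time_ms, e.vesicle, e.pathway) for e in events],
        columns=["trial", "time_ms", "vesicle", "pathway"],
    )


def _trial_seeds(master_seed: int, n_trials: int) -> np.ndarray:
    """Deterministic per-trial seed pairs (channel stream, zone stream)."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(2 * n_trials, dtype=np.uint32).reshape(n_trials, 2)


def run_ensemble(spec: ExperimentSpec, progress: bool = False) -> EnsembleResult:
    """Run ``n_trials`` independent trials; fully reproducible from the
    master seed (per-trial seeds are derived deterministically)."""
    spec.validate()
    cfg = spec.config
    zone = apply_variant(cfg.zone, cfg.zone.variant)
    seeds = _trial_seeds(spec.seed, spec.n_trials)
    t0 = time.time()
    all_events: list = []
    if spec.engine == "hybrid":
        per_vesicle = zone.variant != "phenomenological"
        dt = cfg.hybrid.grid_dt_ms
        for trial in range(spec.n_trials):
            _, ca = hybrid_ca_trace(cfg, spec.protocol, int(seeds[trial, 0]),
                                    per_vesicle=per_vesicle,
                                    flux_scale=spec.flux_scale)
            all_events.extend(simulate_active_zone(
                ca, dt, zone, int(seeds[trial, 1]), trial=trial))
    else:
        from .spatial import run_spatial_trial
        dur = spec.spatial_duration_ms or spec.protocol.duration_ms
        scfg = cfg if spec.flux_scale == 1.0 else cfg.copy()
        if spec.flux_scale != 1.0:
            scfg.channels.flux_open = cfg.channels.flux_open * spec.flux_scale
        for trial in range(spec.n_trials):
            res = run_spatial_trial(scfg, dur, int(seeds[trial, 0]),
                                    trial=trial, stimulus=spec.protocol)
            all_events.extend(res.events)
    meta = dict(
        label=spec.label, engine=spec.engine, seed=spec.seed,
        n_trials=spec.n_trials, flux_scale=spec.flux_scale,
        variant=zone.variant, refractory=zone.refractory,
        depletion_free=zone.depletion_free,
        n_channels=cfg.channels.n_channels, l_c_nm=cfg.geometry.l_c_nm,
        runtime_s=round(time.time() - t0, 3),
    )
    return EnsembleResult(events=events_to_frame(all_events),
                          n_trials=spec.n_trials,
                          duration_ms=spec.protocol.duration_ms,
                          label=spec.label, metadata=meta)


def run_comparison(spec: ExperimentSpec, refractory=None, variant=None,
                   depletion_free=None) -> tuple:
    """Paired ensembles differing only in the stated toggles, with
    common-random-number seeding (same master seed) for variance
    reduction.  Returns (baseline, toggled)."""
    if refractory is None and variant is None and depletion_free is None:
        raise ValueError("at least one toggle must be given")
    base = run_ensemble(spec)
    other = dataclasses.replace(spec, config=spec.config.copy())
    if refractory is not None:
        other.config.zone.refractory = refractory
    if variant is not None:
        other.config.zone.variant = variant
    if depletion_free is not None:
        other.config.zone.depletion_free = depletion_free
    other.label = spec.label + "-toggled"
    return base, run_ensemble(other)


def run_depletion_free(spec: ExperimentSpec) -> EnsembleResult:
    """Ensemble with instantly replaced vesicles (refractory still applies)."""
    spec2 = dataclasses.replace(spec, config=spec.config.copy(),
                                label=spec.label + "-depletion-free")
    spec2.config.zone.depletion_free = True
    return run_ensemble(spec2)


def single_ap_spec(preset: str = "pr02", n_trials: int = 2000,
                   duration_ms: float = 400.0, seed: int = 0,
                   base: SimConfig | None = None,
                   label: str | None = None) -> ExperimentSpec:
    cfg = preset_config(preset, base)
    proto = StimulusProtocol(onsets_ms=[0.0], duration_ms=duration_ms)
    return ExperimentSpec(label=label or f"{preset}-single-ap", config=cfg,
                          protocol=proto, n_trials=n_trials, seed=seed)


def train_spec(preset: str = "pr02", frequency_hz: float = 10.0,
               duration_ms: float = 400.0, n_trials: int = 2000,
               seed: int = 0, base: SimConfig | None = None,
               label: str | None = None) -> ExperimentSpec:
    cfg = preset_config(preset, base)
    proto = make_train(frequency_hz, duration_ms)
    return ExperimentSpec(
        label=label or f"{preset}-train-{frequency_hz:g}Hz", config=cfg,
        protocol=proto, n_trials=n_trials, seed=seed)
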