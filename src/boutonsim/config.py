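"""Model parameterization and configuration files.

All kinetic constants default to the published values for the CA3-CA1
bouton model.  Configuration files (JSON or YAML) use the same units the
constants are usually quoted in (association rates in M^-1 s^-1,
dissociation and fusion rates in s^-1, lengths in nm, times in ms,
concentrations as stated per field).  Internally everything is converted
to a single unit system: ms, µM, mV and µm.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

# unit conversion helpers
PER_M_S_TO_PER_UM_MS = 1e-9     # M^-1 s^-1 -> µM^-1 ms^-1
PER_S_TO_PER_MS = 1e-3          # s^-1 -> ms^-1
IONS_PER_UM3_PER_UM = 602.214   # ions in 1 µm^3 at 1 µM


class ConfigError(ValueError):
    """Raised when a configuration file fails validation."""


@dataclass
class APParams:
    """Action-potential template (the waveform itself is not published;
    this is a parametric stand-in, see :mod:`boutonsim.stimulus`)."""
    baseline_mv: float = -70.0
    peak_mv: float = 34.0
    onset_ms: float = 0.0
    foot_ms: float = 1.7          # conduction/foot delay before upstroke
    rise_ms: float = 0.2
    fall_ms: float = 0.45
    shape: str = "biexp"

    def validate(self) -> None:
        if self.rise_ms <= 0 or self.fall_ms <= 0:
            raise ConfigError("AP rise/fall time constants must be positive")
        if self.peak_mv <= self.baseline_mv:
            raise ConfigError("AP peak must exceed baseline")


@dataclass
class VDCCParams:
    """P/Q-type voltage-dependent calcium channel cluster.

    Gating follows a 5-state linear chain C1=C2=C3=C4=O with
    a_i(v) = a_i0 exp(v/v_i), b_i(v) = b_i0 exp(-v/v_i).
    """
    a0: tuple = (4.04, 6.70, 4.39, 17.33)       # ms^-1
    b0: tuple = (2.88, 6.30, 8.16, 1.84)        # ms^-1
    v: tuple = (49.14, 42.08, 55.31, 26.55)     # mV
    n_channels: int = 48
    cluster_radius_nm: float = 35.0
    # calibrated single-channel flux at resting driving force (ions/ms
    # while open, scaled by the normalized driving force at each voltage).
    flux_open: float = 1169.0
    v_rev_mv: float = 45.0
    ghk_flux: bool = True
    mobility: float = 0.0

    def validate(self) -> None:
        if not (1 <= self.n_channels <= 208):
            raise ConfigError("n_channels must lie in 1..208")
        if self.cluster_radius_nm > 66.0:
            raise ConfigError("cluster radius exceeds 66 nm maximum")
        if any(x <= 0 for x in self.a0 + self.b0):
            raise ConfigError("rate prefactors must be positive")
        if self.flux_open < 0:
            raise ConfigError("flux_open must be nonnegative")


@dataclass
class SensorParams:
    """Dual calcium-sensor release machinery (per docked vesicle).

    Five-site synchronous pathway, two-site asynchronous pathway;
    cooperativity factor b scales successive unbinding steps.
    """
    ks_plus: float = 0.612e8      # M^-1 s^-1
    ks_minus: float = 2.32e3      # s^-1
    ka_plus: float = 3.82e6       # M^-1 s^-1
    ka_minus: float = 13.0        # s^-1
    b: float = 0.25
    gamma: float = 2e3            # s^-1 synchronous fusion
    a: float = 0.025              # asynchronous fusion factor, gamma_a = a*gamma
    delta: float = 0.417e-3       # s^-1 spontaneous fusion
    epsilon_ms: float = 6.34      # refractory recovery time constant
    n_sync_sites: int = 5
    n_async_sites: int = 2
    b_on_async: bool = True       # apply cooperativity to async unbinding too
    delta_from_any_state: bool = False

    def validate(self) -> None:
        if not (0 < self.b <= 1):
            raise ConfigError("cooperativity b must be in (0, 1]")
        if not (0 < self.a < 1):
            raise ConfigError("asynchronous fusion factor a must be in (0, 1)")
        if self.n_sync_sites != 5 or self.n_async_sites != 2:
            raise ConfigError("site counts are fixed at 5 synchronous / 2 asynchronous")
        if self.epsilon_ms <= 0:
            raise ConfigError("epsilon_ms must be positive")

    # internal-unit accessors
    @property
    def ks_plus_um_ms(self) -> float:
        return self.ks_plus * PER_M_S_TO_PER_UM_MS

    @property
    def ks_minus_ms(self) -> float:
        return self.ks_minus * PER_S_TO_PER_MS

    @property
    def ka_plus_um_ms(self) -> float:
        return self.ka_plus * PER_M_S_TO_PER_UM_MS

    @property
    def ka_minus_ms(self) -> float:
        return self.ka_minus * PER_S_TO_PER_MS

    @property
    def gamma_ms(self) -> float:
        return self.gamma * PER_S_TO_PER_MS

    @property
    def delta_ms(self) -> float:
        return self.delta * PER_S_TO_PER_MS


@dataclass
class PhenomenologicalParams:
    """Single-gate model of the whole active zone (infinite RRP, one
    sensor state machine; both pathways fuse at the full rate gamma)."""
    ks_plus: float = 1.91e8
    ks_minus: float = 7.25e3
    ka_plus: float = 3.68e6
    ka_minus: float = 26.0
    b: float = 0.25
    gamma: float = 6e3
    gamma1: float = 0.417e-3      # spontaneous rate (per s)
    epsilon_ms: float = 6.34

    def as_sensor_params(self) -> SensorParams:
        return SensorParams(
            ks_plus=self.ks_plus, ks_minus=self.ks_minus,
            ka_plus=self.ka_plus, ka_minus=self.ka_minus,
            b=self.b, gamma=self.gamma, a=0.999999,
            delta=self.gamma1, epsilon_ms=self.epsilon_ms,
        )


@dataclass
class ZoneConfig:
    """Active-zone level configuration: RRP, refractoriness, variant."""
    sensor: SensorParams = field(default_factory=SensorParams)
    phenomenological_params: PhenomenologicalParams = field(
        default_factory=PhenomenologicalParams)
    rrp: int = 7
    refractory: bool = True
    deterministic_refractory: bool = False
    refractory_dead_time_ms: float = 6.0
    depletion_free: bool = False
    variant: str = "wild-type"    # wild-type | sync-KO | SAKO | phenomenological

    VARIANTS = ("wild-type", "sync-KO", "SAKO", "phenomenological")

    def validate(self) -> None:
        self.sensor.validate()
        if self.variant not in self.VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; options: {self.VARIANTS}")
        if self.rrp < 1:
            raise ConfigError("RRP size must be >= 1")


@dataclass
class BufferParams:
    """Mobile buffer calbindin-D28k: two high-affinity and two
    medium-affinity independent sites per molecule."""
    concentration_um: float = 45.0
    d_cb: float = 28.0            # µm^2/s
    kh_plus: float = 0.55e7       # M^-1 s^-1
    kh_minus: float = 2.6         # s^-1
    km_plus: float = 4.35e7
    km_minus: float = 35.8
    sites_high: int = 2
    sites_medium: int = 2

    def validate(self) -> None:
        if min(self.kh_plus, self.kh_minus, self.km_plus, self.km_minus) <= 0:
            raise ConfigError("buffer rates must be positive")
        if self.sites_high < 1 or self.sites_medium < 1:
            raise ConfigError("site stoichiometry must be >= 1")

    @property
    def total_high_sites_um(self) -> float:
        return self.concentration_um * self.sites_high

    @property
    def total_medium_sites_um(self) -> float:
        return self.concentration_um * self.sites_medium

    @property
    def kd_high_um(self) -> float:
        return (self.kh_minus * PER_S_TO_PER_MS) / (self.kh_plus * PER_M_S_TO_PER_UM_MS)

    @property
    def kd_medium_um(self) -> float:
        return (self.km_minus * PER_S_TO_PER_MS) / (self.km_plus * PER_M_S_TO_PER_UM_MS)


@dataclass
class PumpParams:
    """PMCA pump 4-state cycle with a compensating leak.

    The published per-pump leak constant does not balance extrusion at
    the resting point; the leak influx is therefore normalized at start-up
    so the full system is stationary at the resting calcium level (the
    pumps' stated function).
    """
    density_per_um2: float = 180.0
    kpm1: float = 1.5e7           # M^-1 s^-1
    kpm2: float = 20.0            # s^-1
    kpm3: float = 20.0            # s^-1 (extrusion)
    kpm4: float = 100.0           # s^-1 (reset)
    kpm_leak: float = 12.5        # s^-1, nominal
    balance_leak_at_rest: bool = True
    mobility: float = 0.0

    def validate(self) -> None:
        if min(self.kpm1, self.kpm2, self.kpm3, self.kpm4) <= 0:
            raise ConfigError("pump rates must be positive")


@dataclass
class Geometry:
    """Bouton geometry: 0.5 x 0.5 x 4 µm box, x along the long axis,
    origin at the box center, active zone on the y-min face."""
    box_um: tuple = (4.0, 0.5, 0.5)       # (x, y, z)
    l_c_nm: float = 250.0                  # VDCC cluster -> AZ center distance
    vesicle_ring_radius_nm: float = 17.5   # hexagonal array, central + 6
    probe_offset_nm: float = 10.0          # perpendicular from AZ
    probe_radius_nm: float = 50.0
    clamp_slab_nm: float = 20.0

    def validate(self) -> None:
        if not (10.0 <= self.l_c_nm <= 400.0):
            raise ConfigError("l_c must lie in [10, 400] nm")
        if self.probe_radius_nm <= 0:
            raise ConfigError("probe radius must be positive")

    @property
    def az_center_um(self) -> tuple:
        return (0.0, -self.box_um[1] / 2.0, 0.0)

    @property
    def cluster_center_um(self) -> tuple:
        return (self.l_c_nm * 1e-3, -self.box_um[1] / 2.0, 0.0)

    def vesicle_positions_um(self):
        """Central vesicle plus six on a ring (35 nm cluster diameter)."""
        import numpy as np
        az = np.array(self.az_center_um)
        r = self.vesicle_ring_radius_nm * 1e-3
        pos = [az.copy()]
        for k in range(6):
            ang = k * math.pi / 3.0
            pos.append(az + np.array([r * math.cos(ang), 0.0, r * math.sin(ang)]))
        return np.array(pos)


@dataclass
class DiffusionParams:
    d_ca: float = 220.0           # µm^2/s
    dt_ca_us: float = 1.0         # engine step for calcium (desk scale)
    dt_other_us: float = 1.0      # engine step for everything else
    resting_ca_um: float = 0.1    # 100 nM

    def validate(self) -> None:
        if self.dt_ca_us > self.dt_other_us:
            raise ConfigError("dt_ca must not exceed dt_other")
        if self.resting_ca_um <= 0:
            raise ConfigError("resting calcium must be positive")


@dataclass
class HybridParams:
    """Fast-mode calcium template, calibrated against the spatial engine.

    Local calcium at each vesicle = resting + microdomain + residual:
    the microdomain term is a first-order-filtered copy of the
    instantaneous open-channel source (quasi-steady nanodomain), the
    residual is a deterministic 1-D buffered reaction-diffusion solution
    of the bulk excess along the axon axis.
    """
    amp_um_per_channel: float = 1.7864   # sensor-site µM per weighted open channel
    # two-pole microdomain relaxation kernel, calibrated from the
    # spatial engine's impulse response (fast: buffer capture; slow:
    # intermediate-field drainage)
    tau_md_ms: float = 0.147
    tau_md2_ms: float = 0.601
    w_md_fast: float = 0.91
    l_c_ref_nm: float = 250.0
    lambda_screen_nm: float = 255.0     # distance screening length of the kernel
    grid_dt_ms: float = 0.01
    pde_nx: int = 81
    source_sigma_um: float = 0.35

    def kernel(self, r_nm: float) -> float:
        """Unnormalized steady-source distance kernel exp(-r/lambda)/r."""
        return math.exp(-r_nm / self.lambda_screen_nm) / r_nm

    def amp_at(self, r_nm: float) -> float:
        return self.amp_um_per_channel * self.kernel(r_nm) / self.kernel(self.l_c_ref_nm)


@dataclass
class ProtocolConfig:
    frequency_hz: float = 0.0
    duration_ms: float = 400.0
    first_onset_ms: float = 0.0
    n_trials: int = 2000

    def validate(self) -> None:
        if self.frequency_hz < 0:
            raise ConfigError("frequency must be nonnegative")
        if self.duration_ms <= 0:
            raise ConfigError("duration must be positive")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")


@dataclass
class SimConfig:
    """Full parameterization of one experiment."""
    ap: APParams = field(default_factory=APParams)
    channels: VDCCParams = field(default_factory=VDCCParams)
    sensor: SensorParams = field(default_factory=SensorParams)
    zone: ZoneConfig = field(default_factory=ZoneConfig)
    buffer: BufferParams = field(default_factory=BufferParams)
    pumps: PumpParams = field(default_factory=PumpParams)
    geometry: Geometry = field(default_factory=Geometry)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    hybrid: HybridParams = field(default_factory=HybridParams)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    engine: str = "hybrid"        # hybrid | spatial
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        # keep zone.sensor and top-level sensor as one object
        self.zone.sensor = self.sensor

    def validate(self) -> "SimConfig":
        for section in (self.ap, self.channels, self.sensor, self.zone,
                        self.buffer, self.pumps, self.geometry,
                        self.diffusion, self.protocol):
            section.validate()
        if self.engine not in ("hybrid", "spatial"):
            raise ConfigError("engine must be 'hybrid' or 'spatial'")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def copy(self) -> "SimConfig":
        import copy as _copy
        return _copy.deepcopy(self)


_SECTIONS = {f.name: f.type for f in dataclasses.fields(SimConfig)}


def _apply(obj: Any, data: dict, path: str) -> None:
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, val in data.items():
        if key not in fields:
            raise ConfigError(f"unknown key {path}{key!r}")
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            _apply(cur, val, f"{path}{key}.")
        else:
            if isinstance(cur, tuple) and isinstance(val, list):
                val = tuple(val)
            setattr(obj, key, val)


def config_from_dict(data: dict) -> SimConfig:
    cfg = SimConfig()
    if data:
        _apply(cfg, data, "")
    cfg.__post_init__()
    return cfg.validate()


def load_config(path: str | Path) -> SimConfig:
    """Load and validate a JSON or YAML configuration file.

    An empty file yields the all-defaults configuration.  Unknown keys
    and out-of-range values raise :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data: dict
    if not text.strip():
        data = {}
    elif path.suffix.lower() in (".yaml", ".yml"):
        import yaml
        data = yaml.safe_load(text) or {}
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml
            data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(data)


def save_config(cfg: SimConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2))
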