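"""Dual-sensor release machinery: rate matrix structure, spontaneous
flux, stochastic paths vs Gillespie/master-equation oracles, variants
and the refractory gate."""
import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import ks_2samp

from boutonsim.config import SensorParams, ZoneConfig
from boutonsim.release import (apply_variant, equilibrium_initial_states,
                               fusion_rate, refractory_gate,
                               sensor_rate_matrix, simulate_active_zone,
                               spontaneous_release_rate, stationary_state)


@pytest.fixture
def sensor():
    return SensorParams()


@pytest.fixture
def zone():
    return ZoneConfig()


def _gillespie_first_release(params, ca_um, rng, t_max=2000.0):
    """Independent plain-python Gillespie oracle on the homogeneous chain."""
    ns = na = 0
    t = 0.0
    b = params.b
    ba = params.b if params.b_on_async else 1.0
    while t < t_max:
        rates = []
        moves = []
        if ns < 5:
            rates.append((5 - ns) * params.ks_plus_um_ms * ca_um)
            moves.append("ns+")
        if ns > 0:
            rates.append(ns * params.ks_minus_ms * b ** (ns - 1))
            moves.append("ns-")
        if na < 2:
            rates.append((2 - na) * params.ka_plus_um_ms * ca_um)
            moves.append("na+")
        if na > 0:
            rates.append(na * params.ka_minus_ms * ba ** (na - 1))
            moves.append("na-")
        f = fusion_rate(params, ns, na)
        if f > 0:
            rates.append(f)
            moves.append("fuse")
        tot = sum(rates)
        t += rng.exponential(1.0 / tot)
        mv = rng.choice(moves, p=np.array(rates) / tot)
        if mv == "fuse":
            return t
        ns += 1 if mv == "ns+" else (-1 if mv == "ns-" else 0)
        na += 1 if mv == "na+" else (-1 if mv == "na-" else 0)
    return np.inf


class TestRateMatrix:
    def test_zero_calcium_leaves_only_unbinding_and_delta(self, sensor):
        Q = sensor_rate_matrix(sensor, 0.0)
        # forward binding transitions all zero
        for ns in range(5):
            for na in range(3):
                assert Q[ns * 3 + na, (ns + 1) * 3 + na] == 0.0
        # delta from the fully unbound state persists
        assert Q[0, 18] == pytest.approx(sensor.delta_ms)

    def test_unbinding_rates_follow_cooperativity_law(self, sensor):
        Q = sensor_rate_matrix(sensor, 0.1)
        # ns: 1 -> 0 at ks_minus (2.32e3 /s)
        assert Q[1 * 3, 0] == pytest.approx(2.32, rel=1e-12)
        # ns: 5 -> 4 at 5 ks_minus b^4
        assert Q[5 * 3, 4 * 3] == pytest.approx(5 * 2.32 * 0.25 ** 4, rel=1e-12)

    def test_rows_sum_to_zero(self, sensor):
        Q = sensor_rate_matrix(sensor, 5.0)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_negative_calcium_rejected(self, sensor):
        with pytest.raises(ValueError):
            sensor_rate_matrix(sensor, -1.0)

    def test_spontaneous_zone_rate_at_rest(self, sensor):
        # steady-state fusion flux of the 7-vesicle zone at 100 nM
        rate = spontaneous_release_rate(sensor, ca_um=0.1, n_vesicles=7)
        assert rate == pytest.approx(1.2e-4, abs=0.2e-4)


class TestZoneSimulation:
    def test_no_calcium_no_delta_means_no_release(self, zone):
        zone.sensor.delta = 0.0
        ca = np.zeros((7, 2000))
        ev = simulate_active_zone(ca, 0.01, zone, seed=1, equilibrate=False)
        assert ev == []

    def test_spontaneous_rate_long_run(self, zone):
        # clamped 100 nM, aggregate >= 1e6 ms: rate 1.2e-4 +- 0.2e-4 per ms
        # (plus the Poisson counting error of the finite aggregate)
        ca = np.full((7, 50000), 0.1)  # 500 ms per trial at dt=0.01
        total = 0
        n_trials = 2400
        for s in range(n_trials):
            total += len(simulate_active_zone(ca, 0.01, zone, seed=s))
        t_agg = n_trials * 500.0
        rate = total / t_agg
        sigma = np.sqrt(max(total, 1)) / t_agg
        assert abs(rate - 1.2e-4) < 0.2e-4 + 2.5 * sigma
        # and the stochastic path agrees with the deterministic stationary
        # flux of the same chain
        det = spontaneous_release_rate(zone.sensor, 0.1, 7)
        assert abs(rate - det) < 3 * sigma + 0.05 * det

    def test_first_release_distribution_matches_gillespie_oracle(self, zone):
        # fixed 10 µM, single vesicle, no refractory
        zone.rrp = 1
        zone.refractory = False
        n = 4000
        ca = np.full((1, 30000), 10.0)
        sim = []
        for s in range(n):
            ev = simulate_active_zone(ca, 0.01, zone, seed=s,
                                      equilibrate=False)
            sim.append(ev[0].time_ms if ev else np.inf)
        rng = np.random.default_rng(99)
        oracle = [_gillespie_first_release(zone.sensor, 10.0, rng, t_max=300.0)
                  for _ in range(n)]
        sim = np.array(sim)
        oracle = np.array(oracle)
        # compare finite parts; censoring fraction must agree too
        assert abs(np.isinf(sim).mean() - np.isinf(oracle).mean()) < 0.03
        ks = ks_2samp(sim[np.isfinite(sim)], oracle[np.isfinite(oracle)])
        assert ks.statistic < 0.035

    def test_rrp_conservation(self, zone):
        ca = np.full((7, 20000), 30.0)  # strong sustained drive
        for s in range(5):
            ev = simulate_active_zone(ca, 0.01, zone, seed=s)
            assert len(ev) <= 7

    def test_depletion_free_exponential_intervals(self, zone):
        # constant calcium, refractory off, depletion-free: inter-release
        # intervals at the zone are exponential (CV ~ 1)
        zone.depletion_free = True
        zone.refractory = False
        ca = np.full((7, 100000), 2.0)
        times = []
        for s in range(30):
            ev = simulate_active_zone(ca, 0.01, zone, seed=s)
            tt = np.array([e.time_ms for e in ev])
            times.extend(np.diff(np.sort(tt)))
        iv = np.array(times)
        assert len(iv) > 300
        cv = iv.std() / iv.mean()
        assert abs(cv - 1.0) < 0.1

    def test_occupancy_matches_master_equation(self, zone):
        # stationary (ns, na) law under constant calcium vs linear algebra
        ca_level = 1.0
        pi = stationary_state(zone.sensor, ca_level)
        rng = np.random.default_rng(5)
        ns, na = equilibrium_initial_states(zone, ca_level, 20000, rng)
        emp = np.zeros(18)
        for i in range(len(ns)):
            emp[ns[i] * 3 + na[i]] += 1
        emp /= emp.sum()
        assert np.abs(emp - pi).sum() / 2 < 0.02  # total variation

    def test_seed_reproducibility(self, zone):
        ca = np.full((7, 5000), 5.0)
        e1 = simulate_active_zone(ca, 0.01, zone, seed=77)
        e2 = simulate_active_zone(ca, 0.01, zone, seed=77)
        assert [(e.time_ms, e.vesicle, e.pathway) for e in e1] == \
            [(e.time_ms, e.vesicle, e.pathway) for e in e2]

    def test_trace_count_mismatch_rejected(self, zone):
        with pytest.raises(ValueError):
            simulate_active_zone(np.zeros((3, 100)), 0.01, zone, seed=0)


class TestVariants:
    def test_sync_ko_produces_no_synchronous_events(self, zone):
        z = apply_variant(zone, "sync-KO")
        ca = np.full((7, 20000), 8.0)
        for s in range(10):
            for e in simulate_active_zone(ca, 0.01, z, seed=s):
                assert e.pathway != "synchronous"

    def test_sako_produces_no_asynchronous_events(self, zone):
        z = apply_variant(zone, "SAKO")
        ca = np.full((7, 20000), 8.0)
        for s in range(10):
            for e in simulate_active_zone(ca, 0.01, z, seed=s):
                assert e.pathway != "asynchronous"

    def test_sync_ko_increases_asynchronous_count(self, zone):
        # shared vesicle pool: removing the synchronous sensor frees
        # vesicles for the asynchronous pathway
        ca = np.full((7, 40000), 6.0)
        def count_async(z, n=60):
            tot = 0
            for s in range(n):
                tot += sum(e.pathway == "asynchronous"
                           for e in simulate_active_zone(ca, 0.01, z, seed=s))
            return tot
        n_wt = count_async(apply_variant(zone, "wild-type"))
        n_ko = count_async(apply_variant(zone, "sync-KO"))
        assert n_ko > n_wt

    def test_unknown_variant_rejected(self, zone):
        with pytest.raises(ValueError):
            apply_variant(zone, "quadruple-KO")

    def test_phenomenological_is_single_gate_unlimited(self, zone):
        z = apply_variant(zone, "phenomenological")
        ca = np.full((1, 50000), 5.0)
        ev = simulate_active_zone(ca, 0.01, z, seed=3)
        assert len(ev) > 7  # no RRP limit


class TestRefractoryGate:
    def test_no_releases_gate_always_open(self):
        rng = np.random.default_rng(0)
        assert refractory_gate([], 6.34, rng) == []

    def test_mean_closure_duration(self):
        rng = np.random.default_rng(1)
        n = 10000
        iv = refractory_gate(np.arange(n) * 1e6, 6.34, rng)
        durations = np.array([b - a for a, b in iv])
        sem = durations.std() / np.sqrt(n)
        assert abs(durations.mean() - 6.34) < 3 * sem

    def test_overlapping_closures_merge(self):
        rng = np.random.default_rng(2)
        iv = refractory_gate([0.0, 0.01, 0.02], 50.0, rng)
        assert len(iv) == 1

    def test_refractory_suppresses_short_intervals(self, zone):
        # with the gate on, close release pairs (< 2 ms) are strongly
        # suppressed relative to the gate-off case under strong drive
        ca = np.full((7, 30000), 25.0)
        def short_pairs(refractory, n=150):
            z = ZoneConfig()
            z.refractory = refractory
            z.depletion_free = True
            cnt = 0
            for s in range(n):
                tt = np.sort([e.time_ms for e in
                              simulate_active_zone(ca, 0.01, z, seed=s)])
                cnt += int(np.sum(np.diff(tt) < 2.0))
            return cnt
        n_off = short_pairs(False)
        n_on = short_pairs(True)
        assert n_on < 0.2 * n_off
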