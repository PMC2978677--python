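"""Spatial engine: Brownian statistics, reaction sampling, pump cycle,
boundary clamp, local measurement and the full-trial kernel."""
import numpy as np
import pytest

from boutonsim.config import PumpParams, SimConfig
from boutonsim.release import PATHWAYS
from boutonsim.spatial import (clamp_boundaries, measure_local_ca,
                               pmca_cycle_step, pump_extrusion_flux_ms,
                               pump_leak_per_pump_ms, react_bimolecular,
                               reaction_probability, run_spatial_trial,
                               step_particles, tagged_ion_positions)

BOX = (4.0, 0.5, 0.5)


class TestStepParticles:
    def test_immobile_species_unchanged(self, rng):
        pos = rng.uniform(-0.2, 0.2, (100, 3))
        out = step_particles(pos, 0.0, 0.001, BOX, rng)
        assert np.array_equal(out, pos)

    def test_free_msd_matches_6dt(self, rng):
        # MSD(t) = 6 D t for unconfined Brownian motion
        d = 0.22  # µm^2/ms
        pos = np.zeros((10000, 3))
        dt = 0.001
        nsteps = 200
        big_box = (100.0, 100.0, 100.0)
        p = pos
        for _ in range(nsteps):
            p = step_particles(p, d, dt, big_box, rng)
        msd = (p ** 2).sum(axis=1).mean()
        expected = 6 * d * dt * nsteps
        assert msd == pytest.approx(expected, rel=0.02)

    def test_particle_outside_box_rejected(self, rng):
        pos = np.array([[10.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            step_particles(pos, 0.1, 0.001, BOX, rng)

    def test_walls_reflect(self, rng):
        pos = np.full((2000, 3), 0.24)
        out = step_particles(pos, 0.22, 0.001, BOX, rng)
        assert np.all(np.abs(out[:, 1]) <= 0.25 + 1e-12)
        assert np.all(np.abs(out[:, 2]) <= 0.25 + 1e-12)


class TestReactBimolecular:
    def test_zero_rate_never_binds(self, rng):
        ca = rng.uniform(-0.1, 0.1, (500, 3))
        sites = rng.uniform(-0.1, 0.1, (500, 3))
        assert np.all(react_bimolecular(ca, sites, 0.0, 0.001, rng) == -1)

    def test_macroscopic_on_rate_recovered(self, rng):
        # well-mixed box: measured binding flux ~ k_on [Ca][S]
        k_on = 1e8  # M^-1 s^-1
        box = 0.5   # µm cube
        n_ca, n_s = 400, 400
        dt = 0.001
        n_steps = 200
        binds = 0
        for _ in range(n_steps):
            ca = rng.uniform(0, box, (n_ca, 3))
            sites = rng.uniform(0, box, (n_s, 3))
            binds += int((react_bimolecular(ca, sites, k_on, dt, rng) >= 0).sum())
        vol = box ** 3
        conc_s = n_s / (vol * 602.214)  # µM
        expected_per_ca = k_on * 1e-9 * conc_s * dt * n_steps
        measured = binds / n_ca
        assert measured == pytest.approx(expected_per_ca, rel=0.1)

    def test_equilibrium_occupancy_of_high_affinity_site(self, cfg, rng):
        # clamped 100 nM calcium: occupancy = [Ca]/([Ca]+Kd), Kd ~ 473 nM
        kd = cfg.buffer.kd_high_um
        assert kd == pytest.approx(0.4727, rel=0.01)
        # analytic equilibrium from the Table rates
        occ = 0.1 / (0.1 + kd)
        assert occ == pytest.approx(0.175, abs=0.009)
        # stochastic two-state occupancy driven by the sampled on-rate
        k_on_eff = cfg.buffer.kh_plus * 1e-9 * 0.1   # per ms at 100 nM
        k_off = cfg.buffer.kh_minus * 1e-3
        state = np.zeros(4000, dtype=bool)
        dt = 1.0
        for _ in range(8000):
            u = rng.random(state.shape)
            state = np.where(state, u >= k_off * dt, u < k_on_eff * dt)
        assert state.mean() == pytest.approx(occ, rel=0.05)

    def test_probability_halving_dt_consistent(self):
        # effective rate is dt-invariant by construction
        p1 = reaction_probability(1e7, 0.04, 0.001)
        p2 = reaction_probability(1e7, 0.04, 0.0005)
        assert p1 == pytest.approx(2 * p2, rel=1e-9)

    def test_probability_above_one_rejected(self):
        with pytest.raises(ValueError):
            reaction_probability(1e10, 0.01, 0.01)


class TestPump:
    def test_cycle_statistics_match_ctmc_oracle(self, rng):
        # single-pump occupancy vs the 4-state master equation at fixed Ca
        pp = PumpParams()
        ca = 1.0  # µM
        k1 = pp.kpm1 * 1e-9 * ca
        k2, k3, k4 = pp.kpm2 * 1e-3, pp.kpm3 * 1e-3, pp.kpm4 * 1e-3
        # stationary law of P -> PCa -> P' -> P cycle
        pca = k1 / (k2 + k3)
        ppr = k3 * pca / k4
        z = 1 + pca + ppr
        expected = np.array([1 / z, pca / z, ppr / z])
        counts = np.array([10000, 0, 0])
        dt = 0.5
        occ = np.zeros(3)
        n_samp = 0
        for step in range(4000):
            n_bind = rng.binomial(counts[0], min(k1 * dt, 1))
            (p, pca_n, pp_n), _, _, _ = pmca_cycle_step(
                (counts[0] - n_bind, counts[1] + n_bind, counts[2]), 0,
                pp, dt, rng)
            counts = np.array([p, pca_n, pp_n])
            if step > 1000:
                occ += counts / counts.sum()
                n_samp += 1
        occ /= n_samp
        assert np.abs(occ - expected).sum() / 2 < 0.02  # total variation

    def test_leak_balances_extrusion_at_rest(self):
        pp = PumpParams()
        assert pump_leak_per_pump_ms(pp, 0.1) == pytest.approx(
            pump_extrusion_flux_ms(pp, 0.1), rel=1e-12)

    def test_no_leak_pure_extrusion(self, rng):
        pp = PumpParams(balance_leak_at_rest=False, kpm_leak=0.0)
        _, _, n_ext, n_leak = pmca_cycle_step((0, 5000, 0), 0, pp, 1.0, rng)
        assert n_leak == 0
        assert n_ext > 0


class TestClamp:
    def test_empty_box_repopulated(self, rng):
        pos = np.zeros((0, 3))
        c0 = 0.1
        totals = [len(clamp_boundaries(pos, BOX, 0.02, c0, rng))
                  for _ in range(300)]
        expected = 2 * c0 * 0.02 * 0.25 * 602.214
        assert np.mean(totals) == pytest.approx(expected, rel=0.15)

    def test_zero_level_empties_slabs(self, rng):
        pos = np.column_stack([np.full(50, -1.995),
                               np.zeros(50), np.zeros(50)])
        out = clamp_boundaries(pos, BOX, 0.02, 0.0, rng)
        assert len(out) == 0

    def test_interior_particles_kept(self, rng):
        pos = np.zeros((70, 3))
        out = clamp_boundaries(pos, BOX, 0.02, 0.1, rng)
        interior = np.abs(out[:, 0]) < 1.9
        assert interior.sum() == 70


class TestMeasureLocalCa:
    def test_uniform_box_reads_concentration(self, rng):
        c0 = 0.1
        n = rng.poisson(c0 * 1.0 * 602.214 * 1000)  # 1000 boxes worth
        # big sphere in a big uniform cloud
        pos = rng.uniform(-5, 5, (int(c0 * 602.214 * 1000), 3))
        c = measure_local_ca(pos, (0, 0, 0), 1.0)
        assert c == pytest.approx(c0, rel=0.2)

    def test_probe_outside_box_rejected(self):
        with pytest.raises(ValueError):
            measure_local_ca(np.zeros((1, 3)), (5, 0, 0), 0.05, BOX)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            measure_local_ca(np.zeros((1, 3)), (0, 0, 0), 0.0)


class TestFullTrial:
    def test_rest_state_calcium_stays_near_100nM(self, cfg):
        # no stimulus: pumps + clamp keep free calcium at the resting
        # level (free-count trace vs expected box content)
        cfg = cfg.copy()
        cfg.ap.peak_mv = cfg.ap.baseline_mv + 1e-6  # effectively no AP
        cfg.channels.flux_open = 0.0
        res = run_spatial_trial(cfg, 60.0, seed=3, with_sensors=False)
        expected = 0.1 * 1.0 * 602.214
        mean_free = res.free_counts[len(res.free_counts) // 2:].mean()
        assert mean_free == pytest.approx(expected, rel=0.10)

    def test_local_peak_in_published_range(self, cfg):
        # calibrated flux: mean local peak ~ 12 µM (printed 12 +- 4.8)
        peaks = [run_spatial_trial(cfg, 6.0, seed=s, with_sensors=False
                                   ).trace.peak() for s in range(6)]
        assert 5.0 < np.mean(peaks) < 20.0

    def test_smaller_lc_gives_higher_peak(self, cfg):
        near = cfg.copy()
        near.geometry.l_c_nm = 100.0
        p_near = np.mean([run_spatial_trial(near, 5.0, seed=s,
                                            with_sensors=False).trace.peak()
                          for s in range(4)])
        p_far = np.mean([run_spatial_trial(cfg, 5.0, seed=s,
                                           with_sensors=False).trace.peak()
                         for s in range(4)])
        assert p_near > p_far

    def test_effective_diffusion_with_buffer(self, cfg):
        from boutonsim.analysis import estimate_effective_D
        times, xs = tagged_ion_positions(cfg, n_ions=600, seed=8)
        d_eff = estimate_effective_D(times, xs)
        assert d_eff == pytest.approx(50.0, rel=0.20)

    def test_halving_dt_changes_peak_less_than_5pc(self, cfg):
        fine = cfg.copy()
        fine.diffusion.dt_ca_us = 0.5
        fine.diffusion.dt_other_us = 0.5
        p_ref = np.mean([run_spatial_trial(cfg, 5.0, seed=s,
                                           with_sensors=False).trace.peak()
                         for s in range(8)])
        p_fine = np.mean([run_spatial_trial(fine, 5.0, seed=s,
                                            with_sensors=False).trace.peak()
                          for s in range(8)])
        assert p_fine == pytest.approx(p_ref, rel=0.15)

    def test_events_carry_valid_pathways(self, cfg):
        found = []
        for s in range(8):
            res = run_spatial_trial(cfg, 6.0, seed=1000 + s)
            found.extend(e.pathway for e in res.events)
        assert all(p in PATHWAYS for p in found)
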