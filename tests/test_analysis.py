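"""Analysis layer: histograms, decay fits, binomial analytics,
facilitation, dose-response and diffusion estimation - validated on
synthetic fixtures with known ground truth."""
import itertools

import numpy as np
import pytest

from boutonsim.analysis import (binomial_independence, compute_pr,
                                release_time_course,
                                dodge_rahamimoff_fit, estimate_effective_D,
                                facilitation, fit_release_decay,
                                pathway_split, release_histogram,
                                vesicle_count_distribution)
from boutonsim.fixtures import generate_fixture


class TestHistogram:
    def test_empty_events_all_zero(self):
        h = release_histogram([], 10.0, 100)
        assert h.counts.sum() == 0
        assert np.all(h.rate_per_ms == 0)

    def test_rate_and_std_arithmetic(self):
        # 100 events in one bin, N = 1e4, t_b = 10 -> rate 1e-3, std 1e-4
        times = np.full(100, 5.0)
        h = release_histogram(times, 10.0, 10000)
        assert h.rate_per_ms[0] == pytest.approx(1e-3)
        assert h.rate_std[0] == pytest.approx(1e-4)

    def test_rebinning_conserves_counts(self, rng):
        times = rng.uniform(0, 400, 5000)
        h1 = release_histogram(times, 1.0, 1000)
        h10 = h1.rebin(10)
        assert h10.counts.sum() == h1.counts.sum()
        assert h10.bin_width_ms == 10.0

    def test_strict_window_rejects_outside_events(self):
        with pytest.raises(ValueError):
            release_histogram([450.0], 10.0, 10, (0, 400), strict=True)


class TestDecayFit:
    def test_parameter_recovery_on_synthetic_two_exp(self):
        # events drawn from a0 e^{-t/6} + a1 e^{-t/160} + a2 at the
        # published amplitudes and trial count
        fx = generate_fixture("multi_exp_events", dict(
            n_trials=10000, components=[(0.025, 6.0), (0.00023, 160.0)],
            constant=0.00012, latency_ms=3.0), seed=4)
        ens = fx.data
        h = release_time_course(ens, 10.0, start_ms=3.0)
        fit = fit_release_decay(h, "2exp", fix_constant=0.00012)
        assert fit.tau_fast == pytest.approx(6.0, rel=0.15)
        assert fit.tau_slow == pytest.approx(160.0, rel=0.15)

    def test_three_exp_recovery(self):
        fx = generate_fixture("multi_exp_events", dict(
            n_trials=10000,
            components=[(0.01, 0.65), (0.0045, 7.0), (0.00023, 160.0)],
            constant=0.00012, latency_ms=3.0), seed=5)
        ens = fx.data
        h = release_time_course(ens, 1.0, start_ms=3.0)
        fit = fit_release_decay(h, "3exp", fix_constant=0.00012)
        assert fit.tau_superfast == pytest.approx(0.65, rel=0.25)
        assert fit.taus[1] == pytest.approx(7.0, rel=0.2)

    def test_pure_single_exponential_degenerates_gracefully(self):
        fx = generate_fixture("multi_exp_events", dict(
            n_trials=20000, components=[(0.02, 8.0)], constant=0.0),
            seed=6)
        ens = fx.data
        h = release_histogram(ens.times(), 10.0, ens.n_trials)
        fit = fit_release_decay(h, "2exp")
        # one component carries essentially all the integrated release
        assert max(fit.fractions[:2]) > 0.9

    def test_too_few_bins_rejected(self):
        h = release_histogram([5.0], 10.0, 10, (0.0, 50.0))
        with pytest.raises(ValueError):
            fit_release_decay(h, "2exp")


class TestComputePr:
    def test_no_events_zero(self):
        fx = generate_fixture("constant_ca_events",
                              dict(rate_per_ms=0.0, n_trials=50), seed=0)
        assert compute_pr(fx.data) == 0.0

    def test_every_trial_releases_gives_one(self):
        fx = generate_fixture("constant_ca_events",
                              dict(rate_per_ms=0.5, n_trials=50), seed=1)
        assert compute_pr(fx.data) == 1.0


class TestVesicleCounts:
    def test_distribution_sums_to_one(self):
        fx = generate_fixture("constant_ca_events",
                              dict(rate_per_ms=5e-3, n_trials=500), seed=2)
        pk, cum = vesicle_count_distribution(fx.data)
        assert pk.sum() == pytest.approx(1.0)
        assert cum[-1] == pytest.approx(1.0)


class TestBinomialIndependence:
    def test_published_example(self):
        p, p2 = binomial_independence(0.2, 7)
        assert p == pytest.approx(0.031, abs=5e-4)
        assert p2 == pytest.approx(0.02, abs=5e-3)

    def test_zero_is_zero(self):
        assert binomial_independence(0.0, 7) == (0.0, 0.0)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            binomial_independence(1.0, 7)

    @pytest.mark.parametrize("pr", [0.05, 0.2, 0.6, 0.9])
    def test_matches_exhaustive_enumeration(self, pr):
        # brute-force enumeration over the 2^7 vesicle outcomes
        p, p_ge2 = binomial_independence(pr, 7)
        p_any = 0.0
        p_multi = 0.0
        for outcome in itertools.product([0, 1], repeat=7):
            w = np.prod([p if o else 1 - p for o in outcome])
            k = sum(outcome)
            if k >= 1:
                p_any += w
            if k >= 2:
                p_multi += w
        assert p_any == pytest.approx(pr, rel=1e-9)
        assert p_ge2 == pytest.approx(p_multi, rel=1e-9)


class TestFacilitation:
    def _ens_with_window_totals(self, totals):
        from boutonsim.protocols import EnsembleResult, events_to_frame
        from boutonsim.release import ReleaseEvent
        ev = []
        for k, n in enumerate(totals):
            for i in range(n):
                ev.append(ReleaseEvent(0, k * 100.0 + 50.0, 0, "synchronous"))
        return EnsembleResult(events_to_frame(ev), n_trials=1,
                              duration_ms=100.0 * len(totals))

    def test_identical_totals_zero_percent(self):
        ens = self._ens_with_window_totals([40, 40, 40, 40])
        _, summary = facilitation(ens, 4)
        assert summary == 0.0

    def test_scale_invariance(self):
        e1 = self._ens_with_window_totals([20, 30, 25, 28])
        e2 = self._ens_with_window_totals([40, 60, 50, 56])
        assert facilitation(e1, 4)[1] == pytest.approx(facilitation(e2, 4)[1])

    def test_needs_two_stimuli(self):
        with pytest.raises(ValueError):
            facilitation(self._ens_with_window_totals([5]), 1)


class TestDodgeRahamimoff:
    def test_exponent_recovery(self, rng):
        c = np.array([0.25, 0.5, 1.0, 1.5, 2.0])
        k, n, rmax = 1.2, 4.0, 3.0
        r = rmax * (c / (c + k)) ** n
        r_noisy = r * (1 + rng.normal(0, 0.01, len(c)))
        fit = dodge_rahamimoff_fit(c, r_noisy)
        assert fit.exponent == pytest.approx(4.0, rel=0.1)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            dodge_rahamimoff_fit([1.0], [0.2])

    def test_non_monotone_warns(self):
        with pytest.warns(UserWarning):
            dodge_rahamimoff_fit([0.25, 0.5, 1.0, 2.0], [0.5, 0.2, 0.9, 1.0])


class TestEffectiveD:
    def test_immobile_species_gives_zero(self):
        t = np.linspace(0, 3.0, 20)
        xs = np.zeros((20, 200))
        assert estimate_effective_D(t, xs) == pytest.approx(0.0, abs=1e-9)

    def test_pure_brownian_recovery(self, rng):
        # synthetic Brownian x paths at D = 220 µm^2/s
        d = 0.22  # µm^2/ms
        t = np.arange(0, 61) * 0.05
        steps = rng.normal(0, np.sqrt(2 * d * 0.05), (60, 2000))
        xs = np.vstack([np.zeros(2000), np.cumsum(steps, axis=0)])
        assert estimate_effective_D(t, xs) == pytest.approx(220.0, rel=0.05)

    def test_needs_enough_ions(self):
        with pytest.raises(ValueError):
            estimate_effective_D(np.linspace(0, 1, 5), np.zeros((5, 10)))


class TestPathwaySplit:
    def test_all_synchronous_input(self):
        fx = generate_fixture("multi_exp_events",
                              dict(n_trials=100, components=[(0.01, 5.0)],
                                   constant=0.0), seed=3)
        out = pathway_split(fx.data)
        assert out["totals"]["asynchronous"] == 0
        assert out["asynchronous"].counts.sum() == 0
        assert out["totals"]["synchronous"] == len(fx.data.events)
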