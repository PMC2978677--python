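"""Derived statistics: release histograms, multi-exponential decay fits,
release probabilities, vesicle-count distributions, facilitation,
calcium cooperativity (Dodge-Rahamimoff) and effective diffusion.

Release-rate histograms follow the sqrt(r) convention: the standard
deviation of the count in a temporal bin with r events is sqrt(r), so
the rate per ms is r/(N t_b) with standard error sqrt(r)/(N t_b) for N
trials and bin width t_b.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class ReleaseHistogram:
    """Binned release rate per ms, averaged over an ensemble."""
    edges_ms: np.ndarray
    counts: np.ndarray
    n_trials: int
    bin_width_ms: float

    @property
    def centers_ms(self) -> np.ndarray:
        return 0.5 * (self.edges_ms[:-1] + self.edges_ms[1:])

    @property
    def rate_per_ms(self) -> np.ndarray:
        return self.counts / (self.n_trials * self.bin_width_ms)

    @property
    def rate_std(self) -> np.ndarray:
        return np.sqrt(self.counts) / (self.n_trials * self.bin_width_ms)

    def rebin(self, factor: int) -> "ReleaseHistogram":
        n = (len(self.counts) // factor) * factor
        counts = self.counts[:n].reshape(-1, factor).sum(axis=1)
        edges = self.edges_ms[: n + 1 : factor]
        return ReleaseHistogram(edges, counts, self.n_trials,
                                self.bin_width_ms * factor)


@dataclass
class ExpFitResult:
    """Multi-exponential decomposition of a release transient."""
    model: str                      # '2exp' or '3exp'
    amplitudes: np.ndarray          # per-ms rates, constant term last
    taus: np.ndarray                # ms, fastest first
    fractions: np.ndarray           # integrated share of each component
    fit_start_ms: float
    residual_norm: float

    @property
    def tau_fast(self) -> float:
        return float(self.taus[-2])

    @property
    def tau_slow(self) -> float:
        return float(self.taus[-1])

    @property
    def tau_superfast(self) -> float:
        if self.model != "3exp":
            raise AttributeError("superfast component requires the 3exp model")
        return float(self.taus[0])


def release_histogram(times_ms, bin_width_ms: float, n_trials: int,
                      window_ms: tuple = (0.0, 400.0),
                      strict: bool = False) -> ReleaseHistogram:
    """Exact integer binning of release times over the window."""
    if bin_width_ms <= 0:
        raise ValueError("bin width must be positive")
    times = np.asarray(times_ms, dtype=float)
    if strict and len(times) and (times.min() < window_ms[0] or times.max() > window_ms[1]):
        raise ValueError("events outside the histogram window")
    nbins = int(round((window_ms[1] - window_ms[0]) / bin_width_ms))
    edges = window_ms[0] + np.arange(nbins + 1) * bin_width_ms
    counts, _ = np.histogram(times, bins=edges)
    return ReleaseHistogram(edges, counts, n_trials, bin_width_ms)


def release_time_course(ensemble, bin_width_ms: float,
                        start_ms: float = 3.0) -> ReleaseHistogram:
    """Ensemble release histogram starting at the release latency
    (the published transients start 3 ms after the AP onset)."""
    nbins = int((ensemble.duration_ms - start_ms) // bin_width_ms)
    window = (start_ms, start_ms + nbins * bin_width_ms)
    return release_histogram(ensemble.times(), bin_width_ms,
                             ensemble.n_trials, window)


def fit_release_decay(hist: ReleaseHistogram, model: str = "2exp",
                      fit_start_ms: float = 3.0,
                      tau_guesses=None,
                      fix_constant: float | None = None) -> ExpFitResult:
    """Weighted nonlinear least squares of the binned release rate.

    2exp: a0 exp(-t/tau_fast) + a1 exp(-t/tau_slow) + a2
    3exp: b0 exp(-t/tau_superfast) + b1 exp(-t/tau_fast)
          + b2 exp(-t/tau_slow) + b3

    Per-bin weights follow the sqrt(r) counting error (bins with no
    counts get unit count).  Time constants are fit on a log scale to
    keep them positive and ordered by their initial guesses.  The model
    is averaged exactly over each bin so coarse binning does not distort
    fast components; amplitudes are referenced to t = fit_start_ms.

    ``fix_constant`` pins the constant term to a known baseline (the
    zone's spontaneous release rate); the slow component and a free
    constant are otherwise weakly identified on a 400 ms window.
    """
    keep = hist.edges_ms[:-1] >= fit_start_ms - 1e-9
    if keep.sum() < 6:
        raise ValueError("histogram too short beyond fit_start")
    e0 = hist.edges_ms[:-1][keep]
    e1 = hist.edges_ms[1:][keep]
    y = hist.rate_per_ms[keep]
    sigma = np.sqrt(np.maximum(hist.counts[keep], 1.0)) / (
        hist.n_trials * hist.bin_width_ms)
    n_exp = {"2exp": 2, "3exp": 3}.get(model)
    if n_exp is None:
        raise ValueError("model must be '2exp' or '3exp'")
    if tau_guesses is None:
        tau_guesses = (6.0, 160.0) if n_exp == 2 else (0.7, 7.0, 160.0)
    peak = max(y.max(), 1e-12)
    base = max(np.median(y[-max(len(y) // 5, 2):]), 1e-12)
    width = e1 - e0
    free_const = fix_constant is None
    t_rel = e0 - fit_start_ms

    # segment-based amplitude seeds: read the curve near each component's
    # own time scale (minus the slower contributions)
    def _level(t_target):
        i = int(np.argmin(np.abs(t_rel - t_target)))
        return max(float(y[max(0, i - 1): i + 2].mean()), 1e-12)

    amp0 = []
    for tg in sorted(tau_guesses, reverse=True):
        level = _level(tg / 2.0) * math.exp(0.5)
        amp0.append(max(level - sum(amp0) * 0.5 - base * free_const, 1e-12))
    amp0 = amp0[::-1]
    amp0[0] = max(peak - sum(amp0[1:]) - (base if free_const else fix_constant),
                  1e-12)

    def f(_x, *p):
        # exact bin average of each exponential component, so coarse
        # binning does not distort fast components
        const = p[n_exp] if free_const else fix_constant
        yy = np.full_like(e0, const, dtype=float)
        for a, lt in zip(p[:n_exp], p[n_exp + (1 if free_const else 0):]):
            tau = math.exp(lt)
            yy = yy + a * tau * (np.exp(-t_rel / tau)
                                 - np.exp(-(e1 - fit_start_ms) / tau)) / width
        return yy

    nc = 1 if free_const else 0
    lo = [0.0] * (n_exp + nc) + [math.log(tg / 8.0) for tg in tau_guesses]
    hi = [np.inf] * (n_exp + nc) + [math.log(tg * 8.0) for tg in tau_guesses]
    counts = hist.counts[keep]
    scale_n = hist.n_trials * hist.bin_width_ms

    def nll(p):
        # Poisson likelihood of the bin counts: unbiased at low counts,
        # unlike weighted least squares
        mu = np.clip(f(e0, *p) * scale_n, 1e-12, None)
        return float(np.sum(mu - counts * np.log(mu)))

    from scipy.optimize import minimize
    best = None
    for scale in (1.0, 0.3, 3.0):
        p0 = [a * scale for a in amp0] + ([base] if free_const else []) \
            + [math.log(tg) for tg in tau_guesses]
        res = minimize(nll, p0, method="L-BFGS-B",
                       bounds=list(zip(lo, hi)),
                       options=dict(maxiter=2000))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(
            f"{model} fit failed to converge on {len(e0)} bins "
            f"(start {fit_start_ms} ms)")
    popt = best.x
    amps = popt[:n_exp]
    const = popt[n_exp] if free_const else fix_constant
    taus = np.exp(popt[n_exp + nc:])
    order = np.argsort(taus)
    taus = taus[order]
    amps = amps[order]
    # integrated share of each component over the fit window
    total_t = float(e1[-1] - e0[0])
    integrals = [a * tau * (1.0 - math.exp(-total_t / tau))
                 for a, tau in zip(amps, taus)]
    integrals.append(const * total_t)
    integrals = np.array(integrals)
    fractions = integrals / max(integrals.sum(), 1e-300)
    resid = float(np.sqrt(np.mean((f(e0, *popt) - y) ** 2)))
    return ExpFitResult(model=model, amplitudes=np.append(amps, const),
                        taus=taus, fractions=fractions,
                        fit_start_ms=fit_start_ms, residual_norm=resid)


def compute_pr(ensemble, window_ms: tuple | None = None) -> float:
    """Overall release probability: fraction of trials with >= 1 event."""
    ev = ensemble.events
    if window_ms is not None:
        ev = ev[(ev["time_ms"] >= window_ms[0]) & (ev["time_ms"] < window_ms[1])]
    if ensemble.n_trials < 1:
        raise ValueError("need at least one trial")
    return ev["trial"].nunique() / ensemble.n_trials


def vesicle_count_distribution(ensemble, k_max: int | None = None) -> tuple:
    """P(k) and cumulative distribution of per-trial release counts."""
    counts = ensemble.per_trial_counts
    kmax = int(counts.max()) if k_max is None else k_max
    pk = np.bincount(counts, minlength=kmax + 1)[: kmax + 1] / ensemble.n_trials
    return pk, np.cumsum(pk)


def binomial_independence(pr_zone: float, n_vesicles: int = 7) -> tuple:
    """Closed-form per-vesicle release probability and multi-release
    probability for independent vesicles.

    p = 1 - (1 - pr_zone)^(1/n);  P(>=2) = 1 - (1-p)^n - n p (1-p)^(n-1).
    """
    if not (0.0 <= pr_zone < 1.0):
        raise ValueError("zone release probability must lie in [0, 1)")
    p = 1.0 - (1.0 - pr_zone) ** (1.0 / n_vesicles)
    p_ge2 = 1.0 - (1.0 - p) ** n_vesicles \
        - n_vesicles * p * (1.0 - p) ** (n_vesicles - 1)
    return p, p_ge2


def facilitation(ensemble, n_stimuli: int, window_ms: float = 100.0) -> tuple:
    """Percent facilitation of per-stimulus release totals.

    Counts releases in consecutive windows of ``window_ms`` (one per
    stimulus); facilitation_k = 100 (R_k / R_1 - 1).  Returns
    (per-stimulus percentages for k >= 2, summary = max over k).
    """
    if n_stimuli < 2:
        raise ValueError("facilitation needs at least two stimuli")
    t = ensemble.times()
    totals = np.array([
        ((t >= k * window_ms) & (t < (k + 1) * window_ms)).sum()
        for k in range(n_stimuli)], dtype=float)
    if totals[0] == 0:
        raise ValueError("no release under the first stimulus")
    perc = 100.0 * (totals[1:] / totals[0] - 1.0)
    return perc, float(perc.max())


@dataclass
class DoseResponseFit:
    levels: np.ndarray            # relative extracellular calcium
    responses: np.ndarray         # mean vesicles released in the window
    exponent: float               # apparent cooperativity n
    k_half: float
    r_max: float
    monotone: bool = True


def dodge_rahamimoff_fit(levels, responses,
                         n_trials=None) -> DoseResponseFit:
    """Fit R = R_max (c / (c + K))^n with n and K free.

    The exponent measures the apparent calcium cooperativity of release.
    With ``n_trials`` given (scalar or per-level array), points are
    weighted by their Poisson counting error; responses span orders of
    magnitude, so unweighted least squares would let the saturated top
    levels swamp the low-dose points that carry the cooperativity
    information.
    """
    c = np.asarray(levels, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(c) < 4:
        raise ValueError("need at least 4 dose levels")
    order = np.argsort(c)
    monotone = bool(np.all(np.diff(r[order]) >= -0.05 * max(r.max(), 1e-12)))
    if not monotone:
        warnings.warn("dose-response data are not monotone", stacklevel=2)
    if n_trials is not None:
        nt = np.broadcast_to(np.asarray(n_trials, dtype=float), r.shape)
        sigma = np.sqrt(np.maximum(r * nt, 1.0)) / nt
    else:
        sigma = np.maximum(r, 1e-3 * r.max())  # ~ constant relative error

    def f(cc, log_rmax, log_k, n):
        k = np.exp(log_k)
        return np.exp(log_rmax) * (cc / (cc + k)) ** n

    p0 = [math.log(max(r.max() * 4, 1e-6)), math.log(np.median(c)), 4.0]
    popt, _ = curve_fit(f, c, r, p0=p0, sigma=sigma, maxfev=40000,
                        bounds=([-30, -8, 0.3], [30, 8, 12.0]))
    return DoseResponseFit(levels=c, responses=r, exponent=float(popt[2]),
                           k_half=float(np.exp(popt[1])),
                           r_max=float(np.exp(popt[0])), monotone=monotone)


def estimate_effective_D(times_ms, xs, min_ions: int = 100) -> float:
    """Effective diffusion constant (µm^2/s) from tagged-ion spread.

    Fits the mean-squared displacement along the unconfined x axis,
    MSD_x(t) = 2 D t, through the origin with secant weighting (each
    sample time contributes its displacement-variance estimate of D),
    equivalent to fitting the diffusion-equation Gaussian to the spread.
    """
    xs = np.asarray(xs)
    if xs.shape[1] < min_ions:
        raise ValueError(f"need at least {min_ions} tagged ions")
    disp = xs - xs[0]
    msd = (disp ** 2).mean(axis=1)
    t = np.asarray(times_ms, dtype=float)
    # quasi-linear regime: the second half of the observation window
    # (early times are dominated by the pre-capture free phase)
    mask = t >= 0.5 * t[-1]
    if mask.sum() < 2 or t[-1] <= 0:
        raise ValueError("need more than one sample time")
    d_per_sample = msd[mask] / (2.0 * t[mask])   # µm^2/ms
    return float(np.mean(d_per_sample) * 1e3)    # -> µm^2/s


def pathway_split(ensemble, bin_width_ms: float = 1.0,
                  window_ms: tuple = (0.0, 400.0)) -> dict:
    """Per-pathway histograms and totals."""
    out = {}
    totals = {}
    for pw in ("synchronous", "asynchronous", "spontaneous"):
        times = ensemble.times(pw)
        out[pw] = release_histogram(times, bin_width_ms, ensemble.n_trials,
                                    window_ms)
        totals[pw] = len(times)
    out["totals"] = totals
    sync = totals["synchronous"]
    out["async_sync_ratio"] = (totals["asynchronous"] / sync) if sync else np.inf
    return out
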