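# Methods

`boutonsim` simulates vesicular release at a hippocampal CA3-CA1 en
passant bouton: stochastic opening of a cluster of P/Q-type
voltage-dependent calcium channels (VDCCs), diffusion of the entering
Ca²⁺ through a calbindin-buffered cytosol with PMCA extrusion, and
fusion of docked vesicles governed by a dual calcium-sensor kinetic
scheme with a zone-wide refractory gate.

## Model components

**Geometry.** A 0.5 × 0.5 × 4 µm axon segment (x along the long axis,
origin at the centre). The active zone sits on a membrane face and
holds 7 docked vesicles in a hexagonal array (central vesicle + 6 at
17.5 nm, i.e. 35 nm cluster diameter). The VDCC cluster (disc of 35 nm
radius) is placed a co-localization distance l_c from the active-zone
centre (default 250 nm). Free calcium is clamped at the resting level
(100 nM) in 20 nm slabs at both x-ends. Local calcium is measured in a
sphere (default radius 50 nm) centred 10 nm off the active zone.

**VDCC gating.** A 5-state linear chain C1⇌C2⇌C3⇌C4⇌O with
a_i(v) = a_i0·exp(v/v_i), b_i(v) = b_i0·exp(−v/v_i) (prefactors 4.04,
6.70, 4.39, 17.33 / 2.88, 6.30, 8.16, 1.84 ms⁻¹; voltage constants
49.14, 42.08, 55.31, 26.55 mV). Only O conducts. The single-channel
flux is `flux_open` ions/ms at resting driving force, modulated by the
normalized GHK inward-flux factor w(V) = u/(e^u − 1), u = V/13.27 mV
(unit value at −70 mV). A constant-driving-force mode exists
(`ghk_flux: false`); the voltage-dependent form is used because the
driving force nearly vanishes at the AP peak, so most influx occurs
during repolarization.

**AP template.** The axonal waveform is a biexponential depolarization
from −70 to +34 mV (rise 0.2 ms, fall 0.45 ms, ~0.5 ms half-width —
physiological for small hippocampal boutons) after a 1.7 ms foot
delay. The exact waveform is not constrained by data available to the
package, so the template was calibrated once against three observables
of the reference synapse: the evoked release latency (~3 ms from
stimulus onset, set by the foot delay), the local calcium peak
(12 µM, set by the flux calibration below), and the overall release
probability of the 48-channel / 250 nm configuration (p_r ≈ 0.20, set
by the fall time; a 0.35–0.50 ms scan spans p_r 0.17–0.24). All
template parameters are configuration fields, so a digitized waveform
can be substituted.

**Buffered diffusion.** Free Ca²⁺ diffuses at 220 µm²/s. Calbindin-
D28k (45 µM, D = 28 µm²/s) carries 2 high-affinity sites
(k⁺ = 0.55×10⁷ M⁻¹s⁻¹, k⁻ = 2.6 s⁻¹, K_d ≈ 473 nM) and 2
medium-affinity sites (4.35×10⁷, 35.8 s⁻¹, K_d ≈ 823 nM) per molecule.
PMCA pumps (180 µm⁻², immobile) follow a 4-state cycle
P + Ca →(kpm1) PCa →(kpm3) P′ →(kpm4) P with release-back kpm2 and a
leak influx. Taken literally, the tabulated per-pump leak constant
(12.5 s⁻¹) exceeds per-pump extrusion at 100 nM seventeen-fold and
would push the resting level to several µM; since the pumps' function
in this model is to hold 100 nM, the leak is normalized at start-up so
that leak = extrusion exactly at rest (the printed constant remains
available via `balance_leak_at_rest: false`).

**Release machinery.** Each docked vesicle carries two independent
sensors: five synchronous sites (k_s⁺ = 0.612×10⁸ M⁻¹s⁻¹,
k_s⁻ = 2.32×10³ s⁻¹) fusing at γ = 2×10³ s⁻¹ from full occupancy, and
two asynchronous sites (3.82×10⁶, 13 s⁻¹) fusing at aγ with a = 0.025.
Unbinding from occupancy n proceeds at n·k⁻·b^(n−1) with b = 0.25,
applied to both pathways: this choice pins the stationary zone release
flux at 100 nM to 1.31×10⁻⁴ ms⁻¹ (vs 0.99×10⁻⁴ with b on the
synchronous pathway only) and sets the doubly-bound asynchronous
unbinding to 6.5 s⁻¹ (154 ms), the memory underlying the slow release
component. Spontaneous fusion (δ = 0.417×10⁻³ s⁻¹) fires from the
fully unbound state. Any release closes a zone-wide gate that reopens
after an exponentially distributed delay with mean ε = 6.34 ms
(a deterministic 6 ms dead time is a config option); while closed,
fusion is disabled but binding continues. Releases decrement the
7-vesicle pool unless the zone is depletion-free. Variants: sync-KO
(synchronous pathway removed), SAKO (asynchronous removed), and a
phenomenological single-gate model of the whole zone (its own
published rate set, equal fusion rates, no vesicle limit, sensor state
persists across releases).

## Engines

**Spatial engine** (`boutonsim.spatial`). Free ions are explicit
Brownian particles. Calbindin is represented by its *free-site density
fields* (high/medium) on a 100 nm voxel grid plus explicit *bound-Ca
particles* diffusing at the buffer mobility: binding probability per
ion uses the local free-site density, so local buffer loading near the
cluster, transport of bound calcium, and local re-release are resolved
without pairwise collision detection over ~27k buffer molecules. The
generic pairwise (Doi-scheme) reaction primitive `react_bimolecular`
is exposed and oracle-tested separately. Pumps are surface-uniform and
handled shell-averaged; sensor sites bind collisionally within a 30 nm
radius. Engine steps default to 1 µs for all species (the tabulated
0.1 µs calcium step is a config choice; a convergence test verifies
the single-AP local peak moves < 5% when the step is halved), with
bound-particle moves strided at 10 µs (D_cb is slow). The trial loop
is a fused numba kernel; a single-AP trial of 6–8 ms costs ~2 s.

**Hybrid engine** (`boutonsim.hybrid`). Desk-scale ensembles decompose
the local calcium at each vesicle as

    [Ca](t) = resting + microdomain(t) + residual(t).

The microdomain term is the quasi-steady nanodomain of the open
cluster: the stochastic open-channel count (exact aggregated jump
simulation, per trial) times the driving force, passed through a
two-pole relaxation kernel (0.147 ms / 0.601 ms, weights 0.91/0.09)
measured from the spatial engine's response to a brief forced cluster
opening at a physiological drive level (a full-drive opening saturates
the local buffer and yields an artificially slow kernel), and scaled
by exp(−r/λ)/r with λ = 255 nm measured from the
spatial peak ratio between l_c = 250 and 400 nm. The residual term is
the deterministic bulk excess of the same influx: a 1-D buffered
reaction–diffusion solve along the axon axis (clamped ends, mobile
buffer, pumps), with the source injected *already buffer-captured*
(split between high/medium pools by capture-flux ratio) — the
non-equilibrated free transient is precisely what the microdomain term
represents, and injecting free ions into the PDE double-counts the
peak. The residual is computed once per configuration and shared
across trials; channel gating, the dominant noise source, stays
stochastic per trial. A 400 ms single-AP trial costs ~12 ms, so
10⁴-trial ensembles are routine.

**Calibration chain** (all internal to the model, frozen as config
defaults, recomputable via `boutonsim calibrate` /
`calibrate_hybrid_amplitude`): (1) `flux_open` = 1169 ions/ms from a
secant iteration of spatial trials against the 12 µM mean local peak
of the 48-channel / 250 nm configuration (probe protocol: 50 nm
sphere, 0.2 ms smoothing, mean across-trial maximum); (2) screening
length λ = 255 nm from spatial peaks at two distances; (3) microdomain
kernel from the impulse response; (4) hybrid amplitude 1.786 µM per
weighted open channel so the deterministic-mean template peaks at
12 µM. The calibration anchors are the published peak, latency and
release probability of the reference synapse — never the decay
constants or other derived observables.

## Analysis

Release histograms follow the √r counting convention (rate r/(N·t_b),
s.d. √r/(N·t_b)). Evoked transients are binned from 3 ms (the release
latency) and decomposed into a₀e^(−t/τ_fast) + a₁e^(−t/τ_slow) + a₂
(10 ms bins) or the three-exponential form with τ_superfast (1 ms
bins). Two estimation choices matter and are deliberate:

* **Poisson maximum likelihood on bin counts**, with the model
  integrated exactly over each bin. Weighted least squares with √r
  errors is biased at low counts (synthetic ground truth with
  τ_slow = 160 ms fitted as ~50–70 ms); MLE recovers 159 ± 8 (2-exp)
  and 177 ± 25 (3-exp) at 10⁴-trial counts. Exact bin averaging keeps
  sub-bin components (τ_superfast < bin width) undistorted.
* **The constant term is fixed to the zone's known spontaneous rate**
  (computed deterministically from the sensor CTMC). On a 400 ms
  window a free constant and the slow component are weakly identified;
  the baseline is independently known, so the evoked fit should not
  re-estimate it.

Component fractions integrate each fitted exponential over the window.
Facilitation bins total release into consecutive 100 ms windows (one
per 10 Hz stimulus) and reports the maximal percent increase over the
first window. Calcium cooperativity fits R = R_max·(c/(c+K))^n (n, K,
R_max free) to mean evoked vesicles released in the first 20 ms
(the known spontaneous contribution is subtracted) across relative
influx levels 0.25–2×, with Poisson counting-error weights — responses
span three orders of magnitude, and unweighted least squares would let
the saturated top levels swamp the low-dose points that carry the
cooperativity information. The effective diffusion constant fits
the tagged-ion spread along the unconfined x axis, MSD_x = 2Dt,
averaging the displacement-variance estimates over the second half of
a 3 ms window (the estimate is timescale-dependent: free diffusion
dominates below the ~0.26 ms buffer-capture time, the fully buffered
asymptote ~29 µm²/s takes tens of ms; the window is part of the
measurement definition, chosen to match the duration of an AP-evoked
transient).

## What the synthetic fixtures do and do not show

`boutonsim.fixtures` generates events from known exponential mixtures,
homogeneous Poisson streams, and parametric calcium transients. They
validate the analysis layer (binning, fitting, estimator bias)
independently of the simulator; they do not validate the physics. The
simulator itself is checked against independent oracles: matrix-
exponential master equations (channels, pumps, sensors), a plain-
python Gillespie implementation (first-release times), Brownian MSD
laws, equilibrium occupancies from dissociation constants, and exact
binomial enumeration.

## Problem sizes

Default desk-scale sizes: 2000-trial ensembles (protocols), 6000–10⁴
trials for decay-constant estimation (the τ_slow estimator spread is
~±20 ms at 10⁴ trials), 100 spatial trials for the local-peak
measurement, 1500 tagged ions for diffusion, 5 × 1500 trials for the
dose–response. The published experiments used 10⁴ trials throughout;
all sizes are parameters.

## Known limitations

* The hybrid residual is deterministic (trial-averaged); trial-to-trial
  correlations between bulk residual and channel noise are neglected.
* The spatial engine's mean-field pump handling and voxel-grid buffer
  fields smooth sub-100 nm buffer heterogeneity; the 12 µM anchor
  absorbs this into the flux calibration.
* The distance screening of the hybrid kernel (λ = 255 nm) makes the
  128-channel / 400 nm configuration weaker than the published p_r =
  0.6 attribution; the 72-channel / 250 nm preset is used for p_r ≈ 0.6.
* Published fit constants themselves disagree between figure captions
  and text (6.0/160 vs 7.25/140 ms); this package's estimates land
  within those bands but a single "true" value does not exist.
* No glutamate release/cleft diffusion, no ER/mitochondrial stores, no
  vesicle replenishment, no axonal cable dynamics.
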