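"""Compiled simulation kernels (numba).

Conventions: time in ms, concentrations in µM, lengths in µm.
All kernels draw randomness from numpy's legacy global RNG seeded
per call, so a (kernel, seed) pair is fully reproducible.
"""
from __future__ import annotations

import numpy as np
from numba import njit

IONS_PER_UM3_UM = 602.214  # ions per µm^3 at 1 µM


# ---------------------------------------------------------------------------
# VDCC gating
# ---------------------------------------------------------------------------

@njit(cache=True)
def channel_ensemble_open(a_rates, b_rates, dt, n_channels, seed):
    """Aggregated exact-jump simulation of n iid 5-state channels.

    a_rates, b_rates: (nt, 4) forward/backward rates (1/ms) per sample
    (piecewise constant voltage).  Returns open-channel count per sample
    (state at the start of each sample).
    """
    np.random.seed(seed)
    nt = a_rates.shape[0]
    counts = np.zeros(5, dtype=np.int64)
    counts[0] = n_channels
    nopen = np.zeros(nt, dtype=np.int64)
    rates = np.zeros(8)
    for k in range(nt):
        nopen[k] = counts[4]
        t_loc = 0.0
        while True:
            tot = 0.0
            for i in range(4):
                rates[i] = counts[i] * a_rates[k, i]       # i -> i+1
                rates[4 + i] = counts[i + 1] * b_rates[k, i]  # i+1 -> i
                tot += rates[i] + rates[4 + i]
            if tot <= 0.0:
                break
            t_loc += -np.log(np.random.random()) / tot
            if t_loc >= dt:
                break
            u = np.random.random() * tot
            acc = 0.0
            idx = 0
            for j in range(8):
                acc += rates[j]
                if u < acc:
                    idx = j
                    break
            if idx < 4:
                counts[idx] -= 1
                counts[idx + 1] += 1
            else:
                counts[idx - 4 + 1] -= 1
                counts[idx - 4] += 1
    return nopen


@njit(cache=True)
def channel_single_path(a_rates, b_rates, dt, seed, start_state, max_jumps):
    """Exact jump path of one channel; returns (times, states, n_jumps).

    State codes 0..4 (= C1..C4, O).  Voltage piecewise constant per
    sample of width dt.
    """
    np.random.seed(seed)
    nt = a_rates.shape[0]
    times = np.zeros(max_jumps)
    states = np.zeros(max_jumps, dtype=np.int64)
    nj = 0
    s = start_state
    t_next = 0.0  # pending jump time, exponential clock re-drawn on rate change
    for k in range(nt):
        t0 = k * dt
        t_loc = 0.0
        while True:
            up = a_rates[k, s] if s < 4 else 0.0
            dn = b_rates[k, s - 1] if s > 0 else 0.0
            tot = up + dn
            if tot <= 0.0:
                break
            t_loc += -np.log(np.random.random()) / tot
            if t_loc >= dt:
                break
            if np.random.random() * tot < up:
                s += 1
            else:
                s -= 1
            if nj < max_jumps:
                times[nj] = t0 + t_loc
                states[nj] = s
                nj += 1
    return times[:nj], states[:nj], nj


# ---------------------------------------------------------------------------
# Active-zone dual-sensor CTMC
# ---------------------------------------------------------------------------

@njit(cache=True)
def zone_sim(ca, dt, ksp, ksm, kap, kam, b_s, b_a,
             gamma, agamma, delta, delta_any,
             eps_ms, refractory_mode, dead_ms,
             depletion_free, reset_on_release,
             sync_on, async_on,
             init_ns, init_na, seed, max_events):
    """Exact stochastic path of the active zone.

    ca: (n_ves, nt) local calcium per vesicle (µM), piecewise constant
    per sample of width dt.  refractory_mode: 0 off, 1 exponential
    (mean eps_ms), 2 deterministic dead time.  Returns
    (n_events, times, vesicle_ids, pathway codes) with pathway
    0=synchronous, 1=asynchronous, 2=spontaneous.
    """
    np.random.seed(seed)
    n_ves, nt = ca.shape
    ns = init_ns.copy()
    na = init_na.copy()
    docked = np.ones(n_ves, dtype=np.bool_)
    gate_reopen = -1.0  # gate open when t >= gate_reopen
    ev_t = np.zeros(max_events)
    ev_v = np.zeros(max_events, dtype=np.int64)
    ev_p = np.zeros(max_events, dtype=np.int64)
    n_ev = 0
    rates = np.zeros((n_ves, 5))  # sup, sdown, aup, adown, fuse
    for k in range(nt):
        t0 = k * dt
        t_end = t0 + dt
        t_now = t0
        while t_now < t_end:
            gate_open = t_now >= gate_reopen
            # next deterministic change point (gate reopening)
            t_stop = t_end
            if not gate_open and gate_reopen < t_end:
                t_stop = gate_reopen
            tot = 0.0
            for v in range(n_ves):
                c = ca[v, k]
                r0 = 0.0
                r1 = 0.0
                r2 = 0.0
                r3 = 0.0
                rf = 0.0
                if docked[v]:
                    if sync_on:
                        if ns[v] < 5:
                            r0 = (5 - ns[v]) * ksp * c
                        if ns[v] > 0:
                            r1 = ns[v] * ksm * b_s ** (ns[v] - 1)
                    if async_on:
                        if na[v] < 2:
                            r2 = (2 - na[v]) * kap * c
                        if na[v] > 0:
                            r3 = na[v] * kam * b_a ** (na[v] - 1)
                    if gate_open:
                        if sync_on and ns[v] == 5:
                            rf += gamma
                        if async_on and na[v] == 2:
                            rf += agamma
                        if delta_any or (ns[v] == 0 and na[v] == 0):
                            rf += delta
                rates[v, 0] = r0
                rates[v, 1] = r1
                rates[v, 2] = r2
                rates[v, 3] = r3
                rates[v, 4] = rf
                tot += r0 + r1 + r2 + r3 + rf
            if tot <= 0.0:
                t_now = t_stop
                continue
            t_next = t_now - np.log(np.random.random()) / tot
            if t_next >= t_stop:
                t_now = t_stop
                continue
            t_now = t_next
            u = np.random.random() * tot
            acc = 0.0
            hit_v = -1
            hit_j = -1
            for v in range(n_ves):
                for j in range(5):
                    acc += rates[v, j]
                    if u < acc:
                        hit_v = v
                        hit_j = j
                        break
                if hit_v >= 0:
                    break
            v = hit_v
            if hit_j == 0:
                ns[v] += 1
            elif hit_j == 1:
                ns[v] -= 1
            elif hit_j == 2:
                na[v] += 1
            elif hit_j == 3:
                na[v] -= 1
            else:
                # fusion: attribute pathway proportionally to active routes
                fs = gamma if (sync_on and ns[v] == 5) else 0.0
                fa = agamma if (async_on and na[v] == 2) else 0.0
                fd = delta if (delta_any or (ns[v] == 0 and na[v] == 0)) else 0.0
                uu = np.random.random() * (fs + fa + fd)
                if uu < fs:
                    path = 0
                elif uu < fs + fa:
                    path = 1
                else:
                    path = 2
                if n_ev < max_events:
                    ev_t[n_ev] = t_now
                    ev_v[n_ev] = v
                    ev_p[n_ev] = path
                    n_ev += 1
                if depletion_free:
                    if reset_on_release:
                        ns[v] = 0
                        na[v] = 0
                else:
                    docked[v] = False
                if refractory_mode == 1:
                    gate_reopen = t_now - np.log(np.random.random()) * eps_ms
                elif refractory_mode == 2:
                    gate_reopen = t_now + dead_ms
    return n_ev, ev_t[:n_ev], ev_v[:n_ev], ev_p[:n_ev]


@njit(cache=True)
def sensor_gillespie_first_release(ca_um, params, seed, t_max):
    """First-release time of a single vesicle at constant calcium
    (homogeneous chain, exact Gillespie).  Used as an oracle-style
    fast path; params = (ksp, ksm, kap, kam, b_s, b_a, gamma, agamma,
    delta, delta_any).  Returns release time or -1."""
    np.random.seed(seed)
    ksp, ksm, kap, kam, b_s, b_a, gamma, agamma, delta, delta_any = params
    ns = 0
    na = 0
    t = 0.0
    while t < t_max:
        r_su = (5 - ns) * ksp * ca_um
        r_sd = ns * ksm * b_s ** (ns - 1) if ns > 0 else 0.0
        r_au = (2 - na) * kap * ca_um
        r_ad = na * kam * b_a ** (na - 1) if na > 0 else 0.0
        rf = 0.0
        if ns == 5:
            rf += gamma
        if na == 2:
            rf += agamma
        if delta_any == 1.0 or (ns == 0 and na == 0):
            rf += delta
        tot = r_su + r_sd + r_au + r_ad + rf
        if tot <= 0.0:
            return -1.0
        t += -np.log(np.random.random()) / tot
        u = np.random.random() * tot
        if u < r_su:
            ns += 1
        elif u < r_su + r_sd:
            ns -= 1
        elif u < r_su + r_sd + r_au:
            na += 1
        elif u < r_su + r_sd + r_au + r_ad:
            na -= 1
        else:
            return t
    return -1.0


# ---------------------------------------------------------------------------
# Hybrid-mode helpers
# ---------------------------------------------------------------------------

@njit(cache=True)
def one_pole_filter(x, dt, tau):
    """First-order relaxation toward x(t): dy/dt = (x - y)/tau."""
    y = np.zeros_like(x)
    acc = 0.0
    a = dt / tau
    for k in range(x.shape[0]):
        acc += a * (x[k] - acc)
        y[k] = acc
    return y


@njit(cache=True)
def residual_pde(src_ions_per_ms, dt, nx, dx, area,
                 d_ca, d_cb, c0,
                 khp, khm, kmp, kmm, bh_tot, bm_tot,
                 kpm1, kpm23, kpm3, kpm4, pump_dens, leak_per_pump,
                 src_shape, w_bh, n_record, record_stride):
    """Deterministic 1-D buffered reaction-diffusion of the bulk calcium
    excess along the axon axis; ends clamped at c0.

    The source is injected already buffer-captured (split between the
    high- and medium-affinity pools by w_bh): the non-equilibrated free
    transient near the channel cluster is the microdomain term of the
    hybrid decomposition, not part of the bulk residual.  Returns the
    free calcium at the centre cell on the recording grid."""
    c = np.full(nx, c0)
    bh = np.full(nx, bh_tot * c0 / (c0 + khm / khp))
    bm = np.full(nx, bm_tot * c0 / (c0 + kmm / kmp))
    out = np.zeros(n_record)
    iz = nx // 2
    inv_dx2 = 1.0 / (dx * dx)
    nt = src_ions_per_ms.shape[0]
    for k in range(nt):
        # record at stride (state at start of sample)
        if k % record_stride == 0 and k // record_stride < n_record:
            out[k // record_stride] = c[iz]
        s = src_ions_per_ms[k]
        cn = np.empty(nx)
        bhn = np.empty(nx)
        bmn = np.empty(nx)
        for i in range(nx):
            jh = khp * c[i] * (bh_tot - bh[i]) - khm * bh[i]
            jm = kmp * c[i] * (bm_tot - bm[i]) - kmm * bm[i]
            u = kpm1 * c[i]
            pca = u / kpm23
            pp = kpm3 * pca / kpm4
            pump = pump_dens * (kpm3 * pca / (1.0 + pca + pp) - leak_per_pump) / IONS_PER_UM3_UM
            il = i - 1 if i > 0 else 1
            ir = i + 1 if i < nx - 1 else nx - 2
            lap_c = (c[il] - 2.0 * c[i] + c[ir]) * inv_dx2
            lap_h = (bh[il] - 2.0 * bh[i] + bh[ir]) * inv_dx2
            lap_m = (bm[il] - 2.0 * bm[i] + bm[ir]) * inv_dx2
            cn[i] = c[i] + dt * (d_ca * lap_c - jh - jm - pump)
            bhn[i] = bh[i] + dt * (d_cb * lap_h + jh + s * src_shape[i] * w_bh)
            bmn[i] = bm[i] + dt * (d_cb * lap_m + jm + s * src_shape[i] * (1.0 - w_bh))
        cn[0] = c0
        cn[nx - 1] = c0
        c = cn
        bh = bhn
        bm = bmn
    return out


# ---------------------------------------------------------------------------
# Spatial engine
# ---------------------------------------------------------------------------

@njit(cache=True)
def _reflect(x, lo, hi):
    # single reflection is enough for steps much smaller than the box
    if x < lo:
        x = 2.0 * lo - x
    elif x > hi:
        x = 2.0 * hi - x
    if x < lo:
        x = lo
    elif x > hi:
        x = hi
    return x


@njit(cache=True)
def run_spatial_trial(seed, nt, dt,
                      box, clamp_um,
                      d_ca, d_cb, c0,
                      # buffer
                      khp, khm, kmp, kmm, sh_tot_um, sm_tot_um,
                      # voxel grid for free-site fields
                      nvx, nvy, nvz,
                      # pumps
                      n_pumps, kpm1, kpm2, kpm3, kpm4, leak_ions_per_ms,
                      pump_shell_um,
                      # channels
                      ch_pos, a_rates, b_rates, flux_w,  # (nch,3), (nt,4), (nt,4), (nt,)
                      flux_open,
                      # sensors (0 x 3 array disables)
                      ves_pos, ksp, ksm, kap, kam, b_s, b_a, sensor_radius_um,
                      # fusion / zone gate
                      gamma, agamma, delta, eps_ms, refractory_mode,
                      dead_ms, depletion_free,
                      # probe
                      probe_pos, probe_r,
                      buffer_stride,
                      cap_free):
    """One trial of the particle-based bouton simulation.

    Free Ca ions are explicit particles; calbindin is represented by its
    free-site density fields (high / medium) on a voxel grid plus
    explicit bound-Ca particles that diffuse at the buffer mobility, so
    local buffer loading, transport of bound calcium and local re-release
    are all resolved.  PMCA pumps are surface-uniform and treated in a
    shell-averaged fashion.  Returns (probe_trace_uM, n_open_trace,
    free_count_trace, ves_ns, ves_na, total_injected).
    """
    np.random.seed(seed)
    hx = box[0] / 2.0
    hy = box[1] / 2.0
    hz = box[2] / 2.0
    vol = box[0] * box[1] * box[2]
    # voxel grid
    dvx = box[0] / nvx
    dvy = box[1] / nvy
    dvz = box[2] / nvz
    vox_v = dvx * dvy * dvz
    nvox = nvx * nvy * nvz
    sh = np.empty(nvox)
    sm = np.empty(nvox)
    # equilibrium occupancy at c0
    occ_h = c0 / (c0 + khm / khp)
    occ_m = c0 / (c0 + kmm / kmp)
    sh[:] = sh_tot_um * (1.0 - occ_h) * vox_v * IONS_PER_UM3_UM
    sm[:] = sm_tot_um * (1.0 - occ_m) * vox_v * IONS_PER_UM3_UM

    # free ions
    free = np.zeros((cap_free, 3))
    n_free = np.random.poisson(c0 * vol * IONS_PER_UM3_UM)
    for i in range(n_free):
        free[i, 0] = np.random.uniform(-hx, hx)
        free[i, 1] = np.random.uniform(-hy, hy)
        free[i, 2] = np.random.uniform(-hz, hz)
    # bound ions (positions + site type 0=high 1=medium)
    nb_h = np.random.poisson(sh_tot_um * occ_h * vol * IONS_PER_UM3_UM)
    nb_m = np.random.poisson(sm_tot_um * occ_m * vol * IONS_PER_UM3_UM)
    cap_bound = int((nb_h + nb_m) * 1.5) + cap_free
    bound = np.zeros((cap_bound, 3))
    btype = np.zeros(cap_bound, dtype=np.int8)
    n_bound = nb_h + nb_m
    n_bound_h = nb_h
    for i in range(n_bound):
        bound[i, 0] = np.random.uniform(-hx, hx)
        bound[i, 1] = np.random.uniform(-hy, hy)
        bound[i, 2] = np.random.uniform(-hz, hz)
        btype[i] = 0 if i < nb_h else 1
    # pumps: global state counts
    n_p = n_pumps
    n_pca = 0
    n_pp = 0
    # channels
    nch = ch_pos.shape[0]
    ch_state = np.zeros(nch, dtype=np.int64)
    n_ves = ves_pos.shape[0]
    ves_ns = np.zeros(n_ves, dtype=np.int64)
    ves_na = np.zeros(n_ves, dtype=np.int64)
    ves_docked = np.ones(n_ves, dtype=np.bool_)
    gate_reopen = -1.0
    max_ev = 64
    ev_t = np.zeros(max_ev)
    ev_v = np.zeros(max_ev, dtype=np.int64)
    ev_p = np.zeros(max_ev, dtype=np.int64)
    n_ev = 0

    sig_f = np.sqrt(2.0 * d_ca * dt)
    sig_b = np.sqrt(2.0 * d_cb * dt * buffer_stride)
    probe_vol = 4.0 / 3.0 * np.pi * probe_r ** 3
    shell_vol = 2.0 * (box[0] * box[1] + box[0] * box[2] + box[1] * box[2]) * pump_shell_um
    slab_vol = clamp_um * box[1] * box[2]
    slab_target = c0 * slab_vol * IONS_PER_UM3_UM
    pr2 = probe_r * probe_r
    sr2 = sensor_radius_um * sensor_radius_um
    sens_v = 4.0 / 3.0 * np.pi * sensor_radius_um ** 3
    # per-pair binding rate inside the sensor sphere (1/ms per free site)
    k_pair_s = ksp / (sens_v * IONS_PER_UM3_UM)
    k_pair_a = kap / (sens_v * IONS_PER_UM3_UM)

    trace = np.zeros(nt)
    open_tr = np.zeros(nt, dtype=np.int64)
    free_tr = np.zeros(nt, dtype=np.int64)
    total_in = 0

    lam_b = d_cb * dt / (dvx * dvx)  # site-field diffusion factor (per axis)
    lam_by = d_cb * dt / (dvy * dvy)
    lam_bz = d_cb * dt / (dvz * dvz)

    for k in range(nt):
        # --- channels & influx ---
        n_open = 0
        for c_i in range(nch):
            s = ch_state[c_i]
            up = a_rates[k, s] * dt if s < 4 else 0.0
            dn = b_rates[k, s - 1] * dt if s > 0 else 0.0
            u = np.random.random()
            if u < up:
                ch_state[c_i] = s + 1
            elif u < up + dn:
                ch_state[c_i] = s - 1
            if ch_state[c_i] == 4:
                n_open += 1
                lam = flux_open * flux_w[k] * dt
                n_in = np.random.poisson(lam)
                for _ in range(n_in):
                    if n_free < cap_free:
                        free[n_free, 0] = ch_pos[c_i, 0]
                        free[n_free, 1] = ch_pos[c_i, 1] + 1e-4
                        free[n_free, 2] = ch_pos[c_i, 2]
                        n_free += 1
                        total_in += 1
        open_tr[k] = n_open

        # --- move free ions, walls, clamp, binding, pumps, probe ---
        n_probe = 0
        # pump binding probability (shell-averaged)
        free_pump_conc = n_p / (shell_vol * IONS_PER_UM3_UM)
        p_pump = kpm1 * free_pump_conc * dt
        i = 0
        while i < n_free:
            x = free[i, 0] + sig_f * np.random.normal()
            y = free[i, 1] + sig_f * np.random.normal()
            z = free[i, 2] + sig_f * np.random.normal()
            x = _reflect(x, -hx, hx)
            y = _reflect(y, -hy, hy)
            z = _reflect(z, -hz, hz)
            # clamp slabs: remove (resampled below)
            if x < -hx + clamp_um or x > hx - clamp_um:
                n_free -= 1
                free[i, 0] = free[n_free, 0]
                free[i, 1] = free[n_free, 1]
                free[i, 2] = free[n_free, 2]
                continue
            free[i, 0] = x
            free[i, 1] = y
            free[i, 2] = z
            # voxel
            vx = int((x + hx) / dvx)
            vy = int((y + hy) / dvy)
            vz = int((z + hz) / dvz)
            if vx >= nvx:
                vx = nvx - 1
            if vy >= nvy:
                vy = nvy - 1
            if vz >= nvz:
                vz = nvz - 1
            vid = (vx * nvy + vy) * nvz + vz
            # buffer binding with local free-site densities
            ph = khp * (sh[vid] / (vox_v * IONS_PER_UM3_UM)) * dt
            pm = kmp * (sm[vid] / (vox_v * IONS_PER_UM3_UM)) * dt
            # pump binding only near a wall
            near_wall = (hy - abs(y) < pump_shell_um) or (hz - abs(z) < pump_shell_um) \
                or (hx - abs(x) < pump_shell_um)
            pp_bind = p_pump if near_wall else 0.0
            u = np.random.random()
            if (u < ph + pm) and n_bound < cap_bound:
                bound[n_bound, 0] = x
                bound[n_bound, 1] = y
                bound[n_bound, 2] = z
                if u < ph:
                    btype[n_bound] = 0
                    sh[vid] -= 1.0
                    n_bound_h += 1
                else:
                    btype[n_bound] = 1
                    sm[vid] -= 1.0
                n_bound += 1
                n_free -= 1
                free[i, 0] = free[n_free, 0]
                free[i, 1] = free[n_free, 1]
                free[i, 2] = free[n_free, 2]
                continue
            elif u < ph + pm + pp_bind:
                n_p -= 1
                n_pca += 1
                n_free -= 1
                free[i, 0] = free[n_free, 0]
                free[i, 1] = free[n_free, 1]
                free[i, 2] = free[n_free, 2]
                continue
            # sensor binding
            if n_ves > 0:
                dxa = x - ves_pos[0, 0]
                dya = y - ves_pos[0, 1]
                captured = False
                if dxa * dxa + dya * dya < 0.01:  # within 100 nm of AZ: check all
                    for vv in range(n_ves):
                        ddx = x - ves_pos[vv, 0]
                        ddy = y - ves_pos[vv, 1]
                        ddz = z - ves_pos[vv, 2]
                        if ddx * ddx + ddy * ddy + ddz * ddz < sr2:
                            p_s = k_pair_s * (5 - ves_ns[vv]) * dt
                            p_a = k_pair_a * (2 - ves_na[vv]) * dt
                            uu = np.random.random()
                            if uu < p_s:
                                ves_ns[vv] += 1
                                captured = True
                            elif uu < p_s + p_a:
                                ves_na[vv] += 1
                                captured = True
                            break
                if captured:
                    n_free -= 1
                    free[i, 0] = free[n_free, 0]
                    free[i, 1] = free[n_free, 1]
                    free[i, 2] = free[n_free, 2]
                    continue
            # probe count
            ddx = x - probe_pos[0]
            ddy = y - probe_pos[1]
            ddz = z - probe_pos[2]
            if ddx * ddx + ddy * ddy + ddz * ddz < pr2:
                n_probe += 1
            i += 1
        trace[k] = n_probe / (probe_vol * IONS_PER_UM3_UM)
        free_tr[k] = n_free

        # --- clamp slabs resampled to Poisson(c0 * V_slab) ---
        for side in range(2):
            n_want = np.random.poisson(slab_target)
            for _ in range(n_want):
                if n_free < cap_free:
                    if side == 0:
                        free[n_free, 0] = np.random.uniform(-hx, -hx + clamp_um)
                    else:
                        free[n_free, 0] = np.random.uniform(hx - clamp_um, hx)
                    free[n_free, 1] = np.random.uniform(-hy, hy)
                    free[n_free, 2] = np.random.uniform(-hz, hz)
                    n_free += 1

        # --- bound ions: move (strided); unbinding by aggregated draws ---
        move_bound = (k % buffer_stride == 0)
        if move_bound:
            for i in range(n_bound):
                bx = bound[i, 0] + sig_b * np.random.normal()
                by = bound[i, 1] + sig_b * np.random.normal()
                bz = bound[i, 2] + sig_b * np.random.normal()
                bound[i, 0] = _reflect(bx, -hx, hx)
                bound[i, 1] = _reflect(by, -hy, hy)
                bound[i, 2] = _reflect(bz, -hz, hz)
        for typ in range(2):
            n_t = n_bound_h if typ == 0 else n_bound - n_bound_h
            if n_t <= 0:
                continue
            p_off = (khm if typ == 0 else kmm) * dt
            n_un = np.random.binomial(n_t, p_off)
            for _ in range(n_un):
                # rejection-sample an index of the right type
                i = np.random.randint(0, n_bound)
                tries = 0
                while btype[i] != typ and tries < 64:
                    i = np.random.randint(0, n_bound)
                    tries += 1
                if btype[i] != typ:
                    continue
                vx = int((bound[i, 0] + hx) / dvx)
                vy = int((bound[i, 1] + hy) / dvy)
                vz = int((bound[i, 2] + hz) / dvz)
                if vx >= nvx:
                    vx = nvx - 1
                if vy >= nvy:
                    vy = nvy - 1
                if vz >= nvz:
                    vz = nvz - 1
                vid = (vx * nvy + vy) * nvz + vz
                if typ == 0:
                    sh[vid] += 1.0
                    n_bound_h -= 1
                else:
                    sm[vid] += 1.0
                if n_free < cap_free:
                    free[n_free, 0] = bound[i, 0]
                    free[n_free, 1] = bound[i, 1]
                    free[n_free, 2] = bound[i, 2]
                    n_free += 1
                n_bound -= 1
                bound[i, 0] = bound[n_bound, 0]
                bound[i, 1] = bound[n_bound, 1]
                bound[i, 2] = bound[n_bound, 2]
                btype[i] = btype[n_bound]

        # --- vesicle fusion (first-order per step) + zone gate ---
        t_now = k * dt
        for vv in range(n_ves):
            if not ves_docked[vv]:
                continue
            if t_now < gate_reopen:
                break
            f = 0.0
            if ves_ns[vv] == 5:
                f += gamma
            if ves_na[vv] == 2:
                f += agamma
            if ves_ns[vv] == 0 and ves_na[vv] == 0:
                f += delta
            if f > 0.0 and np.random.random() < f * dt:
                fs = gamma if ves_ns[vv] == 5 else 0.0
                fa = agamma if ves_na[vv] == 2 else 0.0
                uu = np.random.random() * f
                if uu < fs:
                    path = 0
                elif uu < fs + fa:
                    path = 1
                else:
                    path = 2
                if n_ev < max_ev:
                    ev_t[n_ev] = t_now
                    ev_v[n_ev] = vv
                    ev_p[n_ev] = path
                    n_ev += 1
                if depletion_free:
                    ves_ns[vv] = 0
                    ves_na[vv] = 0
                else:
                    ves_docked[vv] = False
                if refractory_mode == 1:
                    gate_reopen = t_now - np.log(np.random.random()) * eps_ms
                elif refractory_mode == 2:
                    gate_reopen = t_now + dead_ms

        # --- sensor unbinding (re-emit ion at the vesicle) ---
        for vv in range(n_ves):
            if ves_ns[vv] > 0:
                r = ves_ns[vv] * ksm * b_s ** (ves_ns[vv] - 1) * dt
                if np.random.random() < r:
                    ves_ns[vv] -= 1
                    if n_free < cap_free:
                        free[n_free, 0] = ves_pos[vv, 0]
                        free[n_free, 1] = ves_pos[vv, 1] + 1e-4
                        free[n_free, 2] = ves_pos[vv, 2]
                        n_free += 1
            if ves_na[vv] > 0:
                r = ves_na[vv] * kam * b_a ** (ves_na[vv] - 1) * dt
                if np.random.random() < r:
                    ves_na[vv] -= 1
                    if n_free < cap_free:
                        free[n_free, 0] = ves_pos[vv, 0]
                        free[n_free, 1] = ves_pos[vv, 1] + 1e-4
                        free[n_free, 2] = ves_pos[vv, 2]
                        n_free += 1

        # --- pump cycle transitions + leak ---
        n_rel = np.random.binomial(n_pca, kpm2 * dt) if n_pca > 0 else 0
        n_ext = np.random.binomial(n_pca - n_rel, kpm3 * dt) if n_pca - n_rel > 0 else 0
        n_rst = np.random.binomial(n_pp, kpm4 * dt) if n_pp > 0 else 0
        n_pca -= n_rel + n_ext
        n_pp += n_ext - n_rst
        n_p += n_rel + n_rst
        n_new = n_rel + np.random.poisson(leak_ions_per_ms * dt)
        for _ in range(n_new):
            if n_free < cap_free:
                # re-entry at a random point on a random wall
                w = np.random.randint(0, 6)
                x = np.random.uniform(-hx, hx)
                y = np.random.uniform(-hy, hy)
                z = np.random.uniform(-hz, hz)
                if w == 0:
                    y = -hy + 1e-4
                elif w == 1:
                    y = hy - 1e-4
                elif w == 2:
                    z = -hz + 1e-4
                elif w == 3:
                    z = hz - 1e-4
                elif w == 4:
                    x = -hx + 1e-4
                else:
                    x = hx - 1e-4
                free[n_free, 0] = x
                free[n_free, 1] = y
                free[n_free, 2] = z
                n_free += 1

        # --- free-site field diffusion (simple explicit stencil) ---
        if move_bound and d_cb > 0.0:
            sh3 = sh.reshape(nvx, nvy, nvz)
            sm3 = sm.reshape(nvx, nvy, nvz)
            for fld in (sh3, sm3):
                tmp = fld.copy()
                for ax_i in range(nvx):
                    il = ax_i - 1 if ax_i > 0 else 1
                    ir = ax_i + 1 if ax_i < nvx - 1 else nvx - 2
                    for ay in range(nvy):
                        jl = ay - 1 if ay > 0 else 1
                        jr = ay + 1 if ay < nvy - 1 else nvy - 2
                        for az in range(nvz):
                            kl = az - 1 if az > 0 else 1
                            kr = az + 1 if az < nvz - 1 else nvz - 2
                            fld[ax_i, ay, az] = tmp[ax_i, ay, az] + buffer_stride * (
                                lam_b * (tmp[il, ay, az] - 2 * tmp[ax_i, ay, az] + tmp[ir, ay, az])
                                + lam_by * (tmp[ax_i, jl, az] - 2 * tmp[ax_i, ay, az] + tmp[ax_i, jr, az])
                                + lam_bz * (tmp[ax_i, ay, kl] - 2 * tmp[ax_i, ay, az] + tmp[ax_i, ay, kr]))
    return (trace, open_tr, free_tr, ves_ns, ves_na, total_in,
            n_ev, ev_t[:n_ev], ev_v[:n_ev], ev_p[:n_ev])


@njit(cache=True)
def run_tagged_diffusion(seed, n_ions, nt, dt, record_stride,
                         box, d_ca, d_cb,
                         k_bind_h, k_bind_m, khm, kmm):
    """Tagged-ion diffusion in an equilibrated buffered medium.

    Ions start at the box centre; binding to the (uniform, equilibrated)
    buffer occurs at the mean-field rates k_bind_* = k_on * [free sites];
    bound ions move at the buffer mobility and unbind at k_off.  Records
    x positions every ``record_stride`` steps.  Returns (n_rec, xs) with
    xs shape (n_rec, n_ions).
    """
    np.random.seed(seed)
    hx = box[0] / 2.0
    hy = box[1] / 2.0
    hz = box[2] / 2.0
    pos = np.zeros((n_ions, 3))
    state = np.zeros(n_ions, dtype=np.int8)  # 0 free, 1 bound-high, 2 bound-med
    n_rec = nt // record_stride + 1
    xs = np.zeros((n_rec, n_ions))
    sig_f = np.sqrt(2.0 * d_ca * dt)
    sig_b = np.sqrt(2.0 * d_cb * dt)
    r = 0
    for k in range(nt):
        if k % record_stride == 0:
            for i in range(n_ions):
                xs[r, i] = pos[i, 0]
            r += 1
        for i in range(n_ions):
            s = state[i]
            sig = sig_f if s == 0 else sig_b
            pos[i, 0] = _reflect(pos[i, 0] + sig * np.random.normal(), -hx, hx)
            pos[i, 1] = _reflect(pos[i, 1] + sig * np.random.normal(), -hy, hy)
            pos[i, 2] = _reflect(pos[i, 2] + sig * np.random.normal(), -hz, hz)
            u = np.random.random()
            if s == 0:
                if u < k_bind_h * dt:
                    state[i] = 1
                elif u < (k_bind_h + k_bind_m) * dt:
                    state[i] = 2
            elif s == 1:
                if u < khm * dt:
                    state[i] = 0
            else:
                if u < kmm * dt:
                    state[i] = 0
    for i in range(n_ions):
        xs[r, i] = pos[i, 0]
    return r + 1, xs
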