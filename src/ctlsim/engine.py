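"""Numba-accelerated whole-run ABM kernel.

The pure-Python reference engine (``ctlsim.abm.step`` and friends) defines the
model semantics readably and is used as an independent oracle in the tests;
this module implements the same update rules as a single compiled loop so that
replicate-heavy experiments (extinction curves, calibrations) are tractable.

Update order within one time step, matching the reference engine:
(1) virion moves / clearance / infection, (2) infected-cell production,
diffuse infection and cytopathic death, (3) CTL updates in a freshly shuffled
order. All randomness comes from numba's global RNG seeded once per run, so a
run is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# site states (must match ctlsim.geometry)
_NONSUS = 0
_SUS = 1
_INF = 2
_DEAD = 3

# run status codes
STATUS_EXTINCT = 0
STATUS_TMAX = 1
STATUS_SATURATED = 2
STATUS_DIED_BEFORE_IC = 3
STATUS_GROWTH_CAP = 4
STATUS_REACHED_TARGET = 5

STATUS_NAMES = {
    STATUS_EXTINCT: "extinct",
    STATUS_TMAX: "t_max",
    STATUS_SATURATED: "saturated",
    STATUS_DIED_BEFORE_IC: "died_before_ic",
    STATUS_GROWTH_CAP: "growth_cap",
    STATUS_REACHED_TARGET: "reached_target",
}


@njit(cache=True, inline="always")
def _mi(delta, extent):
    """Minimum-image scalar displacement."""
    return delta - extent * round(delta / extent)


@njit(cache=True, inline="always")
def _coarse(x):
    """Round to the 1 um contact-detection grid."""
    return math.floor(x + 0.5)


@njit(cache=True)
def _turn_event(k, cx, cy, ch, cseg, inf_list, inf_count, chemo_prob,
                discrete_turns, persistence, n_cols, d, ext_x, ext_y):
    """Re-orient CTL ``k``: directed at the nearest infected cell with
    probability ``chemo_prob`` (falling back to a random turn when no infected
    cell exists), otherwise a +/-45 degree deviation from the current heading.
    Resets the persistent segment."""
    deg45 = math.pi / 4.0
    if (chemo_prob > 0.0 and np.random.random() < chemo_prob
            and inf_count > 0):
        ch[k] = _nearest_inf_bearing(cx[k], cy[k], inf_list, inf_count,
                                     n_cols, d, ext_x, ext_y)
    elif discrete_turns:
        ch[k] += deg45 if np.random.random() < 0.5 else -deg45
    else:
        ch[k] += (np.random.random() * 2.0 - 1.0) * deg45
    cseg[k] = persistence


@njit(cache=True)
def run_abm(seed,
            n_rows, n_cols, d, dt,
            mode_diffuse,
            p_inf, p_cyto, p_prod, p_vclear,
            virion_step, conj_produce,
            state, init_inf_sites,
            n_ctl, ctl_x0, ctl_y0, ctl_h0,
            ctl_step, scan_steps, handling_steps,
            persistence, chemo_prob, contact_radius, discrete_turns,
            i_c, max_growth_steps, max_steps_after,
            sample_every, stop_at_inf):
    """Run one ABM realisation. Returns sampled counts and per-CTL tallies.

    ``state`` is a flat int8 copy of the initial lattice (mutated in place).
    CTL initial positions/headings are pre-drawn by the caller; they become
    active once the infected count reaches ``i_c``.
    """
    np.random.seed(seed)
    n_sites = n_rows * n_cols
    ext_x = n_cols * d
    ext_y = n_rows * d

    # --- site bookkeeping -------------------------------------------------
    sus_list = np.empty(n_sites, dtype=np.int32)
    sus_pos = np.full(n_sites, -1, dtype=np.int32)
    inf_list = np.empty(n_sites, dtype=np.int32)
    inf_pos = np.full(n_sites, -1, dtype=np.int32)
    first_ctl = np.full(n_sites, -1, dtype=np.int32)
    sus_count = 0
    inf_count = 0
    for s in range(n_sites):
        if state[s] == _SUS:
            sus_list[sus_count] = s
            sus_pos[s] = sus_count
            sus_count += 1
    for k in range(init_inf_sites.shape[0]):
        s = init_inf_sites[k]
        # remove from susceptible list, relabel infected
        j = sus_pos[s]
        last_s = sus_list[sus_count - 1]
        sus_list[j] = last_s
        sus_pos[last_s] = j
        sus_pos[s] = -1
        sus_count -= 1
        state[s] = _INF
        inf_list[inf_count] = s
        inf_pos[s] = inf_count
        inf_count += 1
    require_infection = init_inf_sites.shape[0] > 0

    # --- virions ----------------------------------------------------------
    v_cap = 1024
    vx = np.empty(v_cap)
    vy = np.empty(v_cap)
    vh = np.empty(v_cap)
    v_count = 0

    # --- CTL --------------------------------------------------------------
    cx = np.empty(n_ctl)
    cy = np.empty(n_ctl)
    cpx = np.empty(n_ctl)
    cpy = np.empty(n_ctl)
    ch = np.empty(n_ctl)
    cseg = np.empty(n_ctl)
    cstate = np.zeros(n_ctl, dtype=np.int8)  # 0 search, 1 scan, 2 conjugated
    celapsed = np.zeros(n_ctl, dtype=np.int64)
    ceng = np.full(n_ctl, -1, dtype=np.int64)
    clast = np.full(n_ctl, -1, dtype=np.int64)
    kills = np.zeros(n_ctl, dtype=np.int64)
    scans = np.zeros(n_ctl, dtype=np.int64)
    perm = np.arange(n_ctl)

    deaths = np.empty(n_sites, dtype=np.int32)

    # contact-detection neighbourhood half-width (in lattice sites)
    m = int(math.ceil(contact_radius / d)) + 1
    two_pi = 2.0 * math.pi
    deg45 = math.pi / 4.0

    ctl_active = False
    t_intro_step = -1
    if inf_count >= i_c:
        ctl_active = True
        t_intro_step = 0
        for k in range(n_ctl):
            cx[k] = ctl_x0[k]
            cy[k] = ctl_y0[k]
            cpx[k] = cx[k]
            cpy[k] = cy[k]
            ch[k] = ctl_h0[k]
            cseg[k] = persistence

    # --- sampling ---------------------------------------------------------
    max_samples = int((max_growth_steps + max_steps_after) // sample_every) + 4
    samples = np.empty((max_samples, 7))
    n_samp = 0
    dead_count = 0

    # record initial state
    n_conj = 0
    samples[n_samp, 0] = 0.0
    samples[n_samp, 1] = sus_count
    samples[n_samp, 2] = inf_count
    samples[n_samp, 3] = dead_count
    samples[n_samp, 4] = n_ctl if ctl_active else 0
    samples[n_samp, 5] = 0
    samples[n_samp, 6] = v_count
    n_samp += 1

    status = STATUS_TMAX
    step = 0
    last_sampled_step = 0

    while True:
        step += 1

        # ---- (1) virions ------------------------------------------------
        if not mode_diffuse:
            i = 0
            while i < v_count:
                x = vx[i] + virion_step * math.cos(vh[i])
                y = vy[i] + virion_step * math.sin(vh[i])
                x = x % ext_x
                y = y % ext_y
                vx[i] = x
                vy[i] = y
                # nearest susceptible centre within contact radius
                row0 = int(y / d) % n_rows
                col0 = int(x / d) % n_cols
                best_dd = 1e300
                best_s = -1
                best_r = -1
                best_c = -1
                for dr in range(-m, m + 1):
                    for dc in range(-m, m + 1):
                        r = (row0 + dr) % n_rows
                        c = (col0 + dc) % n_cols
                        s = r * n_cols + c
                        if state[s] != _SUS:
                            continue
                        ddx = _mi((c + 0.5) * d - x, ext_x)
                        ddy = _mi((r + 0.5) * d - y, ext_y)
                        dd = ddx * ddx + ddy * ddy
                        if dd > contact_radius * contact_radius:
                            continue
                        if (dd < best_dd
                                or (dd == best_dd
                                    and (r < best_r
                                         or (r == best_r and c < best_c)))):
                            best_dd = dd
                            best_s = s
                            best_r = r
                            best_c = c
                if best_s >= 0:
                    # infect and remove the virion
                    j = sus_pos[best_s]
                    last_s = sus_list[sus_count - 1]
                    sus_list[j] = last_s
                    sus_pos[last_s] = j
                    sus_pos[best_s] = -1
                    sus_count -= 1
                    state[best_s] = _INF
                    inf_list[inf_count] = best_s
                    inf_pos[best_s] = inf_count
                    inf_count += 1
                    v_count -= 1
                    vx[i] = vx[v_count]
                    vy[i] = vy[v_count]
                    vh[i] = vh[v_count]
                    continue
                if np.random.random() < p_vclear:
                    v_count -= 1
                    vx[i] = vx[v_count]
                    vy[i] = vy[v_count]
                    vh[i] = vh[v_count]
                    continue
                i += 1

        # ---- (2) infected cells ------------------------------------------
        c0 = inf_count
        n_deaths = 0
        for ii in range(c0):
            s = inf_list[ii]
            if p_cyto > 0.0 and np.random.random() < p_cyto:
                deaths[n_deaths] = s
                n_deaths += 1
                continue
            if (not conj_produce) and first_ctl[s] >= 0:
                continue
            if mode_diffuse:
                if sus_count > 0 and np.random.random() < p_inf:
                    j = np.random.randint(0, sus_count)
                    t = sus_list[j]
                    last_s = sus_list[sus_count - 1]
                    sus_list[j] = last_s
                    sus_pos[last_s] = j
                    sus_pos[t] = -1
                    sus_count -= 1
                    state[t] = _INF
                    inf_list[inf_count] = t
                    inf_pos[t] = inf_count
                    inf_count += 1
            else:
                if np.random.random() < p_prod:
                    if v_count == v_cap:
                        v_cap *= 2
                        nvx = np.empty(v_cap)
                        nvy = np.empty(v_cap)
                        nvh = np.empty(v_cap)
                        nvx[:v_count] = vx[:v_count]
                        nvy[:v_count] = vy[:v_count]
                        nvh[:v_count] = vh[:v_count]
                        vx = nvx
                        vy = nvy
                        vh = nvh
                    r = s // n_cols
                    c = s % n_cols
                    h = np.random.random() * two_pi
                    # spawn at the parent cell surface along the heading
                    vx[v_count] = ((c + 0.5) * d + 0.5 * d * math.cos(h)) % ext_x
                    vy[v_count] = ((r + 0.5) * d + 0.5 * d * math.sin(h)) % ext_y
                    vh[v_count] = h
                    v_count += 1
        for ii in range(n_deaths):
            s = deaths[ii]
            # cytopathic death: relabel, drop from infected list, release CTL
            j = inf_pos[s]
            last_s = inf_list[inf_count - 1]
            inf_list[j] = last_s
            inf_pos[last_s] = j
            inf_pos[s] = -1
            inf_count -= 1
            state[s] = _DEAD
            dead_count += 1
            first_ctl[s] = -1
            if ctl_active:
                for k in range(n_ctl):
                    if cstate[k] == 2 and ceng[k] == s:
                        cstate[k] = 0
                        ceng[k] = -1
                        celapsed[k] = 0
                        # lysis/turn event for the released CTL
                        _turn_event(k, cx, cy, ch, cseg, inf_list, inf_count,
                     chemo_prob, discrete_turns, persistence,
                     n_cols, d, ext_x, ext_y)

        # ---- (3) CTL ------------------------------------------------------
        if ctl_active and n_ctl > 0:
            for k in range(n_ctl - 1, 0, -1):
                j = np.random.randint(0, k + 1)
                tmp = perm[k]
                perm[k] = perm[j]
                perm[j] = tmp
            for oi in range(n_ctl):
                k = perm[oi]
                st = cstate[k]
                if st == 0:
                    # searching: advance, then entering-contact detection
                    cpx[k] = cx[k]
                    cpy[k] = cy[k]
                    if ctl_step > 0.0:
                        cx[k] = (cx[k] + ctl_step * math.cos(ch[k])) % ext_x
                        cy[k] = (cy[k] + ctl_step * math.sin(ch[k])) % ext_y
                        cseg[k] -= ctl_step
                    # coarse-grain to the 1 um contact grid
                    gx = _coarse(cx[k])
                    gy = _coarse(cy[k])
                    gpx = _coarse(cpx[k])
                    gpy = _coarse(cpy[k])
                    found = -1
                    if gx != gpx or gy != gpy:
                        row0 = int(gy / d) % n_rows
                        col0 = int(gx / d) % n_cols
                        best_dd = 1e300
                        best_inf = False
                        best_r = -1
                        best_c = -1
                        rr = contact_radius * contact_radius
                        for dr in range(-m, m + 1):
                            for dc in range(-m, m + 1):
                                r = (row0 + dr) % n_rows
                                c = (col0 + dc) % n_cols
                                s = r * n_cols + c
                                stt = state[s]
                                if stt == _DEAD:
                                    continue
                                if s == clast[k]:
                                    continue
                                ccx = (c + 0.5) * d
                                ccy = (r + 0.5) * d
                                dxn = _mi(ccx - gx, ext_x)
                                dyn = _mi(ccy - gy, ext_y)
                                ddn = dxn * dxn + dyn * dyn
                                if ddn > rr:
                                    continue
                                dxp = _mi(ccx - gpx, ext_x)
                                dyp = _mi(ccy - gpy, ext_y)
                                if dxp * dxp + dyp * dyp <= rr:
                                    continue  # already in contact: not entering
                                is_inf = stt == _INF
                                better = False
                                if ddn < best_dd:
                                    better = True
                                elif ddn == best_dd:
                                    if is_inf and not best_inf:
                                        better = True
                                    elif is_inf == best_inf and (
                                            r < best_r
                                            or (r == best_r and c < best_c)):
                                        better = True
                                if better:
                                    best_dd = ddn
                                    best_inf = is_inf
                                    best_r = r
                                    best_c = c
                        if best_r >= 0:
                            found = best_r * n_cols + best_c
                    if found >= 0:
                        if state[found] == _INF:
                            cstate[k] = 2
                            celapsed[k] = 0
                            ceng[k] = found
                            if first_ctl[found] < 0:
                                first_ctl[found] = k
                        else:
                            cstate[k] = 1
                            celapsed[k] = 0
                            ceng[k] = found
                            clast[k] = found
                    elif cseg[k] <= 0.0:
                        # spontaneous turn at the end of a persistent segment
                        _turn_event(k, cx, cy, ch, cseg, inf_list, inf_count,
                     chemo_prob, discrete_turns, persistence,
                     n_cols, d, ext_x, ext_y)
                elif st == 1:
                    # scanning an uninfected cell
                    celapsed[k] += 1
                    if celapsed[k] >= scan_steps:
                        scans[k] += 1
                        cstate[k] = 0
                        ceng[k] = -1
                        celapsed[k] = 0
                        _turn_event(k, cx, cy, ch, cseg, inf_list, inf_count,
                     chemo_prob, discrete_turns, persistence,
                     n_cols, d, ext_x, ext_y)
                else:
                    # conjugated to an infected cell
                    s = ceng[k]
                    if state[s] != _INF:
                        # target died under us this step; released next update
                        cstate[k] = 0
                        ceng[k] = -1
                        celapsed[k] = 0
                        _turn_event(k, cx, cy, ch, cseg, inf_list, inf_count,
                     chemo_prob, discrete_turns, persistence,
                     n_cols, d, ext_x, ext_y)
                    else:
                        celapsed[k] += 1
                        if celapsed[k] >= handling_steps and first_ctl[s] == k:
                            # lysis: the first-attached CTL completes handling
                            kills[k] += 1
                            clast[k] = s
                            j = inf_pos[s]
                            last_s = inf_list[inf_count - 1]
                            inf_list[j] = last_s
                            inf_pos[last_s] = j
                            inf_pos[s] = -1
                            inf_count -= 1
                            state[s] = _DEAD
                            dead_count += 1
                            first_ctl[s] = -1
                            # release every CTL attached to this target
                            for k2 in range(n_ctl):
                                if cstate[k2] == 2 and ceng[k2] == s:
                                    cstate[k2] = 0
                                    ceng[k2] = -1
                                    celapsed[k2] = 0
                                    _turn_event(k2, cx, cy, ch, cseg, inf_list, inf_count,
                     chemo_prob, discrete_turns, persistence,
                     n_cols, d, ext_x, ext_y)

        # ---- bookkeeping --------------------------------------------------
        if (not ctl_active) and inf_count >= i_c:
            ctl_active = True
            t_intro_step = step
            for k in range(n_ctl):
                cx[k] = ctl_x0[k]
                cy[k] = ctl_y0[k]
                cpx[k] = cx[k]
                cpy[k] = cy[k]
                ch[k] = ctl_h0[k]
                cseg[k] = persistence
                cstate[k] = 0
                celapsed[k] = 0
                ceng[k] = -1
                clast[k] = -1

        do_sample = (step % sample_every == 0) or (ctl_active
                                                   and t_intro_step == step)
        terminate = False
        if require_infection and inf_count == 0:
            status = (STATUS_EXTINCT if ctl_active
                      else STATUS_DIED_BEFORE_IC)
            terminate = True
        elif stop_at_inf > 0 and inf_count >= stop_at_inf:
            status = STATUS_REACHED_TARGET
            terminate = True
        elif require_infection and sus_count == 0:
            status = STATUS_SATURATED
            terminate = True
        elif not ctl_active:
            if step >= max_growth_steps:
                status = STATUS_GROWTH_CAP
                terminate = True
        else:
            t0 = t_intro_step if t_intro_step >= 0 else 0
            if step - t0 >= max_steps_after:
                status = STATUS_TMAX
                terminate = True

        if do_sample or terminate:
            if step != last_sampled_step and n_samp < max_samples:
                n_conj = 0
                n_free = 0
                if ctl_active:
                    for k in range(n_ctl):
                        if cstate[k] == 2:
                            n_conj += 1
                        else:
                            n_free += 1
                samples[n_samp, 0] = step * dt / 60.0
                samples[n_samp, 1] = sus_count
                samples[n_samp, 2] = inf_count
                samples[n_samp, 3] = dead_count
                samples[n_samp, 4] = n_free
                samples[n_samp, 5] = n_conj
                samples[n_samp, 6] = v_count
                n_samp += 1
                last_sampled_step = step
        if terminate:
            break

    return (samples[:n_samp], status, t_intro_step, kills, scans, inf_count,
            step)


@njit(cache=True)
def _nearest_inf_bearing(x, y, inf_list, inf_count, n_cols, d, ext_x, ext_y):
    """Bearing (rad) from (x, y) to the nearest living infected-site centre,
    minimum-image, ties broken by smallest (row, col)."""
    best_dd = 1e300
    best_dx = 0.0
    best_dy = 0.0
    best_r = -1
    best_c = -1
    for j in range(inf_count):
        s = inf_list[j]
        r = s // n_cols
        c = s % n_cols
        dx = _mi((c + 0.5) * d - x, ext_x)
        dy = _mi((r + 0.5) * d - y, ext_y)
        dd = dx * dx + dy * dy
        if (dd < best_dd
                or (dd == best_dd and (r < best_r
                                       or (r == best_r and c < best_c)))):
            best_dd = dd
            best_dx = dx
            best_dy = dy
            best_r = r
            best_c = c
    return math.atan2(best_dy, best_dx)
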