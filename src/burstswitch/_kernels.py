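"""Numba-compiled simulation cores.

All kernels use the thread-local numpy RNG seeded explicitly at entry, so
a (seed, params, initial) triple maps to one bit-reproducible path.  The
regulation parameters travel as a flat float64 array ``rp``::

    rp = [flag, K, r0, r, n, q0, r1, r2, n1, n2, K1, K2]

with flag 0.0 for toggle regulation and 1.0 for the three-way switch.

Each engine kernel optionally accumulates a time-weighted occupancy
histogram ``W`` on unit protein-number bins (continuous engines are
sampled on a regular time grid instead, which is unbiased for stationary
statistics), and can stop at the first crossing of the switching
boundary N_Y >= N_X.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# channel/burst kind codes for the protein-only SSA
NB_KIND = 0
GB_KIND = 1
CB_KIND = 2


@njit(cache=True)
def _prop(n_self, n_other, rp):
    """Transcription propensity; mirrors model_core.transcription_propensity."""
    if rp[0] == 0.0:  # toggle
        K = rp[1]
        return K * (rp[2] + rp[3] / (1.0 + (n_other / K) ** rp[4]))
    q0, r1, r2, n1, n2, K1, K2 = rp[5], rp[6], rp[7], rp[8], rp[9], rp[10], rp[11]
    f1 = 1.0 / (1.0 + (n_self / K1) ** n1)
    f2 = 1.0 / (1.0 + (n_other / K2) ** n2)
    return q0 * (1.0 + r1 * f1) * (1.0 + r2 * f2)


@njit(cache=True)
def _geom_burst(B):
    """Geometric burst size on {0,1,2,...} with mean B."""
    q = B / (1.0 + B)
    u = 1.0 - np.random.random()  # in (0, 1]
    return int(np.floor(np.log(u) / np.log(q)))


@njit(cache=True)
def _bin(v, nmax):
    i = int(v + 0.5)
    if i < 0:
        i = 0
    elif i >= nmax:
        i = nmax - 1
    return i


@njit(cache=True)
def _occupy(W, do_hist, t0, t1, t_burn, nx, ny, nmax):
    """Add occupancy weight for state (nx, ny) held over [t0, t1)."""
    if not do_hist or t1 <= t_burn:
        return 0.0
    lo = t0 if t0 > t_burn else t_burn
    w = t1 - lo
    if w > 0.0:
        W[_bin(nx, nmax), _bin(ny, nmax)] += w
        return w
    return 0.0


# ---------------------------------------------------------------------------
# Full model (mRNA + protein) SSA
# ---------------------------------------------------------------------------


@njit(cache=True)
def fm_ssa(
    seed,
    t0,
    t_end,
    mX,
    mY,
    NX,
    NY,
    gamma,
    gB,
    gamma0,
    rp,
    W,
    do_hist,
    t_burn,
    stop_on_switch,
    buf,
    cap,
):
    """Direct-method SSA of the full mRNA+protein model.

    Returns (t, mX, mY, NX, NY, n_rec, switch_t, w_tot, int_mX, int_mY,
    int_NX, int_NY, prodX) where switch_t < 0 means no switch occurred,
    w_tot is the accumulated post-burn-in occupancy weight, int_* are
    post-burn-in time integrals of the copy numbers and prodX counts
    protein-X production events.
    """
    np.random.seed(seed)
    t = t0
    n_rec = 0
    switch_t = -1.0
    w_tot = 0.0
    int_mX = 0.0
    int_mY = 0.0
    int_NX = 0.0
    int_NY = 0.0
    prodX = 0.0
    nmax = W.shape[0]
    if cap > 0:
        buf[n_rec, 0] = t
        buf[n_rec, 1] = mX
        buf[n_rec, 2] = mY
        buf[n_rec, 3] = NX
        buf[n_rec, 4] = NY
        n_rec += 1
    while t < t_end:
        aX = _prop(NX, NY, rp)
        aY = _prop(NY, NX, rp)
        c1 = aX
        c2 = c1 + aY
        c3 = c2 + gamma * mX
        c4 = c3 + gamma * mY
        c5 = c4 + gB * mX
        c6 = c5 + gB * mY
        c7 = c6 + gamma0 * NX
        tot = c7 + gamma0 * NY
        if tot <= 0.0:  # absorbing state
            w = _occupy(W, do_hist, t, t_end, t_burn, NX, NY, nmax)
            w_tot += w
            t = t_end
            break
        dt = np.random.exponential(1.0 / tot)
        seg_end = t + dt if t + dt < t_end else t_end
        w = _occupy(W, do_hist, t, seg_end, t_burn, NX, NY, nmax)
        w_tot += w
        if w > 0.0:
            int_mX += mX * w
            int_mY += mY * w
            int_NX += NX * w
            int_NY += NY * w
        t += dt
        if t >= t_end:
            t = t_end
            break
        u = np.random.random() * tot
        if u < c1:
            mX += 1
        elif u < c2:
            mY += 1
        elif u < c3:
            mX -= 1
        elif u < c4:
            mY -= 1
        elif u < c5:
            NX += 1
            prodX += 1.0
        elif u < c6:
            NY += 1
        elif u < c7:
            NX -= 1
        else:
            NY -= 1
        if mX < 0 or mY < 0 or NX < 0 or NY < 0:
            # negative copy number: hard failure sentinel
            return (t, mX, mY, NX, NY, -1, -2.0, w_tot, int_mX, int_mY, int_NX, int_NY, prodX)
        if n_rec < cap:
            buf[n_rec, 0] = t
            buf[n_rec, 1] = mX
            buf[n_rec, 2] = mY
            buf[n_rec, 3] = NX
            buf[n_rec, 4] = NY
            n_rec += 1
        if stop_on_switch and NY >= NX:
            switch_t = t
            break
    return (t, mX, mY, NX, NY, n_rec, switch_t, w_tot, int_mX, int_mY, int_NX, int_NY, prodX)


# ---------------------------------------------------------------------------
# Protein-only SSA: NB / GB / CB
# ---------------------------------------------------------------------------


@njit(cache=True)
def burst_ssa(
    seed,
    t0,
    t_end,
    NX,
    NY,
    kind,
    B,
    gamma0,
    rp,
    W,
    do_hist,
    t_burn,
    stop_on_switch,
    buf,
    cap,
):
    """Direct-method SSA of the protein-only models.

    kind: 0 = NB (single proteins at B-fold rate), 1 = GB (geometric
    bursts), 2 = CB (constant bursts of size B).

    Returns (t, NX, NY, n_rec, switch_t, w_tot, int_NX, int_NY, prodX).
    """
    np.random.seed(seed)
    t = t0
    n_rec = 0
    switch_t = -1.0
    w_tot = 0.0
    int_NX = 0.0
    int_NY = 0.0
    prodX = 0.0
    nmax = W.shape[0]
    Bi = int(B + 0.5)
    if cap > 0:
        buf[n_rec, 0] = t
        buf[n_rec, 1] = NX
        buf[n_rec, 2] = NY
        n_rec += 1
    while t < t_end:
        aX = _prop(NX, NY, rp)
        aY = _prop(NY, NX, rp)
        if kind == 0:
            aX *= B
            aY *= B
        c1 = aX
        c2 = c1 + aY
        c3 = c2 + gamma0 * NX
        tot = c3 + gamma0 * NY
        if tot <= 0.0:  # absorbing state
            w = _occupy(W, do_hist, t, t_end, t_burn, NX, NY, nmax)
            w_tot += w
            if do_hist and t_end > t_burn:
                int_NX += NX * w
                int_NY += NY * w
            t = t_end
            break
        dt = np.random.exponential(1.0 / tot)
        seg_end = t + dt if t + dt < t_end else t_end
        w = _occupy(W, do_hist, t, seg_end, t_burn, NX, NY, nmax)
        w_tot += w
        if w > 0.0:
            int_NX += NX * w
            int_NY += NY * w
        t += dt
        if t >= t_end:
            t = t_end
            break
        u = np.random.random() * tot
        if u < c1:
            if kind == 0:
                k = 1
            elif kind == 1:
                k = _geom_burst(B)
            else:
                k = Bi
            NX += k
            prodX += k
        elif u < c2:
            if kind == 0:
                k = 1
            elif kind == 1:
                k = _geom_burst(B)
            else:
                k = Bi
            NY += k
        elif u < c3:
            NX -= 1
        else:
            NY -= 1
        if NX < 0 or NY < 0:
            return (t, NX, NY, -1, -2.0, w_tot, int_NX, int_NY, prodX)
        if n_rec < cap:
            buf[n_rec, 0] = t
            buf[n_rec, 1] = NX
            buf[n_rec, 2] = NY
            n_rec += 1
        if stop_on_switch and NY >= NX:
            switch_t = t
            break
    return (t, NX, NY, n_rec, switch_t, w_tot, int_NX, int_NY, prodX)


@njit(cache=True)
def mrna_lifecycles(seed, n_rep, gamma, gB):
    """Proteins produced during single mRNA lifetimes (explicit SSA race).

    Simulates n_rep independent mRNA molecules with translation rate gB
    and degradation rate gamma; returns the per-lifetime protein counts.
    """
    np.random.seed(seed)
    out = np.empty(n_rep, dtype=np.int64)
    tot = gamma + gB
    for i in range(n_rep):
        k = 0
        while np.random.random() * tot < gB:
            k += 1
        out[i] = k
    return out


@njit(cache=True)
def geometric_bursts(seed, n, B):
    np.random.seed(seed)
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        out[i] = _geom_burst(B)
    return out


# ---------------------------------------------------------------------------
# Diffusion approximation of the GB model (Euler-Maruyama)
# ---------------------------------------------------------------------------


@njit(cache=True)
def da_gb_sde(
    seed,
    t0,
    t_end,
    x,
    y,
    dt,
    B,
    gamma0,
    K,
    rp,
    W,
    do_hist,
    t_burn,
    stop_on_switch,
    buf,
    cap,
    rec_stride,
    noise_on,
):
    """Euler-Maruyama integration of the GB diffusion approximation.

    Concentrations are kept non-negative by reflection at 0.  Histogram
    occupancy is accumulated per step on protein-number bins N = K*x
    rounded to bin centres.  Returns
    (t, x, y, n_rec, switch_t, w_tot, int_x, int_y).
    """
    np.random.seed(seed)
    t = t0
    n_rec = 0
    switch_t = -1.0
    w_tot = 0.0
    int_x = 0.0
    int_y = 0.0
    nmax = W.shape[0]
    m2 = 2.0 * B * B + B  # second moment of the geometric burst law
    sqdt = np.sqrt(dt)
    step = 0
    if cap > 0:
        buf[n_rec, 0] = t
        buf[n_rec, 1] = x
        buf[n_rec, 2] = y
        n_rec += 1
    while t < t_end - 1e-12:
        aX = _prop(K * x, K * y, rp)
        aY = _prop(K * y, K * x, rp)
        vx = B * aX / K - gamma0 * x
        vy = B * aY / K - gamma0 * y
        if do_hist and t >= t_burn:
            W[_bin(K * x, nmax), _bin(K * y, nmax)] += dt
            w_tot += dt
            int_x += x * dt
            int_y += y * dt
        if noise_on:
            Dx = (aX * m2) / (K * K) + gamma0 * x / K
            Dy = (aY * m2) / (K * K) + gamma0 * y / K
            x = x + vx * dt + np.sqrt(Dx) * sqdt * np.random.normal()
            y = y + vy * dt + np.sqrt(Dy) * sqdt * np.random.normal()
        else:
            x = x + vx * dt
            y = y + vy * dt
        if x < 0.0:
            x = -x
        if y < 0.0:
            y = -y
        t += dt
        step += 1
        if cap > 0 and step % rec_stride == 0 and n_rec < cap:
            buf[n_rec, 0] = t
            buf[n_rec, 1] = x
            buf[n_rec, 2] = y
            n_rec += 1
        if stop_on_switch and y >= x:
            switch_t = t
            break
    return (t, x, y, n_rec, switch_t, w_tot, int_x, int_y)


# ---------------------------------------------------------------------------
# PDMP (three discrete mRNA modes, continuous concentrations)
# ---------------------------------------------------------------------------

MODE_ZERO = 0
MODE_X = 1
MODE_Y = 2


@njit(cache=True)
def _decay(v, gamma0, dt):
    return v * np.exp(-gamma0 * dt)


@njit(cache=True)
def pdmp_ssa(
    seed,
    t0,
    t_end,
    mode,
    x,
    y,
    gamma,
    gamma0,
    gb,
    amax,
    K,
    rp,
    W,
    do_hist,
    t_burn,
    sample_dt,
    stop_on_switch,
    buf,
    cap,
):
    """Finite-gamma PDMP with exact (thinning-based) event sampling.

    gb = gamma*b is the protein production rate in the active modes.
    Mode transition rates: 0->X at a_X(y;x), 0->Y at a_Y(x;y) (thinned
    against the majorant ``amax`` each), X->0 and Y->0 at gamma.

    Occupancy is sampled on a regular grid of spacing sample_dt.
    Returns (t, mode, x, y, n_rec, switch_t, w_tot, time_active).
    """
    np.random.seed(seed)
    t = t0
    n_rec = 0
    switch_t = -1.0
    w_tot = 0.0
    time_active = 0.0
    nmax = W.shape[0]
    c = gb / gamma0  # asymptote of the active-mode flow
    t_sample = t0 + sample_dt
    if cap > 0:
        buf[n_rec, 0] = t
        buf[n_rec, 1] = mode
        buf[n_rec, 2] = x
        buf[n_rec, 3] = y
        n_rec += 1
    while t < t_end:
        if mode == MODE_ZERO:
            # thinning against constant majorant 2*amax
            L = 2.0 * amax
            if L <= 0.0:  # transcription silenced: pure decay forever
                tau = t_end - t + 1.0
            else:
                tau = np.random.exponential(1.0 / L)
            accept = -1
            t_next = t + tau
            if t_next < t_end:
                xn = _decay(x, gamma0, tau)
                yn = _decay(y, gamma0, tau)
                lamX = _prop(K * xn, K * yn, rp)
                lamY = _prop(K * yn, K * xn, rp)
                u = np.random.random() * L
                if u < lamX:
                    accept = MODE_X
                elif u < lamX + lamY:
                    accept = MODE_Y
        else:
            tau = np.random.exponential(1.0 / gamma)
            t_next = t + tau
            accept = MODE_ZERO
        if t_next > t_end:
            t_next = t_end
            accept = -2  # horizon reached
        # crossing of y >= x along the flow (only possible in Y-mode)
        if stop_on_switch and mode == MODE_Y and x > y:
            tc = np.log((c + x - y) / c) / gamma0
            if t + tc <= t_next:
                switch_t = t + tc
        # occupancy samples over [t, t_next)
        while t_sample <= t_next:
            if switch_t >= 0.0 and t_sample > switch_t:
                break
            dtl = t_sample - t
            if mode == MODE_ZERO:
                xs = _decay(x, gamma0, dtl)
                ys = _decay(y, gamma0, dtl)
            elif mode == MODE_X:
                xs = c + (x - c) * np.exp(-gamma0 * dtl)
                ys = _decay(y, gamma0, dtl)
            else:
                xs = _decay(x, gamma0, dtl)
                ys = c + (y - c) * np.exp(-gamma0 * dtl)
            if do_hist and t_sample >= t_burn:
                W[_bin(K * xs, nmax), _bin(K * ys, nmax)] += sample_dt
                w_tot += sample_dt
            t_sample += sample_dt
        if switch_t >= 0.0:
            return (switch_t, mode, x, y, n_rec, switch_t, w_tot, time_active)
        # advance state to t_next
        dtl = t_next - t
        if mode == MODE_ZERO:
            x = _decay(x, gamma0, dtl)
            y = _decay(y, gamma0, dtl)
        elif mode == MODE_X:
            x = c + (x - c) * np.exp(-gamma0 * dtl)
            y = _decay(y, gamma0, dtl)
            time_active += dtl
        else:
            x = _decay(x, gamma0, dtl)
            y = c + (y - c) * np.exp(-gamma0 * dtl)
            time_active += dtl
        t = t_next
        if accept >= 0:
            mode = accept
            if n_rec < cap:
                buf[n_rec, 0] = t
                buf[n_rec, 1] = mode
                buf[n_rec, 2] = x
                buf[n_rec, 3] = y
                n_rec += 1
        if accept == -2:
            break
    return (t, mode, x, y, n_rec, switch_t, w_tot, time_active)


@njit(cache=True)
def shotnoise_ssa(
    seed,
    t0,
    t_end,
    x,
    y,
    b,
    gamma0,
    amax,
    K,
    rp,
    W,
    do_hist,
    t_burn,
    sample_dt,
    stop_on_switch,
    buf,
    cap,
):
    """Shot-noise (gamma -> infinity) limit of the PDMP.

    Burst events for X occur at rate a_X(y;x) and add Exp(mean b) to x
    instantaneously (Y symmetric); between events both concentrations
    decay exponentially at rate gamma0.  Event times are sampled by
    thinning against the constant majorant 2*amax.

    The trajectory buffer records both the pre- and the post-jump state
    at each accepted event time (left-continuous convention).
    Returns (t, x, y, n_rec, switch_t, w_tot, n_events).
    """
    np.random.seed(seed)
    t = t0
    n_rec = 0
    switch_t = -1.0
    w_tot = 0.0
    n_events = 0.0
    nmax = W.shape[0]
    L = 2.0 * amax
    t_sample = t0 + sample_dt
    if cap > 0:
        buf[n_rec, 0] = t
        buf[n_rec, 1] = x
        buf[n_rec, 2] = y
        n_rec += 1
    while t < t_end:
        if L <= 0.0:  # transcription silenced: pure decay forever
            tau = t_end - t + 1.0
        else:
            tau = np.random.exponential(1.0 / L)
        t_next = t + tau
        horizon = False
        if t_next > t_end:
            t_next = t_end
            horizon = True
        # occupancy samples over decay segment [t, t_next)
        while t_sample <= t_next:
            dtl = t_sample - t
            xs = _decay(x, gamma0, dtl)
            ys = _decay(y, gamma0, dtl)
            if do_hist and t_sample >= t_burn:
                W[_bin(K * xs, nmax), _bin(K * ys, nmax)] += sample_dt
                w_tot += sample_dt
            t_sample += sample_dt
        dtl = t_next - t
        x = _decay(x, gamma0, dtl)
        y = _decay(y, gamma0, dtl)
        t = t_next
        if horizon:
            break
        lamX = _prop(K * x, K * y, rp)
        lamY = _prop(K * y, K * x, rp)
        u = np.random.random() * L
        if u < lamX + lamY:
            if n_rec < cap:  # pre-jump point
                buf[n_rec, 0] = t
                buf[n_rec, 1] = x
                buf[n_rec, 2] = y
                n_rec += 1
            z = np.random.exponential(b)
            if u < lamX:
                x += z
            else:
                y += z
            n_events += 1.0
            if n_rec < cap:  # post-jump point
                buf[n_rec, 0] = t
                buf[n_rec, 1] = x
                buf[n_rec, 2] = y
                n_rec += 1
            if stop_on_switch and y >= x:
                switch_t = t
                break
    return (t, x, y, n_rec, switch_t, w_tot, n_events)
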