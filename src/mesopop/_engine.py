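"""Numba-compiled integration loops.

Three back ends share the same elementary numerics (exact exponential
one-step updates of membrane and synaptic variables, trapezoidal hazard
average, per-bin firing probability 1 - exp(-lambda_bar*dt)):

* ``meso_loop``   -- stochastic mesoscopic population equations: expected
  survival numbers ``m_k``, survival variances ``v_k``, free-neuron pool
  ``(x, z)``, quasi-renewal threshold sweep, effective firing
  probability and one random draw per population per step.
* ``micro_loop``  -- neuron-by-neuron GIF/GLM network with fixed
  in-degree connectivity (one Bernoulli draw per active neuron).
* ``density_loop`` -- the intermediate binomial survival-number process
  (one binomial draw per occupied last-spike bin), which conserves the
  neuron count exactly.

All randomness flows through numba's ``np.random`` state, seeded once
per call, so runs are bit-reproducible for a given seed.
"""

import numpy as np
from numba import njit

EXP_CLAMP = 20.0

# sampling modes
BINOMIAL, POISSON, GAUSSIAN, DETERMINISTIC = 0, 1, 2, 3


@njit(cache=False)
def _hazard(u, th, c, delta_u):
    x = (u - th) / delta_u
    if x > EXP_CLAMP:
        x = EXP_CLAMP
    return c * np.exp(x)


@njit(cache=False)
def _sample(nbar, n_int, mode):
    """Draw the spike count for one population and step."""
    if mode == DETERMINISTIC:
        return nbar
    if mode == BINOMIAL:
        p = nbar / n_int
        if p > 1.0:
            p = 1.0
        return float(np.random.binomial(n_int, p))
    if mode == POISSON:
        d = float(np.random.poisson(nbar))
        return d if d < n_int else float(n_int)
    # gaussian
    d = np.round(nbar + np.sqrt(nbar) * np.random.normal())
    if d < 0.0:
        d = 0.0
    if d > n_int:
        d = float(n_int)
    return d


@njit(cache=False)
def meso_loop(
    n_steps, dt, M,
    Ni, K, kref,            # int64[M]
    em,                     # exp(-dt/tau_m), float64[M]
    u_rest, u_r, u_th, c_, delta_u,   # float64[M]
    is_glm,                 # bool[M]
    cA, cY,                 # float64[M, M] input-integration coefficients
    es,                     # exp(-dt/tau_s[b]), float64[M]
    dly,                    # int64[M, M] delays in steps
    ext,                    # float64[n_steps, M] external drive RI_ext
    n_comp,                 # int64[M] number of threshold-kernel components
    eg,                     # exp(-dt/tau_theta), float64[M, L]
    wfree,                  # J_l * exp(-K*dt/tau_l), float64[M, L]
    theta_tab,              # theta(j*dt), float64[M, Kmax+2]
    qr_tab,                 # theta_tilde(j*dt)/N, float64[M, Kmax+2]
    eta_tab,                # eta(j*dt), float64[M, Kmax+2]
    mode, det_steps, seed,
    dn_out, abar_out, free_dist_out,
):
    """Integrate the mesoscopic population equations.

    Returns 0 on success, or 1 + the step index at which a non-finite
    expected spike count was first encountered.
    """
    np.random.seed(seed)
    Kmax = 0
    Dmax = 1
    for a in range(M):
        if K[a] > Kmax:
            Kmax = K[a]
        for b in range(M):
            if dly[a, b] > Dmax:
                Dmax = dly[a, b]
    H0 = Kmax + Dmax + 2

    N = Ni.astype(np.float64)
    m = np.zeros((M, Kmax))
    v = np.zeros((M, Kmax))
    ub = np.zeros((M, Kmax))
    lam = np.zeros((M, Kmax))
    dnfull = np.zeros((n_steps + H0, M))
    h = np.empty(M)
    lam_free = np.empty(M)
    x = np.zeros(M)
    z = np.zeros(M)
    y = np.zeros((M, M))
    Lmax = eg.shape[1]
    g = np.zeros((M, Lmax))

    # initialization: full synchronization at t = -dt
    for a in range(M):
        dnfull[H0 - 1, a] = N[a]
        slot = (K[a] - 1)  # bin k = -1 maps to slot (-1) mod K
        m[a, slot] = N[a]
        for j in range(Kmax):
            ub[a, j] = u_r[a]
        h[a] = u_rest[a]
        lam_free[a] = _hazard(h[a], u_th[a], c_[a], delta_u[a])

    for l in range(n_steps):
        for a in range(M):
            Ka = K[a]
            kra = kref[a]
            eps = 1e-15 * N[a]

            # --- 1. synaptic input, integrated over one step ---
            htot = ext[l, a] * (1.0 - em[a])
            for b in range(M):
                if cA[a, b] != 0.0 or cY[a, b] != 0.0:
                    a_del = dnfull[H0 + l - dly[a, b], b] / (N[b] * dt)
                    htot += cA[a, b] * a_del + cY[a, b] * (y[a, b] - a_del)
                    y[a, b] = a_del + (y[a, b] - a_del) * es[b]

            # --- 2. free neurons ---
            h_new = u_rest[a] + (h[a] - u_rest[a]) * em[a] + htot
            th_free = u_th[a]
            for li in range(n_comp[a]):
                g[a, li] = g[a, li] * eg[a, li] + (
                    dnfull[H0 + l - Ka, a] / (N[a] * dt)
                ) * (1.0 - eg[a, li])
                th_free += wfree[a, li] * g[a, li]
            lf_new = _hazard(h_new, th_free, c_[a], delta_u[a])
            p_free = -np.expm1(-0.5 * (lam_free[a] + lf_new) * dt)

            # --- 3. refractory sweep over k = l-K .. l-1 ---
            # threshold accumulator, advanced-time initial condition
            thhat = th_free - qr_tab[a, Ka + 1] * dnfull[H0 + l - Ka, a]
            sum_pm = 0.0
            sum_m = 0.0
            sum_pv = 0.0
            sum_v = 0.0
            x_inc = 0.0
            z_inc = 0.0
            for k in range(l - Ka, l):
                slot = k % Ka
                j = l + 1 - k  # age of this cohort at t_{l+1}, 2 .. K+1
                if is_glm[a]:
                    u_new = h_new + eta_tab[a, j]
                elif j <= kra:
                    u_new = u_r[a]
                else:
                    u_new = u_rest[a] + (ub[a, slot] - u_rest[a]) * em[a] + htot
                ub[a, slot] = u_new
                mo = m[a, slot]
                vo = v[a, slot]
                if j <= kra or (mo <= eps and vo <= eps):
                    l_new = 0.0
                else:
                    l_new = _hazard(u_new, thhat + theta_tab[a, j], c_[a], delta_u[a])
                p_k = -np.expm1(-0.5 * (lam[a, slot] + l_new) * dt)
                lam[a, slot] = l_new
                thhat += qr_tab[a, j] * dnfull[H0 + k, a]
                # sums use the pre-update (time t_l) moments
                sum_pm += p_k * mo
                sum_m += mo
                sum_pv += p_k * vo
                sum_v += vo
                mn = (1.0 - p_k) * mo
                vn = (1.0 - p_k) * (1.0 - p_k) * vo + p_k * mo
                m[a, slot] = mn
                v[a, slot] = vn
                if k == l - Ka:
                    x_inc = mn
                    z_inc = vn

            # --- 4. effective firing probability ---
            denom = sum_v + z[a]
            if denom > 0.0:
                p_eff = (sum_pv + p_free * z[a]) / denom
            else:
                p_eff = p_free

            # --- 5. expected spike count ---
            nbar = sum_pm + p_free * x[a] + p_eff * (N[a] - sum_m - x[a])
            if not np.isfinite(nbar):
                return 1 + l
            if nbar < 0.0:
                nbar = 0.0
            if nbar > N[a]:
                nbar = N[a]

            # --- 6. sample the activity ---
            if l < det_steps:
                dn = nbar
            else:
                dn = _sample(nbar, Ni[a], mode)

            # --- 7. free pool moments ---
            z[a] = (1.0 - p_free) * (1.0 - p_free) * z[a] + p_free * x[a] + z_inc
            x[a] = (1.0 - p_free) * x[a] + x_inc

            # --- 8. boundary condition for the newest bin ---
            slot = l % Ka
            m[a, slot] = dn
            v[a, slot] = 0.0
            ub[a, slot] = u_r[a]
            lam[a, slot] = 0.0

            dnfull[H0 + l, a] = dn
            dn_out[l, a] = dn
            abar_out[l, a] = nbar
            free_dist_out[l, a] = h_new - th_free
            h[a] = h_new
            lam_free[a] = lf_new
    return 0


@njit(cache=False)
def micro_loop(
    n_steps, dt, M, Ntot,
    pop_of,                 # int64[Ntot]
    kref, em, es,           # per population / per source
    u_rest, u_r, u_th, c_, delta_u,
    is_glm,
    cAw, cYw,               # float64[M, M] per-synapse input coefficients
    dly,                    # int64[M, M]
    ext,                    # float64[n_steps, M]
    n_comp, eg, jump_th,    # threshold kernel: decay factors and spike jumps
    n_eta, ee, jump_eta,    # GLM spike-after-potential kernel
    radj_idx, radj_ptr,     # reverse adjacency: targets of each source neuron
    seed, record_raster,
    dn_out,                 # float64[n_steps, M]
    raster_t, raster_i,     # int64 buffers (may be length 0)
):
    """Neuron-level network simulation; returns the raster length."""
    np.random.seed(seed)
    Dmax = 1
    for a in range(M):
        for b in range(M):
            if dly[a, b] > Dmax:
                Dmax = dly[a, b]
    D = Dmax + 1

    u = np.empty(Ntot)
    hfree = np.empty(Ntot)
    lastbin = np.full(Ntot, -1, dtype=np.int64)  # synchronized at t = -dt
    lam_prev = np.zeros(Ntot)
    y = np.zeros((Ntot, M))
    Lt = eg.shape[1]
    Le = ee.shape[1]
    thst = np.zeros((Ntot, Lt))
    etst = np.zeros((Ntot, Le))
    arr = np.zeros((D, Ntot, M))
    for i in range(Ntot):
        a = pop_of[i]
        u[i] = u_r[a]
        hfree[i] = u_rest[a]
        # the synchronizing spike at t = -dt loads the kernels
        for li in range(n_comp[a]):
            thst[i, li] = jump_th[a, li]
        for li in range(n_eta[a]):
            etst[i, li] = jump_eta[a, li]

    n_raster = 0
    cap = raster_t.shape[0]
    for l in range(n_steps):
        slot = l % D
        for i in range(Ntot):
            a = pop_of[i]
            htot = ext[l, a] * (1.0 - em[a])
            for b in range(M):
                if cAw[a, b] != 0.0 or cYw[a, b] != 0.0:
                    a_rate = arr[slot, i, b] / dt
                    htot += cAw[a, b] * a_rate + cYw[a, b] * (y[i, b] - a_rate)
                    y[i, b] = a_rate + (y[i, b] - a_rate) * es[b]
                arr[slot, i, b] = 0.0

            age = l + 1 - lastbin[i]
            if is_glm[a]:
                hfree[i] = u_rest[a] + (hfree[i] - u_rest[a]) * em[a] + htot
                u_new = hfree[i]
                for li in range(n_eta[a]):
                    etst[i, li] *= ee[a, li]
                    u_new += etst[i, li]
            elif age <= kref[a]:
                u_new = u_r[a]
            else:
                u_new = u_rest[a] + (u[i] - u_rest[a]) * em[a] + htot

            th_new = u_th[a]
            for li in range(n_comp[a]):
                thst[i, li] *= eg[a, li]
                th_new += thst[i, li]

            if age <= kref[a]:
                l_new = 0.0
            else:
                l_new = _hazard(u_new, th_new, c_[a], delta_u[a])
            p = -np.expm1(-0.5 * (lam_prev[i] + l_new) * dt)
            spiked = False
            if p > 0.0:
                spiked = np.random.random() < p
            if spiked:
                dn_out[l, a] += 1.0
                lastbin[i] = l
                lam_prev[i] = 0.0
                if not is_glm[a]:
                    u_new = u_r[a]
                for li in range(n_comp[a]):
                    thst[i, li] += jump_th[a, li]
                for li in range(n_eta[a]):
                    etst[i, li] += jump_eta[a, li]
                for q in range(radj_ptr[i], radj_ptr[i + 1]):
                    tgt = radj_idx[q]
                    d = dly[pop_of[tgt], a]
                    arr[(l + d) % D, tgt, a] += 1.0
                if record_raster and n_raster < cap:
                    raster_t[n_raster] = l
                    raster_i[n_raster] = i
                    n_raster += 1
            else:
                lam_prev[i] = l_new
            u[i] = u_new
    return n_raster


@njit(cache=False)
def density_loop(
    n_steps, dt,
    n_int, kref, em,
    u_rest, u_r, u_th, c_, delta_u,
    is_glm,
    cA, cY, es, dstep,      # scalars: self-coupling of the single population
    ext,                    # float64[n_steps]
    theta_tab, qr_tab, eta_tab,   # float64[n_steps + 2], full-history kernels
    j_qr_cut,               # last age index with a non-negligible qr kernel
    seed,
    dn_out,                 # int64[n_steps]
):
    """Binomial survival-number process for one population, full history.

    Bin b = 0 holds the synchronized cohort (last spike at t = -dt); bin
    b = k + 1 holds cohort k.  Returns 0 on success or -(1 + l) if the
    conservation sum_k m(t_l, t_k) = N is violated at step l (which
    would indicate a programming error, not a statistical fluctuation).
    """
    np.random.seed(seed)
    N = float(n_int)
    m = np.zeros(n_steps + 1, dtype=np.int64)
    ub = np.full(n_steps + 1, u_r)
    lam = np.zeros(n_steps + 1)
    dnfull = np.zeros(n_steps + 1, dtype=np.int64)
    m[0] = n_int
    dnfull[0] = n_int
    y = 0.0
    hfree = u_rest
    b_min = 0

    for l in range(n_steps):
        htot = ext[l] * (1.0 - em)
        if cA != 0.0 or cY != 0.0:
            bdel = l - dstep + 1
            a_del = dnfull[bdel] / (N * dt) if bdel >= 0 else 0.0
            htot += cA * a_del + cY * (y - a_del)
            y = a_del + (y - a_del) * es
        hfree = u_rest + (hfree - u_rest) * em + htot

        # bins below b_min are exhausted (m = 0) and, being older than the
        # reach of the quasi-renewal kernel, contribute nothing to any
        # younger cohort's threshold either
        b_lo = l + 2 - j_qr_cut
        if b_lo > b_min:
            b_lo = b_min
        if b_lo < 0:
            b_lo = 0
        thhat = u_th
        dn = 0
        for b in range(b_lo, l + 1):
            j = l + 2 - b  # age of cohort b (= bin k = b-1) at t_{l+1}
            if is_glm:
                u_new = hfree + eta_tab[j]
            elif j <= kref:
                u_new = u_r
            else:
                u_new = u_rest + (ub[b] - u_rest) * em + htot
            ub[b] = u_new
            if j <= kref or m[b] == 0:
                l_new = 0.0
            else:
                l_new = _hazard(u_new, thhat + theta_tab[j], c_, delta_u)
            p = -np.expm1(-0.5 * (lam[b] + l_new) * dt)
            lam[b] = l_new
            if j <= j_qr_cut:
                thhat += qr_tab[j] * dnfull[b]
            if m[b] > 0 and p > 0.0:
                xlk = np.random.binomial(m[b], p)
                m[b] -= xlk
                dn += xlk
        m[l + 1] = dn
        dnfull[l + 1] = dn
        dn_out[l] = dn
        while b_min <= l and m[b_min] == 0:
            b_min += 1
        total = 0
        for b in range(b_min, l + 2):
            total += m[b]
        if total != n_int:
            return -(1 + l)
    return 0
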