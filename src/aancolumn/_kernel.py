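"""Fused per-step update kernel (numba-accelerated when available).

One call advances gating variables (exponential Euler via the voltage
lookup tables), intrinsic and synaptic conductances, the semi-implicit
membrane update with a midpoint conductance corrector, and the calcium
pool, for all compartments, and accumulates the per-layer dipole.  Semantics are identical to the
pure-numpy path in ``engine.integrate``; an equivalence test keeps the
two in lockstep.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco


@njit(cache=True, fastmath=True)
def fused_step(v, v_new, v_pred, m, h, n_gate, q, ca, syn_a, syn_b, i_inj,
               tab_vmin, inv_dv,
               m_inf, dm_inf, fm, dfm,
               h_inf, dh_inf, fh, dfh,
               n_inf, dn_inf, fn, dfn,
               q_inf, dq_inf, fq, dfq,
               nmda, dnmda,
               nbr_idx, nbr_g,
               g_na_max, g_k_max, g_leak, e_leak, cap,
               ca_pos, g_ca_max, g_kca_max, i_ca_rest,
               erev, norm, kca_kd,
               ca_baseline, ca_tau, ca_influx,
               conn_a, conn_b, conn_gdz, conn_cls,
               dt, e_na, e_k, e_ca):
    n = v.shape[0]
    ntab = m_inf.shape[0]

    # gate advance on the old voltage (exponential Euler over dt)
    for i in range(n):
        u = (v[i] - tab_vmin) * inv_dv
        if u < 0.0:
            u = 0.0
        elif u > ntab - 1.001:
            u = ntab - 1.001
        k = int(u)
        w = u - k
        m[i] += ((m_inf[k] + dm_inf[k] * w) - m[i]) * (fm[k] + dfm[k] * w)
        h[i] += ((h_inf[k] + dh_inf[k] * w) - h[i]) * (fh[k] + dfh[k] * w)
        n_gate[i] += ((n_inf[k] + dn_inf[k] * w) - n_gate[i]) \
            * (fn[k] + dfn[k] * w)
        p = ca_pos[i]
        if p >= 0:
            q[p] += ((q_inf[k] + dq_inf[k] * w) - q[p]) \
                * (fq[k] + dfq[k] * w)

    # membrane update: predictor with start-of-step voltages, then a
    # corrector that averages the voltage-dependent conductive terms
    # (NMDA block, axial sources) between the old and predicted voltage
    # (midpoint rule); gate-driven conductances are shared by both passes
    for rep in range(2):
        out = v_pred if rep == 0 else v_new
        for i in range(n):
            g_na = g_na_max[i] * m[i] * m[i] * m[i] * h[i]
            nn = n_gate[i]
            g_k = g_k_max[i] * nn * nn * nn * nn
            p = ca_pos[i]

            gs_base = g_na + g_k + g_leak[i]
            ge_base = g_na * e_na + g_k * e_k + g_leak[i] * e_leak[i]
            if p >= 0:
                g_ca = g_ca_max[p] * q[p] * q[p]
                g_kca = g_kca_max[p] * ca[p] / (ca[p] + kca_kd)
                gs_base += g_ca + g_kca
                ge_base += g_ca * e_ca + g_kca * e_k
            for r in range(4):
                if r != 1:
                    g_r = norm[r] * (syn_b[r, i] - syn_a[r, i])
                    gs_base += g_r
                    ge_base += g_r * erev[r]
            g_nmda = norm[1] * (syn_b[1, i] - syn_a[1, i])

            n_src = 1 if rep == 0 else 2
            g_sum = 0.0
            g_e = 0.0
            for src in range(n_src):
                vv = v[i] if src == 0 else v_pred[i]
                u = (vv - tab_vmin) * inv_dv
                if u < 0.0:
                    u = 0.0
                elif u > ntab - 1.001:
                    u = ntab - 1.001
                k = int(u)
                w = u - k
                g_n = g_nmda * (nmda[k] + dnmda[k] * w)
                gs = gs_base + g_n
                ge = ge_base + g_n * erev[1]
                for jn in range(nbr_idx.shape[1]):
                    g_ax = nbr_g[i, jn]
                    if g_ax > 0.0:
                        gs += g_ax
                        j = nbr_idx[i, jn]
                        ge += g_ax * (v[j] if src == 0 else v_pred[j])
                g_sum += gs
                g_e += ge
            if rep == 1:
                g_sum *= 0.5
                g_e *= 0.5
            v_inf = (g_e + i_inj[i]) / g_sum
            out[i] = v_inf + (v[i] - v_inf) * np.exp(-dt * g_sum / cap[i])

    # calcium pool on the midpoint voltage
    for i in range(n):
        p = ca_pos[i]
        if p >= 0:
            vmid = 0.5 * (v[i] + v_new[i])
            g_ca = g_ca_max[p] * q[p] * q[p]
            i_ca = g_ca * (vmid - e_ca) - i_ca_rest[p]
            c = ca[p] + dt * (-ca_influx * i_ca
                              - (ca[p] - ca_baseline) / ca_tau)
            ca[p] = c if c > 0.0 else 0.0

    dip23 = 0.0
    dip5 = 0.0
    for c in range(conn_a.shape[0]):
        contrib = conn_gdz[c] * (v_new[conn_a[c]] - v_new[conn_b[c]])
        if conn_cls[c] == 0:
            dip23 += contrib
        elif conn_cls[c] == 1:
            dip5 += contrib
    return dip23, dip5
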