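"""Compiled daily loop (numba) used for calibration and ensemble work.

This mirrors :func:`soilweb.engine.daily_step` operation for operation; the
test suite asserts numerical agreement between the two paths.  Configuration
is flattened into plain arrays by :func:`pack_config` and the whole multi-year
loop runs inside one jitted function.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core_state import GUILDS, POOLS, PoolVector, SiteConfig
from .engine import TRACE_COLUMNS, SimulationResult
from .foodweb import F_FAEC_MAX, LITTER, ROOTS, SOM, DOM

__all__ = ["pack_config", "run_compiled"]

# scalar-vector indices (sc array)
(
    S_THICK, S_PH, S_KD, S_MASS, S_FDOM, S_DOMRET, S_EXUD, S_LITFALL, S_ROOTLIT,
    S_MYCALLOC, S_ROOTB, S_IMAXMAT, S_IMAXSUB, S_FCMESO, S_FPV, S_PVBMAX,
    S_VERATIO, S_TPVB, S_KAG, S_CAG, S_PVAGCAP, S_BLRATE, S_BSRATE,
    S_LFCN, S_LFREC, S_RLCN, S_RLREC, S_LQCN, S_LQREC, S_SQCN, S_SQREC,
) = range(31)

# guild-parameter matrix columns (gp array)
(
    G_GMAX, G_R, G_D, G_FFAEC, G_MFAEC, G_CN, G_PMCN, G_PMREC,
    G_TMIN, G_TOPT, G_TMAX, G_Q10,
) = range(12)

I_ENG = GUILDS.index("engineers")
I_FUNGI = GUILDS.index("fungi")
I_MYC = GUILDS.index("mycorrhiza")


def pack_config(config: SiteConfig):
    """Flatten a SiteConfig into the arrays the kernel consumes."""
    tex = config.texture
    sc = np.zeros(31)
    sc[S_THICK] = tex.layer_thickness
    sc[S_PH] = tex.ph
    sc[S_KD] = config.k_d
    sc[S_MASS] = config.soil_mass
    sc[S_FDOM] = config.f_dom
    sc[S_DOMRET] = config.dom_return_rate
    sc[S_EXUD] = config.inputs.exudation
    sc[S_LITFALL] = config.inputs.litter_fall
    sc[S_ROOTLIT] = config.inputs.root_litter
    sc[S_MYCALLOC] = config.inputs.myc_allocation
    sc[S_ROOTB] = config.inputs.root_biomass
    sc[S_IMAXSUB] = config.i_max_mat_subsoil
    sc[S_FCMESO] = 1.0 if config.fc_includes_meso else 0.0
    sc[S_FPV] = config.f_pv
    sc[S_PVBMAX] = config.pv_bmax
    sc[S_VERATIO] = config.ve_ratio
    sc[S_TPVB] = config.tpv_b
    sc[S_KAG] = config.k_ag
    sc[S_CAG] = config.c_ag
    sc[S_PVAGCAP] = config.pv_ag_cap
    sc[S_BLRATE] = config.bioturb_litter_rate
    sc[S_BSRATE] = config.bioturb_som_rate
    sc[S_LFCN] = config.litterfall_quality.cn
    sc[S_LFREC] = config.litterfall_quality.rec
    sc[S_RLCN] = config.rootlitter_quality.cn
    sc[S_RLREC] = config.rootlitter_quality.rec
    sc[S_LQCN] = config.litter_quality.cn
    sc[S_LQREC] = config.litter_quality.rec
    sc[S_SQCN] = config.som_quality.cn
    sc[S_SQREC] = config.som_quality.rec

    gp = np.zeros((9, 12))
    acc = np.zeros((9, 5))
    for gi, name in enumerate(GUILDS):
        g = config.guilds[name]
        gp[gi] = (
            g.g_max, g.r, g.d, g.f_faec, g.m_faec, g.cn, g.p_m_cn, g.p_m_rec,
            g.t_min, g.t_opt, g.t_max, g.q10,
        )
        for c in g.accessible_classes:
            acc[gi, c] = 1.0

    n = len(config.diet)
    lcons = np.zeros(n, dtype=np.int64)
    lsub = np.zeros(n, dtype=np.int64)
    ltype = np.zeros(n, dtype=np.int64)  # 0 litter, 1 som, 2 roots, 3 prey
    lks = np.zeros(n)
    dmask = np.zeros((n, 5))
    rmask = np.zeros((n, 5))
    for i, link in enumerate(config.diet):
        gi = GUILDS.index(link.consumer)
        lcons[i] = gi
        lks[i] = link.k_s
        cons_acc = link.pore_classes or config.guilds[link.consumer].accessible_classes
        if link.substrate == "litter":
            lsub[i] = LITTER
            ltype[i] = 0
            continue
        if link.substrate == "som":
            lsub[i] = SOM
            ltype[i] = 1
            domain = (0, 1, 2, 3, 4)
        elif link.substrate == "roots":
            lsub[i] = ROOTS
            ltype[i] = 2
            domain = (3, 4)
        else:
            lsub[i] = POOLS.index(link.substrate)
            ltype[i] = 3
            domain = config.guilds[link.substrate].accessible_classes
        for c in domain:
            dmask[i, c] = 1.0
            if c in cons_acc:
                rmask[i, c] = 1.0

    # initial state via the same path the reference uses
    from .core_state import init_state

    pools, pore, water = init_state(config)
    sc[S_IMAXMAT] = water.i_max_mat
    b0 = pools.as_array()
    pv_text = pore.pv_text.copy()
    sw0 = water.sw
    return sc, gp, acc, lcons, lsub, ltype, lks, dmask, rmask, pv_text, b0, sw0


@njit(cache=False)
def _loop(nd, p_mm, e_mm, t_air, sc, gp, acc, lcons, lsub, ltype, lks,
          dmask, rmask, pv_text, b0, sw0, trace):  # pragma: no cover - jitted
    nl = lcons.shape[0]
    b = b0.copy()
    sw = sw0
    pv_b = 0.0
    lq_cn = sc[S_LQCN]
    lq_rec = sc[S_LQREC]
    sq_cn = sc[S_SQCN]
    sq_rec = sc[S_SQREC]
    thick = sc[S_THICK]
    ph = sc[S_PH]

    co2_cum = 0.0
    leach_cum = 0.0
    biot_cum = 0.0
    inputs_cum = 0.0
    resp_cum = np.zeros(9)
    cons_cum = np.zeros(nl)
    b_lit_cum = 0.0
    b_som_cum = 0.0

    pv = np.zeros(5)
    w = np.zeros(5)
    m = np.zeros(5)
    geff = np.zeros(9)
    f_r = np.zeros(9)
    growth = np.zeros(nl)
    cons = np.zeros(nl)
    fae = np.zeros(nl)
    resp = np.zeros(9)
    turn = np.zeros(9)
    avail = np.zeros(13)
    out = np.zeros(13)
    scale = np.zeros(13)
    delta = np.zeros(12)
    err = 0

    for day in range(nd):
        # (a) porosity
        som = b[10]
        if som <= 0.0:
            ag = 0.0
        else:
            ag = sc[S_CAG] * (b[I_FUNGI] + b[I_MYC]) / som
            if ag > 1.0:
                ag = 1.0
        ag_term = sc[S_KAG] * (ag / 2.0) * som
        cap = sc[S_PVAGCAP] / 2.0
        if ag_term > cap:
            ag_term = cap
        meso_shift = (ag / 4.0) * pv_text[3]
        pv[0] = pv_text[0]
        pv[1] = pv_text[1] + ag_term + meso_shift
        pv[2] = pv_text[2] + ag_term + meso_shift
        pv[3] = pv_text[3] - (1.0 - sc[S_FPV]) * pv_b - (ag / 2.0) * pv_text[3]
        pv[4] = pv_text[4] + pv_b
        for c in range(5):
            if pv[c] < 0.0:
                pv[c] = 0.0
        pv_tot = pv[0] + pv[1] + pv[2] + pv[3] + pv[4]

        # (b) water balance
        if sw > pv_tot:
            sw = pv_tot
        sa = pv[4] / 1000.0
        if sa > 1.0:
            sa = 1.0
        fc = pv[0] + pv[1] + pv[2]
        if sc[S_FCMESO] > 0.5:
            fc += pv[3]
        p_net = p_mm[day] - e_mm[day]
        runoff = 0.0
        drain = 0.0
        if p_net > 0.0:
            imaxpor = pv[4] * thick + sc[S_IMAXSUB]
            runoff = p_net - (imaxpor + sc[S_IMAXMAT])
            if runoff < 0.0:
                runoff = 0.0
            peff = p_net - runoff
            mf = (pv_tot - sw) * thick
            alt = sc[S_IMAXMAT] * (1.0 - sa)
            if alt < mf:
                mf = alt
            alt = peff * (1.0 - sa)
            if alt < mf:
                mf = alt
            if mf < 0.0:
                mf = 0.0
            bypass = peff - mf
            sw += mf / thick
            spill = sw - fc
            if spill < 0.0:
                spill = 0.0
            sw -= spill
            drain = bypass + spill * thick
        elif p_net < 0.0:
            floor = sw
            if pv[0] < floor:
                floor = pv[0]
            sw = sw + p_net / thick
            if sw < floor:
                sw = floor
        # allocation smallest-first
        rem = sw
        partial = -1
        for c in range(5):
            wc = rem
            if pv[c] < wc:
                wc = pv[c]
            w[c] = wc
            rem -= wc
            if partial < 0 and pv[c] > 0.0 and wc < pv[c]:
                partial = c

        # (c) DOM leaching + slow re-stabilization to SOM
        drain_lm3 = drain / thick
        leach = 0.0
        if b[11] > 0.0 and sw > 0.0 and drain_lm3 > 0.0:
            conc = b[11] * (1.0 / (1.0 + sc[S_KD] * sc[S_MASS])) / sw
            leach = conc * drain_lm3
            if leach > b[11]:
                leach = b[11]
        b[11] -= leach
        leach_cum += leach
        ret = sc[S_DOMRET] * b[11]
        b[11] -= ret
        b[10] += ret

        # (d) per-class moisture modifiers
        if pv_tot <= 0.0:
            m_tot = 0.0
        else:
            x = sw / pv_tot
            if x < 0.5:
                m_tot = 4.0 * x * (1.0 - x)
            else:
                m_tot = 1.0
        for c in range(5):
            m[c] = 0.0
        if partial >= 0 and m_tot > 0.0:
            wp = w[partial]
            apv = pv[partial] - wp
            tot = apv + wp
            if tot > 0.0:
                m[partial] = (apv / tot) * m_tot
                if partial + 1 < 5 and pv[partial + 1] > 0.0:
                    m[partial + 1] = (wp / tot) * m_tot
        den_l = pv[1] + pv[2] + pv[3] + pv[4]
        if den_l > 0.0:
            lit_m = (pv[1] * m[1] + pv[2] * m[2] + pv[3] * m[3] + pv[4] * m[4]) / den_l
        else:
            lit_m = 0.0

        # (e) effective g_max and respiration temperature factor per guild
        t = t_air[day]
        for gi in range(9):
            tmin = gp[gi, G_TMIN]
            topt = gp[gi, G_TOPT]
            tmax = gp[gi, G_TMAX]
            q10 = gp[gi, G_Q10]
            if t < tmin or t >= tmax:
                m_t = 0.0
                f_r[gi] = 0.0
            else:
                f_r[gi] = q10 ** ((t - topt) / 10.0)
                if t < topt:
                    m_t = f_r[gi]
                else:
                    m_t = 1.0
            base = gp[gi, G_GMAX]
            if gi == I_ENG:
                if ph < 3.0:
                    base = 0.0
                elif ph < 5.0:
                    base = (base / 2.0) * (ph - 3.0)
            elif gi == 0:
                if ph <= 2.9:
                    mph = 1.0 / ((3.0 - ph) * 10.0)
                    if mph > 1.0:
                        mph = 1.0
                    base *= mph
            elif gi == I_FUNGI or gi == I_MYC:
                if ph >= 8.1:
                    mph = 1.0 / ((ph - 8.0) * 10.0)
                    if mph > 1.0:
                        mph = 1.0
                    base *= mph
            geff[gi] = base * m_t

        # (f) link fluxes
        for i in range(nl):
            gi = lcons[i]
            si = lsub[i]
            if si == 12:
                s = sc[S_ROOTB]
            else:
                s = b[si]
            lt = ltype[i]
            if lt == 0:
                fa = lit_m
            else:
                den = 0.0
                num = 0.0
                for c in range(5):
                    den += dmask[i, c] * pv[c]
                    num += rmask[i, c] * pv[c] * m[c]
                if den <= 0.0:
                    fa = 0.0
                else:
                    fa = num / den
                    if fa > 1.0:
                        fa = 1.0
            m_q = 1.0
            if lt == 0 or lt == 1:
                cn_s = lq_cn if lt == 0 else sq_cn
                rec_s = lq_rec if lt == 0 else sq_rec
                m_cn = (gp[gi, G_CN] / cn_s) ** gp[gi, G_PMCN]
                if m_cn > 1.0:
                    m_cn = 1.0
                m_rec = 1.0 - gp[gi, G_PMREC] * rec_s
                if m_rec > 1.0:
                    m_rec = 1.0
                m_q = m_cn * m_rec
            if s > 0.0:
                g = geff[gi] * m_q * (s * fa / (lks[i] + s)) * b[gi]
            else:
                g = 0.0
            growth[i] = g
            ff = gp[gi, G_FFAEC]
            if lt == 0 or lt == 1:
                cn_s = lq_cn if lt == 0 else sq_cn
                feff = ff + gp[gi, G_MFAEC] * ((cn_s - gp[gi, G_CN]) / cn_s) * ff
                if feff < 0.0:
                    feff = 0.0
                if feff > F_FAEC_MAX:
                    feff = F_FAEC_MAX
                cons[i] = g / (1.0 - feff)
                fae[i] = cons[i] - g
            else:
                cons[i] = g * (1.0 + ff)
                fae[i] = g * ff

        for gi in range(9):
            resp[gi] = gp[gi, G_R] * f_r[gi] * b[gi]
            turn[gi] = gp[gi, G_D] * b[gi]

        # (g) limiter + Euler update
        for j in range(12):
            avail[j] = b[j]
            out[j] = 0.0
        avail[12] = sc[S_ROOTB]
        out[12] = 0.0
        for i in range(nl):
            out[lsub[i]] += cons[i]
        for gi in range(9):
            out[gi] += resp[gi] + turn[gi]
        for j in range(13):
            if out[j] > avail[j] and out[j] > 0.0:
                scale[j] = avail[j] / out[j]
            else:
                scale[j] = 1.0
        for i in range(nl):
            s_i = scale[lsub[i]]
            cons[i] *= s_i
            growth[i] *= s_i
            fae[i] *= s_i
        r_tot = 0.0
        for gi in range(9):
            resp[gi] *= scale[gi]
            turn[gi] *= scale[gi]
            r_tot += resp[gi]

        for j in range(12):
            delta[j] = 0.0
        root_cons = 0.0
        for i in range(nl):
            si = lsub[i]
            if si < 12:
                delta[si] -= cons[i]
            else:
                root_cons += cons[i]
            delta[lcons[i]] += growth[i]
            delta[10] += fae[i]
        for gi in range(9):
            delta[gi] -= resp[gi] + turn[gi]
            delta[10] += turn[gi]
        delta[9] += sc[S_LITFALL]
        delta[10] += sc[S_ROOTLIT]
        delta[I_MYC] += sc[S_MYCALLOC]
        dom_prod = sc[S_FDOM] * r_tot
        delta[11] += dom_prod + sc[S_EXUD]

        for j in range(12):
            b[j] += delta[j]
            if b[j] < 0.0:
                if b[j] < -1e-9:
                    err = day + 1
                b[j] = 0.0
        co2_cum += r_tot * (1.0 - sc[S_FDOM])
        inputs_cum += (sc[S_LITFALL] + sc[S_ROOTLIT] + sc[S_MYCALLOC]
                       + sc[S_EXUD] + root_cons)
        for gi in range(9):
            resp_cum[gi] += resp[gi]
        for i in range(nl):
            cons_cum[i] += cons[i]

        # (h) quality updates (nitrogen-conserving C:N mixing); faeces carry
        # the pre-update quality of their substrate
        lq_cn_old = lq_cn
        lq_rec_old = lq_rec
        lf = sc[S_LITFALL]
        retained = b[9] - lf
        if retained < 0.0:
            retained = 0.0
        c_tot = retained + lf
        if c_tot > 0.0:
            n_tot = retained / lq_cn + lf / sc[S_LFCN]
            rec_mass = retained * lq_rec + lf * sc[S_LFREC]
            if n_tot > 0.0:
                lq_cn = c_tot / n_tot
            lq_rec = rec_mass / c_tot
            if lq_rec > 1.0:
                lq_rec = 1.0

        c_in = sc[S_ROOTLIT]
        n_in = sc[S_ROOTLIT] / sc[S_RLCN]
        rec_in = sc[S_ROOTLIT] * sc[S_RLREC]
        for i in range(nl):
            if fae[i] > 0.0:
                si = lsub[i]
                if si == 9:
                    cn_f = lq_cn_old
                    rec_f = lq_rec_old
                elif si == 10:
                    cn_f = sq_cn
                    rec_f = sq_rec
                elif si == 12:
                    cn_f = sc[S_RLCN]
                    rec_f = 0.0
                else:
                    cn_f = gp[si, G_CN]
                    rec_f = 0.0
                c_in += fae[i]
                n_in += fae[i] / cn_f
                rec_in += fae[i] * rec_f
        for gi in range(9):
            if turn[gi] > 0.0:
                c_in += turn[gi]
                n_in += turn[gi] / gp[gi, G_CN]
        retained_s = b[10] - c_in
        if retained_s < 0.0:
            retained_s = 0.0
        c_tot = retained_s + c_in
        if c_tot > 0.0:
            n_tot = retained_s / sq_cn + n_in
            rec_mass = retained_s * sq_rec + rec_in
            if n_tot > 0.0:
                sq_cn = c_tot / n_tot
            sq_rec = rec_mass / c_tot
            if sq_rec > 1.0:
                sq_rec = 1.0

        # (i) engineers: burrow volume then bioturbation exports
        dug = sc[S_VERATIO] * b[I_ENG]
        if dug > sc[S_PVBMAX]:
            dug = sc[S_PVBMAX]
        relict = (pv[4] - pv_text[4]) * (1.0 - sc[S_TPVB])
        pv_b = dug
        if relict > pv_b:
            pv_b = relict
        if pv_b < 0.0:
            pv_b = 0.0
        bl = sc[S_BLRATE] * b[I_ENG]
        if bl > b[9]:
            bl = b[9]
        bs = sc[S_BSRATE] * b[I_ENG]
        if bs > b[10]:
            bs = b[10]
        b[9] -= bl
        b[10] -= bs
        biot_cum += bl + bs
        b_lit_cum += bl
        b_som_cum += bs

        # trace row
        trace[day, 0] = day
        for j in range(12):
            trace[day, 1 + j] = b[j]
        trace[day, 13] = sw
        for c in range(5):
            trace[day, 14 + c] = pv[c]
            trace[day, 19 + c] = w[c]
        trace[day, 24] = runoff
        trace[day, 25] = drain
        trace[day, 26] = leach
        trace[day, 27] = r_tot

    return (b, co2_cum, leach_cum, biot_cum, inputs_cum, resp_cum, cons_cum,
            b_lit_cum, b_som_cum, lq_cn, lq_rec, sq_cn, sq_rec, err)


def run_compiled(config: SiteConfig, climate, n_days: int) -> SimulationResult:
    """Pack the configuration, run the jitted loop, unpack the result."""
    packed = pack_config(config)
    trace = np.empty((n_days, len(TRACE_COLUMNS)))
    res = _loop(
        n_days,
        np.ascontiguousarray(climate.p[:n_days], dtype=np.float64),
        np.ascontiguousarray(climate.e[:n_days], dtype=np.float64),
        np.ascontiguousarray(climate.t[:n_days], dtype=np.float64),
        *packed,
        trace,
    )
    (b, co2_cum, leach_cum, biot_cum, inputs_cum, resp_cum, cons_cum,
     b_lit_cum, b_som_cum, lq_cn, lq_rec, sq_cn, sq_rec, err) = res
    if err:
        raise FloatingPointError(f"limiter failed on day {err - 1}")
    pools = PoolVector(**{p: float(v) for p, v in zip(POOLS, b)})
    pools.co2_cum = co2_cum
    pools.dom_leached_cum = leach_cum
    pools.bioturb_export_cum = biot_cum
    pools.inputs_cum = inputs_cum
    return SimulationResult(
        trace=trace,
        final_pools=pools,
        resp_cum=resp_cum,
        cons_cum=cons_cum,
        link_meta=[(l.consumer, l.substrate) for l in config.diet],
        bioturb_litter_cum=b_lit_cum,
        bioturb_som_cum=b_som_cum,
        config=config,
    )
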