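"""Compiled inner loop of the 1D FSI solver.

A numba port of ``Simulator``'s cycle loop: identical scheme (finite-volume
Richtmyer Lax-Wendroff, characteristic boundary closure, junction/Windkessel
Newton solves), scalar loops instead of vectorized numpy.  The numpy path in
``solver.py`` remains the reference implementation; an equivalence test in
the suite holds the two together.

The kernel communicates failures through a status code:
0 ok, 1 invalid state, 2 CFL violation, 3 junction Newton failure,
4 area outside the tabulated tube-law range.
"""

from __future__ import annotations

import math

import numba
import numpy as np

__all__ = ["advance_cycle", "STATUS_MESSAGES"]

STATUS_MESSAGES = {
    1: "invalid state (negative area or NaN)",
    2: "CFL violated",
    3: "junction Newton failed",
    4: "area left the tabulated tube-law range",
}


@numba.njit(cache=True, inline="always")
def _lut(tab, i, a, A0, anorm0, dnorm, ntab):
    pos = (a / A0[i] - anorm0) / dnorm
    if pos < 0.0:
        pos = 0.0
    hi = ntab - 1.000001
    if pos > hi:
        pos = hi
    idx = int(pos)
    frac = pos - idx
    return tab[i, idx] * (1.0 - frac) + tab[i, idx + 1] * frac


@numba.njit(cache=True)
def advance_cycle(
    # state (updated in place)
    A, Q, Afc, Qfc, wk_P, wk_Qprev,
    # history buffers (n_steps x ...)
    hist_A, hist_Q, hist_fA, hist_fQ,
    # grid
    ncells, cell_start, face_start, seg_of_cell, dx_cell, dx_seg,
    # tables
    Ptab, dPtab, ctab, Btab, Itab, A0, anorm0, dnorm, ntab, A_lo, A_hi,
    # junctions / terminals
    jp, jc1, jc2, tseg, wk_R1, wk_R2, wk_tau, zero_res,
    # inflow at half times, scalars
    q_in_half, dt, fric, t0, newton_tol, newton_maxiter,
):
    """March one cardiac cycle; returns (status, max_defect, v_in, v_out)."""
    n_steps = q_in_half.shape[0]
    n_seg = ncells.shape[0]
    n_cell = A.shape[0]
    nj = jp.shape[0]
    nt = tseg.shape[0]
    dth = 0.5 * dt
    root = 0  # topological order puts the root first
    max_defect = 0.0
    v_in = 0.0
    v_out = 0.0

    B = np.empty(n_cell)
    ccell = np.empty(n_cell)
    u = np.empty(n_cell)
    F2 = np.empty(n_cell)
    S2 = np.empty(n_cell)

    for k in range(n_steps):
        qmax = 0.0
        for c in range(n_cell):
            a = A[c]
            q = Q[c]
            if not (a > 0.0) or not np.isfinite(a) or not np.isfinite(q):
                return 1, max_defect, v_in, v_out
            i = seg_of_cell[c]
            if a < A_lo[i] or a > A_hi[i]:
                return 4, max_defect, v_in, v_out
            uu = q / a
            cc = _lut(ctab, i, a, A0, anorm0, dnorm, ntab)
            if (abs(uu) + cc) * dt > dx_cell[c]:
                return 2, max_defect, v_in, v_out
            B[c] = _lut(Btab, i, a, A0, anorm0, dnorm, ntab)
            u[c] = uu
            ccell[c] = cc
            F2[c] = q * uu + B[c]
            S2[c] = -fric * math.sqrt(a / math.pi) * uu
            if abs(q) > qmax:
                qmax = abs(q)

        # interior faces (Richtmyer half step)
        for i in range(n_seg):
            cs = cell_start[i]
            fs = face_start[i]
            dxi = dx_seg[i]
            for j in range(1, ncells[i]):
                L = cs + j - 1
                f = fs + j
                Afc[f] = 0.5 * (A[L] + A[L + 1]) - dth / dxi * (Q[L + 1] - Q[L])
                Qfc[f] = (0.5 * (Q[L] + Q[L + 1]) - dth / dxi * (F2[L + 1] - F2[L])
                          + 0.25 * dt * (S2[L] + S2[L + 1]))

        # inlet face: impose Q, solve A from the left-running characteristic
        c0 = cell_start[root]
        f_in = face_start[root]
        dxr = dx_seg[root]
        xf = (ccell[c0] - u[c0]) * dth
        if xf < 0.5 * dxr:
            xf = 0.5 * dxr
        elif xf > 1.5 * dxr:
            xf = 1.5 * dxr
        frac = (xf - 0.5 * dxr) / dxr
        a_f = (1.0 - frac) * A[c0] + frac * A[c0 + 1]
        q_f = (1.0 - frac) * Q[c0] + frac * Q[c0 + 1]
        w2 = q_f / a_f - _lut(Itab, root, a_f, A0, anorm0, dnorm, ntab)
        q_in = q_in_half[k]
        a = Afc[f_in]
        for _ in range(newton_maxiter):
            g = q_in / a - _lut(Itab, root, a, A0, anorm0, dnorm, ntab) - w2
            dg = -q_in / (a * a) - _lut(ctab, root, a, A0, anorm0, dnorm, ntab) / a
            step = g / dg
            a -= step
            if abs(step) < 1e-14 * a:
                break
        Afc[f_in] = a
        Qfc[f_in] = q_in

        # junction faces
        p_scale = 1.0e3
        for m in range(nt):
            if abs(wk_P[m]) > p_scale - 1.0e3:
                p_scale = 1.0e3 + abs(wk_P[m])
        q_scale = 1.0e-8 + qmax
        tol_accept = max(1.0e-11, 10.0 * newton_tol)
        for jn in range(nj):
            ip = jp[jn]
            i1 = jc1[jn]
            i2 = jc2[jn]
            pl = cell_start[ip] + ncells[ip] - 1
            c10 = cell_start[i1]
            c20 = cell_start[i2]

            # characteristic feet
            dxp = dx_seg[ip]
            xf = (u[pl] + ccell[pl]) * dth
            if xf < 0.5 * dxp:
                xf = 0.5 * dxp
            elif xf > 1.5 * dxp:
                xf = 1.5 * dxp
            frac = (xf - 0.5 * dxp) / dxp
            a_p = (1.0 - frac) * A[pl] + frac * A[pl - 1]
            q_p = (1.0 - frac) * Q[pl] + frac * Q[pl - 1]
            w1 = q_p / a_p + _lut(Itab, ip, a_p, A0, anorm0, dnorm, ntab)

            dx1 = dx_seg[i1]
            xf = (ccell[c10] - u[c10]) * dth
            if xf < 0.5 * dx1:
                xf = 0.5 * dx1
            elif xf > 1.5 * dx1:
                xf = 1.5 * dx1
            frac = (xf - 0.5 * dx1) / dx1
            a_1 = (1.0 - frac) * A[c10] + frac * A[c10 + 1]
            q_1 = (1.0 - frac) * Q[c10] + frac * Q[c10 + 1]
            w2_1 = q_1 / a_1 - _lut(Itab, i1, a_1, A0, anorm0, dnorm, ntab)

            dx2 = dx_seg[i2]
            xf = (ccell[c20] - u[c20]) * dth
            if xf < 0.5 * dx2:
                xf = 0.5 * dx2
            elif xf > 1.5 * dx2:
                xf = 1.5 * dx2
            frac = (xf - 0.5 * dx2) / dx2
            a_2 = (1.0 - frac) * A[c20] + frac * A[c20 + 1]
            q_2 = (1.0 - frac) * Q[c20] + frac * Q[c20 + 1]
            w2_2 = q_2 / a_2 - _lut(Itab, i2, a_2, A0, anorm0, dnorm, ntab)

            fp = face_start[ip] + ncells[ip]
            f1 = face_start[i1]
            f2 = face_start[i2]
            ap = Afc[fp]
            a1 = Afc[f1]
            a2 = Afc[f2]

            res = 1.0e300
            best = 1.0e300
            stall = 0
            for _ in range(newton_maxiter):
                ipI = _lut(Itab, ip, ap, A0, anorm0, dnorm, ntab)
                ipc = _lut(ctab, ip, ap, A0, anorm0, dnorm, ntab)
                i1I = _lut(Itab, i1, a1, A0, anorm0, dnorm, ntab)
                i1c = _lut(ctab, i1, a1, A0, anorm0, dnorm, ntab)
                i2I = _lut(Itab, i2, a2, A0, anorm0, dnorm, ntab)
                i2c = _lut(ctab, i2, a2, A0, anorm0, dnorm, ntab)
                qp = ap * (w1 - ipI)
                q1 = a1 * (w2_1 + i1I)
                q2 = a2 * (w2_2 + i2I)
                pp = _lut(Ptab, ip, ap, A0, anorm0, dnorm, ntab)
                p1 = _lut(Ptab, i1, a1, A0, anorm0, dnorm, ntab)
                p2 = _lut(Ptab, i2, a2, A0, anorm0, dnorm, ntab)
                dpp = _lut(dPtab, ip, ap, A0, anorm0, dnorm, ntab)
                dp1 = _lut(dPtab, i1, a1, A0, anorm0, dnorm, ntab)
                dp2 = _lut(dPtab, i2, a2, A0, anorm0, dnorm, ntab)
                r1 = (pp - p1) / p_scale
                r2 = (pp - p2) / p_scale
                r3 = (qp - q1 - q2) / q_scale
                res = abs(r1)
                if abs(r2) > res:
                    res = abs(r2)
                if abs(r3) > res:
                    res = abs(r3)
                if res < newton_tol:
                    break
                if res >= 0.5 * best:
                    stall += 1
                    if stall >= 3 and res < tol_accept:
                        break
                else:
                    stall = 0
                if res < best:
                    best = res
                a11 = dpp / p_scale
                a12 = -dp1 / p_scale
                a21 = dpp / p_scale
                a23 = -dp2 / p_scale
                a31 = (w1 - ipI - ipc) / q_scale
                a32 = -(w2_1 + i1I + i1c) / q_scale
                a33 = -(w2_2 + i2I + i2c) / q_scale
                det = -a11 * a23 * a32 - a12 * (a21 * a33 - a23 * a31)
                d1 = -r1 * a23 * a32 - a12 * (r2 * a33 - a23 * r3)
                d2 = a11 * (r2 * a33 - a23 * r3) - r1 * (a21 * a33 - a23 * a31)
                d3 = (-a11 * a32 * r2 - a12 * (a21 * r3 - r2 * a31)
                      + r1 * a21 * a32)
                ap -= d1 / det
                a1 -= d2 / det
                a2 -= d3 / det
            if not res < tol_accept:
                return 3, max_defect, v_in, v_out
            qp = ap * (w1 - _lut(Itab, ip, ap, A0, anorm0, dnorm, ntab))
            q1 = a1 * (w2_1 + _lut(Itab, i1, a1, A0, anorm0, dnorm, ntab))
            q2 = a2 * (w2_2 + _lut(Itab, i2, a2, A0, anorm0, dnorm, ntab))
            defect = abs(qp - q1 - q2) * 1.0e6  # m^3/s -> mL/s
            if defect > max_defect:
                max_defect = defect
            qp = q1 + q2  # exact mass closure
            Afc[fp] = ap
            Qfc[fp] = qp
            Afc[f1] = a1
            Qfc[f1] = q1
            Afc[f2] = a2
            Qfc[f2] = q2

        # terminal faces (implicit-Euler RCR coupled to the characteristic)
        for m in range(nt):
            i = tseg[m]
            tl = cell_start[i] + ncells[i] - 1
            ft = face_start[i] + ncells[i]
            dxt = dx_seg[i]
            xf = (u[tl] + ccell[tl]) * dth
            if xf < 0.5 * dxt:
                xf = 0.5 * dxt
            elif xf > 1.5 * dxt:
                xf = 1.5 * dxt
            frac = (xf - 0.5 * dxt) / dxt
            a_f = (1.0 - frac) * A[tl] + frac * A[tl - 1]
            q_f = (1.0 - frac) * Q[tl] + frac * Q[tl - 1]
            w1 = q_f / a_f + _lut(Itab, i, a_f, A0, anorm0, dnorm, ntab)

            tau = wk_tau[m]
            denom = 1.0 + dt / tau
            if zero_res[m]:
                dpdq = 0.0
            else:
                dpdq = (wk_R1[m] + dt * (wk_R1[m] + wk_R2[m]) / tau) / denom

            a = Afc[ft]
            for _ in range(newton_maxiter):
                i_t = _lut(Itab, i, a, A0, anorm0, dnorm, ntab)
                c_t = _lut(ctab, i, a, A0, anorm0, dnorm, ntab)
                q = a * (w1 - i_t)
                if zero_res[m]:
                    p_out = 0.0
                else:
                    p_out = (wk_P[m] + wk_R1[m] * (q - wk_Qprev[m])
                             + dt * q * (wk_R1[m] + wk_R2[m]) / tau) / denom
                g = _lut(Ptab, i, a, A0, anorm0, dnorm, ntab) - p_out
                dg = _lut(dPtab, i, a, A0, anorm0, dnorm, ntab) \
                    - dpdq * (w1 - i_t - c_t)
                step = g / dg
                a -= step
                if abs(step) < 1e-14 * a:
                    break
            q = a * (w1 - _lut(Itab, i, a, A0, anorm0, dnorm, ntab))
            if zero_res[m]:
                wk_P[m] = 0.0
            else:
                wk_P[m] = (wk_P[m] + wk_R1[m] * (q - wk_Qprev[m])
                           + dt * q * (wk_R1[m] + wk_R2[m]) / tau) / denom
            wk_Qprev[m] = q
            Afc[ft] = a
            Qfc[ft] = q

        # conservative cell update from face fluxes
        for i in range(n_seg):
            cs = cell_start[i]
            fs = face_start[i]
            dxi = dx_seg[i]
            nci = ncells[i]
            # face fluxes for this segment
            for j in range(nci):
                fl = fs + j
                fr = fs + j + 1
                afl = Afc[fl]
                afr = Afc[fr]
                qfl = Qfc[fl]
                qfr = Qfc[fr]
                F2l = qfl * qfl / afl + _lut(Btab, i, afl, A0, anorm0, dnorm, ntab)
                F2r = qfr * qfr / afr + _lut(Btab, i, afr, A0, anorm0, dnorm, ntab)
                S2l = -fric * math.sqrt(afl / math.pi) * qfl / afl
                S2r = -fric * math.sqrt(afr / math.pi) * qfr / afr
                c = cs + j
                A[c] = A[c] - dt / dxi * (qfr - qfl)
                Q[c] = Q[c] - dt / dxi * (F2r - F2l) + dth * (S2l + S2r)

        # record history and volume audit
        for c in range(n_cell):
            hist_A[k, c] = A[c]
            hist_Q[k, c] = Q[c]
        for f in range(Afc.shape[0]):
            hist_fA[k, f] = Afc[f]
            hist_fQ[k, f] = Qfc[f]
        v_in += Qfc[f_in] * dt
        for m in range(nt):
            v_out += Qfc[face_start[tseg[m]] + ncells[tseg[m]]] * dt

    return 0, max_defect, v_in, v_out
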