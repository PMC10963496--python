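"""Compiled time-stepping kernel for the 1D network solver.

Everything here works on flat arrays in CGS units. The network is packed
by the driver (:mod:`pulmo1d.solver`) into per-vessel node slices; one call
to :func:`advance_cycle` advances the full network state by one cardiac
cycle, writing every time level into the provided store arrays.

Interior scheme: Richtmyer two-step Lax-Wendroff on the conservative form

    d/dt [A, Q] + d/dx [Q, ac*Q^2/A + B(A;x)] = [0, S_fric + S_geom]

with ac = (gamma+2)/(gamma+1), the pressure-flux potential
B = (4*K/(9*rho)) * A^(3/2) / sqrt(A0(x)) obtained from the linear tube
law, friction S_fric = -2*pi*mu*(gamma+2)/rho * Q/A, and the geometric
source S_geom = (4*K/(9*rho)) * (A/A0)^(3/2) * dA0/dx that balances the
explicit x-dependence of B in tapered vessels. The discrete dA0/dx values
supplied by the driver are finite differences of the nodal A0, which makes
the rest state (A = A0, Q = 0) an exact discrete equilibrium.

Boundary and junction closure: each boundary node is treated as a half
cell whose continuity update uses the adjacent half-step (midpoint) flux
and the time-averaged boundary flow,

    A_b^{n+1} = A_b^n -+ (2*dt/dx) * ( Q_half_adjacent
                                       - (Q_b^n + Q_b^{n+1})/2 ),

so the boundary area is a linear function of the unknown boundary flow.
The remaining relations are physical: prescribed inlet flow, flow
conservation plus pressure continuity at bifurcations (2x2 Newton on the
daughter flows), and the implicit-Euler WK3 outlet relation (scalar
Newton). Because every coupling condition is imposed on the same
trapezoidal boundary fluxes that drive the half-cell updates, the scheme
conserves mass over a periodic cycle to Newton/convergence precision.
"""

import numpy as np
from numba import njit

# return flags from advance_cycle
OK = 0
ERR_CFL = 1
ERR_NEG_AREA = 2
ERR_NEWTON_INLET = 3
ERR_NEWTON_JUNCTION = 4
ERR_NEWTON_OUTLET = 5

_NEWTON_MAXIT = 50


@njit(cache=True, inline="always")
def _wave_speed(a, a0, k, rho):
    return np.sqrt((2.0 * k / (3.0 * rho)) * np.sqrt(a / a0))


@njit(cache=True, inline="always")
def _pressure(a, a0, k, pd):
    return (4.0 / 3.0) * k * (np.sqrt(a / a0) - 1.0) + pd


@njit(cache=True, inline="always")
def _dpda(a, a0, k):
    return (2.0 / 3.0) * k / np.sqrt(a * a0)


@njit(cache=True)
def advance_cycle(
    A,
    Q,
    Astore,
    Qstore,
    off,
    moff,
    dxs,
    Kv,
    A0,
    dA0,
    A0m,
    dA0m,
    gamma,
    rho,
    mu,
    pd,
    jp,
    jd1,
    jd2,
    tvi,
    Rp,
    Rd,
    Cw,
    pout,
    qin,
    dt,
):
    """Advance one cardiac cycle of ``steps = Astore.shape[0]`` time steps.

    Returns (flag, s_max) where s_max is the largest observed Courant
    number (|u|+c)*dt/dx. A and Q are updated in place; row k of the
    store arrays holds the state at t = (k+1)*dt.
    """
    nv = off.shape[0] - 1
    nn = A.shape[0]
    steps = Astore.shape[0]
    nj = jp.shape[0]
    nt = tvi.shape[0]

    ac = (gamma + 2.0) / (gamma + 1.0)
    fc = 2.0 * np.pi * mu * (gamma + 2.0) / rho  # friction: -fc*Q/A

    An = np.empty(nn)
    Qn = np.empty(nn)
    F2 = np.empty(nn)
    Ah = np.empty(moff[nv])
    Qh = np.empty(moff[nv])

    s_max = 0.0

    for k in range(steps):
        # ---- CFL monitor on current state -------------------------------
        for v in range(nv):
            kk = Kv[v]
            inv_dx = dt / dxs[v]
            for i in range(off[v], off[v + 1]):
                if A[i] <= 0.0:
                    return ERR_NEG_AREA, s_max
                c = _wave_speed(A[i], A0[i], kk, rho)
                s = (abs(Q[i] / A[i]) + c) * inv_dx
                if s > s_max:
                    s_max = s
        if s_max > 1.0:
            return ERR_CFL, s_max

        # ---- interior update (two-step Lax-Wendroff) --------------------
        for v in range(nv):
            i0 = off[v]
            i1 = off[v + 1]
            m0 = moff[v]
            kk = Kv[v]
            bcoef = 4.0 * kk / (9.0 * rho)
            dx = dxs[v]
            lam = dt / dx

            for i in range(i0, i1):
                F2[i] = ac * Q[i] * Q[i] / A[i] + bcoef * A[i] * np.sqrt(
                    A[i] / A0[i]
                )

            # half step at cell midpoints
            for j in range(i1 - i0 - 1):
                i = i0 + j
                m = m0 + j
                aavg = 0.5 * (A[i] + A[i + 1])
                qavg = 0.5 * (Q[i] + Q[i + 1])
                s2 = (
                    -fc * qavg / aavg
                    + bcoef * (aavg / A0m[m]) ** 1.5 * dA0m[m]
                )
                Ah[m] = aavg - 0.5 * lam * (Q[i + 1] - Q[i])
                Qh[m] = (
                    qavg - 0.5 * lam * (F2[i + 1] - F2[i]) + 0.5 * dt * s2
                )
                if Ah[m] <= 0.0:
                    return ERR_NEG_AREA, s_max

            # full step on interior nodes
            for j in range(1, i1 - i0 - 1):
                i = i0 + j
                m = m0 + j
                f2r = ac * Qh[m] * Qh[m] / Ah[m] + bcoef * Ah[m] * np.sqrt(
                    Ah[m] / A0m[m]
                )
                f2l = ac * Qh[m - 1] * Qh[m - 1] / Ah[m - 1] + bcoef * Ah[
                    m - 1
                ] * np.sqrt(Ah[m - 1] / A0m[m - 1])
                aavg = 0.5 * (Ah[m] + Ah[m - 1])
                qavg = 0.5 * (Qh[m] + Qh[m - 1])
                # the distension ratio is measured against the average of
                # the midpoint reference areas (== aavg at rest), so the
                # geometric source balances the flux difference exactly
                # in equilibrium even for tapered vessels
                a0avg = 0.5 * (A0m[m] + A0m[m - 1])
                s2 = (
                    -fc * qavg / aavg
                    + bcoef * (aavg / a0avg) ** 1.5 * dA0[i]
                )
                An[i] = A[i] - lam * (Qh[m] - Qh[m - 1])
                Qn[i] = Q[i] - lam * (f2r - f2l) + dt * s2
                if An[i] <= 0.0:
                    return ERR_NEG_AREA, s_max

        # ---- inlet (root vessel, node 0): prescribed flow ---------------
        # half-cell continuity with the trapezoidal boundary flux
        i0 = off[0]
        q_mid = 0.5 * (qin[k] + qin[k + 1])
        An[i0] = A[i0] - (2.0 * dt / dxs[0]) * (Qh[moff[0]] - q_mid)
        Qn[i0] = qin[k + 1]
        if An[i0] <= 0.0:
            return ERR_NEWTON_INLET, s_max

        # ---- junctions: continuity + mass + pressure continuity ---------
        for jj in range(nj):
            vp = jp[jj]
            v1 = jd1[jj]
            v2 = jd2[jj]
            ip = off[vp + 1] - 1
            ia = off[v1]
            ib = off[v2]
            kp = Kv[vp]
            k1 = Kv[v1]
            k2 = Kv[v2]

            # A_parent = cp0 - kap*(Q1+Q2); A_daughter = cd0 + kad*Qd
            kap = dt / dxs[vp]
            ka1 = dt / dxs[v1]
            ka2 = dt / dxs[v2]
            cp0 = A[ip] + 2.0 * kap * Qh[moff[vp + 1] - 1] - kap * Q[ip]
            c10 = A[ia] - 2.0 * ka1 * Qh[moff[v1]] + ka1 * Q[ia]
            c20 = A[ib] - 2.0 * ka2 * Qh[moff[v2]] + ka2 * Q[ib]

            q1 = Q[ia]
            q2 = Q[ib]
            ok = False
            for _ in range(_NEWTON_MAXIT):
                ap = cp0 - kap * (q1 + q2)
                a1 = c10 + ka1 * q1
                a2 = c20 + ka2 * q2
                if ap <= 0.0 or a1 <= 0.0 or a2 <= 0.0:
                    return ERR_NEG_AREA, s_max
                pp = _pressure(ap, A0[ip], kp, pd)
                p1 = _pressure(a1, A0[ia], k1, pd)
                p2 = _pressure(a2, A0[ib], k2, pd)
                r1 = pp - p1
                r2 = pp - p2
                ps = abs(pp) + 1.0
                if abs(r1) < 1.0e-12 * ps and abs(r2) < 1.0e-12 * ps:
                    ok = True
                    break
                dpp = _dpda(ap, A0[ip], kp)
                dp1 = _dpda(a1, A0[ia], k1)
                dp2 = _dpda(a2, A0[ib], k2)
                # J = [[-kap*dpp - ka1*dp1, -kap*dpp],
                #      [-kap*dpp, -kap*dpp - ka2*dp2]]; solve J d = -r
                j11 = -kap * dpp - ka1 * dp1
                j12 = -kap * dpp
                j22 = -kap * dpp - ka2 * dp2
                det = j11 * j22 - j12 * j12
                if det == 0.0:
                    break
                d1 = (-r1 * j22 + r2 * j12) / det
                d2 = (-r2 * j11 + r1 * j12) / det
                q1 += d1
                q2 += d2
            if not ok:
                return ERR_NEWTON_JUNCTION, s_max
            An[ip] = cp0 - kap * (q1 + q2)
            Qn[ip] = q1 + q2
            An[ia] = c10 + ka1 * q1
            Qn[ia] = q1
            An[ib] = c20 + ka2 * q2
            Qn[ib] = q2

        # ---- Windkessel outlets -----------------------------------------
        for tt in range(nt):
            v = tvi[tt]
            ie = off[v + 1] - 1
            kk = Kv[v]
            kae = dt / dxs[v]
            ce0 = A[ie] + 2.0 * kae * Qh[moff[v + 1] - 1] - kae * Q[ie]

            rp = Rp[tt]
            rd = Rd[tt]
            cw = Cw[tt]
            beta = rd * cw / dt
            denom = 1.0 + beta
            rq = (rp + rd + rp * beta) / denom
            p_old = _pressure(A[ie], A0[ie], kk, pd) - pout
            q_old = Q[ie]
            # implicit-Euler WK3: p_new = (beta*p_old - rp*beta*q_old)/denom
            #                             + rq*q_new
            p_hist = (beta * p_old - rp * beta * q_old) / denom

            qe = Q[ie]
            ok = False
            for _ in range(_NEWTON_MAXIT):
                a = ce0 - kae * qe
                if a <= 0.0:
                    return ERR_NEG_AREA, s_max
                pe = _pressure(a, A0[ie], kk, pd)
                g = pe - pout - p_hist - rq * qe
                # scale includes the absolute pressure level: g is a small
                # difference of large tube-law terms
                ps = abs(pe) + abs(p_hist) + abs(rq * qe) + 1.0
                if abs(g) < 1.0e-11 * ps:
                    ok = True
                    break
                dg = -kae * _dpda(a, A0[ie], kk) - rq
                qe -= g / dg
            if not ok:
                return ERR_NEWTON_OUTLET, s_max
            An[ie] = ce0 - kae * qe
            Qn[ie] = qe

        # ---- commit -----------------------------------------------------
        for i in range(nn):
            A[i] = An[i]
            Q[i] = Qn[i]
            Astore[k, i] = An[i]
            Qstore[k, i] = Qn[i]

    return OK, s_max
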