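"""Compiled kernels for the 1D proximal solver.

Everything here operates on flat arrays prepared by :mod:`pulmuq.solver`:
vessel states are concatenated node-wise, boundary structures are encoded as
integer index arrays, and one call advances the full network by one cardiac
cycle.  The scheme is Richtmyer two-step Lax-Wendroff on the conservative
form with flux

    F = (q,  (g+2)/(g+1) q^2/A + B(A)/rho),   B(A) = (f/3) A^{3/2} / sqrt(A0)

(f = 4K/3 is the wall coefficient, so dB/dA = A dp/dA and the pressure
gradient term is exactly conservative within a uniform vessel) and source
S = (0, -2 pi nu (g+2) q/A).  Boundary and junction closures use outgoing
Riemann-invariant extrapolation W+- = u +- 4c evaluated at the characteristic
foot, combined with the physical constraint (prescribed flow, prescribed
pressure, or junction continuity) via damped Newton iteration.

Status codes returned by ``advance_cycle``: 0 ok, 1 CFL violation,
2 nonphysical state (NaN / nonpositive area), 3 Newton failure.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_CFL = 1
STATUS_NONPHYSICAL = 2
STATUS_NEWTON = 3


@njit(cache=True, fastmath=False)
def _wave_speed(A, A0, f, rho):
    return np.sqrt(0.5 * f / rho * np.sqrt(A / A0))


@njit(cache=True, fastmath=False)
def _pressure(A, A0, f):
    return f * (np.sqrt(A / A0) - 1.0)


@njit(cache=True, fastmath=False)
def _foot_invariant(Aa, qa, Ab, qb, A0, f, rho, dt, dx, sign, fric):
    """Outgoing invariant at the characteristic foot next to a boundary node.

    (Aa, qa) is the boundary node, (Ab, qb) its interior neighbour, both at
    the old time level.  sign=+1 for an x=L end (invariant u + 4c leaving
    through x=L), sign=-1 for an x=0 end (u - 4c leaving through x=0).
    The invariant is advanced by the friction source along the
    characteristic, d(u +- 4c)/dt = fric * u / A with fric = -2 pi nu (g+2);
    omitting it biases steady pressure drops at first order in dx.
    """
    ua = qa / Aa
    ca = _wave_speed(Aa, A0, f, rho)
    lam = ua + sign * ca
    xi = sign * lam * dt / dx
    if xi < 0.0:
        xi = 0.0
    elif xi > 1.0:
        xi = 1.0
    Af = (1.0 - xi) * Aa + xi * Ab
    qf = (1.0 - xi) * qa + xi * qb
    uf = qf / Af
    cf = _wave_speed(Af, A0, f, rho)
    return uf + sign * 4.0 * cf + dt * fric * uf / Af


@njit(cache=True, fastmath=False)
def _solve_prescribed_q(qb, W, A0, f, rho, Aguess, sign):
    """Area at an end with prescribed flow: qb/A + sign*4c(A) = W."""
    A = Aguess
    for _ in range(60):
        c = _wave_speed(A, A0, f, rho)
        g = qb / A + sign * 4.0 * c - W
        dg = -qb / (A * A) + sign * c / A
        if dg == 0.0:
            break
        step = -g / dg
        # keep the iterate physical
        if A + step < 0.05 * A0:
            step = 0.05 * A0 - A
        A += step
        if abs(g) < 1e-12 * (abs(W) + 1.0) and abs(step) < 1e-12 * A0 + 1e-14:
            return A
    c = _wave_speed(A, A0, f, rho)
    if abs(qb / A + sign * 4.0 * c - W) < 1e-9 * (abs(W) + 1.0):
        return A
    return -1.0


@njit(cache=True, fastmath=False)
def _solve_q_pressure(qhist, gcoef, W, A0, f, rho, Aguess, sign):
    """Area at an end whose flow depends on its own new pressure.

    Solves (qhist + gcoef * p(A))/A + sign*4c(A) = W.  This makes the
    instantaneous (tau = 0) tap of the admittance convolution implicit, which
    is required for stability of the structured-tree coupling; gcoef is the
    zero-lag kernel weight (signed for the port orientation).
    """
    A = Aguess
    for _ in range(60):
        c = _wave_speed(A, A0, f, rho)
        p = _pressure(A, A0, f)
        qb = qhist + gcoef * p
        g = qb / A + sign * 4.0 * c - W
        dpdA = f / (2.0 * np.sqrt(A * A0))
        dg = (gcoef * dpdA * A - qb) / (A * A) + sign * c / A
        if dg == 0.0:
            break
        step = -g / dg
        if A + step < 0.05 * A0:
            step = 0.05 * A0 - A
        elif A + step > 30.0 * A0:
            step = 30.0 * A0 - A
        A += step
        if abs(g) < 1e-12 * (abs(W) + 1.0) and abs(step) < 1e-12 * A0 + 1e-14:
            return A
    # bisection fallback on a wide physical bracket
    lo = 0.05 * A0
    hi = 30.0 * A0

    def _g(Ax):
        cx = _wave_speed(Ax, A0, f, rho)
        return (qhist + gcoef * _pressure(Ax, A0, f)) / Ax + sign * 4.0 * cx - W

    glo = _g(lo)
    ghi = _g(hi)
    if glo * ghi > 0.0:
        return -1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        gm = _g(mid)
        if glo * gm <= 0.0:
            hi = mid
            ghi = gm
        else:
            lo = mid
            glo = gm
        if hi - lo < 1e-13 * A0:
            break
    A = 0.5 * (lo + hi)
    if abs(_g(A)) < 1e-8 * (abs(W) + 1.0):
        return A
    return -1.0


@njit(cache=True, fastmath=False)
def _solve_junction(W, A0s, fs, rho, sgn, Aout):
    """Junction of three vessel ends: mass balance + static-pressure continuity.

    For end k: u_k = W_k - sgn_k*4c(A_k); flow into the junction node is
    sgn_k * A_k u_k (sgn=+1 for an x=L end, -1 for an x=0 end).  Solves
    sum_k sgn_k A_k u_k = 0,  p_0(A_0) = p_1(A_1) = p_2(A_2)
    by damped Newton on (A_0, A_1, A_2); returns True on convergence.
    """
    A = Aout  # modified in place; seeded with current boundary areas
    q = np.empty(3)
    dq = np.empty(3)
    p = np.empty(3)
    dp = np.empty(3)
    d = np.empty(3)
    for it in range(60):
        for k in range(3):
            c = _wave_speed(A[k], A0s[k], fs[k], rho)
            u = W[k] - sgn[k] * 4.0 * c
            q[k] = sgn[k] * A[k] * u
            # d(Au)/dA = u - sgn*A*(dc4/dA) = u - sgn*c
            dq[k] = sgn[k] * (u - sgn[k] * c)
            p[k] = _pressure(A[k], A0s[k], fs[k])
            dp[k] = fs[k] / (2.0 * np.sqrt(A[k] * A0s[k]))
        F0 = q[0] + q[1] + q[2]
        F1 = p[0] - p[1]
        F2 = p[0] - p[2]
        # u = W -+ 4c cancels two large terms, so the flow residual has a
        # machine-noise floor on the A*|W| scale
        qsc = abs(q[0]) + abs(q[1]) + abs(q[2]) + 1e-8
        noise = 1e-13 * (
            A[0] * abs(W[0]) + A[1] * abs(W[1]) + A[2] * abs(W[2])
        )
        psc = 1e-8 * fs[0]  # ~1e-8 relative on the wall-law pressure scale
        if abs(F0) < 1e-11 * qsc + noise and abs(F1) < psc and abs(F2) < psc:
            return True
        # Jacobian rows: [dq0, dq1, dq2], [dp0, -dp1, 0], [dp0, 0, -dp2]
        a11, a12, a13 = dq[0], dq[1], dq[2]
        a21, a22 = dp[0], -dp[1]
        a31, a33 = dp[0], -dp[2]
        # solve 3x3 (sparse pattern) by elimination
        det = a11 * a22 * a33 - a12 * a21 * a33 - a13 * a31 * a22
        if det == 0.0 or a22 == 0.0 or a33 == 0.0:
            return False
        d[0] = (-F0 * a22 * a33 + F1 * a12 * a33 + F2 * a13 * a22) / det
        d[1] = (-F1 - a21 * d[0]) / a22
        d[2] = (-F2 - a31 * d[0]) / a33
        # damped update with positivity clamp
        scale = 1.0
        for k in range(3):
            if d[k] != 0.0 and A[k] + scale * d[k] < 0.05 * A0s[k]:
                scale = min(scale, (0.05 * A0s[k] - A[k]) / d[k])
        for k in range(3):
            A[k] += scale * d[k]
    return False


@njit(cache=True, fastmath=False)
def advance_cycle(
    A,
    q,
    offsets,
    nnod,
    A0v,
    fv,
    dxv,
    rho,
    nu,
    gamma,
    dt,
    n_steps,
    step0,
    qin,
    pla,
    inlet_v,
    outlet_v,
    junc_v,
    junc_end,
    pair_art,
    pair_vein,
    kern,
    ring_pA,
    ring_pV,
    P_out,
    Q_out,
    A_out,
):
    """Advance the whole network by one cycle of ``n_steps`` time steps.

    Rows s of the output arrays hold the state at local time (s+1)*dt.
    Returns (status, cfl_max, offending_vessel).
    """
    nv = offsets.size - 1
    N = offsets[nv]
    npair = pair_art.size
    nj = junc_v.shape[0]
    M = kern.shape[3]
    stride = n_steps // M
    dtau = (n_steps * dt) / M
    fac = (gamma + 2.0) / (gamma + 1.0)
    fric = -2.0 * np.pi * nu * (gamma + 2.0)

    Aold = np.empty(N)
    qold = np.empty(N)
    Ah = np.empty(N)
    qh = np.empty(N)
    cfl_max = 0.0
    bad_vessel = -1

    for step in range(n_steps):
        gstep = step0 + step
        pos = gstep % n_steps  # ring index of the old time level

        for i in range(N):
            Aold[i] = A[i]
            qold[i] = q[i]

        # --- interior Lax-Wendroff update -------------------------------
        for v in range(nv):
            i0 = offsets[v]
            n = nnod[v]
            A0 = A0v[v]
            f = fv[v]
            dx = dxv[v]
            bcoef = f / (3.0 * np.sqrt(A0))
            lmax = 0.0
            for jj in range(n):
                Aj = Aold[i0 + jj]
                if not (Aj > 0.0) or not np.isfinite(Aj):
                    return STATUS_NONPHYSICAL, cfl_max, v
                sp = abs(qold[i0 + jj] / Aj) + _wave_speed(Aj, A0, f, rho)
                if sp > lmax:
                    lmax = sp
            courant = lmax * dt / dx
            if courant > cfl_max:
                cfl_max = courant
            if courant >= 1.0:
                return STATUS_CFL, cfl_max, v
            for jj in range(n - 1):
                Al = Aold[i0 + jj]
                ql = qold[i0 + jj]
                Ar = Aold[i0 + jj + 1]
                qr = qold[i0 + jj + 1]
                F2l = fac * ql * ql / Al + bcoef * Al * np.sqrt(Al) / rho
                F2r = fac * qr * qr / Ar + bcoef * Ar * np.sqrt(Ar) / rho
                S2l = fric * ql / Al
                S2r = fric * qr / Ar
                Ah[i0 + jj] = 0.5 * (Al + Ar) - 0.5 * dt / dx * (qr - ql)
                qh[i0 + jj] = (
                    0.5 * (ql + qr)
                    - 0.5 * dt / dx * (F2r - F2l)
                    + 0.25 * dt * (S2l + S2r)
                )
                if not (Ah[i0 + jj] > 0.0):
                    return STATUS_NONPHYSICAL, cfl_max, v
            for jj in range(1, n - 1):
                Alh = Ah[i0 + jj - 1]
                qlh = qh[i0 + jj - 1]
                Arh = Ah[i0 + jj]
                qrh = qh[i0 + jj]
                F2l = fac * qlh * qlh / Alh + bcoef * Alh * np.sqrt(Alh) / rho
                F2r = fac * qrh * qrh / Arh + bcoef * Arh * np.sqrt(Arh) / rho
                S2l = fric * qlh / Alh
                S2r = fric * qrh / Arh
                A[i0 + jj] = Aold[i0 + jj] - dt / dx * (qrh - qlh)
                q[i0 + jj] = (
                    qold[i0 + jj] - dt / dx * (F2r - F2l) + 0.5 * dt * (S2l + S2r)
                )

        # --- inflow boundary (prescribed q at x=0 of the inlet vessel) ---
        v = inlet_v
        i0 = offsets[v]
        qb = qin[(gstep + 1) % n_steps]
        W = _foot_invariant(
            Aold[i0], qold[i0], Aold[i0 + 1], qold[i0 + 1],
            A0v[v], fv[v], rho, dt, dxv[v], -1.0, fric,
        )
        Anew = _solve_prescribed_q(qb, W, A0v[v], fv[v], rho, Aold[i0], -1.0)
        if Anew <= 0.0:
            return STATUS_NEWTON, cfl_max, v
        A[i0] = Anew
        q[i0] = qb

        # --- junctions ---------------------------------------------------
        Wj = np.empty(3)
        A0j = np.empty(3)
        fj = np.empty(3)
        sgnj = np.empty(3)
        Aj3 = np.empty(3)
        for jn in range(nj):
            for k in range(3):
                v = junc_v[jn, k]
                i0 = offsets[v]
                n = nnod[v]
                if junc_end[jn, k] == 1:  # x = L end
                    ia = i0 + n - 1
                    ib = i0 + n - 2
                    sgn = 1.0
                else:
                    ia = i0
                    ib = i0 + 1
                    sgn = -1.0
                Wj[k] = _foot_invariant(
                    Aold[ia], qold[ia], Aold[ib], qold[ib],
                    A0v[v], fv[v], rho, dt, dxv[v], sgn, fric,
                )
                A0j[k] = A0v[v]
                fj[k] = fv[v]
                sgnj[k] = sgn
                Aj3[k] = Aold[ia]
            ok = _solve_junction(Wj, A0j, fj, rho, sgnj, Aj3)
            if not ok:
                return STATUS_NEWTON, cfl_max, junc_v[jn, 0]
            # ends 1 and 2 from the characteristics; end 0 balances mass
            # exactly (k=0 is the single end on its side of the junction)
            qsum = 0.0
            for k in range(3):
                v = junc_v[jn, k]
                i0 = offsets[v]
                n = nnod[v]
                c = _wave_speed(Aj3[k], A0j[k], fj[k], rho)
                u = Wj[k] - sgnj[k] * 4.0 * c
                qk = Aj3[k] * u if k > 0 else 0.0
                qsum += sgnj[k] * qk
                idx = i0 + n - 1 if junc_end[jn, k] == 1 else i0
                A[idx] = Aj3[k]
                q[idx] = qk
            v = junc_v[jn, 0]
            i0 = offsets[v]
            n = nnod[v]
            idx = i0 + n - 1 if junc_end[jn, 0] == 1 else i0
            q[idx] = -sgnj[0] * qsum

        # --- structured-tree coupling at the terminal pairs --------------
        # q(t^{n+1}) = sum_m y(m dtau) p(t^{n+1} - m dtau) dtau: lags m >= 1
        # come from the ring history, the zero-lag own-port term is implicit
        # in the boundary Newton (stability), the zero-lag cross-port term is
        # lagged by one dt.
        for pp in range(npair):
            qa = kern[pp, 0, 1, 0] * ring_pV[pp, pos]
            qv = kern[pp, 1, 0, 0] * ring_pA[pp, pos]
            for m in range(1, M):
                idx = (pos + 1 - m * stride) % n_steps
                pa = ring_pA[pp, idx]
                pv = ring_pV[pp, idx]
                qa += kern[pp, 0, 0, m] * pa + kern[pp, 0, 1, m] * pv
                qv += kern[pp, 1, 0, m] * pa + kern[pp, 1, 1, m] * pv
            qa *= dtau
            qv *= -dtau  # vein flow is out of the bed (toward the atrium)

            va = pair_art[pp]
            i0 = offsets[va]
            n = nnod[va]
            ia = i0 + n - 1
            W = _foot_invariant(
                Aold[ia], qold[ia], Aold[ia - 1], qold[ia - 1],
                A0v[va], fv[va], rho, dt, dxv[va], 1.0, fric,
            )
            ga = kern[pp, 0, 0, 0] * dtau
            Anew = _solve_q_pressure(qa, ga, W, A0v[va], fv[va], rho, Aold[ia], 1.0)
            if Anew <= 0.0:
                return STATUS_NEWTON, cfl_max, va
            A[ia] = Anew
            q[ia] = qa + ga * _pressure(Anew, A0v[va], fv[va])

            vv = pair_vein[pp]
            i0 = offsets[vv]
            W = _foot_invariant(
                Aold[i0], qold[i0], Aold[i0 + 1], qold[i0 + 1],
                A0v[vv], fv[vv], rho, dt, dxv[vv], -1.0, fric,
            )
            gv = -kern[pp, 1, 1, 0] * dtau
            Anew = _solve_q_pressure(qv, gv, W, A0v[vv], fv[vv], rho, Aold[i0], -1.0)
            if Anew <= 0.0:
                return STATUS_NEWTON, cfl_max, vv
            A[i0] = Anew
            q[i0] = qv + gv * _pressure(Anew, A0v[vv], fv[vv])

        # --- left-atrial pressure at the venous outlets (x = L) ----------
        pb = pla[(gstep + 1) % n_steps]
        for oo in range(outlet_v.size):
            v = outlet_v[oo]
            i0 = offsets[v]
            n = nnod[v]
            ia = i0 + n - 1
            Ab = A0v[v] * (1.0 + pb / fv[v]) ** 2
            W = _foot_invariant(
                Aold[ia], qold[ia], Aold[ia - 1], qold[ia - 1],
                A0v[v], fv[v], rho, dt, dxv[v], 1.0, fric,
            )
            A[ia] = Ab
            q[ia] = Ab * (W - 4.0 * _wave_speed(Ab, A0v[v], fv[v], rho))

        # --- push new terminal pressures into the ring buffers -----------
        newpos = (gstep + 1) % n_steps
        for pp in range(npair):
            va = pair_art[pp]
            ia = offsets[va] + nnod[va] - 1
            ring_pA[pp, newpos] = _pressure(A[ia], A0v[va], fv[va])
            vv = pair_vein[pp]
            iv = offsets[vv]
            ring_pV[pp, newpos] = _pressure(A[iv], A0v[vv], fv[vv])

        # --- record ------------------------------------------------------
        for v in range(nv):
            i0 = offsets[v]
            for jj in range(nnod[v]):
                A_out[step, i0 + jj] = A[i0 + jj]
                Q_out[step, i0 + jj] = q[i0 + jj]
                P_out[step, i0 + jj] = _pressure(A[i0 + jj], A0v[v], fv[v])

    return STATUS_OK, cfl_max, bad_vessel
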