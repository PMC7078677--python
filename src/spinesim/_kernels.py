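"""Numba-compiled inner kernels for the membrane force and RK4 integrator.

The membrane force is the exact analytic gradient of the *discretized*
energy

    E = P * Omega + tau * S + 2 kappa * sum_k H_k^2 ds_k

with the shoelace area Omega, perimeter S, circumradius curvature
H_k = 2 cross(e1, e2) / (L1 L2 L3) and arc weight ds_k = (L1 + L2) / 2
(notation: e1 = x_k - x_{k-1}, e2 = x_{k+1} - x_k, e3 = x_{k+1} - x_{k-1}).
Keeping force and energy consistent at the discrete level makes the force
checkable against finite differences of the energy to round-off-limited
accuracy.

These kernels are hot: a 90-minute simulation evaluates the force a few
million times on ~100-vertex meshes.
"""

import numba
import numpy as np

__all__ = ["membrane_force_kernel", "rk4_substep", "advance_interval"]


@numba.njit(cache=True, fastmath=True)
def _force_into(pos, P, tau, kappa, out, work):  # pragma: no cover - compiled
    """Write the membrane force (negative energy gradient) into *out*.

    *work* is an (n, 4) scratch array holding per-edge quantities
    (ex, ey, 1/L, L) for edge k -> k+1; edge lengths are shared between the
    two incident vertex stencils (and e3 = e1 + e2), which roughly halves
    the sqrt/division count of a naive per-vertex evaluation.
    """
    n = pos.shape[0]
    grad = out
    for k in range(n):
        grad[k, 0] = 0.0
        grad[k, 1] = 0.0

    for k in range(n):
        kn = k + 1 if k < n - 1 else 0
        ex = pos[kn, 0] - pos[k, 0]
        ey = pos[kn, 1] - pos[k, 1]
        L = np.sqrt(ex * ex + ey * ey)
        work[k, 0] = ex
        work[k, 1] = ey
        work[k, 2] = 1.0 / L if L > 0.0 else 0.0
        work[k, 3] = L

    for k in range(n):
        kp = k - 1 if k > 0 else n - 1
        kn = k + 1 if k < n - 1 else 0

        # pressure: d(P*Omega)/dx_k with shoelace Omega
        grad[k, 0] += P * 0.5 * (pos[kn, 1] - pos[kp, 1])
        grad[k, 1] += P * 0.5 * (pos[kp, 0] - pos[kn, 0])

        e1x = work[kp, 0]
        e1y = work[kp, 1]
        inv1 = work[kp, 2]
        L1 = work[kp, 3]
        e2x = work[k, 0]
        e2y = work[k, 1]
        inv2 = work[k, 2]
        L2 = work[k, 3]

        # tension: d(tau*S)/dx_k = tau * (e1/L1 - e2/L2)
        grad[k, 0] += tau * (e1x * inv1 - e2x * inv2)
        grad[k, 1] += tau * (e1y * inv1 - e2y * inv2)

        # bending term T_k = 4 kappa cross^2 (L1+L2) / (L1^2 L2^2 L3^2),
        # scattered onto x_{k-1}, x_k, x_{k+1} by the chain rule.
        if kappa > 0.0 and L1 > 0.0 and L2 > 0.0:
            e3x = e1x + e2x
            e3y = e1y + e2y
            L3sq = e3x * e3x + e3y * e3y
            if L3sq > 0.0:
                L3 = np.sqrt(L3sq)
                inv3 = 1.0 / L3
                cr = e1x * e2y - e1y * e2x
                inv = (inv1 * inv1) * (inv2 * inv2) * (inv3 * inv3)
                s12 = L1 + L2
                dT_dcr = 8.0 * kappa * cr * s12 * inv
                common = 4.0 * kappa * cr * cr * inv
                dT_dL1 = common * (1.0 - 2.0 * s12 * inv1)
                dT_dL2 = common * (1.0 - 2.0 * s12 * inv2)
                dT_dL3 = common * (-2.0 * s12 * inv3)

                g1x = dT_dcr * e2y + dT_dL1 * e1x * inv1
                g1y = -dT_dcr * e2x + dT_dL1 * e1y * inv1
                g2x = -dT_dcr * e1y + dT_dL2 * e2x * inv2
                g2y = dT_dcr * e1x + dT_dL2 * e2y * inv2
                g3x = dT_dL3 * e3x * inv3
                g3y = dT_dL3 * e3y * inv3

                grad[kp, 0] += -g1x - g3x
                grad[kp, 1] += -g1y - g3y
                grad[k, 0] += g1x - g2x
                grad[k, 1] += g1y - g2y
                grad[kn, 0] += g2x + g3x
                grad[kn, 1] += g2y + g3y

    for k in range(n):
        grad[k, 0] = -grad[k, 0]
        grad[k, 1] = -grad[k, 1]


@numba.njit(cache=True, fastmath=False)
def membrane_force_kernel(pos, P, tau, kappa):  # pragma: no cover - compiled
    out = np.empty_like(pos)
    work = np.empty((pos.shape[0], 4))
    _force_into(pos, P, tau, kappa, out, work)
    return out


@numba.njit(cache=True, fastmath=False)
def rk4_substep(pos, free, f_fil, h, zeta, P, tau, kappa):  # pragma: no cover
    """One classical RK4 step of dx/dt = zeta*(F_mem(x) + F_fil).

    F_mem is re-evaluated at every stage; F_fil is held constant.  Fixed
    vertices (``free == False``) do not move.  Returns the new positions and
    the maximum displacement of any free vertex.
    """
    n = pos.shape[0]

    k1 = zeta * (membrane_force_kernel(pos, P, tau, kappa) + f_fil)
    for i in range(n):
        if not free[i]:
            k1[i, 0] = 0.0
            k1[i, 1] = 0.0
    k2 = zeta * (membrane_force_kernel(pos + 0.5 * h * k1, P, tau, kappa) + f_fil)
    for i in range(n):
        if not free[i]:
            k2[i, 0] = 0.0
            k2[i, 1] = 0.0
    k3 = zeta * (membrane_force_kernel(pos + 0.5 * h * k2, P, tau, kappa) + f_fil)
    for i in range(n):
        if not free[i]:
            k3[i, 0] = 0.0
            k3[i, 1] = 0.0
    k4 = zeta * (membrane_force_kernel(pos + h * k3, P, tau, kappa) + f_fil)

    new = np.empty_like(pos)
    maxdisp = 0.0
    for i in range(n):
        if free[i]:
            dx = h / 6.0 * (k1[i, 0] + 2.0 * k2[i, 0] + 2.0 * k3[i, 0] + k4[i, 0])
            dy = h / 6.0 * (k1[i, 1] + 2.0 * k2[i, 1] + 2.0 * k3[i, 1] + k4[i, 1])
            new[i, 0] = pos[i, 0] + dx
            new[i, 1] = pos[i, 1] + dy
            d = np.sqrt(dx * dx + dy * dy)
            if d > maxdisp:
                maxdisp = d
        else:
            new[i, 0] = pos[i, 0]
            new[i, 1] = pos[i, 1]
    return new, maxdisp


@numba.njit(cache=True, fastmath=True)
def advance_interval(pos, free, f_fil, dt, d_tol, zeta, P, tau, kappa,
                     max_halvings):  # pragma: no cover - compiled
    """Adaptive integration of one tick of length *dt*.

    Sub-steps are halved until no free vertex moves farther than d_tol
    within a sub-step, and doubled again after 8 consecutive acceptances.
    The stage-1 force is reused across rejected attempts (the position has
    not changed), and all stage buffers are allocated once.  Returns
    (positions, status); status 0 = ok, 1 = the sub-step fell below
    dt / 2**max_halvings (stability failure).
    """
    n = pos.shape[0]
    cur = pos.copy()
    f1 = np.empty((n, 2))
    fs = np.empty((n, 2))
    work = np.empty((n, 4))
    stage = np.empty((n, 2))
    trial = np.empty((n, 2))
    k_acc = np.empty((n, 2))

    remaining = dt
    h = dt
    h_floor = dt / 2.0 ** max_halvings
    f1_valid = False
    consec = 0
    while remaining > 1e-12 * dt:
        if h > remaining:
            h = remaining
        if not f1_valid:
            _force_into(cur, P, tau, kappa, f1, work)
            f1_valid = True

        # stage 1
        for i in range(n):
            if free[i]:
                kx = zeta * (f1[i, 0] + f_fil[i, 0])
                ky = zeta * (f1[i, 1] + f_fil[i, 1])
            else:
                kx = 0.0
                ky = 0.0
            k_acc[i, 0] = kx
            k_acc[i, 1] = ky
            stage[i, 0] = cur[i, 0] + 0.5 * h * kx
            stage[i, 1] = cur[i, 1] + 0.5 * h * ky
        _force_into(stage, P, tau, kappa, fs, work)
        # stage 2
        for i in range(n):
            if free[i]:
                kx = zeta * (fs[i, 0] + f_fil[i, 0])
                ky = zeta * (fs[i, 1] + f_fil[i, 1])
            else:
                kx = 0.0
                ky = 0.0
            k_acc[i, 0] += 2.0 * kx
            k_acc[i, 1] += 2.0 * ky
            stage[i, 0] = cur[i, 0] + 0.5 * h * kx
            stage[i, 1] = cur[i, 1] + 0.5 * h * ky
        _force_into(stage, P, tau, kappa, fs, work)
        # stage 3
        for i in range(n):
            if free[i]:
                kx = zeta * (fs[i, 0] + f_fil[i, 0])
                ky = zeta * (fs[i, 1] + f_fil[i, 1])
            else:
                kx = 0.0
                ky = 0.0
            k_acc[i, 0] += 2.0 * kx
            k_acc[i, 1] += 2.0 * ky
            stage[i, 0] = cur[i, 0] + h * kx
            stage[i, 1] = cur[i, 1] + h * ky
        _force_into(stage, P, tau, kappa, fs, work)
        # stage 4 and trial position
        maxdisp = 0.0
        for i in range(n):
            if free[i]:
                kx = zeta * (fs[i, 0] + f_fil[i, 0])
                ky = zeta * (fs[i, 1] + f_fil[i, 1])
                dx = h / 6.0 * (k_acc[i, 0] + kx)
                dy = h / 6.0 * (k_acc[i, 1] + ky)
                trial[i, 0] = cur[i, 0] + dx
                trial[i, 1] = cur[i, 1] + dy
                d2 = dx * dx + dy * dy
                if d2 > maxdisp:
                    maxdisp = d2
            else:
                trial[i, 0] = cur[i, 0]
                trial[i, 1] = cur[i, 1]

        if maxdisp <= d_tol * d_tol:
            tmp = cur
            cur = trial
            trial = tmp
            remaining -= h
            f1_valid = False
            consec += 1
            if consec >= 8 and h < dt:
                h = 2.0 * h
                consec = 0
        else:
            consec = 0
            h = 0.5 * h
            if h < h_floor:
                return cur, 1
    return cur, 0
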