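"""Compiled numerical kernels (numba).

Everything here operates on flat float64 arrays: the 10-dimensional state, the
parameter vector of :meth:`lanmm.params.ModelParams.as_vector`, and for the
two-column model a 20-dimensional state plus a 4-vector of coupling gains
[K_ff, K_fb_P11, K_fb_P12, K_fb_SST].

Parameter vector layout::

    p[0:3]   A_A, A_Gs, A_Gf      synaptic gains, mV
    p[3:6]   a_A, a_Gs, a_Gf      kernel rates, 1/s
    p[6:19]  C1..C13              connectivity
    p[19]    phi0                 half-max rate, 1/s
    p[20]    r                    sigmoid slope, 1/mV
    p[21:26] v0 for P1,SS,SST,P2,PV, mV
    p[26:28] phi_e1, phi_e2       external rates, 1/s

Fixed-step RK4 is used throughout: with the fastest kernel rate a_Gf = 220 1/s
a step of 1e-4 s resolves the stiffest relaxation with |a*dt| ~ 0.02, giving
local truncation errors far below the analysis tolerances while keeping runs
bit-deterministic.
"""

import numpy as np
from numba import njit

__all__ = [
    "rhs10",
    "jac10",
    "rk4_final",
    "rk4_path",
    "flow_and_monodromy",
    "benettin_increments",
    "rhs20",
    "jac20",
    "rk4_final20",
    "rk4_path20",
    "flow_and_monodromy20",
]


@njit(cache=True)
def _sig(v, phi0, r, v0):
    z = r * (v0 - v)
    if z > 700.0:
        z = 700.0
    elif z < -700.0:
        z = -700.0
    return 2.0 * phi0 / (1.0 + np.exp(z))


@njit(cache=True)
def _dsig(v, phi0, r, v0):
    s = _sig(v, phi0, r, v0)
    return r * s * (1.0 - s / (2.0 * phi0))


@njit(cache=True)
def rhs10(y, p):
    AA, AGs, AGf = p[0], p[1], p[2]
    aA, aGs, aGf = p[3], p[4], p[5]
    C = p[6:19]
    phi0, r = p[19], p[20]
    q = AA / aA  # steady AMPA gain converting rates to mV
    F1 = C[2] * q * p[26]
    F2 = C[7] * q * p[27]

    a1 = C[0] * y[1] + C[1] * y[2] + F1 + C[10] * y[3]
    a2 = C[3] * y[0]
    a3 = C[4] * y[0]
    a4 = C[5] * y[3] + C[6] * y[4] + F2 + C[11] * y[0]
    a5 = C[8] * y[3] + C[9] * y[4] + C[12] * y[0]

    d = np.empty(10)
    d[0] = y[5]
    d[1] = y[6]
    d[2] = y[7]
    d[3] = y[8]
    d[4] = y[9]
    d[5] = aA * AA * _sig(a1, phi0, r, p[21]) - 2.0 * aA * y[5] - aA * aA * y[0]
    d[6] = aA * AA * _sig(a2, phi0, r, p[22]) - 2.0 * aA * y[6] - aA * aA * y[1]
    d[7] = aGs * AGs * _sig(a3, phi0, r, p[23]) - 2.0 * aGs * y[7] - aGs * aGs * y[2]
    d[8] = aA * AA * _sig(a4, phi0, r, p[24]) - 2.0 * aA * y[8] - aA * aA * y[3]
    d[9] = aGf * AGf * _sig(a5, phi0, r, p[25]) - 2.0 * aGf * y[9] - aGf * aGf * y[4]
    return d


@njit(cache=True)
def jac10(y, p):
    AA, AGs, AGf = p[0], p[1], p[2]
    aA, aGs, aGf = p[3], p[4], p[5]
    C = p[6:19]
    phi0, r = p[19], p[20]
    q = AA / aA
    F1 = C[2] * q * p[26]
    F2 = C[7] * q * p[27]

    a1 = C[0] * y[1] + C[1] * y[2] + F1 + C[10] * y[3]
    a2 = C[3] * y[0]
    a3 = C[4] * y[0]
    a4 = C[5] * y[3] + C[6] * y[4] + F2 + C[11] * y[0]
    a5 = C[8] * y[3] + C[9] * y[4] + C[12] * y[0]

    g1 = aA * AA * _dsig(a1, phi0, r, p[21])
    g2 = aA * AA * _dsig(a2, phi0, r, p[22])
    g3 = aGs * AGs * _dsig(a3, phi0, r, p[23])
    g4 = aA * AA * _dsig(a4, phi0, r, p[24])
    g5 = aGf * AGf * _dsig(a5, phi0, r, p[25])

    J = np.zeros((10, 10))
    for i in range(5):
        J[i, 5 + i] = 1.0
    # y6 block (P1)
    J[5, 1] = g1 * C[0]
    J[5, 2] = g1 * C[1]
    J[5, 3] = g1 * C[10]
    J[5, 0] = -aA * aA
    J[5, 5] = -2.0 * aA
    # y7 block (SS)
    J[6, 0] = g2 * C[3]
    J[6, 1] = -aA * aA
    J[6, 6] = -2.0 * aA
    # y8 block (SST)
    J[7, 0] = g3 * C[4]
    J[7, 2] = -aGs * aGs
    J[7, 7] = -2.0 * aGs
    # y9 block (P2)
    J[8, 3] = g4 * C[5] - aA * aA
    J[8, 4] = g4 * C[6]
    J[8, 0] = g4 * C[11]
    J[8, 8] = -2.0 * aA
    # y10 block (PV)
    J[9, 3] = g5 * C[8]
    J[9, 4] = g5 * C[9] - aGf * aGf
    J[9, 0] = g5 * C[12]
    J[9, 9] = -2.0 * aGf
    return J


@njit(cache=True)
def _rk4_step(y, p, dt):
    k1 = rhs10(y, p)
    k2 = rhs10(y + 0.5 * dt * k1, p)
    k3 = rhs10(y + 0.5 * dt * k2, p)
    k4 = rhs10(y + dt * k3, p)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@njit(cache=True)
def rk4_final(y0, p, dt, nsteps):
    """Integrate nsteps of RK4 and return only the final state."""
    y = y0.copy()
    for _ in range(nsteps):
        y = _rk4_step(y, p, dt)
    return y


@njit(cache=True)
def rk4_path(y0, p, dt, n_sub, n_rec):
    """Record n_rec+1 states (including y0) every n_sub RK4 steps of size dt."""
    out = np.empty((n_rec + 1, 10))
    y = y0.copy()
    out[0] = y
    for i in range(n_rec):
        for _ in range(n_sub):
            y = _rk4_step(y, p, dt)
        out[i + 1] = y
    return out


# -- variational flow (monodromy) ------------------------------------------------


@njit(cache=True)
def _var_rhs(y, V, p):
    dy = rhs10(y, p)
    J = jac10(y, p)
    dV = J @ V
    return dy, dV


@njit(cache=True)
def flow_and_monodromy(y0, p, T, nsteps):
    """Integrate the flow and the 10x10 variational equations over [0, T].

    Returns (y(T), M) where M = dPhi_T/dy0 is the monodromy matrix when y0
    lies on a periodic orbit of period T.
    """
    dt = T / nsteps
    y = y0.copy()
    V = np.eye(10)
    for _ in range(nsteps):
        k1y, k1V = _var_rhs(y, V, p)
        k2y, k2V = _var_rhs(y + 0.5 * dt * k1y, V + 0.5 * dt * k1V, p)
        k3y, k3V = _var_rhs(y + 0.5 * dt * k2y, V + 0.5 * dt * k2V, p)
        k4y, k4V = _var_rhs(y + dt * k3y, V + dt * k3V, p)
        y = y + (dt / 6.0) * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
        V = V + (dt / 6.0) * (k1V + 2.0 * k2V + 2.0 * k3V + k4V)
    return y, V


# -- Benettin tangent dynamics ---------------------------------------------------


@njit(cache=True)
def _tan_rhs(y, v1, v2, p):
    dy = rhs10(y, p)
    J = jac10(y, p)
    return dy, J @ v1, J @ v2


@njit(cache=True)
def benettin_increments(y0, p, dt, n_trans, n_ren, ren_steps):
    """Per-renormalization log stretch factors for the two leading directions.

    Integrates the flow plus two tangent vectors; every ``ren_steps`` RK4 steps
    the tangent frame is Gram-Schmidt re-orthonormalized and the log norms are
    recorded.  The Lyapunov exponents are the time averages of the increments.

    Returns (log1, log2, y_final): arrays of length n_ren with the log stretch
    of the first tangent vector and of the orthogonalized second vector.
    """
    y = y0.copy()
    for _ in range(n_trans):
        y = _rk4_step(y, p, dt)
    v1 = np.zeros(10)
    v2 = np.zeros(10)
    v1[0] = 1.0
    v2[1] = 1.0
    log1 = np.empty(n_ren)
    log2 = np.empty(n_ren)
    for r in range(n_ren):
        for _ in range(ren_steps):
            k1y, k1a, k1b = _tan_rhs(y, v1, v2, p)
            k2y, k2a, k2b = _tan_rhs(y + 0.5 * dt * k1y, v1 + 0.5 * dt * k1a, v2 + 0.5 * dt * k1b, p)
            k3y, k3a, k3b = _tan_rhs(y + 0.5 * dt * k2y, v1 + 0.5 * dt * k2a, v2 + 0.5 * dt * k2b, p)
            k4y, k4a, k4b = _tan_rhs(y + dt * k3y, v1 + dt * k3a, v2 + dt * k3b, p)
            y = y + (dt / 6.0) * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
            v1 = v1 + (dt / 6.0) * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
            v2 = v2 + (dt / 6.0) * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
        n1 = np.sqrt(np.sum(v1 * v1))
        v1 = v1 / n1
        proj = np.sum(v2 * v1)
        v2 = v2 - proj * v1
        n2 = np.sqrt(np.sum(v2 * v2))
        v2 = v2 / n2
        log1[r] = np.log(n1)
        log2[r] = np.log(n2)
    return log1, log2, y


# -- two-column model ------------------------------------------------------------


@njit(cache=True)
def rhs20(z, p, g):
    """Two coupled columns; z[0:10] column 1 (low-level), z[10:20] column 2.

    Feedforward: deep superficial pyramidal of column 1 (P12) -> superficial
    pyramidal of column 2 (P22), gain g[0].  Feedback: deep pyramidal of
    column 2 (P21) -> P11 (g[1]), P12 (g[2]) and SST of column 1 (g[3]).
    Coupled rates enter the target membrane potentials through the steady
    AMPA gain q = A_A/a_A, the same convention as the external drives.  All
    four pyramidal populations receive the same external rate p[26] (= p[27]).
    """
    AA, AGs, AGf = p[0], p[1], p[2]
    aA, aGs, aGf = p[3], p[4], p[5]
    C = p[6:19]
    phi0, r = p[19], p[20]
    q = AA / aA
    F1 = C[2] * q * p[26]
    F2 = C[7] * q * p[27]

    # column-2 deep pyramidal (P21) membrane potential and rate: no feedback in
    a1_2 = C[0] * z[11] + C[1] * z[12] + F1 + C[10] * z[13]
    s21 = _sig(a1_2, phi0, r, p[21])

    # column-1 arguments, with feedback injections
    a1_1 = C[0] * z[1] + C[1] * z[2] + F1 + C[10] * z[3] + g[1] * q * s21
    a2_1 = C[3] * z[0]
    a3_1 = C[4] * z[0] + g[3] * q * s21
    a4_1 = C[5] * z[3] + C[6] * z[4] + F2 + C[11] * z[0] + g[2] * q * s21
    a5_1 = C[8] * z[3] + C[9] * z[4] + C[12] * z[0]
    s12 = _sig(a4_1, phi0, r, p[24])

    # column-2 arguments, with feedforward injection into P22
    a2_2 = C[3] * z[10]
    a3_2 = C[4] * z[10]
    a4_2 = C[5] * z[13] + C[6] * z[14] + F2 + C[11] * z[10] + g[0] * q * s12
    a5_2 = C[8] * z[13] + C[9] * z[14] + C[12] * z[10]

    d = np.empty(20)
    for i in range(5):
        d[i] = z[5 + i]
        d[10 + i] = z[15 + i]
    d[5] = aA * AA * _sig(a1_1, phi0, r, p[21]) - 2.0 * aA * z[5] - aA * aA * z[0]
    d[6] = aA * AA * _sig(a2_1, phi0, r, p[22]) - 2.0 * aA * z[6] - aA * aA * z[1]
    d[7] = aGs * AGs * _sig(a3_1, phi0, r, p[23]) - 2.0 * aGs * z[7] - aGs * aGs * z[2]
    d[8] = aA * AA * _sig(a4_1, phi0, r, p[24]) - 2.0 * aA * z[8] - aA * aA * z[3]
    d[9] = aGf * AGf * _sig(a5_1, phi0, r, p[25]) - 2.0 * aGf * z[9] - aGf * aGf * z[4]
    d[15] = aA * AA * _sig(a1_2, phi0, r, p[21]) - 2.0 * aA * z[15] - aA * aA * z[10]
    d[16] = aA * AA * _sig(a2_2, phi0, r, p[22]) - 2.0 * aA * z[16] - aA * aA * z[11]
    d[17] = aGs * AGs * _sig(a3_2, phi0, r, p[23]) - 2.0 * aGs * z[17] - aGs * aGs * z[12]
    d[18] = aA * AA * _sig(a4_2, phi0, r, p[24]) - 2.0 * aA * z[18] - aA * aA * z[13]
    d[19] = aGf * AGf * _sig(a5_2, phi0, r, p[25]) - 2.0 * aGf * z[19] - aGf * aGf * z[14]
    return d


@njit(cache=True)
def jac20(z, p, g):
    """Analytic 20x20 Jacobian of :func:`rhs20` (chain rule through couplings)."""
    AA, AGs, AGf = p[0], p[1], p[2]
    aA, aGs, aGf = p[3], p[4], p[5]
    C = p[6:19]
    phi0, r = p[19], p[20]
    q = AA / aA
    F1 = C[2] * q * p[26]
    F2 = C[7] * q * p[27]

    a1_2 = C[0] * z[11] + C[1] * z[12] + F1 + C[10] * z[13]
    s21 = _sig(a1_2, phi0, r, p[21])
    ds21 = _dsig(a1_2, phi0, r, p[21])

    a1_1 = C[0] * z[1] + C[1] * z[2] + F1 + C[10] * z[3] + g[1] * q * s21
    a2_1 = C[3] * z[0]
    a3_1 = C[4] * z[0] + g[3] * q * s21
    a4_1 = C[5] * z[3] + C[6] * z[4] + F2 + C[11] * z[0] + g[2] * q * s21
    a5_1 = C[8] * z[3] + C[9] * z[4] + C[12] * z[0]
    ds12 = _dsig(a4_1, phi0, r, p[24])

    a2_2 = C[3] * z[10]
    a3_2 = C[4] * z[10]
    a4_2 = C[5] * z[13] + C[6] * z[14] + F2 + C[11] * z[10] + g[0] * q * _sig(a4_1, phi0, r, p[24])
    a5_2 = C[8] * z[13] + C[9] * z[14] + C[12] * z[10]

    J = np.zeros((20, 20))
    for i in range(5):
        J[i, 5 + i] = 1.0
        J[10 + i, 15 + i] = 1.0

    # gradient of s21 w.r.t. column-2 states (indices 11, 12, 13)
    w21 = np.zeros(20)
    w21[11] = ds21 * C[0]
    w21[12] = ds21 * C[1]
    w21[13] = ds21 * C[10]

    # gradient of a4_1 (membrane potential of P12) w.r.t. all states
    wa41 = np.zeros(20)
    wa41[0] = C[11]
    wa41[3] = C[5]
    wa41[4] = C[6]
    for k in range(20):
        wa41[k] += g[2] * q * w21[k]

    # column 1, P1 block
    gP1 = aA * AA * _dsig(a1_1, phi0, r, p[21])
    J[5, 1] += gP1 * C[0]
    J[5, 2] += gP1 * C[1]
    J[5, 3] += gP1 * C[10]
    for k in range(20):
        J[5, k] += gP1 * g[1] * q * w21[k]
    J[5, 0] += -aA * aA
    J[5, 5] += -2.0 * aA
    # column 1, SS block
    gSS = aA * AA * _dsig(a2_1, phi0, r, p[22])
    J[6, 0] += gSS * C[3]
    J[6, 1] += -aA * aA
    J[6, 6] += -2.0 * aA
    # column 1, SST block (feedback target)
    gSST = aGs * AGs * _dsig(a3_1, phi0, r, p[23])
    J[7, 0] += gSST * C[4]
    for k in range(20):
        J[7, k] += gSST * g[3] * q * w21[k]
    J[7, 2] += -aGs * aGs
    J[7, 7] += -2.0 * aGs
    # column 1, P2 block (feedback target)
    gP2 = aA * AA * ds12
    for k in range(20):
        J[8, k] += gP2 * wa41[k]
    J[8, 3] += -aA * aA
    J[8, 8] += -2.0 * aA
    # column 1, PV block
    gPV = aGf * AGf * _dsig(a5_1, phi0, r, p[25])
    J[9, 3] += gPV * C[8]
    J[9, 4] += gPV * C[9]
    J[9, 0] += gPV * C[12]
    J[9, 4] += -aGf * aGf
    J[9, 9] += -2.0 * aGf

    # column 2, P1 block
    hP1 = aA * AA * ds21
    J[15, 11] += hP1 * C[0]
    J[15, 12] += hP1 * C[1]
    J[15, 13] += hP1 * C[10]
    J[15, 10] += -aA * aA
    J[15, 15] += -2.0 * aA
    # column 2, SS block
    hSS = aA * AA * _dsig(a2_2, phi0, r, p[22])
    J[16, 10] += hSS * C[3]
    J[16, 11] += -aA * aA
    J[16, 16] += -2.0 * aA
    # column 2, SST block
    hSST = aGs * AGs * _dsig(a3_2, phi0, r, p[23])
    J[17, 10] += hSST * C[4]
    J[17, 12] += -aGs * aGs
    J[17, 17] += -2.0 * aGs
    # column 2, P2 block (feedforward target): input depends on s12, hence on
    # both columns through wa41
    hP2 = aA * AA * _dsig(a4_2, phi0, r, p[24])
    J[18, 13] += hP2 * C[5]
    J[18, 14] += hP2 * C[6]
    J[18, 10] += hP2 * C[11]
    for k in range(20):
        J[18, k] += hP2 * g[0] * q * ds12 * wa41[k]
    J[18, 13] += -aA * aA
    J[18, 18] += -2.0 * aA
    # column 2, PV block
    hPV = aGf * AGf * _dsig(a5_2, phi0, r, p[25])
    J[19, 13] += hPV * C[8]
    J[19, 14] += hPV * C[9]
    J[19, 10] += hPV * C[12]
    J[19, 14] += -aGf * aGf
    J[19, 19] += -2.0 * aGf
    return J


@njit(cache=True)
def _rk4_step20(z, p, g, dt):
    k1 = rhs20(z, p, g)
    k2 = rhs20(z + 0.5 * dt * k1, p, g)
    k3 = rhs20(z + 0.5 * dt * k2, p, g)
    k4 = rhs20(z + dt * k3, p, g)
    return z + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@njit(cache=True)
def rk4_final20(z0, p, g, dt, nsteps):
    z = z0.copy()
    for _ in range(nsteps):
        z = _rk4_step20(z, p, g, dt)
    return z


@njit(cache=True)
def rk4_path20(z0, p, g, dt, n_sub, n_rec):
    out = np.empty((n_rec + 1, 20))
    z = z0.copy()
    out[0] = z
    for i in range(n_rec):
        for _ in range(n_sub):
            z = _rk4_step20(z, p, g, dt)
        out[i + 1] = z
    return out


@njit(cache=True)
def flow_and_monodromy20(z0, p, g, T, nsteps):
    dt = T / nsteps
    z = z0.copy()
    V = np.eye(20)
    for _ in range(nsteps):
        k1y = rhs20(z, p, g)
        k1V = jac20(z, p, g) @ V
        y2 = z + 0.5 * dt * k1y
        k2y = rhs20(y2, p, g)
        k2V = jac20(y2, p, g) @ (V + 0.5 * dt * k1V)
        y3 = z + 0.5 * dt * k2y
        k3y = rhs20(y3, p, g)
        k3V = jac20(y3, p, g) @ (V + 0.5 * dt * k2V)
        y4 = z + dt * k3y
        k4y = rhs20(y4, p, g)
        k4V = jac20(y4, p, g) @ (V + dt * k3V)
        z = z + (dt / 6.0) * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
        V = V + (dt / 6.0) * (k1V + 2.0 * k2V + 2.0 * k3V + k4V)
    return z, V
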