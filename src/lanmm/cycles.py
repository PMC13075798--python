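"""Periodic orbits by single shooting, Floquet analysis, and cycle branches.

A periodic orbit is a zero of the shooting system

    Phi_T(x) - x = 0,      f(x0_ref) . (x - x0_ref) = 0,

where Phi_T is the time-T flow and the second equation is a Poincare phase
condition (the section through a reference point, orthogonal to the vector
field there).  The monodromy matrix M = dPhi_T/dx is integrated alongside the
orbit via the variational equations; its eigenvalues are the Floquet
multipliers.  One multiplier is always 1 (the flow direction); the orbit is
stable iff every other multiplier lies inside the unit circle.

Branches of orbits are continued in a parameter by pseudo-arclength, which
also tracks unstable cycles (simulation cannot: they repel).  Along a branch,
folds of cycles (FLC, multiplier +1 / parameter fold), torus bifurcations
(TR, complex pair leaving the unit circle) and period doublings (PD, real
multiplier through -1) are detected and refined by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fast
from .equilibria import ConvergenceError, _vary_index
from .model import membrane_potentials
from .params import ModelParams

__all__ = [
    "PeriodicOrbit",
    "CycleBranch",
    "FlowSystem",
    "lanmm_flow",
    "find_cycle",
    "cycle_from_simulation",
    "continue_cycles",
    "detect_cycle_bifurcations",
]

#: target RK4 step inside shooting integrations (s)
SHOOT_DT = 2.5e-5
#: shooting residual tolerance (state units, mV)
SHOOT_TOL = 1e-8


class FlowSystem:
    """Flow plus variational integration for one continued parameter.

    Wraps the compiled kernels so the shooting and continuation code is
    independent of the concrete model (single column or two-column).
    """

    def __init__(self, dim, rhs, flow, flow_var, observables):
        self.dim = dim
        self.rhs = rhs                # rhs(y, th) -> (dim,)
        self.flow = flow              # flow(y, th, T, nsteps) -> (dim,)
        self.flow_var = flow_var      # flow_var(y, th, T, nsteps) -> (y_T, M)
        self.observables = observables  # observables(states) -> (vP1, vP2)


def lanmm_flow(params: ModelParams, vary: str = "phi_e1") -> FlowSystem:
    p = params.as_vector()
    idx = _vary_index(vary)

    def with_theta(th):
        q = p.copy()
        q[idx] = th
        return q

    def rhs(y, th):
        return _fast.rhs10(y, with_theta(th))

    def flow(y, th, T, nsteps):
        return _fast.rk4_final(y, with_theta(th), T / nsteps, nsteps)

    def flow_var(y, th, T, nsteps):
        return _fast.flow_and_monodromy(y, with_theta(th), T, nsteps)

    def observables(states):
        return membrane_potentials(states, params)

    return FlowSystem(10, rhs, flow, flow_var, observables)


@dataclass(frozen=True)
class PeriodicOrbit:
    """A converged periodic orbit with its Floquet spectrum."""

    theta: float
    anchor_state: np.ndarray
    period: float
    floquet_multipliers: np.ndarray
    amp_vP1: float
    amp_vP2: float
    phi_e1: float | None = None
    phi_e2: float | None = None

    @property
    def trivial_multiplier(self) -> complex:
        """The multiplier closest to +1 (flow direction; always ~1)."""
        return complex(self.floquet_multipliers[np.argmin(np.abs(self.floquet_multipliers - 1.0))])

    @property
    def nontrivial_multipliers(self) -> np.ndarray:
        i = np.argmin(np.abs(self.floquet_multipliers - 1.0))
        return np.delete(self.floquet_multipliers, i)

    @property
    def stable(self) -> bool:
        return bool(np.all(np.abs(self.nontrivial_multipliers) < 1.0))

    @property
    def frequency(self) -> float:
        return 1.0 / self.period


@dataclass
class CycleBranch:
    """Ordered sequence of periodic orbits with detected bifurcations."""

    vary: str
    orbits: list = field(default_factory=list)
    bifurcations: list = field(default_factory=list)

    @property
    def thetas(self) -> np.ndarray:
        return np.array([o.theta for o in self.orbits])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                self.vary: self.thetas,
                "period": [o.period for o in self.orbits],
                "amp_vP1": [o.amp_vP1 for o in self.orbits],
                "amp_vP2": [o.amp_vP2 for o in self.orbits],
                "stable": [o.stable for o in self.orbits],
                "max_nontrivial_mult": [float(np.max(np.abs(o.nontrivial_multipliers)))
                                        for o in self.orbits],
            }
        )


def _nsteps(T: float) -> int:
    return max(1000, int(np.ceil(T / SHOOT_DT)))


def _orbit_amplitudes(sys: FlowSystem, x: np.ndarray, th: float, T: float, n=400):
    """Peak-to-peak observable amplitudes over one period."""
    dt = T / n
    states = np.empty((n, sys.dim))
    y = x.copy()
    for i in range(n):
        states[i] = y
        y = sys.flow(y, th, dt, max(1, int(np.ceil(dt / SHOOT_DT))))
    v1, v2 = sys.observables(states)
    return float(np.ptp(v1)), float(np.ptp(v2))


def _shoot_newton(sys: FlowSystem, x0, T0, th, maxiter=30):
    """Newton solve of the shooting system at fixed parameter value."""
    n = sys.dim
    x, T = np.asarray(x0, dtype=float).copy(), float(T0)
    f_ref = sys.rhs(x, th)
    nf = np.linalg.norm(f_ref)
    if nf < 1e-8:
        raise ConvergenceError("phase reference is an equilibrium")
    f_ref = f_ref / nf
    x_ref = x.copy()
    for _ in range(maxiter):
        yT, M = sys.flow_var(x, th, T, _nsteps(T))
        r = np.concatenate([yT - x, [f_ref @ (x - x_ref)]])
        if np.max(np.abs(r)) < SHOOT_TOL:
            return x, T, M
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = M - np.eye(n)
        A[:n, n] = sys.rhs(yT, th)
        A[n, :n] = f_ref
        try:
            d = np.linalg.solve(A, -r)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular shooting system") from exc
        # damped update; period must stay positive and bounded
        lam = 1.0
        while T + lam * d[n] <= 0.2 * T:
            lam *= 0.5
        x = x + lam * d[:n]
        T = T + lam * d[n]
        if not np.all(np.isfinite(x)) or T > 100.0:
            raise ConvergenceError("shooting iteration diverged")
    raise ConvergenceError("shooting Newton did not converge")


def _make_orbit(sys: FlowSystem, params, vary, x, T, th, M) -> PeriodicOrbit:
    mult = np.linalg.eigvals(M)
    a1, a2 = _orbit_amplitudes(sys, x, th, T)
    if a1 + a2 < 1e-6:
        raise ConvergenceError("converged to an equilibrium (zero-amplitude orbit)")
    kw = {"phi_e1": None, "phi_e2": None}
    if params is not None:
        kw = {"phi_e1": params.inputs.phi_e1, "phi_e2": params.inputs.phi_e2}
        if vary in kw:
            kw[vary] = th
    return PeriodicOrbit(theta=float(th), anchor_state=x, period=float(T),
                         floquet_multipliers=mult, amp_vP1=a1, amp_vP2=a2, **kw)


def find_cycle(
    params: ModelParams,
    guess_state,
    guess_period: float,
    vary: str = "phi_e1",
    theta: float | None = None,
) -> PeriodicOrbit:
    """Converge a periodic orbit near a guess (typically from simulation).

    Solves the shooting system by Newton with the monodromy matrix from the
    variational flow; raises if the iteration fails or lands on an
    equilibrium.
    """
    sys = lanmm_flow(params, vary)
    th = params.as_vector()[_vary_index(vary)] if theta is None else float(theta)
    x, T, M = _shoot_newton(sys, guess_state, guess_period, th)
    return _make_orbit(sys, params, vary, x, T, th, M)


def cycle_from_simulation(
    params: ModelParams,
    t_transient: float = 20.0,
    t_probe: float = 4.0,
    vary: str = "phi_e1",
) -> PeriodicOrbit:
    """Seed and converge a stable cycle from a transient-free simulation.

    The period guess is the median inter-peak interval of vP1 (falling back
    to vP2 when vP1 is nearly flat).
    """
    from scipy.signal import find_peaks

    from .simulate import SolverSettings, integrate

    ts = integrate(params, SolverSettings(t_transient=t_transient, t_record=t_probe,
                                          keep_states=True))
    x_end = ts.states[-1]
    for chan in ("vP1", "vP2"):
        x = ts.channel(chan)
        if np.ptp(x) < 1e-3:
            continue
        peaks, _ = find_peaks(x - x.mean(), prominence=0.3 * np.ptp(x))
        if len(peaks) >= 3:
            T0 = float(np.median(np.diff(peaks)) / ts.sample_rate)
            return find_cycle(params, x_end, T0, vary=vary)
    raise ConvergenceError("no sustained oscillation found to seed a cycle")


# --------------------------------------------------------------------------- #
# pseudo-arclength continuation of cycles
# --------------------------------------------------------------------------- #

#: scaled-metric weights: orbits live in (x [mV], T [s], theta [1/s])
X_SCALE = 100.0
T_SCALE = 100.0


def _cycle_tangent(sys, x, T, th, M, prev=None, dth=1e-3):
    """Unit tangent of the cycle branch in the scaled metric."""
    n = sys.dim
    yT = sys.flow(x, th, T, _nsteps(T))
    dphi_dth = (sys.flow(x, th + dth, T, _nsteps(T)) - sys.flow(x, th - dth, T, _nsteps(T))) / (2 * dth)
    f_ref = sys.rhs(x, th)
    f_ref = f_ref / np.linalg.norm(f_ref)
    A = np.zeros((n + 2, n + 2))
    A[:n, :n] = M - np.eye(n)
    A[:n, n] = sys.rhs(yT, th)
    A[:n, n + 1] = dphi_dth
    A[n, :n] = f_ref
    if prev is None:
        A[n + 1, n + 1] = 1.0
    else:
        A[n + 1, :] = prev
    b = np.zeros(n + 2)
    b[n + 1] = 1.0
    v = np.linalg.solve(A, b)
    w = v.copy()
    w[:n] *= X_SCALE
    w[n] *= T_SCALE
    v /= np.linalg.norm(w)
    if prev is not None:
        wp = prev.copy()
        wp[:n] *= X_SCALE
        wp[n] *= T_SCALE
        w = v.copy()
        w[:n] *= X_SCALE
        w[n] *= T_SCALE
        if np.dot(w, wp) < 0:
            v = -v
    return v


def _cycle_corrector(sys, z_pred, tan, x_ref, f_ref, maxiter=10, dth=1e-3):
    """Newton on [shooting residual; phase; arclength orthogonality]."""
    n = sys.dim
    z = z_pred.copy()
    scale2 = np.ones(n + 2)
    scale2[:n] = X_SCALE**2
    scale2[n] = T_SCALE**2
    M = None
    for _ in range(maxiter):
        x, T, th = z[:n], z[n], z[n + 1]
        if T <= 0:
            raise ConvergenceError("negative period")
        yT, M = sys.flow_var(x, th, T, _nsteps(T))
        r = np.concatenate([yT - x, [f_ref @ (x - x_ref)], [0.0]])
        if np.max(np.abs(r[: n + 1])) < SHOOT_TOL:
            return z, M
        A = np.zeros((n + 2, n + 2))
        A[:n, :n] = M - np.eye(n)
        A[:n, n] = sys.rhs(yT, th)
        A[:n, n + 1] = (sys.flow(x, th + dth, T, _nsteps(T))
                        - sys.flow(x, th - dth, T, _nsteps(T))) / (2 * dth)
        A[n, :n] = f_ref
        A[n + 1, :] = tan * scale2
        try:
            d = np.linalg.solve(A, -r)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular cycle corrector") from exc
        z = z + d
        if not np.all(np.isfinite(z)):
            raise ConvergenceError("cycle corrector diverged")
    raise ConvergenceError("cycle corrector exceeded iterations")


def continue_cycles(
    start: PeriodicOrbit,
    params: ModelParams,
    vary: str = "phi_e1",
    range_: tuple[float, float] = (0.0, 600.0),
    step: float = 1.0,
    max_step: float = 8.0,
    min_step: float = 1e-4,
    max_points: int = 4000,
    min_amplitude: float = 0.02,
    detect: bool = True,
    direction: str | None = None,
    flow: FlowSystem | None = None,
) -> CycleBranch:
    """Pseudo-arclength continuation of a cycle branch from a converged orbit.

    Tracks the branch through folds (including unstable segments, which
    simulation cannot reach); terminates at the range boundary, when the
    amplitude collapses (approach to a Hopf point), or when the corrector
    fails at the minimum step.  ``flow`` overrides the default single-column
    flow system (the two-column model passes its own).
    """
    sys = lanmm_flow(params, vary) if flow is None else flow
    lo, hi = min(range_), max(range_)
    x, T, th = start.anchor_state.copy(), start.period, start.theta
    x, T, M = _shoot_newton(sys, x, T, th)
    orbits = [_make_orbit(sys, params, vary, x, T, th, M)]
    tan = _cycle_tangent(sys, x, T, th, M)
    if direction == "up":
        target = hi
    elif direction == "down":
        target = lo
    else:  # head toward the far end of the range
        target = hi if abs(hi - th) > abs(lo - th) else lo
    if (target - th) * tan[-1] < 0:
        tan = -tan
    h = step
    n = sys.dim
    d_prev = None
    while len(orbits) < max_points:
        last = orbits[-1]
        z_prev = np.concatenate([last.anchor_state, [last.period, last.theta]])
        f_ref = sys.rhs(last.anchor_state, last.theta)
        f_ref = f_ref / np.linalg.norm(f_ref)
        ok = False
        while h >= min_step:
            z_pred = z_prev + h * tan
            try:
                z_new, M = _cycle_corrector(sys, z_pred, tan, last.anchor_state, f_ref)
                sec = z_new - z_prev
                sec_s = sec.copy()
                sec_s[:n] *= X_SCALE
                sec_s[n] *= T_SCALE
                tan_s = tan.copy()
                tan_s[:n] *= X_SCALE
                tan_s[n] *= T_SCALE
                if np.linalg.norm(sec_s) > 3.0 * h or np.dot(sec_s, tan_s) <= 0:
                    raise ConvergenceError("cycle corrector left trust region")
                if abs(z_new[n] - last.period) > 0.5 * last.period:
                    raise ConvergenceError("period jumped")
                ok = True
                break
            except ConvergenceError:
                h *= 0.5
        if not ok:
            break  # branch lost (e.g. amplitude -> 0 at a Hopf)
        x, T, th = z_new[:n], float(z_new[n]), float(z_new[n + 1])
        try:
            orbit = _make_orbit(sys, params, vary, x, T, th, M)
        except ConvergenceError:
            break  # collapsed onto the equilibrium
        d_new = orbit.theta - last.theta
        orbits.append(orbit)
        if orbit.amp_vP1 + orbit.amp_vP2 < min_amplitude:
            break
        # passing through a Hopf point: the family shrinks onto the
        # equilibrium and re-emerges phase-mirrored, reversing the parameter
        # direction at near-zero amplitude (a true fold of cycles reverses
        # at finite amplitude and is kept)
        if (d_prev is not None and d_new * d_prev < 0
                and orbit.amp_vP1 + orbit.amp_vP2 < 1.0):
            break
        if abs(d_new) > 1e-12:
            d_prev = d_new
        if not (lo - 1e-9 <= th <= hi + 1e-9):
            break
        tan = _cycle_tangent(sys, x, T, th, M, prev=tan)
        h = min(h * 1.4, max_step)
    branch = CycleBranch(vary=vary, orbits=orbits)
    if detect and len(orbits) >= 3:
        branch.bifurcations = detect_cycle_bifurcations(branch, params, vary, flow=flow)
    return branch


# --------------------------------------------------------------------------- #
# cycle bifurcations
# --------------------------------------------------------------------------- #


def _tr_measure(orbit: PeriodicOrbit) -> float:
    """max |mu| - 1 over complex (non-real) nontrivial multipliers."""
    mult = orbit.nontrivial_multipliers
    cplx = mult[np.abs(mult.imag) > 1e-4]
    if len(cplx) == 0:
        return -1.0
    return float(np.max(np.abs(cplx)) - 1.0)


def _pd_measure(orbit: PeriodicOrbit) -> float:
    """max(-Re mu) - 1 over real negative multipliers: > 0 past a PD."""
    mult = orbit.nontrivial_multipliers
    real_neg = mult[(np.abs(mult.imag) <= 1e-4) & (mult.real < 0)]
    if len(real_neg) == 0:
        return -1.0
    return float(np.max(-real_neg.real) - 1.0)


def _bisect_cycle_event(sys, params, vary, a: PeriodicOrbit, b: PeriodicOrbit,
                        measure, iters=25):
    """Bisection in the parameter between two orbits bracketing an event."""
    s_a = measure(a)
    th_lo, th_hi = a.theta, b.theta
    x, T = a.anchor_state.copy(), a.period
    orb = a
    for _ in range(iters):
        if abs(th_hi - th_lo) < 1e-6 * max(1.0, abs(th_hi)):
            break
        th_mid = 0.5 * (th_lo + th_hi)
        try:
            x_m, T_m, M = _shoot_newton(sys, x, T, th_mid)
            orb = _make_orbit(sys, params, vary, x_m, T_m, th_mid, M)
        except ConvergenceError:
            break
        if (measure(orb) > 0) == (s_a > 0):
            th_lo = th_mid
            x, T = x_m, T_m
        else:
            th_hi = th_mid
    return orb


def detect_cycle_bifurcations(branch: CycleBranch, params: ModelParams,
                              vary: str = "phi_e1",
                              flow: FlowSystem | None = None) -> list:
    """FLC (parameter fold), TR (complex pair through the unit circle) and PD
    (real multiplier through -1) events along a continued cycle branch.

    FLC is reported at the branch's geometric parameter fold; TR and PD are
    refined by bisection on the defining multiplier condition.
    """
    sys = lanmm_flow(params, vary) if flow is None else flow
    orbits = branch.orbits
    out = []
    th = branch.thetas
    dth = np.diff(th)
    for i in range(1, len(dth)):
        if dth[i - 1] * dth[i] < 0:
            # quadratic extremum through the three surrounding orbits
            t0, t1, t2 = th[i - 1], th[i], th[i + 1]
            denom = t0 - 2 * t1 + t2
            th_f = t1 if abs(denom) < 1e-14 else t1 - (t2 - t0) ** 2 / (8 * denom)
            o = orbits[i]
            mult = o.nontrivial_multipliers
            real_m = mult[np.abs(mult.imag) <= 1e-4]
            diag = float(real_m.real[np.argmin(np.abs(real_m.real - 1.0))]) if len(real_m) else np.nan
            out.append(_cycle_bif("FLC", th_f, o, diag, params, vary))
    for meas, kind in ((_tr_measure, "torus"), (_pd_measure, "period_doubling")):
        vals = [meas(o) for o in orbits]
        for i in range(len(orbits) - 1):
            if (vals[i] > 0) != (vals[i + 1] > 0) and min(vals[i], vals[i + 1]) > -1.0 + 1e-12:
                orb = _bisect_cycle_event(sys, params, vary, orbits[i], orbits[i + 1], meas)
                out.append(_cycle_bif(kind, orb.theta, orb, meas(orb) + 1.0, params, vary))
    out.sort(key=lambda bp: bp.theta)
    return out


def _cycle_bif(kind, th, orbit, diag, params, vary):
    from .equilibria import BifurcationPoint

    if params is not None:
        kw = {"phi_e1": params.inputs.phi_e1, "phi_e2": params.inputs.phi_e2}
        if vary in kw:
            kw[vary] = float(th)
    else:
        kw = {"phi_e1": None, "phi_e2": None}
    return BifurcationPoint(kind=kind, theta=float(th), state=orbit.anchor_state,
                            diagnostic=float(diag), frequency=1.0 / orbit.period,
                            phi_e1=kw["phi_e1"], phi_e2=kw["phi_e2"])
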