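"""Fixed points, pseudo-arclength continuation, and codim-1 bifurcations.

Equilibrium branches of the model are S-shaped in the drive ``phi_e1``, so
they are traced by pseudo-arclength continuation (secant predictor, Newton
corrector on the bordered system) rather than parameter stepping.  Folds are
refined by Newton on the extended fold system (f = 0, J v = 0, c.v = 1);
Hopf points by bisection on the real part of the crossing complex pair.

The machinery is generic over the vector field (a :class:`ContinuationProblem`
bundles f, its state Jacobian and its parameter derivative), which lets the
two-column model reuse it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fast
from .params import ModelParams

__all__ = [
    "EquilibriumPoint",
    "EquilibriumBranch",
    "BifurcationPoint",
    "ContinuationProblem",
    "find_equilibrium",
    "continue_branch",
    "detect_codim1",
    "classify_snic",
    "trace_locus_2param",
]

RESIDUAL_TOL = 1e-10


class ConvergenceError(RuntimeError):
    """Newton or continuation failed to converge."""


# --------------------------------------------------------------------------- #
# problem abstraction
# --------------------------------------------------------------------------- #


class ContinuationProblem:
    """A vector field f(y, theta) with Jacobians, for one scalar parameter.

    Parameters
    ----------
    f, jac : callables
        ``f(y, theta) -> (n,)`` and ``jac(y, theta) -> (n, n)``.
    dim : int
        State dimension n.
    jac_theta : callable, optional
        ``jac_theta(y, theta) -> (n,)``; defaults to a central difference.
    """

    def __init__(self, f, jac, dim, jac_theta=None, relax=None):
        self.f = f
        self.jac = jac
        self.dim = dim
        self._jac_theta = jac_theta
        #: optional relax(y, theta, t) -> y: integrate the flow for t seconds,
        #: used to pull a poor starting guess into a Newton basin
        self.relax = relax

    def jac_theta(self, y, th, h=1e-5):
        if self._jac_theta is not None:
            return self._jac_theta(y, th)
        scale = max(1.0, abs(th))
        hh = h * scale
        return (self.f(y, th + hh) - self.f(y, th - hh)) / (2 * hh)


def _vary_index(vary: str) -> int:
    if vary == "phi_e1":
        return 26
    if vary == "phi_e2":
        return 27
    if vary.startswith("C") and vary[1:].isdigit() and 1 <= int(vary[1:]) <= 13:
        return 6 + int(vary[1:]) - 1
    raise ValueError(f"cannot continue in parameter {vary!r}")


def lanmm_problem(params: ModelParams, vary: str = "phi_e1") -> ContinuationProblem:
    """Continuation problem for the single-column model in one parameter."""
    p = params.as_vector()
    idx = _vary_index(vary)

    def f(y, th):
        q = p.copy()
        q[idx] = th
        return _fast.rhs10(y, q)

    def jac(y, th):
        q = p.copy()
        q[idx] = th
        return _fast.jac10(y, q)

    def relax(y, th, t):
        q = p.copy()
        q[idx] = th
        return _fast.rk4_final(np.asarray(y, float), q, 1e-4, int(round(t / 1e-4)))

    return ContinuationProblem(f, jac, 10, relax=relax)


# --------------------------------------------------------------------------- #
# data containers
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class EquilibriumPoint:
    """A converged fixed point with its linearization."""

    theta: float
    state: np.ndarray
    eigenvalues: np.ndarray
    phi_e1: float | None = None
    phi_e2: float | None = None

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigenvalues.real < 0))

    @property
    def leading_real_part(self) -> float:
        return float(self.eigenvalues.real.max())


@dataclass(frozen=True)
class BifurcationPoint:
    """A refined codim-1 bifurcation on a branch.

    ``diagnostic`` is the defining quantity at detection (eigenvalue real
    part, branch tangent parameter component, or multiplier modulus minus 1);
    ``frequency`` is |Im lambda|/2pi for Hopf points (Hz), the emergent-cycle
    frequency.
    """

    kind: str
    theta: float
    state: np.ndarray
    diagnostic: float
    frequency: float | None = None
    phi_e1: float | None = None
    phi_e2: float | None = None


@dataclass
class EquilibriumBranch:
    """Ordered continuation curve with detected bifurcations."""

    vary: str
    points: list = field(default_factory=list)
    bifurcations: list = field(default_factory=list)

    @property
    def thetas(self) -> np.ndarray:
        return np.array([pt.theta for pt in self.points])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                self.vary: self.thetas,
                "stable": [pt.stable for pt in self.points],
                "leading_re": [pt.leading_real_part for pt in self.points],
            }
        )


# --------------------------------------------------------------------------- #
# Newton solvers
# --------------------------------------------------------------------------- #


def _newton(problem: ContinuationProblem, y0, th, tol=RESIDUAL_TOL, maxiter=60):
    """Damped Newton solve of f(y, theta) = 0 at fixed theta."""
    y = np.asarray(y0, dtype=float).copy()
    r = problem.f(y, th)
    best = np.max(np.abs(r))
    for _ in range(maxiter):
        if best < tol:
            return y
        try:
            step = np.linalg.solve(problem.jac(y, th), -r)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Jacobian at theta={th}") from exc
        lam = 1.0
        for _ in range(30):
            y_new = y + lam * step
            r_new = problem.f(y_new, th)
            nrm = np.max(np.abs(r_new))
            if np.isfinite(nrm) and nrm < best:
                y, r, best = y_new, r_new, nrm
                break
            lam *= 0.5
        else:
            raise ConvergenceError(f"Newton line search stalled at theta={th}")
    if best < tol:
        return y
    raise ConvergenceError(f"Newton did not converge at theta={th} (residual {best:.2e})")


def find_equilibrium(params: ModelParams, guess=None) -> EquilibriumPoint:
    """Damped-Newton fixed point of the model at its configured inputs.

    The returned point has residual below 1e-10 and carries the eigenvalues
    of the analytic Jacobian; at any equilibrium the derivative components
    y6..y10 vanish identically.
    """
    prob = lanmm_problem(params, "phi_e1")
    th = params.inputs.phi_e1
    y = _newton(prob, np.zeros(10) if guess is None else guess, th)
    ev = np.linalg.eigvals(prob.jac(y, th))
    return EquilibriumPoint(theta=th, state=y, eigenvalues=ev,
                            phi_e1=params.inputs.phi_e1, phi_e2=params.inputs.phi_e2)


# --------------------------------------------------------------------------- #
# pseudo-arclength continuation
# --------------------------------------------------------------------------- #

#: weight applied to state components in the arclength metric: state entries
#: are O(0.1) mV while the drive spans hundreds of 1/s, and without weighting
#: the fold region would be traversed in a single step.
STATE_SCALE = 100.0


def _tangent(problem, y, th, prev=None):
    """Unit tangent of the branch in the scaled (state, theta) metric."""
    J = problem.jac(y, th)
    fth = problem.jac_theta(y, th)
    n = problem.dim
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = J
    A[:n, n] = fth
    if prev is None:
        A[n, n] = 1.0
    else:
        A[n, :] = prev
    b = np.zeros(n + 1)
    b[n] = 1.0
    try:
        v = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        A[n, :] = np.random.default_rng(0).normal(size=n + 1)
        v = np.linalg.solve(A, b)
    w = v.copy()
    w[:n] *= STATE_SCALE
    v /= np.linalg.norm(w)
    if prev is not None:
        # orient consistently with the previous tangent in the scaled metric
        # (the raw dot is dominated by the parameter component near folds)
        w_prev = prev.copy()
        w_prev[:n] *= STATE_SCALE
        w = v.copy()
        w[:n] *= STATE_SCALE
        if np.dot(w, w_prev) < 0:
            v = -v
    return v


def _corrector(problem, y_pred, th_pred, tangent, tol=RESIDUAL_TOL, maxiter=12):
    """Newton on [f; tangent-orthogonality] from the predicted point."""
    n = problem.dim
    y, th = y_pred.copy(), th_pred
    scale2 = np.ones(n + 1)
    scale2[:n] = STATE_SCALE**2
    for _ in range(maxiter):
        r = problem.f(y, th)
        if np.max(np.abs(r)) < tol:
            return y, th
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = problem.jac(y, th)
        A[:n, n] = problem.jac_theta(y, th)
        A[n, :] = tangent * scale2
        b = np.empty(n + 1)
        b[:n] = -r
        b[n] = 0.0
        try:
            d = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular bordered system")
        y = y + d[:n]
        th = th + d[n]
        if not np.all(np.isfinite(y)):
            raise ConvergenceError("corrector diverged")
    raise ConvergenceError("corrector exceeded iteration budget")


def continue_problem(
    problem: ContinuationProblem,
    th_start: float,
    th_end: float,
    y_start=None,
    step: float = 0.5,
    max_step: float = 5.0,
    min_step: float = 1e-4,
    max_points: int = 50000,
    overshoot: float = 250.0,
) -> list[EquilibriumPoint]:
    """Trace an equilibrium branch from th_start toward th_end.

    Folds are traversed via arclength stepping; the step adapts on corrector
    performance.  The branch may leave the stated range on the starting side
    by up to ``overshoot`` (S-shaped curves can close through a fold outside
    the physical window before returning); it stops hard at the far end (the
    boundary point is appended via a natural-parameter solve) or when the
    point budget is exhausted.
    """
    lo, hi = min(th_start, th_end), max(th_start, th_end)
    soft_lo, soft_hi = lo, hi
    if th_start <= th_end:
        soft_lo = lo - overshoot
    else:
        soft_hi = hi + overshoot
    guess = np.zeros(problem.dim) if y_start is None else y_start
    try:
        y = _newton(problem, guess, th_start)
    except ConvergenceError:
        if problem.relax is None:
            raise
        y = _newton(problem, problem.relax(guess, th_start, 10.0), th_start)
    pts = [(th_start, y)]
    tan = _tangent(problem, y, th_start)
    if (th_end - th_start) * tan[-1] < 0:
        tan = -tan
    h = step
    while len(pts) < max_points:
        th_prev, y_prev = pts[-1]
        ok = False
        while h >= min_step:
            y_pred = y_prev + h * tan[: problem.dim]
            th_pred = th_prev + h * tan[-1]
            try:
                y_new, th_new = _corrector(problem, y_pred, th_pred, tan)
                # reject corrections that leave the local branch segment or
                # land behind the current point (both happen near folds when
                # the orthogonality hyperplane cuts the branch twice)
                dist = np.hypot(STATE_SCALE * np.linalg.norm(y_new - y_prev), th_new - th_prev)
                sec = np.empty(problem.dim + 1)
                sec[: problem.dim] = STATE_SCALE * (y_new - y_prev)
                sec[-1] = th_new - th_prev
                tan_s = tan.copy()
                tan_s[: problem.dim] *= STATE_SCALE
                if dist > 3.0 * h or np.dot(sec, tan_s) <= 0:
                    raise ConvergenceError("corrector left trust region")
                ok = True
                break
            except ConvergenceError:
                h *= 0.5
        if not ok:
            raise ConvergenceError(f"continuation stalled near theta={th_prev}")
        if not (soft_lo - 1e-9 <= th_new <= soft_hi + 1e-9):
            bound = hi if th_new > soft_hi else lo
            if lo <= pts[-1][0] <= hi:  # only clamp if we exit from inside
                try:
                    y_b = _newton(problem, y_new, bound)
                    pts.append((bound, y_b))
                except ConvergenceError:
                    pass
            break
        pts.append((th_new, y_new))
        tan = _tangent(problem, y_new, th_new, prev=tan)
        # step adaptation: fast corrector -> grow, slow handled by halving above
        h = min(h * 1.4, max_step)
    out = []
    for th, yy in pts:
        ev = np.linalg.eigvals(problem.jac(yy, th))
        out.append(EquilibriumPoint(theta=th, state=yy, eigenvalues=ev))
    return out


def continue_branch(
    params: ModelParams,
    vary: str = "phi_e1",
    range_: tuple[float, float] = (0.0, 600.0),
    step: float = 0.5,
    start_state=None,
    detect: bool = True,
    classify_hopf: bool = False,
) -> EquilibriumBranch:
    """Continue the model's equilibrium branch in one parameter.

    Points carry stability flags; with ``detect=True`` folds and Hopf points
    are located and refined (see :func:`detect_codim1`).
    """
    prob = lanmm_problem(params, vary)
    pts = continue_problem(prob, range_[0], range_[1], y_start=start_state, step=step)
    fixed = {"phi_e1": params.inputs.phi_e1, "phi_e2": params.inputs.phi_e2}
    enriched = []
    for pt in pts:
        kw = dict(fixed)
        if vary in kw:
            kw[vary] = pt.theta
        enriched.append(
            EquilibriumPoint(theta=pt.theta, state=pt.state, eigenvalues=pt.eigenvalues,
                             phi_e1=kw["phi_e1"], phi_e2=kw["phi_e2"])
        )
    branch = EquilibriumBranch(vary=vary, points=enriched)
    if detect:
        branch.bifurcations = detect_codim1(branch, prob, params=params, vary=vary,
                                            classify_hopf=classify_hopf)
    return branch


# --------------------------------------------------------------------------- #
# bifurcation detection and refinement
# --------------------------------------------------------------------------- #


def _bracket_fold(problem, y_a, th_a, tan, h=0.02, max_steps=2000):
    """Walk the branch with small arclength steps until the parameter
    component of the tangent flips sign; return the extremum triplet."""
    pts = [(th_a, y_a)]
    sign0 = np.sign(tan[-1])
    extra = 2
    for _ in range(max_steps):
        th_prev, y_prev = pts[-1]
        y_pred = y_prev + h * tan[: problem.dim]
        th_pred = th_prev + h * tan[-1]
        y_new, th_new = _corrector(problem, y_pred, th_pred, tan)
        pts.append((th_new, y_new))
        tan = _tangent(problem, y_new, th_new, prev=tan)
        if np.sign(tan[-1]) != sign0 and len(pts) >= 3:
            if extra == 0:
                break
            extra -= 1
    # extremum of theta over the walked points
    i = int(np.argmax([sign0 * t for t, _ in pts]))
    i = min(max(i, 1), len(pts) - 2)
    return pts[i - 1], pts[i], pts[i + 1]


def _refine_fold(problem, y_a, th_a, tan):
    """Locate a fold: tight arclength bracketing, quadratic estimate, then
    damped Newton on the extended fold system (f, J v, c.v - 1)."""
    n = problem.dim
    try:
        (t0, p0), (t1, p1), (t2, p2) = _bracket_fold(problem, y_a, th_a, tan)
        denom = t0 - 2 * t1 + t2
        if abs(denom) > 1e-14:
            s_star = np.clip(0.5 * (t0 - t2) / denom, -1.0, 1.0)
            th_est = t1 + 0.5 * s_star * (t2 - t0) + 0.5 * s_star**2 * denom
            y_est = p1 + 0.5 * s_star * (p2 - p0)
        else:
            th_est, y_est = t1, p1
    except ConvergenceError:
        th_est, y_est = th_a, y_a
    J = problem.jac(y_est, th_est)
    w, V = np.linalg.eig(J)
    real_idx = np.where(np.abs(w.imag) < 1e-6)[0]
    i = real_idx[np.argmin(np.abs(w[real_idx]))] if len(real_idx) else np.argmin(np.abs(w))
    v = np.real(V[:, i])
    v /= np.linalg.norm(v)
    c = v.copy()

    def F(z):
        y, vv, th = z[:n], z[n : 2 * n], z[2 * n]
        Jm = problem.jac(y, th)
        return np.concatenate([problem.f(y, th), Jm @ vv, [c @ vv - 1.0]])

    z = np.concatenate([y_est, v, [th_est]])
    best = np.max(np.abs(F(z)))
    for _ in range(40):
        r = F(z)
        if np.max(np.abs(r)) < 1e-8:
            break
        m = 2 * n + 1
        A = np.zeros((m, m))
        for j in range(m):
            hj = 1e-6 * max(1.0, abs(z[j]))
            e = np.zeros(m)
            e[j] = hj
            A[:, j] = (F(z + e) - F(z - e)) / (2 * hj)
        try:
            dz = np.linalg.solve(A, -r)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        improved = False
        for _ in range(20):
            z_new = z + lam * dz
            nrm = np.max(np.abs(F(z_new)))
            if np.isfinite(nrm) and nrm < best:
                z, best = z_new, nrm
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
    if abs(float(z[2 * n]) - th_est) > 5.0:  # Newton wandered off; keep bracket value
        return y_est, th_est
    return z[:n], float(z[2 * n])


def _complex_leading_re(problem, y, th, min_imag=1.0):
    ev = np.linalg.eigvals(problem.jac(y, th))
    cplx = ev[np.abs(ev.imag) > min_imag]
    if len(cplx) == 0:
        return None, None
    i = np.argmax(cplx.real)
    return float(cplx.real[i]), float(abs(cplx.imag[i]))


def _n_unstable_complex(problem, y, th, min_imag=1.0):
    ev = np.linalg.eigvals(problem.jac(y, th))
    return int(np.sum((ev.real > 0) & (ev.imag > min_imag)))


def _refine_hopf(problem, y_lo, th_lo, th_hi, tol=1e-8):
    """Bisect the parameter at which the number of unstable complex pairs
    changes; return the pair closest to the imaginary axis there."""
    y = _newton(problem, y_lo, th_lo)
    n_lo = _n_unstable_complex(problem, y, th_lo)
    for _ in range(60):
        if abs(th_hi - th_lo) < tol * max(1.0, abs(th_hi)):
            break
        th_mid = 0.5 * (th_lo + th_hi)
        y = _newton(problem, y, th_mid)
        if _n_unstable_complex(problem, y, th_mid) == n_lo:
            th_lo = th_mid
        else:
            th_hi = th_mid
    th_star = 0.5 * (th_lo + th_hi)
    y = _newton(problem, y, th_star)
    ev = np.linalg.eigvals(problem.jac(y, th_star))
    cplx = ev[ev.imag > 1.0]
    i = np.argmin(np.abs(cplx.real))
    return y, th_star, float(cplx.real[i]), float(cplx.imag[i]) / (2 * np.pi)


def detect_codim1(
    branch: EquilibriumBranch,
    problem: ContinuationProblem | None = None,
    params: ModelParams | None = None,
    vary: str | None = None,
    classify_hopf: bool = False,
) -> list[BifurcationPoint]:
    """Locate folds and Hopf points along a continued branch.

    Folds are flagged where the branch tangent's parameter component changes
    sign and refined on the extended fold system; Hopf points where the number
    of complex eigenvalues in the right half plane changes, refined by
    bisection.  With ``classify_hopf`` each Hopf is probed by a short
    simulation just past the point to decide super/subcriticality.
    """
    pts = branch.points
    if len(pts) < 3:
        return []
    if problem is None:
        if params is None:
            raise ValueError("need problem or params")
        problem = lanmm_problem(params, vary or branch.vary)
    found: list[BifurcationPoint] = []

    def n_unstable_cplx(pt):
        ev = pt.eigenvalues
        return int(np.sum((ev.real > 0) & (ev.imag > 1.0)))

    th = branch.thetas
    dth = np.diff(th)
    for i in range(1, len(dth)):
        if dth[i - 1] * dth[i] < 0:  # parameter fold
            a = pts[i - 1]
            tan = _tangent(problem, a.state, a.theta)
            sec = np.concatenate([pts[i].state - a.state, [pts[i].theta - a.theta]])
            if np.dot(tan, sec) < 0:
                tan = -tan
            y_f, th_f = _refine_fold(problem, a.state, a.theta, tan)
            ev = np.linalg.eigvals(problem.jac(y_f, th_f))
            diag = float(ev.real[np.argmin(np.abs(ev))])
            found.append(_mk_bif("fold", th_f, y_f, diag, None, pts[i], branch.vary))
    for i in range(len(pts) - 1):
        a, b = pts[i], pts[i + 1]
        if n_unstable_cplx(a) != n_unstable_cplx(b) and abs(b.theta - a.theta) > 1e-12:
            lo, hi = (a, b) if a.theta < b.theta else (b, a)
            try:
                y_h, th_h, g, freq = _refine_hopf(problem, lo.state, lo.theta, hi.theta)
            except ConvergenceError:
                continue
            if abs(g) > 0.05:
                # complex count changed without an imaginary-axis crossing
                # (e.g. two real eigenvalues merging on the middle branch)
                continue
            kind = "hopf"
            if classify_hopf and params is not None:
                kind = _hopf_criticality(params, branch.vary, th_h, y_h, problem)
            found.append(_mk_bif(kind, th_h, y_h, g, freq, a, branch.vary))
    found.sort(key=lambda bp: bp.theta)
    return found


def _mk_bif(kind, th, y, diag, freq, ref_pt, vary):
    kw = {"phi_e1": ref_pt.phi_e1, "phi_e2": ref_pt.phi_e2}
    if vary in kw and kw[vary] is not None:
        kw[vary] = th
    return BifurcationPoint(kind=kind, theta=float(th), state=y, diagnostic=diag,
                            frequency=freq, phi_e1=kw["phi_e1"], phi_e2=kw["phi_e2"])


def _params_at(params: ModelParams, vary: str, th: float) -> ModelParams:
    if vary == "phi_e1":
        return params.with_inputs(phi_e1=th)
    if vary == "phi_e2":
        return params.with_inputs(phi_e2=th)
    return params.with_connectivity(**{vary: th})


def _oscillation_amplitude(params, state0, t_transient=15.0, t_record=3.0):
    from .simulate import SolverSettings, integrate

    ts = integrate(params, SolverSettings(t_transient=t_transient, t_record=t_record),
                   initial=state0)
    return float(np.ptp(ts.vP1) + np.ptp(ts.vP2))


def _hopf_criticality(params, vary, th_h, y_h, problem, delta=3.0):
    """Probe simulation just past the Hopf: supercritical if a small stable
    cycle exists on the unstable-equilibrium side with amplitude shrinking
    toward the point (square-root scaling)."""
    side = None
    for s in (+1, -1):
        try:
            y_eq = _newton(problem, y_h, th_h + s * delta)
        except ConvergenceError:
            continue
        g, _ = _complex_leading_re(problem, y_eq, th_h + s * delta)
        if g is not None and g > 0:
            side = s
            break
    if side is None:
        return "hopf"
    amps = []
    for d in (delta, delta / 4):
        pr = _params_at(params, vary, th_h + side * d)
        amps.append(_oscillation_amplitude(pr, y_h + 1e-3))
    if amps[1] < 0.75 * amps[0] and amps[0] < 50.0:
        return "hopf_super"
    return "hopf_sub"


# --------------------------------------------------------------------------- #
# SNIC classification and two-parameter loci
# --------------------------------------------------------------------------- #


def _mean_period(params, state0, t_record=20.0):
    """Period of the large-amplitude oscillation via mean inter-peak interval."""
    from scipy.signal import find_peaks

    from .simulate import SolverSettings, integrate

    ts = integrate(params, SolverSettings(t_transient=10.0, t_record=t_record),
                   initial=state0)
    x = ts.vP1 - ts.vP1.mean()
    if np.ptp(x) < 0.5:
        return None
    peaks, _ = find_peaks(x, prominence=0.25 * np.ptp(x))
    if len(peaks) < 3:
        return None
    return float(np.mean(np.diff(peaks)) / ts.sample_rate)


def classify_snic(fold: BifurcationPoint, params: ModelParams, vary: str = "phi_e1",
                  delta: float = 2.0) -> BifurcationPoint:
    """Relabel a fold as SNIC if a large-amplitude cycle with period diverging
    toward the fold exists just past it.

    Past the fold the two collided equilibria are gone; the invariant circle
    they sat on persists as a periodic orbit whose period grows like the
    inverse square root of the distance to the bifurcation.
    """
    prob = lanmm_problem(params, vary)
    side = None
    for s in (+1, -1):
        try:
            y_eq = _newton(prob, fold.state, fold.theta + s * delta)
            if np.linalg.norm(y_eq - fold.state) > 0.05:
                side = s  # Newton jumped to a distant attractor: locals gone
        except ConvergenceError:
            side = s
        if side:
            break
    if side is None:
        return fold
    periods = []
    for d in (delta, delta / 4):
        try:
            pr = _params_at(params, vary, fold.theta + side * d)
        except ValueError:
            # probing side lies at unphysical parameter values (e.g. negative
            # input rates): no orbit can be exhibited there, keep the fold
            return fold
        periods.append(_mean_period(pr, fold.state))
    if periods[0] is not None and periods[1] is not None and periods[1] > 1.05 * periods[0]:
        return BifurcationPoint(kind="SNIC", theta=fold.theta, state=fold.state,
                                diagnostic=fold.diagnostic, frequency=None,
                                phi_e1=fold.phi_e1, phi_e2=fold.phi_e2)
    return fold


def _select_locus_point(bifs: list[BifurcationPoint], kind: str, window=(0.0, 600.0)):
    """Pick the branch event matching a named locus, inside the window.

    ``SNIC``/``fold``: the fold terminating the low-input steady branch
    (largest parameter among in-window folds).  ``HB1``: Hopf with emergent
    frequency below 25 Hz (alpha-range onset).  ``HB2``: Hopf at gamma
    frequency (>= 25 Hz).
    """
    lo, hi = window
    inside = [b for b in bifs if lo <= b.theta <= hi]
    if kind in ("fold", "SNIC"):
        folds = [b for b in inside if b.kind in ("fold", "SNIC")]
        return max(folds, key=lambda b: b.theta) if folds else None
    hopfs = [b for b in inside if b.kind.startswith("hopf") and b.frequency is not None]
    if kind == "HB1":
        cand = [b for b in hopfs if b.frequency < 25.0]
    elif kind == "HB2":
        cand = [b for b in hopfs if b.frequency >= 25.0]
    else:
        raise ValueError(f"unknown locus kind {kind!r}")
    return min(cand, key=lambda b: b.theta) if cand else None


def trace_locus_2param(
    params: ModelParams,
    kind: str,
    grid_phi2,
    phi1_range: tuple[float, float] = (0.0, 600.0),
    step: float = 1.0,
) -> list[BifurcationPoint]:
    """Trace a bifurcation locus over a grid of phi_e2 values.

    For each phi_e2 the phi_e1 branch is continued and the matching event
    (see :func:`_select_locus_point`) collected; grid values where the event
    has left the range are omitted.
    """
    locus = []
    for phi2 in grid_phi2:
        pr = params.with_inputs(phi_e2=float(phi2))
        try:
            branch = continue_branch(pr, "phi_e1", phi1_range, step=step)
        except ConvergenceError:
            continue
        hit = _select_locus_point(branch.bifurcations, kind, window=phi1_range)
        if hit is not None:
            locus.append(hit)
    return locus
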