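"""Composite experiments: PV-interneuron dysfunction and two coupled columns.

The PV scan reduces the PV -> P2 coupling C7 from its standard value 550
(the proposed effect of amyloid-beta oligomer accumulation on fast
interneuron synapses) and recomputes, for each value, the bifurcation loci
that organize multifrequency activity: the SNIC fold, the slow-rhythm Hopf
(HB1+) and the gamma Hopf (HB2+), over a window of the two external drives.
The scalar "coexistence fraction" is the fraction of the window where the
slow cycle (between the SNIC and HB1 loci) and the fast cycle (past the HB2
locus) coexist -- the shaded overlap region whose growth or collapse tracks
hyperexcitability and gamma extinction.

The two-column model couples two identical columns: feedforward from the
superficial pyramidal population of column 1 to the superficial pyramidal
population of column 2, feedback from the deep pyramidal population of
column 2 to the deep and superficial pyramidal populations and the slow
interneurons of column 1.  Coupled rates enter the target membrane
potentials through the steady AMPA gain A_A/a_A, the same convention used
for the external drives, so the state stays 20-dimensional.  The coupling
gains are package defaults chosen to be comparable to the intracolumn
long-range constants (C11-C13); they are explicit configuration, not
canonical values.  All four pyramidal populations receive the same external
rate phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _fast
from .equilibria import (
    BifurcationPoint,
    ContinuationProblem,
    EquilibriumBranch,
    EquilibriumPoint,
    _select_locus_point,
    continue_branch,
    continue_problem,
    detect_codim1,
)
from .cycles import CycleBranch, FlowSystem, PeriodicOrbit, _make_orbit, _shoot_newton
from .params import ModelParams

__all__ = [
    "PVScanResult",
    "pv_scan",
    "TwoColumnParams",
    "two_column_rhs",
    "two_column_jacobian",
    "two_column_observables",
    "two_column_integrate",
    "two_column_problem",
    "two_column_branch",
    "two_column_flow",
    "two_column_cycle",
    "two_column_cycles",
]


# --------------------------------------------------------------------------- #
# PV dysfunction scan
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class PVScanEntry:
    """Loci and coexistence fraction for one value of the PV->P2 coupling."""

    c7: float
    phi2_grid: np.ndarray
    snic: np.ndarray  # phi_e1 of the SNIC fold per phi_e2 (NaN if absent)
    hb1: np.ndarray   # slow-rhythm Hopf
    hb2: np.ndarray   # gamma Hopf (-inf: gamma unstable already at phi_e1=0)
    coexistence_fraction: float


@dataclass
class PVScanResult:
    entries: list = field(default_factory=list)

    def entry(self, c7: float) -> PVScanEntry:
        for e in self.entries:
            if e.c7 == c7:
                return e
        raise KeyError(c7)

    def to_frame(self):
        import pandas as pd

        rows = []
        for e in self.entries:
            for k, phi2 in enumerate(e.phi2_grid):
                rows.append({"C7": e.c7, "phi_e2": phi2, "snic": e.snic[k],
                             "hb1": e.hb1[k], "hb2": e.hb2[k]})
        return pd.DataFrame(rows)


def pv_scan(
    params: ModelParams,
    c7_values=(550.0, 300.0, 150.0, 75.0),
    phi2_grid=None,
    phi1_range: tuple = (0.0, 600.0),
    phi1_cells: int = 48,
) -> PVScanResult:
    """Recompute the SNIC/HB1/HB2 loci and the cycle-coexistence fraction for
    each PV->P2 coupling value.

    The baseline C7 = 550 uses exactly the same code path as the equilibrium
    module, so its loci agree bit-for-bit with a direct branch computation.
    """
    phi2_grid = np.linspace(0.0, 350.0, 8) if phi2_grid is None else np.asarray(phi2_grid, float)
    out = PVScanResult()
    phi1_axis = np.linspace(phi1_range[0], phi1_range[1], phi1_cells)
    for c7 in c7_values:
        base = params.with_connectivity(C7=float(c7))
        snic = np.full(len(phi2_grid), np.nan)
        hb1 = np.full(len(phi2_grid), np.nan)
        hb2 = np.full(len(phi2_grid), np.nan)
        # loci are selected over a window extended below zero drive: a locus
        # that crossed to negative phi_e1 means the corresponding cycle is
        # present for every physical phi_e1 at that phi_e2
        wide = (phi1_range[0] - 150.0, phi1_range[1])
        for k, phi2 in enumerate(phi2_grid):
            pr = base.with_inputs(phi_e2=float(phi2))
            try:
                branch = continue_branch(pr, "phi_e1", phi1_range)
            except Exception:
                continue
            for kind, arr in (("SNIC", snic), ("HB1", hb1), ("HB2", hb2)):
                hit = _select_locus_point(branch.bifurcations, kind, window=wide)
                if hit is not None:
                    arr[k] = hit.theta
        # coexistence: slow cycle between SNIC and HB1, fast cycle past HB2
        hits = 0
        for k in range(len(phi2_grid)):
            if np.isnan(snic[k]) or np.isnan(hb1[k]):
                continue
            for a in phi1_axis:
                slow = snic[k] <= a <= hb1[k]
                fast = (not np.isnan(hb2[k])) and a >= hb2[k]
                if slow and fast:
                    hits += 1
        frac = hits / max(1, len(phi2_grid) * phi1_cells)
        out.entries.append(PVScanEntry(c7=float(c7), phi2_grid=phi2_grid.copy(),
                                       snic=snic, hb1=hb1, hb2=hb2,
                                       coexistence_fraction=frac))
    return out


# --------------------------------------------------------------------------- #
# two-column model
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class TwoColumnParams:
    """Two identical columns with feedforward/feedback coupling.

    ``phi`` (1/s) is the shared external rate into all four pyramidal
    populations.  Gains are dimensionless contact counts for the coupled
    rates; zero gains decouple the columns exactly.  The default gains are a
    documented placeholder set of the same order as the intracolumn
    constants C11-C13, not canonical values.
    """

    column: ModelParams = field(default_factory=ModelParams)
    phi: float = 120.0
    k_ff: float = 50.0       # P12 -> P22 (superficial feedforward)
    k_fb_p11: float = 30.0   # P21 -> P11 (deep feedback)
    k_fb_p12: float = 30.0   # P21 -> P12
    k_fb_sst: float = 10.0   # P21 -> SST of column 1

    def gains(self) -> np.ndarray:
        return np.array([self.k_ff, self.k_fb_p11, self.k_fb_p12, self.k_fb_sst])

    def as_vector(self, phi: float | None = None) -> np.ndarray:
        # write the drive directly into the flat vector: continuation may
        # probe (unphysical) negative rates while rounding a fold
        phi = self.phi if phi is None else phi
        p = self.column.as_vector()
        p[26] = p[27] = phi
        return p

    def with_phi(self, phi: float) -> "TwoColumnParams":
        return replace(self, phi=float(phi))


def _check20(state) -> np.ndarray:
    z = np.asarray(state, dtype=float)
    if z.shape != (20,) or not np.all(np.isfinite(z)):
        raise ValueError("two-column state must be 20 finite values")
    return z


def two_column_rhs(state, params: TwoColumnParams) -> np.ndarray:
    """Time derivative of the 20-dimensional coupled-column state."""
    return _fast.rhs20(_check20(state), params.as_vector(), params.gains())


def two_column_jacobian(state, params: TwoColumnParams) -> np.ndarray:
    """Analytic 20x20 Jacobian (chain rule through the coupling terms)."""
    return _fast.jac20(_check20(state), params.as_vector(), params.gains())


def two_column_observables(states, params: TwoColumnParams):
    """(vP11, vP12, vP21, vP22) for one state or an array of states.

    First index: column; second index: layer (1 deep, 2 superficial).
    """
    Z = np.asarray(states, dtype=float)
    C = params.column.connectivity
    def deep(z):
        return C.C1 * z[..., 1] + C.C2 * z[..., 2] + C.C11 * z[..., 3]
    def sup(z):
        return C.C6 * z[..., 3] + C.C7 * z[..., 4] + C.C12 * z[..., 0]
    c1, c2 = Z[..., :10], Z[..., 10:]
    return deep(c1), sup(c1), deep(c2), sup(c2)


def two_column_integrate(
    params: TwoColumnParams,
    t_transient: float = 10.0,
    t_record: float = 30.0,
    sample_rate: float = 1000.0,
    dt: float = 1e-4,
    initial=None,
):
    """Fixed-step integration; returns (t, states) sampled at sample_rate."""
    z0 = np.zeros(20) if initial is None else _check20(initial)
    p = params.as_vector()
    g = params.gains()
    n_trans = int(round(t_transient / dt))
    if n_trans:
        z0 = _fast.rk4_final20(z0, p, g, dt, n_trans)
    n_sub = int(round(1.0 / (sample_rate * dt)))
    n_rec = int(round(t_record * sample_rate))
    path = _fast.rk4_path20(z0, p, g, dt, n_sub, n_rec)[:-1]
    if not np.all(np.isfinite(path)):
        raise RuntimeError("two-column trajectory blew up")
    t = np.arange(n_rec) / sample_rate
    return t, path


def two_column_problem(params: TwoColumnParams) -> ContinuationProblem:
    """Continuation problem in the shared pyramidal drive phi."""
    g = params.gains()

    def f(z, th):
        return _fast.rhs20(z, params.as_vector(th), g)

    def jac(z, th):
        return _fast.jac20(z, params.as_vector(th), g)

    return ContinuationProblem(f, jac, 20)


def two_column_flow(params: TwoColumnParams) -> FlowSystem:
    g = params.gains()

    def rhs(z, th):
        return _fast.rhs20(z, params.as_vector(th), g)

    def flow(z, th, T, nsteps):
        return _fast.rk4_final20(z, params.as_vector(th), g, T / nsteps, nsteps)

    def flow_var(z, th, T, nsteps):
        return _fast.flow_and_monodromy20(z, params.as_vector(th), g, T, nsteps)

    def observables(states):
        v11, v12, _, _ = two_column_observables(states, params)
        return v11, v12

    return FlowSystem(20, rhs, flow, flow_var, observables)


def two_column_branch(
    params: TwoColumnParams,
    phi_range: tuple = (0.0, 600.0),
    step: float = 0.5,
    start_state=None,
) -> EquilibriumBranch:
    """Equilibrium branch of the coupled system in phi, with fold and Hopf
    detection, via the same continuation machinery as the single column."""
    prob = two_column_problem(params)
    pts = continue_problem(prob, phi_range[0], phi_range[1], y_start=start_state, step=step)
    enriched = [
        EquilibriumPoint(theta=pt.theta, state=pt.state, eigenvalues=pt.eigenvalues,
                         phi_e1=pt.theta, phi_e2=pt.theta)
        for pt in pts
    ]
    branch = EquilibriumBranch(vary="phi", points=enriched)
    branch.bifurcations = detect_codim1(branch, prob)
    return branch


def two_column_cycle(params: TwoColumnParams, guess_state, guess_period: float,
                     phi: float | None = None) -> PeriodicOrbit:
    """Converge a periodic orbit of the coupled system by shooting."""
    sys = two_column_flow(params)
    th = params.phi if phi is None else float(phi)
    x, T, M = _shoot_newton(sys, guess_state, guess_period, th)
    return _make_orbit(sys, None, "phi", x, T, th, M)


def two_column_cycles(
    params: TwoColumnParams,
    start: PeriodicOrbit,
    phi_range: tuple = (0.0, 600.0),
    **kwargs,
) -> CycleBranch:
    """Continue a cycle branch of the coupled system in phi, with the same
    Floquet-based FLC/torus/period-doubling detection as the single column."""
    from .cycles import continue_cycles

    return continue_cycles(start, None, "phi", phi_range,
                           flow=two_column_flow(params), **kwargs)
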