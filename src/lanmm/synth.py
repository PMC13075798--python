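"""Synthetic signals and reference systems with known ground truth.

Every estimator in the analysis pipeline is validated against inputs whose
answer is known in closed form, independent of the neural mass model:

* phase-amplitude-coupled test signals with a controllable coupling depth,
  for the modulation-index estimator;
* small flows with analytically known Lyapunov spectra (a linear contraction,
  a limit-cycle normal form, an isometric torus flow), for the Benettin
  estimator;
* direct kernel convolution, the defining integral form of the synapse,
  as the oracle for its second-order ODE form.

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import psp_kernel
from .params import SynapseKernel
from .simulate import TimeSeries

__all__ = [
    "SyntheticPACSpec",
    "synthetic_pac_signal",
    "ReferenceSystem",
    "reference_le_system",
    "convolution_oracle",
    "benettin_reference",
]

DEFAULT_SEED = 12345


@dataclass(frozen=True)
class SyntheticPACSpec:
    """Amplitude-modulated two-tone signal with coupling depth d in [0, 1].

    x(t) = sin(2 pi f_slow t)
         + [1 - d + d (1 + sin(2 pi f_slow t)) / 2] sin(2 pi f_fast t)
         + noise

    At d = 0 the fast amplitude is constant (no coupling); at d = 1 it swings
    between 0.5 and 1.5 in lockstep with the slow phase.
    """

    slow_freq: float = 5.0
    fast_freq: float = 40.0
    coupling_depth: float = 1.0
    noise_sd: float = 0.0
    duration: float = 20.0
    sample_rate: float = 1000.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling_depth <= 1.0):
            raise ValueError("coupling_depth must be in [0, 1]")
        if self.fast_freq <= self.slow_freq:
            raise ValueError("fast_freq must exceed slow_freq")
        if self.sample_rate <= 2 * self.fast_freq:
            raise ValueError("sample_rate must exceed twice fast_freq")


def synthetic_pac_signal(spec: SyntheticPACSpec) -> TimeSeries:
    """Generate the PAC test signal on both observable channels."""
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    slow = np.sin(2 * np.pi * spec.slow_freq * t)
    d = spec.coupling_depth
    envelope = 1.0 - d + d * (1.0 + slow) / 2.0
    x = slow + envelope * np.sin(2 * np.pi * spec.fast_freq * t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        x = x + rng.normal(scale=spec.noise_sd, size=n)
    return TimeSeries(t=t, vP1=x.copy(), vP2=x.copy(), sample_rate=spec.sample_rate)


@dataclass(frozen=True)
class ReferenceSystem:
    """A small flow with analytically known two largest Lyapunov exponents."""

    label: str
    dim: int
    rhs: callable
    jac: callable
    known_l1: float
    known_l2: float
    initial: np.ndarray


def reference_le_system(label: str, kappa: float = 1.0, omega: float = 2.0) -> ReferenceSystem:
    """Reference flows for the Lyapunov estimator.

    ``linear_stable``: dx/dt = diag(-1, -3) x, exponents (-1, -3).
    ``harmonic_pair``: limit-cycle normal form dr/dt = kappa r (1 - r^2),
    dtheta/dt = omega; exponents (0, -2 kappa).
    ``quasiperiodic_torus_flow``: two uncoupled rotations at incommensurate
    frequencies; all exponents 0 (isometric flow).
    """
    if label == "linear_stable":
        A = np.diag([-1.0, -3.0])

        def rhs(y):
            return A @ y

        def jac(y):
            return A

        return ReferenceSystem(label, 2, rhs, jac, -1.0, -3.0,
                               initial=np.array([1.0, 1.0]))

    if label == "harmonic_pair":

        def rhs(y):
            x, z = y
            r2 = x * x + z * z
            return np.array([kappa * x * (1 - r2) - omega * z,
                             kappa * z * (1 - r2) + omega * x])

        def jac(y):
            x, z = y
            r2 = x * x + z * z
            return np.array([
                [kappa * (1 - r2) - 2 * kappa * x * x, -2 * kappa * x * z - omega],
                [omega - 2 * kappa * x * z, kappa * (1 - r2) - 2 * kappa * z * z],
            ])

        return ReferenceSystem(label, 2, rhs, jac, 0.0, -2.0 * kappa,
                               initial=np.array([1.0, 0.0]))

    if label == "quasiperiodic_torus_flow":
        w1, w2 = 1.0, np.sqrt(2.0)
        A = np.zeros((4, 4))
        A[0, 1], A[1, 0] = -w1, w1
        A[2, 3], A[3, 2] = -w2, w2

        def rhs(y):
            return A @ y

        def jac(y):
            return A

        return ReferenceSystem(label, 4, rhs, jac, 0.0, 0.0,
                               initial=np.array([1.0, 0.0, 1.0, 0.0]))

    raise ValueError(f"unknown reference system {label!r}")


def benettin_reference(
    system: ReferenceSystem,
    t_transient: float = 20.0,
    t_accumulate: float = 200.0,
    renorm_interval: float = 0.1,
    dt: float = 1e-3,
) -> tuple[float, float]:
    """Benettin estimate of the two largest exponents of a reference flow.

    Same algorithm as the model-specific estimator (RK4 for the flow and the
    tangent pair, periodic Gram-Schmidt), in plain numpy since the reference
    systems are tiny.
    """
    n = system.dim

    def step(y, v1, v2, h):
        def f(yy, a, b):
            J = system.jac(yy)
            return system.rhs(yy), J @ a, J @ b

        k1 = f(y, v1, v2)
        k2 = f(y + 0.5 * h * k1[0], v1 + 0.5 * h * k1[1], v2 + 0.5 * h * k1[2])
        k3 = f(y + 0.5 * h * k2[0], v1 + 0.5 * h * k2[1], v2 + 0.5 * h * k2[2])
        k4 = f(y + h * k3[0], v1 + h * k3[1], v2 + h * k3[2])
        y = y + (h / 6) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        v1 = v1 + (h / 6) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        v2 = v2 + (h / 6) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        return y, v1, v2

    y = system.initial.astype(float).copy()
    for _ in range(int(round(t_transient / dt))):
        y, _, _ = step(y, np.zeros(n), np.zeros(n), dt)
    v1 = np.zeros(n)
    v2 = np.zeros(n)
    v1[0] = 1.0
    v2[min(1, n - 1)] = 1.0
    ren_steps = max(1, int(round(renorm_interval / dt)))
    n_ren = int(round(t_accumulate / (ren_steps * dt)))
    s1 = s2 = 0.0
    for _ in range(n_ren):
        for _ in range(ren_steps):
            y, v1, v2 = step(y, v1, v2, dt)
        n1 = np.linalg.norm(v1)
        v1 /= n1
        v2 -= (v2 @ v1) * v1
        n2 = np.linalg.norm(v2)
        v2 /= n2
        s1 += np.log(n1)
        s2 += np.log(n2)
    span = n_ren * ren_steps * dt
    l1, l2 = s1 / span, s2 / span
    return (l1, l2) if l1 >= l2 else (l2, l1)


def convolution_oracle(rate_signal, kernel: SynapseKernel, sample_rate: float) -> np.ndarray:
    """PSP from direct discrete convolution of a rate signal with the kernel.

    Independent oracle for the second-order ODE form of the synapse: for a
    constant rate p the output settles to (A/a) p; for a unit-area impulse it
    reproduces the sampled kernel itself.
    """
    rate_signal = np.asarray(rate_signal, dtype=float)
    dt = 1.0 / sample_rate
    # kernel support: e^{-a t} t decays below 1e-12 of peak well before 30/a
    t_k = np.arange(int(np.ceil(30.0 / kernel.rate_a * sample_rate))) * dt
    h = psp_kernel(t_k, kernel)
    return np.convolve(rate_signal, h)[: len(rate_signal)] * dt
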