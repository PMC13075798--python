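"""Core LaNMM equations: kernels, sigmoid, vector field, Jacobian, observables.

The model is ten first-order ODEs: five postsynaptic-potential variables
``y1..y5`` (mV) paired with their derivatives ``y6..y10`` (mV/s).  Each pair
implements one second-order synapse

    y'' + 2a y' + a^2 y = A a sigma(v_pre)

with the kernel constants (A, a) of the presynaptic transmitter and the
presynaptic population's membrane potential ``v_pre``, a weighted sum of PSPs
and external drive.  External rates ``phi_e`` enter the membrane potential as
steady AMPA potentials (A_A/a_A)*phi_e, the DC gain of the synaptic kernel.

Public functions accept :class:`~lanmm.params.ModelParams`; the hot loops live
in :mod:`lanmm._fast` and operate on the flat parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _fast
from .params import ModelParams, SynapseKernel, SigmoidParams

__all__ = [
    "psp_kernel",
    "frequency_response",
    "sigmoid",
    "sigmoid_derivative",
    "input_rate_to_potential",
    "rhs",
    "jacobian",
    "observables",
    "membrane_potentials",
    "Observables",
]


def psp_kernel(t, k: SynapseKernel):
    """Postsynaptic potential kernel h(t) = A*a*t*exp(-a*t), zero for t < 0.

    Parameters
    ----------
    t : float or array
        Time in seconds.
    k : SynapseKernel
        Kernel constants (gain mV, rate 1/s).

    Returns
    -------
    float or ndarray
        Potential in mV. Peaks at ``A/e`` at t = 1/a; integrates to ``A/a``.
    """
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, k.gain_A * k.rate_a * t * np.exp(-k.rate_a * np.where(t >= 0, t, 0.0)), 0.0)
    return out if out.ndim else float(out)


def frequency_response(omega, k: SynapseKernel):
    """Fourier transform of the kernel, H(j*omega) = A*a / (a + j*omega)^2.

    The magnitude decreases monotonically in |omega|; the DC gain is A/a.
    """
    omega = np.asarray(omega, dtype=float)
    out = k.gain_A * k.rate_a / (k.rate_a + 1j * omega) ** 2
    return out if out.ndim else complex(out)


def sigmoid(v, p: SigmoidParams):
    """Potential-to-rate sigmoid, 2*phi0 / (1 + exp(r*(v0 - v))), in 1/s.

    Saturates to 0 and 2*phi0; overflow-safe for arbitrarily large |v|.
    """
    v = np.asarray(v, dtype=float)
    z = np.clip(p.slope_r * (p.v0 - v), -700.0, 700.0)
    out = 2.0 * p.phi0 / (1.0 + np.exp(z))
    return out if out.ndim else float(out)


def sigmoid_derivative(v, p: SigmoidParams):
    """d(sigma)/dv = r * sigma * (1 - sigma / (2*phi0)), in 1/(s*mV)."""
    s = sigmoid(v, p)
    return p.slope_r * s * (1.0 - s / (2.0 * p.phi0))


def input_rate_to_potential(rate, k: SynapseKernel):
    """Steady-state PSP (mV) of kernel ``k`` driven by a constant rate (1/s).

    Since the kernel integrates to A/a, a constant presynaptic rate settles to
    the potential (A/a)*rate. This conversion is how the external drives
    phi_e1, phi_e2 enter the pyramidal membrane potentials.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("input rate must be nonnegative")
    out = (k.gain_A / k.rate_a) * rate
    return out if out.ndim else float(out)


def _check_state(state) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    if y.shape != (10,):
        raise ValueError(f"state must have length 10, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite values")
    return y


def rhs(state, params: ModelParams) -> np.ndarray:
    """Time derivative of the ten-dimensional state.

    The system is autonomous: the derivative depends only on the state and
    the parameters (external drives are constant rates).
    """
    y = _check_state(state)
    return _fast.rhs10(y, params.as_vector())


def jacobian(state, params: ModelParams) -> np.ndarray:
    """Analytic 10x10 Jacobian of :func:`rhs` at ``state``.

    Rows for y1..y5 are the [0 I] selectors onto y6..y10; the remaining rows
    differentiate the sigmoid blocks using sigma'(v) = r*sigma*(1 - sigma/(2*phi0)).
    """
    y = _check_state(state)
    return _fast.jac10(y, params.as_vector())


@dataclass(frozen=True)
class Observables:
    """Pyramidal membrane potentials read out from the state (mV)."""

    vP1: float
    vP2: float


def observables(state, params: ModelParams) -> Observables:
    """Membrane potentials of the two pyramidal populations.

    vP1 = C1*y2 + C2*y3 + C11*y4 (deep-layer pyramidal)
    vP2 = C6*y4 + C7*y5 + C12*y1 (superficial pyramidal)
    """
    y = np.asarray(state, dtype=float)
    C = params.connectivity
    if y.ndim == 1:
        return Observables(
            vP1=float(C.C1 * y[1] + C.C2 * y[2] + C.C11 * y[3]),
            vP2=float(C.C6 * y[3] + C.C7 * y[4] + C.C12 * y[0]),
        )
    raise ValueError("observables expects a single state; use membrane_potentials for arrays")


def membrane_potentials(states: np.ndarray, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (vP1, vP2) for an array of states with shape (n, 10)."""
    Y = np.asarray(states, dtype=float)
    C = params.connectivity
    vP1 = C.C1 * Y[..., 1] + C.C2 * Y[..., 2] + C.C11 * Y[..., 3]
    vP2 = C.C6 * Y[..., 3] + C.C7 * Y[..., 4] + C.C12 * Y[..., 0]
    return vP1, vP2
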