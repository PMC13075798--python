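import numpy as np
import pytest

from lanmm.params import ModelParams
from lanmm.simulate import SolverSettings


@pytest.fixture(scope="session")
def table1() -> ModelParams:
    """The standard parameter set."""
    return ModelParams()


@pytest.fixture(scope="session")
def quick_settings() -> SolverSettings:
    """Short integration for tests that only need a settled attractor."""
    return SolverSettings(t_transient=10.0, t_record=10.0)


@pytest.fixture(scope="session")
def spectral_settings() -> SolverSettings:
    """Long enough for 0.1 Hz Welch resolution with several averages."""
    return SolverSettings(t_transient=10.0, t_record=50.0)


@pytest.fixture(scope="session")
def branch_phi2_0(table1):
    """Equilibrium branch over phi_e1 at phi_e2 = 0, with detections."""
    from lanmm.equilibria import continue_branch

    return continue_branch(table1.with_inputs(0.0, 0.0), "phi_e1", (0.0, 600.0))


@pytest.fixture(scope="session")
def alpha_orbit(table1):
    """Converged stable alpha cycle at (phi_e1, phi_e2) = (250, 0)."""
    from lanmm.cycles import cycle_from_simulation

    return cycle_from_simulation(table1.with_inputs(250.0, 0.0))


def rhs_complex_oracle(y, p):
    """Complex-step-capable mirror of the vector field, written directly from
    the model equations; used to differentiate to machine precision."""
    AA, AGs, AGf, aA, aGs, aGf = p[:6]
    C = p[6:19]
    phi0, r = p[19], p[20]

    def sig(v, v0):
        return 2 * phi0 / (1 + np.exp(r * (v0 - v)))

    q = AA / aA
    a1 = C[0] * y[1] + C[1] * y[2] + C[2] * q * p[26] + C[10] * y[3]
    a2 = C[3] * y[0]
    a3 = C[4] * y[0]
    a4 = C[5] * y[3] + C[6] * y[4] + C[7] * q * p[27] + C[11] * y[0]
    a5 = C[8] * y[3] + C[9] * y[4] + C[12] * y[0]
    d = np.empty(10, dtype=complex)
    d[:5] = y[5:]
    d[5] = aA * AA * sig(a1, p[21]) - 2 * aA * y[5] - aA**2 * y[0]
    d[6] = aA * AA * sig(a2, p[22]) - 2 * aA * y[6] - aA**2 * y[1]
    d[7] = aGs * AGs * sig(a3, p[23]) - 2 * aGs * y[7] - aGs**2 * y[2]
    d[8] = aA * AA * sig(a4, p[24]) - 2 * aA * y[8] - aA**2 * y[3]
    d[9] = aGf * AGf * sig(a5, p[25]) - 2 * aGf * y[9] - aGf**2 * y[4]
    return d
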