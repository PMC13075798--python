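"""Model parameterization: synaptic kernels, sigmoids, connectivity, inputs.

The laminar neural mass model (LaNMM) couples a Jansen–Rit circuit (deep-layer
pyramidal cells P1, spiny stellate cells SS, slow somatostatin interneurons
SST) with a PING circuit (superficial pyramidal cells P2, fast parvalbumin
interneurons PV).  Every synapse is one of three second-order kernels (AMPA,
slow GABA, fast GABA); connectivity constants C1..C13 count average synaptic
contacts; the two external drives ``phi_e1`` and ``phi_e2`` are presynaptic
firing rates onto P1 and P2.

:class:`ModelParams` holds the full parameter set.  Default construction
reproduces the standard values used throughout the analysis; a canonical copy
ships as ``data/table1.json`` and round-trips bit-exactly through
:meth:`ModelParams.to_json` / :meth:`ModelParams.from_json`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from importlib import resources

import numpy as np

__all__ = [
    "SynapseKernel",
    "SigmoidParams",
    "Connectivity",
    "ExternalInputs",
    "ModelParams",
    "POPULATIONS",
    "PARAM_VEC_SIZE",
]

#: population order used everywhere (state blocks, sigmoid table)
POPULATIONS = ("P1", "SS", "SST", "P2", "PV")


@dataclass(frozen=True)
class SynapseKernel:
    """Second-order synaptic kernel h(t) = A·a·t·exp(-a·t) for t >= 0.

    Parameters
    ----------
    gain_A : float
        Synaptic gain in mV. Positive for excitatory (AMPA), negative for
        inhibitory (GABA) synapses.
    rate_a : float
        Inverse time constant of the postsynaptic potential, 1/s. Must be
        positive.
    label : str
        One of ``"AMPA"``, ``"GABA_slow"``, ``"GABA_fast"``.
    """

    gain_A: float
    rate_a: float
    label: str

    def __post_init__(self) -> None:
        if self.rate_a <= 0:
            raise ValueError(f"rate_a must be positive, got {self.rate_a}")
        if self.label not in ("AMPA", "GABA_slow", "GABA_fast"):
            raise ValueError(f"unknown kernel label {self.label!r}")
        if self.label == "AMPA" and self.gain_A <= 0:
            raise ValueError("AMPA gain must be positive")
        if self.label.startswith("GABA") and self.gain_A >= 0:
            raise ValueError("GABA gain must be negative")


@dataclass(frozen=True)
class SigmoidParams:
    """Potential-to-rate sigmoid sigma(v) = 2*phi0 / (1 + exp(r*(v0 - v))).

    ``phi0`` (1/s) is the half-maximal firing rate, ``v0`` (mV) the potential
    at which it is reached, ``slope_r`` (1/mV) the steepness at threshold.
    """

    v0: float
    phi0: float = 2.5
    slope_r: float = 0.56

    def __post_init__(self) -> None:
        if self.phi0 <= 0 or self.slope_r <= 0:
            raise ValueError("phi0 and slope_r must be positive")


@dataclass(frozen=True)
class Connectivity:
    """Average numbers of synaptic contacts between population types.

    ``C7`` is the PV -> P2 coupling reduced in the amyloid-beta /
    PV-dysfunction scenario.
    """

    C1: float = 108.0
    C2: float = 33.7
    C3: float = 1.0
    C4: float = 135.0
    C5: float = 33.75
    C6: float = 70.0
    C7: float = 550.0
    C8: float = 1.0
    C9: float = 200.0
    C10: float = 100.0
    C11: float = 80.0
    C12: float = 200.0
    C13: float = 30.0

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if val < 0:
                raise ValueError(f"{name} must be nonnegative, got {val}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f"C{i}") for i in range(1, 14)])


@dataclass(frozen=True)
class ExternalInputs:
    """External presynaptic rates (1/s) onto P1 (``phi_e1``) and P2 (``phi_e2``)."""

    phi_e1: float = 200.0
    phi_e2: float = 90.0

    def __post_init__(self) -> None:
        if self.phi_e1 < 0 or self.phi_e2 < 0:
            raise ValueError("external input rates must be nonnegative")


def _default_kernels() -> dict:
    return {
        "AMPA": SynapseKernel(3.25, 100.0, "AMPA"),
        "GABA_slow": SynapseKernel(-22.0, 50.0, "GABA_slow"),
        "GABA_fast": SynapseKernel(-30.0, 220.0, "GABA_fast"),
    }


def _default_sigmoids() -> dict:
    # all populations share (phi0, r); only P2 has the lower threshold v0=1 mV
    return {pop: SigmoidParams(v0=(1.0 if pop == "P2" else 6.0)) for pop in POPULATIONS}


#: length of the flat parameter vector used by the compiled kernels
PARAM_VEC_SIZE = 28


@dataclass(frozen=True)
class ModelParams:
    """Complete LaNMM parameter set (kernels, sigmoids, connectivity, inputs)."""

    kernels: dict = field(default_factory=_default_kernels)
    sigmoids: dict = field(default_factory=_default_sigmoids)
    connectivity: Connectivity = field(default_factory=Connectivity)
    inputs: ExternalInputs = field(default_factory=ExternalInputs)

    def __post_init__(self) -> None:
        if set(self.kernels) != {"AMPA", "GABA_slow", "GABA_fast"}:
            raise ValueError("kernels must define AMPA, GABA_slow, GABA_fast")
        if set(self.sigmoids) != set(POPULATIONS):
            raise ValueError(f"sigmoids must define {POPULATIONS}")

    # -- convenient accessors -------------------------------------------------
    @property
    def ampa(self) -> SynapseKernel:
        return self.kernels["AMPA"]

    @property
    def gaba_slow(self) -> SynapseKernel:
        return self.kernels["GABA_slow"]

    @property
    def gaba_fast(self) -> SynapseKernel:
        return self.kernels["GABA_fast"]

    def with_inputs(self, phi_e1: float | None = None, phi_e2: float | None = None) -> "ModelParams":
        """Return a copy with one or both external input rates replaced."""
        new = ExternalInputs(
            phi_e1 if phi_e1 is not None else self.inputs.phi_e1,
            phi_e2 if phi_e2 is not None else self.inputs.phi_e2,
        )
        return replace(self, inputs=new)

    def with_connectivity(self, **kwargs: float) -> "ModelParams":
        """Return a copy with some connectivity constants replaced (e.g. C7=300)."""
        return replace(self, connectivity=replace(self.connectivity, **kwargs))

    # -- flat vector for the compiled kernels ---------------------------------
    def as_vector(self) -> np.ndarray:
        """Pack into the flat float64 vector consumed by the jitted kernels.

        Layout: [A_A, A_Gs, A_Gf, a_A, a_Gs, a_Gf, C1..C13, phi0, r,
        v0(P1), v0(SS), v0(SST), v0(P2), v0(PV), phi_e1, phi_e2].
        """
        k = self.kernels
        p = np.empty(PARAM_VEC_SIZE)
        p[0] = k["AMPA"].gain_A
        p[1] = k["GABA_slow"].gain_A
        p[2] = k["GABA_fast"].gain_A
        p[3] = k["AMPA"].rate_a
        p[4] = k["GABA_slow"].rate_a
        p[5] = k["GABA_fast"].rate_a
        p[6:19] = self.connectivity.as_array()
        p[19] = self.sigmoids["P1"].phi0
        p[20] = self.sigmoids["P1"].slope_r
        for i, pop in enumerate(POPULATIONS):
            p[21 + i] = self.sigmoids[pop].v0
        p[26] = self.inputs.phi_e1
        p[27] = self.inputs.phi_e2
        return p

    # -- JSON round trip ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kernels": {k: asdict(v) for k, v in self.kernels.items()},
            "sigmoids": {k: asdict(v) for k, v in self.sigmoids.items()},
            "connectivity": asdict(self.connectivity),
            "inputs": asdict(self.inputs),
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            kernels={k: SynapseKernel(**v) for k, v in d["kernels"].items()},
            sigmoids={k: SigmoidParams(**v) for k, v in d["sigmoids"].items()},
            connectivity=Connectivity(**d["connectivity"]),
            inputs=ExternalInputs(**d["inputs"]),
        )

    @classmethod
    def from_json(cls, source) -> "ModelParams":
        """Load from a JSON string or a path to a JSON file."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            with open(text) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))

    @classmethod
    def table1(cls) -> "ModelParams":
        """The canonical standard parameter set shipped with the package."""
        ref = resources.files("lanmm").joinpath("data/table1.json")
        return cls.from_json(ref.read_text())
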