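{
  "connectivity": {
    "C1": 108.0,
    "C10": 100.0,
    "C11": 80.0,
    "C12": 200.0,
    "C13": 30.0,
    "C2": 33.7,
    "C3": 1.0,
    "C4": 135.0,
    "C5": 33.75,
    "C6": 70.0,
    "C7": 550.0,
    "C8": 1.0,
    "C9": 200.0
  },
  "inputs": {
    "phi_e1": 200.0,
    "phi_e2": 90.0
  },
  "kernels": {
    "AMPA": {
      "gain_A": 3.25,
      "label": "AMPA",
      "rate_a": 100.0
    },
    "GABA_fast": {
      "gain_A": -30.0,
      "label": "GABA_fast",
      "rate_a": 220.0
    },
    "GABA_slow": {
      "gain_A": -22.0,
      "label": "GABA_slow",
      "rate_a": 50.0
    }
  },
  "sigmoids": {
    "P1": {
      "phi0": 2.5,
      "slope_r": 0.56,
      "v0": 6.0
    },
    "P2": {
      "phi0": 2.5,
      "slope_r": 0.56,
      "v0": 1.0
    },
    "PV": {
      "phi0": 2.5,
      "slope_r": 0.56,
      "v0": 6.0
    },
    "SS": {
      "phi0": 2.5,
      "slope_r": 0.56,
      "v0": 6.0
    },
    "SST": {
      "phi0": 2.5,
      "slope_r": 0.56,
      "v0": 6.0
    }
  }
}
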