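{
  "version": "1.0",
  "scales": {
    "EISENBERG_HYDROPHOBICITY": {
      "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
      "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
      "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
      "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08
    },
    "KYTE_DOOLITTLE_HYDROPATHICITY": {
      "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
      "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
      "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
      "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2
    },
    "HOPP_WOODS_HYDROPHILICITY": {
      "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
      "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
      "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
      "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5
    }
  }
}
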