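{
  "name": "lna-nn-increments",
  "version": "1.0",
  "description": "Nearest-neighbor perturbation increments (ddH in kcal/mol, ddS in cal/(mol*K)) for a locked-nucleic-acid residue in a DNA duplex, indexed by the identity of the perturbed dinucleotide stack. Each modified residue perturbs both adjacent stacks; stacks flanked by two modified residues are attenuated by the consecutive_attenuation factor because strict nearest-neighbor additivity over-predicts the stability of contiguous LNA runs.",
  "citation": "McTigue PM, Peterson RJ, Kahn JD (2004) Sequence-dependent thermodynamic parameters for locked nucleic acid (LNA)-DNA duplex formation. Biochemistry 43:5388-5405 (single-substitution parameterization).",
  "consecutive_attenuation": 0.5,
  "stacks": {
    "AA": {"ddH": 0.707, "ddS": 2.477},
    "AC": {"ddH": 1.131, "ddS": 4.064},
    "AG": {"ddH": 0.264, "ddS": 2.613},
    "AT": {"ddH": 2.282, "ddS": 7.457},
    "CA": {"ddH": 1.049, "ddS": 4.32},
    "CC": {"ddH": 2.096, "ddS": 7.996},
    "CG": {"ddH": 0.785, "ddS": 3.709},
    "CT": {"ddH": 0.708, "ddS": 4.175},
    "GA": {"ddH": 3.162, "ddS": 10.544},
    "GC": {"ddH": -0.36, "ddS": -0.251},
    "GG": {"ddH": -2.844, "ddS": -6.68},
    "GT": {"ddH": -0.212, "ddS": 0.073},
    "TA": {"ddH": -0.046, "ddS": 1.562},
    "TC": {"ddH": 1.893, "ddS": 6.685},
    "TG": {"ddH": -1.54, "ddS": -3.044},
    "TT": {"ddH": 1.528, "ddS": 5.298}
  }
}
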