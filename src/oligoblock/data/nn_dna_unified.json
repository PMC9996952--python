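{
  "name": "unified-dna-nn",
  "version": "1.0",
  "description": "Unified nearest-neighbor thermodynamic parameters for DNA/DNA duplexes. dH in kcal/mol, dS in cal/(mol*K), measured at 1 M NaCl.",
  "citation": "SantaLucia J Jr (1998) A unified view of polymer, dumbbell, and oligonucleotide DNA nearest-neighbor thermodynamics. PNAS 95:1460-1465; SantaLucia J Jr & Hicks D (2004) Annu Rev Biophys Biomol Struct 33:415-440.",
  "stacks": {
    "AA": {"dH": -7.9, "dS": -22.2},
    "TT": {"dH": -7.9, "dS": -22.2},
    "AT": {"dH": -7.2, "dS": -20.4},
    "TA": {"dH": -7.2, "dS": -21.3},
    "CA": {"dH": -8.5, "dS": -22.7},
    "TG": {"dH": -8.5, "dS": -22.7},
    "GT": {"dH": -8.4, "dS": -22.4},
    "AC": {"dH": -8.4, "dS": -22.4},
    "CT": {"dH": -7.8, "dS": -21.0},
    "AG": {"dH": -7.8, "dS": -21.0},
    "GA": {"dH": -8.2, "dS": -22.2},
    "TC": {"dH": -8.2, "dS": -22.2},
    "CG": {"dH": -10.6, "dS": -27.2},
    "GC": {"dH": -9.8, "dS": -24.4},
    "GG": {"dH": -8.0, "dS": -19.9},
    "CC": {"dH": -8.0, "dS": -19.9}
  },
  "initiation": {
    "terminal_GC": {"dH": 0.1, "dS": -2.8},
    "terminal_AT": {"dH": 2.3, "dS": 4.1}
  }
}
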