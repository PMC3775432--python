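{
  "scale": "kyte-doolittle",
  "version": 1,
  "comment": "Hydrophobicity h on the Kyte-Doolittle hydropathy scale (positive = hydrophobic). pka_side: side-chain pKa; charge_sign: +1 base, -1 acid, 0 non-ionizable.",
  "residues": {
    "A": {"name": "Ala", "h": 1.8,  "pka_side": null, "charge_sign": 0},
    "R": {"name": "Arg", "h": -4.5, "pka_side": 12.5, "charge_sign": 1},
    "N": {"name": "Asn", "h": -3.5, "pka_side": null, "charge_sign": 0},
    "D": {"name": "Asp", "h": -3.5, "pka_side": 3.9,  "charge_sign": -1},
    "C": {"name": "Cys", "h": 2.5,  "pka_side": 8.4,  "charge_sign": -1},
    "Q": {"name": "Gln", "h": -3.5, "pka_side": null, "charge_sign": 0},
    "E": {"name": "Glu", "h": -3.5, "pka_side": 4.1,  "charge_sign": -1},
    "G": {"name": "Gly", "h": -0.4, "pka_side": null, "charge_sign": 0},
    "H": {"name": "His", "h": -3.2, "pka_side": 6.0,  "charge_sign": 1},
    "I": {"name": "Ile", "h": 4.5,  "pka_side": null, "charge_sign": 0},
    "L": {"name": "Leu", "h": 3.8,  "pka_side": null, "charge_sign": 0},
    "K": {"name": "Lys", "h": -3.9, "pka_side": 10.5, "charge_sign": 1},
    "M": {"name": "Met", "h": 1.9,  "pka_side": null, "charge_sign": 0},
    "F": {"name": "Phe", "h": 2.8,  "pka_side": null, "charge_sign": 0},
    "P": {"name": "Pro", "h": -1.6, "pka_side": null, "charge_sign": 0},
    "S": {"name": "Ser", "h": -0.8, "pka_side": null, "charge_sign": 0},
    "T": {"name": "Thr", "h": -0.7, "pka_side": null, "charge_sign": 0},
    "W": {"name": "Trp", "h": -0.9, "pka_side": null, "charge_sign": 0},
    "Y": {"name": "Tyr", "h": -1.3, "pka_side": 10.5, "charge_sign": -1},
    "V": {"name": "Val", "h": 4.2,  "pka_side": null, "charge_sign": 0}
  }
}
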