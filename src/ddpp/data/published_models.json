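{
  "everolimus": {
    "genes": ["AKT2", "TSC1", "FKBP1A", "TSC2", "RPTOR", "RHEB", "PIK3CA", "PIK3CB"],
    "method": "fold_abs",
    "channel": "tumor",
    "slope": 1.499e-13,
    "intercept": 3.134,
    "r": 0.99,
    "p": 5.67e-05,
    "n": 6
  },
  "axitinib": {
    "genes": ["KIT", "KITLG"],
    "method": "sum",
    "channel": "normal",
    "slope": 2.014e-02,
    "intercept": 4.36,
    "r": 0.99,
    "p": 4.68e-04,
    "n": 5
  },
  "trametinib": {
    "genes": ["MAPK1", "ARAF", "RAF1", "MAP2K1", "MAP2K2", "HRAS", "MAPK3", "MAPK10", "KSR1"],
    "method": "fold",
    "channel": "tumor",
    "slope": -6.872e-15,
    "intercept": 7.745,
    "r": -0.99,
    "p": 0.026,
    "n": 3
  },
  "afatinib": {
    "genes": ["NRG4", "NRG2"],
    "method": "sum",
    "channel": "tumor",
    "slope": -4.558e-02,
    "intercept": 2.549,
    "r": -1.0,
    "p": 8.4e-04,
    "n": 3
  },
  "fgfr": {
    "genes": ["FGF10", "FGF16", "FGF5", "FGF2", "FGF13"],
    "method": "sum",
    "channel": "normal",
    "slope": -5.273e-02,
    "intercept": 5.135,
    "r": -1.0,
    "p": 3.27e-03,
    "n": 3
  },
  "anti-pd1": {
    "genes": ["TLR4", "PDCD1LG2", "CD274", "FCGR3A", "CTLA4", "CD28"],
    "method": "fold",
    "channel": "normal",
    "slope": 7.856e-10,
    "intercept": -1.583,
    "r": 1.0,
    "p": 8.15e-04,
    "n": 3
  }
}
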