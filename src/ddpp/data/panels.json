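{
  "everolimus": {
    "genes": ["PIK3CA", "PIK3CB", "AKT1", "MTOR", "FKBP1A", "RPS6KB1", "EIF4EBP1", "HIF1A", "TSC1", "TSC2", "AKT2", "RPTOR", "PTEN", "RHEB", "MLST8", "RICTOR", "VEGFA"],
    "aliases": {"FKB-12": "FKBP1A", "S6K1": "RPS6KB1", "4EBP1": "EIF4EBP1", "HIF1": "HIF1A"},
    "source": "17 mTOR-pathway key genes: upstream regulators, MTORC1/MTORC2 members, downstream effectors"
  },
  "axitinib": {
    "genes": ["VEGFA", "VEGFB", "VEGFC", "PDGFA", "PDGFB", "FLT1", "KDR", "FLT4", "PDGFRA", "PDGFRB", "KIT", "KITLG", "FIGF"],
    "aliases": {"VEGFR1": "FLT1", "VEGFR2": "KDR", "VEGFR3": "FLT4", "VEGFD": "FIGF"},
    "source": "13 angiogenesis key genes: VEGF receptors and ligands, PDGF axis, KIT/KITLG"
  },
  "trametinib": {
    "genes": ["MAP2K1", "MAP2K2", "ARAF", "BRAF", "RAF1", "MAPK3", "MAPK1", "MAPK10", "KRAS", "HRAS", "NRAS", "KSR1", "RAP1A"],
    "aliases": {"MEK1": "MAP2K1", "MEK2": "MAP2K2", "ERK1": "MAPK3", "ERK2": "MAPK1", "CRAF": "RAF1"},
    "source": "13 MAPK-pathway key genes: RAF/MEK/ERK cascade and RAS family"
  },
  "afatinib": {
    "genes": ["EGFR", "ERBB2", "ERBB3", "ERBB4", "EGF", "TGFA", "AREG", "EREG", "HBEGF", "BTC", "NRG1", "NRG2", "NRG4"],
    "aliases": {"HER2": "ERBB2", "HER3": "ERBB3", "HER4": "ERBB4"},
    "source": "13 ERBB-family key genes: the four receptors and their ligands"
  },
  "fgfr": {
    "genes": ["FGFR1", "FGFR2", "FGFR3", "FGFR4", "FGF1", "FGF2", "FGF3", "FGF4", "FGF5", "FGF6", "FGF7", "FGF8", "FGF9", "FGF10", "FGF13", "FGF16", "FGF17", "FGF18", "FGF19"],
    "aliases": {},
    "source": "FGFR1-4 plus 15 FGF ligands; the ligand list beyond FGF1-10 (FGF13, FGF16, FGF17, FGF18, FGF19) completes the 19-gene family and covers every gene of the published five-gene predictor"
  },
  "anti-pd1": {
    "genes": ["CD274", "PDCD1LG2", "PDCD1", "CTLA4", "CD28", "CD80", "CD86", "LAG3", "TLR4", "CD8A", "FCGR3A", "FOXP3"],
    "aliases": {"PDL-1": "CD274", "PD-L1": "CD274", "PDL-2": "PDCD1LG2", "PD-L2": "PDCD1LG2", "PD-1": "PDCD1", "CTLA-4": "CTLA4", "LAG-3": "LAG3", "TLR-4": "TLR4", "CD16": "FCGR3A"},
    "source": "12 immuno-oncology key genes: checkpoint axis plus effector-infiltrate markers (CD8A cytotoxic T, FCGR3A NK, FOXP3 T-reg)"
  }
}
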