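{
  "_comment": "Reconstructed literature defaults for published comparator signatures. Gene lists are approximate reconstructions from the original publications, bundled for convenience; edit or replace with the exact lists for any serious benchmark.",
  "IFNG_6gene": {
    "type": "mean",
    "genes": ["IFNG", "STAT1", "IDO1", "CXCL9", "CXCL10", "HLA-DRA"]
  },
  "Tcell_inflamed_GEP": {
    "type": "mean",
    "genes": ["CCL5", "CD27", "CD274", "CD276", "CD8A", "CMKLR1", "CXCL9",
              "CXCR6", "HLA-DQA1", "HLA-DRB1", "HLA-E", "IDO1", "LAG3",
              "NKG7", "PDCD1LG2", "PSMB10", "STAT1", "TIGIT"]
  },
  "Chemokine": {
    "type": "mean",
    "genes": ["CCL2", "CCL3", "CCL4", "CCL5", "CCL8", "CCL18", "CCL19",
              "CCL21", "CXCL9", "CXCL10", "CXCL11", "CXCL13"]
  },
  "CYT": {
    "type": "geomean",
    "genes": ["GZMA", "PRF1"]
  },
  "MHC_I": {
    "type": "mean",
    "genes": ["HLA-A", "HLA-B", "HLA-C", "B2M", "TAP1", "TAP2"]
  },
  "MHC_II": {
    "type": "mean",
    "genes": ["HLA-DRA", "HLA-DRB1", "HLA-DQA1", "HLA-DQB1", "HLA-DPA1",
              "HLA-DPB1"]
  },
  "CD8A_CSF1R_ratio": {
    "type": "ratio",
    "numerator": "CD8A",
    "denominator": "CSF1R"
  },
  "IMPRES_like_pairs": {
    "type": "pairs",
    "pairs": [["PDCD1", "TNFSF4"], ["CD27", "PDCD1"], ["CTLA4", "TNFSF4"],
              ["CD40", "CD28"], ["CD86", "TNFSF14"], ["CD28", "CD86"],
              ["CD80", "TNFSF9"], ["CD274", "VSIR"], ["CD86", "HAVCR2"],
              ["CD40", "PDCD1"], ["CD86", "CD200"], ["CD40", "CD80"],
              ["CD28", "CD276"], ["CD40", "PDCD1LG2"], ["TNFRSF14", "CD86"]]
  }
}
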