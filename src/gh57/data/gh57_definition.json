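{
  "format_version": 1,
  "family": "GH57",
  "fingerprint": {
    "length": 36,
    "csr_spans": [[1, 5], [6, 11], [12, 17], [18, 27], [28, 36]],
    "nucleophile_pos": 15,
    "donor_pos": 20,
    "diagnostic_positions": [1, 12, 23, 35, 36]
  },
  "groups": [
    {"name": "AAMY", "full_name": "alpha-amylase", "kind": "enzyme", "partner": null, "archaea": 99, "bacteria": 55, "characterized": 1, "mean_length": 414},
    {"name": "AAMY-like", "full_name": "alpha-amylase-like protein", "kind": "like-protein", "partner": "AAMY", "archaea": 60, "bacteria": 66, "characterized": 0, "mean_length": 443},
    {"name": "4AGT", "full_name": "4-alpha-glucanotransferase", "kind": "enzyme", "partner": null, "archaea": 38, "bacteria": 69, "characterized": 5, "mean_length": 670},
    {"name": "4AGT-like", "full_name": "4-alpha-glucanotransferase-like protein", "kind": "like-protein", "partner": "4AGT", "archaea": 0, "bacteria": 63, "characterized": 0, "mean_length": 623},
    {"name": "APU", "full_name": "amylopullulanase", "kind": "enzyme", "partner": null, "archaea": 74, "bacteria": 194, "characterized": 8, "mean_length": 814},
    {"name": "APU-CMD", "full_name": "amylopullulanase-cyclomaltodextrinase", "kind": "enzyme", "partner": null, "archaea": 20, "bacteria": 20, "characterized": 4, "mean_length": 529},
    {"name": "APU-CMD-like", "full_name": "amylopullulanase-cyclomaltodextrinase-like protein", "kind": "like-protein", "partner": "APU-CMD", "archaea": 0, "bacteria": 5, "characterized": 0, "mean_length": 728},
    {"name": "MGA", "full_name": "maltogenic amylase", "kind": "enzyme", "partner": null, "archaea": 34, "bacteria": 0, "characterized": 3, "mean_length": 590},
    {"name": "AGAL-related", "full_name": "alpha-galactosidase-related enzyme", "kind": "enzyme", "partner": null, "archaea": 0, "bacteria": 15, "characterized": 0, "mean_length": 660},
    {"name": "AGAL", "full_name": "alpha-galactosidase", "kind": "enzyme", "partner": null, "archaea": 14, "bacteria": 0, "characterized": 1, "mean_length": 362},
    {"name": "MGA-like", "full_name": "maltogenic amylase-like protein", "kind": "like-protein", "partner": "MGA", "archaea": 0, "bacteria": 1, "characterized": 0, "mean_length": 479},
    {"name": "NSA", "full_name": "non-specified amylase", "kind": "enzyme", "partner": null, "archaea": 18, "bacteria": 152, "characterized": 1, "mean_length": 785},
    {"name": "GBE-like", "full_name": "alpha-glucan branching enzyme-like protein", "kind": "like-protein", "partner": "GBE", "archaea": 0, "bacteria": 60, "characterized": 0, "mean_length": 520},
    {"name": "GBE", "full_name": "alpha-glucan branching enzyme", "kind": "enzyme", "partner": null, "archaea": 26, "bacteria": 519, "characterized": 4, "mean_length": 546}
  ],
  "diagnostic_rules": {
    "AAMY": {"1": "E|Q", "12": "R|E", "23": "T", "35": "Y", "36": "Y"},
    "4AGT": {"12": "aromatic", "23": "K"},
    "APU": {"12": "aromatic", "35": "W", "36": "W"},
    "APU-CMD": {"12": "aromatic"},
    "MGA": {"12": "aromatic", "23": "A", "35": "F", "36": "W"},
    "AGAL-related": {"12": "aromatic", "23": "F", "35": "T", "36": "K|H"},
    "AGAL": {"12": "aromatic", "23": "F", "35": "G", "36": "W"},
    "NSA": {"12": "aromatic", "23": "S", "35": "F", "36": "F"},
    "GBE": {"12": "aromatic", "23": "L", "35": "F", "36": "!aromatic"}
  }
}
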