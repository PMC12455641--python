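{
  "description": "Default mevalonate + beta-carotene pathway reconstruction for recombinant S. cerevisiae. 29 metabolites, 14 enzymes, 22 reactions; CrtI desaturation is split into four sequential steps. Concentration bounds in mol/L; unbalanced bounds are literature-informed estimates and can be replaced by the user.",
  "metabolites": [
    {"id": "accoa",   "name": "acetyl-CoA",                 "balanced": false, "conc_lo": 1e-05, "conc_hi": 1e-03},
    {"id": "coa",     "name": "coenzyme A",                 "balanced": false, "conc_lo": 1e-05, "conc_hi": 1e-03},
    {"id": "aacoa",   "name": "acetoacetyl-CoA",            "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "hmgcoa",  "name": "3-hydroxy-3-methylglutaryl-CoA", "balanced": true, "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "nadph",   "name": "NADPH",                      "balanced": false, "conc_lo": 1e-05, "conc_hi": 1e-03},
    {"id": "nadp",    "name": "NADP+",                      "balanced": false, "conc_lo": 1e-06, "conc_hi": 1e-04},
    {"id": "mev",     "name": "(R)-mevalonate",             "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "atp",     "name": "ATP",                        "balanced": false, "conc_lo": 1e-03, "conc_hi": 1e-02},
    {"id": "adp",     "name": "ADP",                        "balanced": false, "conc_lo": 1e-04, "conc_hi": 1e-03},
    {"id": "mevp",    "name": "mevalonate 5-phosphate",     "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "mevpp",   "name": "mevalonate 5-diphosphate",   "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "pi",      "name": "orthophosphate",             "balanced": false, "conc_lo": 5e-03, "conc_hi": 5e-02},
    {"id": "co2",     "name": "CO2 (dissolved)",            "balanced": false, "conc_lo": 1e-04, "conc_hi": 1e-02},
    {"id": "ipp",     "name": "isopentenyl diphosphate",    "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "dmapp",   "name": "dimethylallyl diphosphate",  "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "grpp",    "name": "geranyl diphosphate",        "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "frpp",    "name": "farnesyl diphosphate",       "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "ggpp",    "name": "geranylgeranyl diphosphate", "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "ppi",     "name": "diphosphate",                "balanced": false, "conc_lo": 1e-04, "conc_hi": 1e-03},
    {"id": "psql",    "name": "presqualene diphosphate",    "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "sql",     "name": "squalene",                   "balanced": false, "conc_lo": 1e-08, "conc_hi": 1e-03},
    {"id": "phyto",   "name": "phytoene",                   "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "phytofl", "name": "phytofluene",                "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "zcaro",   "name": "zeta-carotene",              "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "neuros",  "name": "neurosporene",               "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "lyco",    "name": "lycopene",                   "balanced": true,  "conc_lo": 1e-11, "conc_hi": 1e-01},
    {"id": "b_car",   "name": "beta-carotene",              "balanced": true,  "conc_lo": 1e-09, "conc_hi": 1e-01},
    {"id": "fad",     "name": "FAD (desaturase-bound)",     "balanced": false, "conc_lo": 1e-06, "conc_hi": 1e-04},
    {"id": "fadh2",   "name": "FADH2 (desaturase-bound)",   "balanced": false, "conc_lo": 1e-07, "conc_hi": 1e-05}
  ],
  "enzymes": ["ERG10", "ERG13", "HMG1", "HMG2", "ERG12", "ERG8", "MVD1", "IDI1",
              "ERG20", "BTS1", "CrtE", "ERG9", "CrtYB", "CrtI"],
  "reactions": [
    {"id": "ERG10",  "enzyme": "ERG10", "stoich": {"accoa": -2, "aacoa": 1, "coa": 1}},
    {"id": "ERG13",  "enzyme": "ERG13", "stoich": {"accoa": -1, "aacoa": -1, "hmgcoa": 1, "coa": 1}},
    {"id": "HMG1",   "enzyme": "HMG1",  "stoich": {"hmgcoa": -1, "nadph": -2, "mev": 1, "coa": 1, "nadp": 2}},
    {"id": "HMG2",   "enzyme": "HMG2",  "stoich": {"hmgcoa": -1, "nadph": -2, "mev": 1, "coa": 1, "nadp": 2}},
    {"id": "ERG12",  "enzyme": "ERG12", "stoich": {"mev": -1, "atp": -1, "mevp": 1, "adp": 1}},
    {"id": "ERG8",   "enzyme": "ERG8",  "stoich": {"mevp": -1, "atp": -1, "mevpp": 1, "adp": 1}},
    {"id": "MVD1",   "enzyme": "MVD1",  "stoich": {"mevpp": -1, "atp": -1, "ipp": 1, "adp": 1, "pi": 1, "co2": 1}},
    {"id": "IDI1",   "enzyme": "IDI1",  "stoich": {"ipp": -1, "dmapp": 1}},
    {"id": "ERG20a", "enzyme": "ERG20", "stoich": {"dmapp": -1, "ipp": -1, "grpp": 1, "ppi": 1}},
    {"id": "ERG20b", "enzyme": "ERG20", "stoich": {"grpp": -1, "ipp": -1, "frpp": 1, "ppi": 1}},
    {"id": "BTS1",   "enzyme": "BTS1",  "stoich": {"frpp": -1, "ipp": -1, "ggpp": 1, "ppi": 1}},
    {"id": "CrtE",   "enzyme": "CrtE",  "stoich": {"frpp": -1, "ipp": -1, "ggpp": 1, "ppi": 1}},
    {"id": "ERG9a",  "enzyme": "ERG9",  "stoich": {"frpp": -2, "psql": 1, "ppi": 1}},
    {"id": "ERG9b",  "enzyme": "ERG9",  "stoich": {"psql": -1, "nadph": -1, "sql": 1, "nadp": 1, "ppi": 1}},
    {"id": "CrtYBa", "enzyme": "CrtYB", "stoich": {"ggpp": -2, "phyto": 1, "ppi": 2}},
    {"id": "CrtI1",  "enzyme": "CrtI",  "stoich": {"phyto": -1, "fad": -1, "phytofl": 1, "fadh2": 1}},
    {"id": "CrtI2",  "enzyme": "CrtI",  "stoich": {"phytofl": -1, "fad": -1, "zcaro": 1, "fadh2": 1}},
    {"id": "CrtI3",  "enzyme": "CrtI",  "stoich": {"zcaro": -1, "fad": -1, "neuros": 1, "fadh2": 1}},
    {"id": "CrtI4",  "enzyme": "CrtI",  "stoich": {"neuros": -1, "fad": -1, "lyco": 1, "fadh2": 1}},
    {"id": "CrtYBb", "enzyme": "CrtYB", "stoich": {"lyco": -1, "b_car": 1}},
    {"id": "SK_lyc",   "is_sink": true, "stoich": {"lyco": -1}},
    {"id": "SK_b_car", "is_sink": true, "stoich": {"b_car": -1}}
  ],
  "regulation": [
    {"reaction": "ERG13", "effector": "aacoa", "mode": "competitive_inhibition"},
    {"reaction": "ERG13", "effector": "coa",   "mode": "competitive_inhibition"},
    {"reaction": "ERG12", "effector": "grpp",  "mode": "competitive_inhibition"},
    {"reaction": "ERG12", "effector": "frpp",  "mode": "competitive_inhibition"},
    {"reaction": "ERG12", "effector": "ggpp",  "mode": "competitive_inhibition"},
    {"reaction": "HMG2",  "effector": "ggpp",  "mode": "allosteric_inhibition"}
  ],
  "isozyme_groups": [["HMG1", "HMG2"], ["BTS1", "CrtE"]],
  "promiscuous_groups": [["CrtYBa", "CrtYBb"]]
}
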