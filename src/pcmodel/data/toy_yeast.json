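{
 "schema_version": 1,
 "name": "toy_yeast",
 "amino_acid_model": "lumped",
 "metabolites": [
  {
   "id": "glc_ext",
   "carbon": 6,
   "boundary": true,
   "mass": 0.18,
   "role": ""
  },
  {
   "id": "o2_ext",
   "carbon": 0,
   "boundary": true,
   "mass": null,
   "role": ""
  },
  {
   "id": "etoh_ext",
   "carbon": 2,
   "boundary": true,
   "mass": null,
   "role": ""
  },
  {
   "id": "co2_ext",
   "carbon": 1,
   "boundary": true,
   "mass": null,
   "role": ""
  },
  {
   "id": "glc",
   "carbon": 6,
   "boundary": false,
   "mass": null,
   "role": ""
  },
  {
   "id": "pyr",
   "carbon": 3,
   "boundary": false,
   "mass": null,
   "role": ""
  },
  {
   "id": "o2",
   "carbon": 0,
   "boundary": false,
   "mass": null,
   "role": ""
  },
  {
   "id": "atp",
   "carbon": 0,
   "boundary": false,
   "mass": null,
   "role": "energy"
  },
  {
   "id": "nadh",
   "carbon": 0,
   "boundary": false,
   "mass": null,
   "role": ""
  },
  {
   "id": "aa",
   "carbon": 5,
   "boundary": false,
   "mass": null,
   "role": "amino_acid"
  },
  {
   "id": "carb",
   "carbon": 6,
   "boundary": false,
   "mass": null,
   "role": ""
  }
 ],
 "reactions": [
  {
   "id": "t_glc",
   "stoichiometry": {
    "glc_ext": -1.0,
    "glc": 1.0
   },
   "lb": 0.0,
   "ub": null,
   "tags": [
    "uptake"
   ]
  },
  {
   "id": "t_o2",
   "stoichiometry": {
    "o2_ext": -1.0,
    "o2": 1.0
   },
   "lb": 0.0,
   "ub": null,
   "tags": []
  },
  {
   "id": "glycolysis",
   "stoichiometry": {
    "glc": -1.0,
    "pyr": 2.0,
    "atp": 2.0,
    "nadh": 2.0
   },
   "lb": 0.0,
   "ub": null,
   "tags": []
  },
  {
   "id": "fermentation",
   "stoichiometry": {
    "pyr": -1.0,
    "nadh": -1.0,
    "etoh_ext": 1.0,
    "co2_ext": 1.0
   },
   "lb": 0.0,
   "ub": null,
   "tags": []
  },
  {
   "id": "pyr_ox",
   "stoichiometry": {
    "pyr": -1.0,
    "co2_ext": 3.0,
    "nadh": 5.0,
    "atp": 1.0
   },
   "lb": 0.0,
   "ub": null,
   "tags": []
  },
  {
   "id": "respiration",
   "stoichiometry": {
    "nadh": -1.0,
    "o2": -0.5,
    "atp": 1.0
   },
   "lb": 0.0,
   "ub": null,
   "tags": []
  },
  {
   "id": "aa_synth",
   "stoichiometry": {
    "glc": -1.0,
    "atp": -2.0,
    "nadh": -1.0,
    "aa": 1.0,
    "co2_ext": 1.0
   },
   "lb": 0.0,
   "ub": null,
   "tags": []
  },
  {
   "id": "carb_synth",
   "stoichiometry": {
    "glc": -1.0,
    "atp": -1.0,
    "carb": 1.0
   },
   "lb": 0.0,
   "ub": null,
   "tags": []
  }
 ],
 "proteins": [
  {
   "id": "HXT",
   "length": 550,
   "compartment": "plasma_membrane",
   "w": null,
   "k_deg": 0.02,
   "utr_length": 50,
   "is_ribosome": false,
   "is_unspecified": false,
   "import_route": "none",
   "fixed_level": null
  },
  {
   "id": "GLY",
   "length": 5000,
   "compartment": "cytosol",
   "w": null,
   "k_deg": 0.02,
   "utr_length": 50,
   "is_ribosome": false,
   "is_unspecified": false,
   "import_route": "none",
   "fixed_level": null
  },
  {
   "id": "FER",
   "length": 1500,
   "compartment": "cytosol",
   "w": null,
   "k_deg": 0.02,
   "utr_length": 50,
   "is_ribosome": false,
   "is_unspecified": false,
   "import_route": "none",
   "fixed_level": null
  },
  {
   "id": "PDH",
   "length": 3000,
   "compartment": "mito_matrix",
   "w": null,
   "k_deg": 0.02,
   "utr_length": 50,
   "is_ribosome": false,
   "is_unspecified": false,
   "import_route": "mitochondrial",
   "fixed_level": null
  },
  {
   "id": "RESP_N",
   "length": 4000,
   "compartment": "mito_inner_membrane",
   "w": null,
   "k_deg": 0.02,
   "utr_length": 50,
   "is_ribosome": false,
   "is_unspecified": false,
   "import_route": "mitochondrial",
   "fixed_level": null
  },
  {
   "id": "COX_M",
   "length": 1000,
   "compartment": "mito_inner_membrane",
   "w": null,
   "k_deg": 0.02,
   "utr_length": 0,
   "is_ribosome": false,
   "is_unspecified": false,
   "import_route": "none",
   "fixed_level": null
  },
  {
   "id": "TOM",
   "length": 2000,
   "compartment": "mito_inner_membrane",
   "w": null,
   "k_deg": 0.02,
   "utr_length": 50,
   "is_ribosome": false,
   "is_unspecified": false,
   "import_route": "mitochondrial",
   "fixed_level": null
  },
  {
   "id": "AAS",
   "length": 4000,
   "compartment": "cytosol",
   "w": null,
   "k_deg": 0.02,
   "utr_length": 50,
   "is_ribosome": false,
   "is_unspecified": false,
   "import_route": "none",
   "fixed_level": null
  },
  {
   "id": "CBS",
   "length": 2500,
   "compartment": "cytosol",
   "w": null,
   "k_deg": 0.02,
   "utr_length": 50,
   "is_ribosome": false,
   "is_unspecified": false,
   "import_route": "none",
   "fixed_level": null
  },
  {
   "id": "RIB",
   "length": 12000,
   "compartment": "cytosol",
   "w": null,
   "k_deg": 0.0,
   "utr_length": 50,
   "is_ribosome": true,
   "is_unspecified": false,
   "import_route": "none",
   "fixed_level": null
  },
  {
   "id": "MRIB",
   "length": 3000,
   "compartment": "mito_matrix",
   "w": null,
   "k_deg": 0.0,
   "utr_length": 50,
   "is_ribosome": true,
   "is_unspecified": false,
   "import_route": "mitochondrial",
   "fixed_level": null
  },
  {
   "id": "UP",
   "length": 400,
   "compartment": "cytosol",
   "w": null,
   "k_deg": 0.0,
   "utr_length": 0,
   "is_ribosome": false,
   "is_unspecified": true,
   "import_route": "none",
   "fixed_level": null
  }
 ],
 "complexes": [
  {
   "id": "RESPC",
   "subunits": {
    "RESP_N": 1,
    "COX_M": 1
   },
   "compartment": "mito_inner_membrane"
  }
 ],
 "compartments": [
  {
   "id": "cytosol",
   "kind": "volumetric",
   "capacity": 0.3137,
   "fill_rule": "equality",
   "organelle": "cytoplasmic"
  },
  {
   "id": "plasma_membrane",
   "kind": "membrane",
   "capacity": 7.5,
   "fill_rule": "inequality",
   "organelle": "cytoplasmic"
  },
  {
   "id": "mito_matrix",
   "kind": "volumetric",
   "capacity": 0.12,
   "fill_rule": "inequality",
   "organelle": "mitochondrial"
  },
  {
   "id": "mito_inner_membrane",
   "kind": "membrane",
   "capacity": 258.0,
   "fill_rule": "inequality",
   "organelle": "mitochondrial"
  }
 ],
 "catalysis": [
  {
   "reaction": "t_glc",
   "catalyst": "HXT",
   "kcat": 104800.0,
   "saturation": 1.0
  },
  {
   "reaction": "glycolysis",
   "catalyst": "GLY",
   "kcat": 240000.0,
   "saturation": 1.0
  },
  {
   "reaction": "fermentation",
   "catalyst": "FER",
   "kcat": 400000.0,
   "saturation": 1.0
  },
  {
   "reaction": "pyr_ox",
   "catalyst": "PDH",
   "kcat": 100000.0,
   "saturation": 1.0
  },
  {
   "reaction": "respiration",
   "catalyst": "RESPC",
   "kcat": 50000.0,
   "saturation": 1.0
  },
  {
   "reaction": "aa_synth",
   "catalyst": "AAS",
   "kcat": 30000.0,
   "saturation": 1.0
  },
  {
   "reaction": "carb_synth",
   "catalyst": "CBS",
   "kcat": 200000.0,
   "saturation": 1.0
  }
 ],
 "ribosome": {
  "k_el": 36000.0,
  "f_inactive": 0.15,
  "sigma": 0.85,
  "mito_k_el": 22000.0
 },
 "biomass": {
  "composition": {
   "carb": 3.33
  },
  "gam": 44.9,
  "ngam": 1.0,
  "protein_per_gdw": 0.46
 },
 "conditions": {
  "name": "glucose",
  "carbon_ngam": 0.0,
  "min_up_fraction": 0.245,
  "cells_per_gdw": 67000000000.0
 },
 "import": {
  "importer": "TOM",
  "k_import": 3600.0
 }
}
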