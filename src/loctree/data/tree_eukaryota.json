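{
  "domain": "eukaryota",
  "root": "secretory_vs_not",
  "nodes": {
    "secretory_vs_not": ["secretory", "non_secretory"],

    "secretory": ["extra-cellular", "secretory_retained"],
    "secretory_retained": ["plasma membrane", "secretory_organelles"],
    "secretory_organelles": ["er_split", "golgi_vacuole"],
    "er_split": ["endoplasmic reticulum", "endoplasmic reticulum membrane"],
    "golgi_vacuole": ["golgi_split", "vacuole_split"],
    "golgi_split": ["golgi apparatus", "golgi apparatus membrane"],
    "vacuole_split": ["vacuole", "vacuole membrane"],

    "non_secretory": ["nucleocytosolic", "organellar"],
    "nucleocytosolic": ["cytosol", "nuclear_split"],
    "nuclear_split": ["nucleus", "nucleus membrane"],
    "organellar": ["mito_perox", "plastid_like"],
    "mito_perox": ["mito_split", "perox_split"],
    "mito_split": ["mitochondrion", "mitochondrion membrane"],
    "perox_split": ["peroxisome", "peroxisome membrane"],
    "plastid_like": ["plastid", "chloro_split"],
    "chloro_split": ["chloroplast", "chloroplast membrane"]
  }
}
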