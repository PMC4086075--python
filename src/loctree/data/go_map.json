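{
  "chloroplast": [["chloroplast", "GO:0009507"]],
  "chloroplast membrane": [["chloroplast membrane", "GO:0031969"]],
  "cytosol": [["cytosol", "GO:0005829"]],
  "endoplasmic reticulum": [["endoplasmic reticulum", "GO:0005783"]],
  "endoplasmic reticulum membrane": [["endoplasmic reticulum membrane", "GO:0005789"]],
  "extra-cellular": [["extracellular region", "GO:0005576"]],
  "fimbrium": [["pilus", "GO:0009289"]],
  "golgi apparatus": [["Golgi apparatus", "GO:0005794"]],
  "golgi apparatus membrane": [["Golgi membrane", "GO:0000139"]],
  "mitochondrion": [["mitochondrion", "GO:0005739"]],
  "mitochondrion membrane": [["mitochondrial membrane", "GO:0031966"]],
  "nucleus": [["nucleus", "GO:0005634"]],
  "nucleus membrane": [["nuclear envelope", "GO:0005635"]],
  "outer membrane": [["cell outer membrane", "GO:0009279"]],
  "periplasmic space": [["periplasmic space", "GO:0042597"]],
  "peroxisome": [["peroxisome", "GO:0005777"]],
  "peroxisome membrane": [["peroxisomal membrane", "GO:0005778"]],
  "plasma membrane": [["plasma membrane", "GO:0005886"]],
  "plastid": [["plastid", "GO:0009536"]],
  "vacuole": [["vacuole", "GO:0005773"]],
  "vacuole membrane": [["vacuolar membrane", "GO:0005774"]]
}
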