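{
  "description": "Gel-estimated ITS amplicon sizes and HaeIII/RsaI restriction fragment patterns for seven kefir yeast isolates.",
  "units": "bp",
  "patterns": [
    {"strain": "Candida inconspicua IG 11", "amplicon_bp": 460,
     "fragments": {"HaeIII": [290, 90, 80], "RsaI": [360, 100]}},
    {"strain": "Debaryomyces hansenii 1", "amplicon_bp": 640,
     "fragments": {"HaeIII": [410, 140, 90], "RsaI": [450, 190]}},
    {"strain": "Debaryomyces hansenii IG II", "amplicon_bp": 640,
     "fragments": {"HaeIII": [410, 140, 90], "RsaI": [450, 190]}},
    {"strain": "Debaryomyces hansenii IG 01", "amplicon_bp": 640,
     "fragments": {"HaeIII": [410, 140, 90], "RsaI": [450, 190]}},
    {"strain": "Kazachstania unispora IG 16", "amplicon_bp": 690,
     "fragments": {"HaeIII": [550, 130], "RsaI": [510, 110, 70]}},
    {"strain": "Kluyveromyces marxianus IG 1", "amplicon_bp": 700,
     "fragments": {"HaeIII": [620, 80], "RsaI": [630, 70]}},
    {"strain": "Zygotorulaspora florentina IG 12", "amplicon_bp": 600,
     "fragments": {"HaeIII": [600], "RsaI": [520, 80]}}
  ]
}
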