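# Pathogen-type classes for infection preferred terms.
# MedDRA's HLGT hierarchy is licensed content, so this is a small editable
# synthetic stand-in listing explicit member PTs per class; real analyses
# should replace it with the HLGT membership from a licensed dictionary.
bacterial:
  - Bacterial infection
  - Sepsis
  - Bacteraemia
  - Pneumonia bacterial
  - Clostridium difficile infection
  - Staphylococcal infection
fungal:
  - Fungal infection
  - Candida infection
  - Aspergillus infection
  - Pneumocystis jirovecii pneumonia
  - Fungal sepsis
viral:
  - Viral infection
  - Cytomegalovirus infection
  - Herpes zoster
  - COVID-19
  - Epstein-Barr virus infection
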