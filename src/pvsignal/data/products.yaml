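# Default product name lists: product -> DRUGNAME / PROD_AI synonyms.
# Matching is exact on normalized strings (upper-cased, trimmed, internal
# whitespace collapsed); extend with the spelling variants present in your
# extract.
tisagenlecleucel:
  - TISAGENLECLEUCEL
  - KYMRIAH
axicabtagene ciloleucel:
  - AXICABTAGENE CILOLEUCEL
  - YESCARTA
brexucabtagene autoleucel:
  - BREXUCABTAGENE AUTOLEUCEL
  - TECARTUS
lisocabtagene maraleucel:
  - LISOCABTAGENE MARALEUCEL
  - BREYANZI
idecabtagene vicleucel:
  - IDECABTAGENE VICLEUCEL
  - ABECMA
ciltacabtagene autoleucel:
  - CILTACABTAGENE AUTOLEUCEL
  - CARVYKTI
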