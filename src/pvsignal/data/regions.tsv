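country	region
US	North America
CA	North America
MX	North America
PR	North America
GB	Europe
DE	Europe
FR	Europe
IT	Europe
ES	Europe
NL	Europe
BE	Europe
SE	Europe
NO	Europe
DK	Europe
FI	Europe
PL	Europe
AT	Europe
CH	Europe
IE	Europe
PT	Europe
GR	Europe
CZ	Europe
HU	Europe
JP	Asia
CN	Asia
KR	Asia
IN	Asia
TW	Asia
SG	Asia
TH	Asia
MY	Asia
PH	Asia
VN	Asia
HK	Asia
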