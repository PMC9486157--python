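country,region
AD,Europe
AE,Asia
AF,Asia
AG,North America
AI,North America
AL,Europe
AM,Asia
AO,Africa
AR,South America
AT,Europe
AU,Oceania
AW,North America
AZ,Asia
BA,Europe
BB,North America
BD,Asia
BE,Europe
BF,Africa
BG,Europe
BH,Asia
BI,Africa
BJ,Africa
BM,North America
BN,Asia
BO,South America
BR,South America
BS,North America
BT,Asia
BW,Africa
BY,Europe
BZ,North America
CA,North America
CD,Africa
CF,Africa
CG,Africa
CH,Europe
CI,Africa
CL,South America
CM,Africa
CN,Asia
CO,South America
CR,North America
CU,North America
CV,Africa
CY,Asia
CZ,Europe
DE,Europe
DJ,Africa
DK,Europe
DM,North America
DO,North America
DZ,Africa
EC,South America
EE,Europe
EG,Africa
ER,Africa
ES,Europe
ET,Africa
FI,Europe
FJ,Oceania
FM,Oceania
FR,Europe
GA,Africa
GB,Europe
GD,North America
GE,Asia
GH,Africa
GI,Europe
GL,North America
GM,Africa
GN,Africa
GQ,Africa
GR,Europe
GT,North America
GW,Africa
GY,South America
HK,Asia
HN,North America
HR,Europe
HT,North America
HU,Europe
ID,Asia
IE,Europe
IL,Asia
IN,Asia
IQ,Asia
IR,Asia
IS,Europe
IT,Europe
JM,North America
JO,Asia
JP,Asia
KE,Africa
KG,Asia
KH,Asia
KI,Oceania
KM,Africa
KN,North America
KP,Asia
KR,Asia
KW,Asia
KY,North America
KZ,Asia
LA,Asia
LB,Asia
LC,North America
LI,Europe
LK,Asia
LR,Africa
LS,Africa
LT,Europe
LU,Europe
LV,Europe
LY,Africa
MA,Africa
MC,Europe
MD,Europe
ME,Europe
MG,Africa
MH,Oceania
MK,Europe
ML,Africa
MM,Asia
MN,Asia
MO,Asia
MR,Africa
MT,Europe
MU,Africa
MV,Asia
MW,Africa
MX,North America
MY,Asia
MZ,Africa
NA,Africa
NE,Africa
NG,Africa
NI,North America
NL,Europe
NO,Europe
NP,Asia
NR,Oceania
NZ,Oceania
OM,Asia
PA,North America
PE,South America
PG,Oceania
PH,Asia
PK,Asia
PL,Europe
PR,North America
PT,Europe
PW,Oceania
PY,South America
QA,Asia
RO,Europe
RS,Europe
RU,Europe
RW,Africa
SA,Asia
SB,Oceania
SC,Africa
SD,Africa
SE,Europe
SG,Asia
SI,Europe
SK,Europe
SL,Africa
SM,Europe
SN,Africa
SO,Africa
SR,South America
SS,Africa
ST,Africa
SV,North America
SY,Asia
SZ,Africa
TD,Africa
TG,Africa
TH,Asia
TJ,Asia
TL,Asia
TM,Asia
TN,Africa
TO,Oceania
TR,Asia
TT,North America
TV,Oceania
TW,Asia
TZ,Africa
UA,Europe
UG,Africa
US,North America
UY,South America
UZ,Asia
VA,Europe
VC,North America
VE,South America
VN,Asia
VU,Oceania
WS,Oceania
YE,Asia
ZA,Africa
ZM,Africa
ZW,Africa
UNITED STATES,North America
UNITED KINGDOM,Europe
CANADA,North America
FRANCE,Europe
GERMANY,Europe
ITALY,Europe
SPAIN,Europe
JAPAN,Asia
CHINA,Asia
AUSTRALIA,Oceania
BRAZIL,South America
INDIA,Asia
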