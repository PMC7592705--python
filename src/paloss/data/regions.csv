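iso3,region
ARG,South and Central America
BOL,South and Central America
BRA,South and Central America
CHL,South and Central America
COL,South and Central America
CRI,South and Central America
ECU,South and Central America
GTM,South and Central America
MEX,South and Central America
PER,South and Central America
PRY,South and Central America
VEN,South and Central America
CAN,North America
USA,North America
BLR,Eastern Europe
POL,Eastern Europe
ROU,Eastern Europe
RUS,Eastern Europe
UKR,Eastern Europe
AUT,Western Europe
DEU,Western Europe
ESP,Western Europe
FIN,Western Europe
FRA,Western Europe
GBR,Western Europe
ITA,Western Europe
NOR,Western Europe
SWE,Western Europe
AGO,Africa and the Middle East
CIV,Africa and the Middle East
CMR,Africa and the Middle East
COD,Africa and the Middle East
COG,Africa and the Middle East
GAB,Africa and the Middle East
GHA,Africa and the Middle East
IRN,Africa and the Middle East
KEN,Africa and the Middle East
MDG,Africa and the Middle East
MOZ,Africa and the Middle East
NGA,Africa and the Middle East
TZA,Africa and the Middle East
ZMB,Africa and the Middle East
IDN,Southeast Asia
KHM,Southeast Asia
LAO,Southeast Asia
MMR,Southeast Asia
MYS,Southeast Asia
PHL,Southeast Asia
THA,Southeast Asia
VNM,Southeast Asia
AUS,Rest of Asia and Oceania
CHN,Rest of Asia and Oceania
IND,Rest of Asia and Oceania
JPN,Rest of Asia and Oceania
NPL,Rest of Asia and Oceania
NZL,Rest of Asia and Oceania
PNG,Rest of Asia and Oceania
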