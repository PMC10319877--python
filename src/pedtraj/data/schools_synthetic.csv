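# SYNTHETIC school coordinates: plausible Barcelona-area locations used by
# the trajectory simulator and the default run configuration. They are NOT
# the real school addresses.
code,latitude,longitude
OAK,41.4010,2.1280
VER,41.3880,2.1860
VIR,41.4190,2.1660
SAN,41.4350,2.1910
IPC,41.3940,2.1750
BEL,41.3500,2.1110
MON,41.3640,2.1500
ZAF,41.4130,2.1870
IFT,41.4210,2.1560
SGV,41.3150,2.0140
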