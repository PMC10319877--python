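district,surface_km2,housing_units,school_codes
Sarrià,6.105,74729,OAK
Ciutat Vella,1.296,55663,VER
Horta-Guinardó,2.898,78367,VIR;IFT
Sant Andreu,1.906,70056,SAN
L'Eixample,3.719,143403,IPC
L'Hospitalet,3.010,111363,BEL
Sants-Montjuïc,2.516,90449,MON
Sant Martí,2.889,111536,ZAF
Viladecans,3.811,24221,SGV
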