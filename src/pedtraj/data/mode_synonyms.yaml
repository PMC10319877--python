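# Bilingual (Catalan / English) synonym table mapping nickname tokens to
# transport modes and companionship. Editable: add tokens as new spellings
# appear in collected nicknames. Matching is case-insensitive.
modes:
  walk: [walk, walking, peu, apeu, caminant, foot]
  bus: [bus, autobus]
  car: [car, cotxe, coche]
  scooter: [scooter, patinet]
  bike: [bike, bici, bicicleta, cycling]
  metro: [metro, subway]
  train: [train, tren]
companionship:
  alone: [alone, sol, sola, solo]
  accompanied: [accompanied, acompanyat, acompanyada, junts, grup, group, friends]
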