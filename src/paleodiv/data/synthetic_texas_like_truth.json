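{
  "seed": 1729,
  "sub_seed": 60,
  "original_zones": {
    "Pueblo": "Coyotean",
    "Moran": "Coyotean",
    "Putnam": "Coyotean",
    "Admiral": "Seymourian",
    "Belle Plains": "Seymourian",
    "Clyde": "Mitchellcreekian",
    "Lueders": "Mitchellcreekian",
    "Arroyo": "Redtankian",
    "Vale": "Redtankian",
    "Choza": "Redtankian",
    "San Angelo": "Littlecrotonian"
  },
  "redefined_zones": {
    "Pueblo": "Coyotean",
    "Moran": "Coyotean",
    "Putnam": "Seymourian",
    "Admiral": "Seymourian",
    "Belle Plains": "Mitchellcreekian",
    "Clyde": "Mitchellcreekian",
    "Lueders": "Mitchellcreekian",
    "Arroyo": "Redtankian",
    "Vale": "Redtankian",
    "Choza": "Redtankian",
    "San Angelo": "Littlecrotonian"
  },
  "block_partition": [
    [
      "Pueblo",
      "Moran"
    ],
    [
      "Putnam",
      "Admiral"
    ],
    [
      "Belle Plains",
      "Clyde",
      "Lueders"
    ],
    [
      "Arroyo",
      "Vale",
      "Choza"
    ],
    [
      "San Angelo"
    ]
  ],
  "true_unit_richness": {
    "Pueblo": 12,
    "Moran": 11,
    "Putnam": 11,
    "Admiral": 12,
    "Belle Plains": 13,
    "Clyde": 13,
    "Lueders": 12,
    "Arroyo": 36,
    "Vale": 21,
    "Choza": 6,
    "San Angelo": 8
  }
}
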