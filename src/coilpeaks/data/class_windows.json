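{
  "windows": [
    {"residue": "A", "atom": "CA", "class": "alpha", "mean": 55.2,  "sd": 1.2},
    {"residue": "A", "atom": "CA", "class": "coil",  "mean": 53.2,  "sd": 1.2},
    {"residue": "A", "atom": "CA", "class": "beta",  "mean": 51.2,  "sd": 1.5},
    {"residue": "A", "atom": "CB", "class": "alpha", "mean": 18.2,  "sd": 1.2},
    {"residue": "A", "atom": "CB", "class": "coil",  "mean": 18.9,  "sd": 1.2},
    {"residue": "A", "atom": "CB", "class": "beta",  "mean": 21.4,  "sd": 0.9},
    {"residue": "A", "atom": "CO", "class": "alpha", "mean": 179.3, "sd": 1.3},
    {"residue": "A", "atom": "CO", "class": "coil",  "mean": 177.6, "sd": 1.3},
    {"residue": "A", "atom": "CO", "class": "beta",  "mean": 176.0, "sd": 1.5},

    {"residue": "L", "atom": "CA", "class": "alpha", "mean": 57.1,  "sd": 1.2},
    {"residue": "L", "atom": "CA", "class": "coil",  "mean": 54.5,  "sd": 1.2},
    {"residue": "L", "atom": "CA", "class": "beta",  "mean": 52.8,  "sd": 1.5},
    {"residue": "L", "atom": "CB", "class": "alpha", "mean": 41.2,  "sd": 1.2},
    {"residue": "L", "atom": "CB", "class": "coil",  "mean": 41.9,  "sd": 1.2},
    {"residue": "L", "atom": "CB", "class": "beta",  "mean": 43.3,  "sd": 1.6},
    {"residue": "L", "atom": "CO", "class": "alpha", "mean": 178.4, "sd": 1.3},
    {"residue": "L", "atom": "CO", "class": "coil",  "mean": 177.1, "sd": 1.3},
    {"residue": "L", "atom": "CO", "class": "beta",  "mean": 175.6, "sd": 1.5},

    {"residue": "G", "atom": "CA", "class": "alpha", "mean": 46.9,  "sd": 1.2},
    {"residue": "G", "atom": "CA", "class": "coil",  "mean": 44.8,  "sd": 1.2},
    {"residue": "G", "atom": "CA", "class": "beta",  "mean": 44.0,  "sd": 1.2},
    {"residue": "G", "atom": "CO", "class": "alpha", "mean": 177.4, "sd": 1.3},
    {"residue": "G", "atom": "CO", "class": "coil",  "mean": 174.3, "sd": 1.3},
    {"residue": "G", "atom": "CO", "class": "beta",  "mean": 171.8, "sd": 1.5},

    {"residue": "S", "atom": "CA", "class": "alpha", "mean": 60.9,  "sd": 1.2},
    {"residue": "S", "atom": "CA", "class": "coil",  "mean": 58.3,  "sd": 1.2},
    {"residue": "S", "atom": "CA", "class": "beta",  "mean": 57.0,  "sd": 1.5},
    {"residue": "S", "atom": "CB", "class": "alpha", "mean": 62.9,  "sd": 1.2},
    {"residue": "S", "atom": "CB", "class": "coil",  "mean": 63.8,  "sd": 1.2},
    {"residue": "S", "atom": "CB", "class": "beta",  "mean": 65.4,  "sd": 1.2},

    {"residue": "T", "atom": "CA", "class": "alpha", "mean": 64.5,  "sd": 1.2},
    {"residue": "T", "atom": "CA", "class": "coil",  "mean": 61.8,  "sd": 1.2},
    {"residue": "T", "atom": "CA", "class": "beta",  "mean": 60.5,  "sd": 1.5},
    {"residue": "T", "atom": "CB", "class": "alpha", "mean": 68.8,  "sd": 1.2},
    {"residue": "T", "atom": "CB", "class": "coil",  "mean": 69.8,  "sd": 1.2},
    {"residue": "T", "atom": "CB", "class": "beta",  "mean": 71.5,  "sd": 1.2}
  ],
  "positive_phi_anchors": [
    {"residue": "A", "atoms": {"CA": 53.3, "CB": 16.0, "CO": 177.0}},
    {"residue": "L", "atoms": {"CA": 53.7, "CB": 39.2, "CO": 176.5}},
    {"residue": "G", "atoms": {"CA": 45.1, "CO": 174.8}},
    {"residue": "S", "atoms": {"CA": 57.8, "CB": 63.0}},
    {"residue": "T", "atoms": {"CA": 60.8, "CB": 69.6}}
  ],
  "extended_direction": {"CA": -1, "CB": 1, "CO": -1},
  "positive_phi_radius_ppm": 1.5
}
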