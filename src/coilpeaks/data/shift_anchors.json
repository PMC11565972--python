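{
 "kernel_width": 12.0,
 "anchors": [
  {
   "residue": "A",
   "atom": "CA",
   "basin": "alpha",
   "shift": 55.3,
   "slope_phi": 2.2,
   "slope_psi": 2.2
  },
  {
   "residue": "A",
   "atom": "CA",
   "basin": "ppii_coil",
   "shift": 53.25,
   "slope_phi": 2.5384615384615383,
   "slope_psi": 2.5384615384615383
  },
  {
   "residue": "A",
   "atom": "CA",
   "basin": "beta",
   "shift": 51.3,
   "slope_phi": 2.5384615384615383,
   "slope_psi": 2.5384615384615383
  },
  {
   "residue": "A",
   "atom": "CA",
   "basin": "positive_phi",
   "shift": 53.3,
   "slope_phi": 2.5,
   "slope_psi": 2.5
  },
  {
   "residue": "A",
   "atom": "CB",
   "basin": "alpha",
   "shift": 18.0,
   "slope_phi": 2.2,
   "slope_psi": -2.2
  },
  {
   "residue": "A",
   "atom": "CB",
   "basin": "ppii_coil",
   "shift": 18.6,
   "slope_phi": 2.5384615384615383,
   "slope_psi": -2.5384615384615383
  },
  {
   "residue": "A",
   "atom": "CB",
   "basin": "beta",
   "shift": 21.0,
   "slope_phi": 2.5384615384615383,
   "slope_psi": -2.5384615384615383
  },
  {
   "residue": "A",
   "atom": "CB",
   "basin": "positive_phi",
   "shift": 16.0,
   "slope_phi": 2.5,
   "slope_psi": -2.5
  },
  {
   "residue": "A",
   "atom": "CO",
   "basin": "alpha",
   "shift": 179.4,
   "slope_phi": -2.2,
   "slope_psi": 2.2
  },
  {
   "residue": "A",
   "atom": "CO",
   "basin": "ppii_coil",
   "shift": 177.8,
   "slope_phi": -2.5384615384615383,
   "slope_psi": 2.5384615384615383
  },
  {
   "residue": "A",
   "atom": "CO",
   "basin": "beta",
   "shift": 176.1,
   "slope_phi": -2.5384615384615383,
   "slope_psi": 2.5384615384615383
  },
  {
   "residue": "A",
   "atom": "CO",
   "basin": "positive_phi",
   "shift": 177.0,
   "slope_phi": -2.5,
   "slope_psi": 2.5
  },
  {
   "residue": "L",
   "atom": "CA",
   "basin": "alpha",
   "shift": 56.9,
   "slope_phi": 1.85,
   "slope_psi": 1.85
  },
  {
   "residue": "L",
   "atom": "CA",
   "basin": "ppii_coil",
   "shift": 54.5,
   "slope_phi": 2.1576923076923076,
   "slope_psi": 2.1576923076923076
  },
  {
   "residue": "L",
   "atom": "CA",
   "basin": "beta",
   "shift": 52.4,
   "slope_phi": 2.1576923076923076,
   "slope_psi": 2.1576923076923076
  },
  {
   "residue": "L",
   "atom": "CA",
   "basin": "positive_phi",
   "shift": 53.7,
   "slope_phi": 2.1,
   "slope_psi": 2.1
  },
  {
   "residue": "L",
   "atom": "CB",
   "basin": "alpha",
   "shift": 41.2,
   "slope_phi": 1.85,
   "slope_psi": -1.85
  },
  {
   "residue": "L",
   "atom": "CB",
   "basin": "ppii_coil",
   "shift": 41.6,
   "slope_phi": 2.1576923076923076,
   "slope_psi": -2.1576923076923076
  },
  {
   "residue": "L",
   "atom": "CB",
   "basin": "beta",
   "shift": 42.7,
   "slope_phi": 2.1576923076923076,
   "slope_psi": -2.1576923076923076
  },
  {
   "residue": "L",
   "atom": "CB",
   "basin": "positive_phi",
   "shift": 39.2,
   "slope_phi": 2.1,
   "slope_psi": -2.1
  },
  {
   "residue": "L",
   "atom": "CO",
   "basin": "alpha",
   "shift": 178.5,
   "slope_phi": -1.85,
   "slope_psi": 1.85
  },
  {
   "residue": "L",
   "atom": "CO",
   "basin": "ppii_coil",
   "shift": 177.1,
   "slope_phi": -2.1576923076923076,
   "slope_psi": 2.1576923076923076
  },
  {
   "residue": "L",
   "atom": "CO",
   "basin": "beta",
   "shift": 175.7,
   "slope_phi": -2.1576923076923076,
   "slope_psi": 2.1576923076923076
  },
  {
   "residue": "L",
   "atom": "CO",
   "basin": "positive_phi",
   "shift": 176.5,
   "slope_phi": -2.1,
   "slope_psi": 2.1
  },
  {
   "residue": "G",
   "atom": "CA",
   "basin": "alpha",
   "shift": 45.92,
   "slope_phi": 1.62,
   "slope_psi": 1.62
  },
  {
   "residue": "G",
   "atom": "CA",
   "basin": "ppii_coil",
   "shift": 44.17,
   "slope_phi": 1.62,
   "slope_psi": 1.62
  },
  {
   "residue": "G",
   "atom": "CA",
   "basin": "beta",
   "shift": 43.27,
   "slope_phi": 1.62,
   "slope_psi": 1.62
  },
  {
   "residue": "G",
   "atom": "CA",
   "basin": "positive_phi",
   "shift": 45.07,
   "slope_phi": 1.62,
   "slope_psi": 1.62
  },
  {
   "residue": "G",
   "atom": "CO",
   "basin": "alpha",
   "shift": 175.3,
   "slope_phi": -1.62,
   "slope_psi": 1.62
  },
  {
   "residue": "G",
   "atom": "CO",
   "basin": "ppii_coil",
   "shift": 173.75,
   "slope_phi": -1.62,
   "slope_psi": 1.62
  },
  {
   "residue": "G",
   "atom": "CO",
   "basin": "beta",
   "shift": 172.8,
   "slope_phi": -1.62,
   "slope_psi": 1.62
  },
  {
   "residue": "G",
   "atom": "CO",
   "basin": "positive_phi",
   "shift": 174.6,
   "slope_phi": -1.62,
   "slope_psi": 1.62
  },
  {
   "residue": "S",
   "atom": "CA",
   "basin": "alpha",
   "shift": 60.9,
   "slope_phi": 2.2,
   "slope_psi": 2.2
  },
  {
   "residue": "S",
   "atom": "CA",
   "basin": "ppii_coil",
   "shift": 58.3,
   "slope_phi": 2.5384615384615383,
   "slope_psi": 2.5384615384615383
  },
  {
   "residue": "S",
   "atom": "CA",
   "basin": "beta",
   "shift": 57.0,
   "slope_phi": 2.5384615384615383,
   "slope_psi": 2.5384615384615383
  },
  {
   "residue": "S",
   "atom": "CA",
   "basin": "positive_phi",
   "shift": 57.8,
   "slope_phi": 2.5,
   "slope_psi": 2.5
  },
  {
   "residue": "S",
   "atom": "CB",
   "basin": "alpha",
   "shift": 62.9,
   "slope_phi": 2.2,
   "slope_psi": -2.2
  },
  {
   "residue": "S",
   "atom": "CB",
   "basin": "ppii_coil",
   "shift": 63.8,
   "slope_phi": 2.5384615384615383,
   "slope_psi": -2.5384615384615383
  },
  {
   "residue": "S",
   "atom": "CB",
   "basin": "beta",
   "shift": 65.4,
   "slope_phi": 2.5384615384615383,
   "slope_psi": -2.5384615384615383
  },
  {
   "residue": "S",
   "atom": "CB",
   "basin": "positive_phi",
   "shift": 63.0,
   "slope_phi": 2.5,
   "slope_psi": -2.5
  },
  {
   "residue": "S",
   "atom": "CO",
   "basin": "alpha",
   "shift": 176.2,
   "slope_phi": -2.2,
   "slope_psi": 2.2
  },
  {
   "residue": "S",
   "atom": "CO",
   "basin": "ppii_coil",
   "shift": 174.6,
   "slope_phi": -2.5384615384615383,
   "slope_psi": 2.5384615384615383
  },
  {
   "residue": "S",
   "atom": "CO",
   "basin": "beta",
   "shift": 173.4,
   "slope_phi": -2.5384615384615383,
   "slope_psi": 2.5384615384615383
  },
  {
   "residue": "S",
   "atom": "CO",
   "basin": "positive_phi",
   "shift": 174.0,
   "slope_phi": -2.5,
   "slope_psi": 2.5
  },
  {
   "residue": "T",
   "atom": "CA",
   "basin": "alpha",
   "shift": 64.5,
   "slope_phi": 2.2,
   "slope_psi": 2.2
  },
  {
   "residue": "T",
   "atom": "CA",
   "basin": "ppii_coil",
   "shift": 61.8,
   "slope_phi": 2.5384615384615383,
   "slope_psi": 2.5384615384615383
  },
  {
   "residue": "T",
   "atom": "CA",
   "basin": "beta",
   "shift": 60.5,
   "slope_phi": 2.5384615384615383,
   "slope_psi": 2.5384615384615383
  },
  {
   "residue": "T",
   "atom": "CA",
   "basin": "positive_phi",
   "shift": 60.8,
   "slope_phi": 2.5,
   "slope_psi": 2.5
  },
  {
   "residue": "T",
   "atom": "CB",
   "basin": "alpha",
   "shift": 68.8,
   "slope_phi": 2.2,
   "slope_psi": -2.2
  },
  {
   "residue": "T",
   "atom": "CB",
   "basin": "ppii_coil",
   "shift": 69.8,
   "slope_phi": 2.5384615384615383,
   "slope_psi": -2.5384615384615383
  },
  {
   "residue": "T",
   "atom": "CB",
   "basin": "beta",
   "shift": 71.5,
   "slope_phi": 2.5384615384615383,
   "slope_psi": -2.5384615384615383
  },
  {
   "residue": "T",
   "atom": "CB",
   "basin": "positive_phi",
   "shift": 69.6,
   "slope_phi": 2.5,
   "slope_psi": -2.5
  },
  {
   "residue": "T",
   "atom": "CO",
   "basin": "alpha",
   "shift": 175.9,
   "slope_phi": -2.2,
   "slope_psi": 2.2
  },
  {
   "residue": "T",
   "atom": "CO",
   "basin": "ppii_coil",
   "shift": 174.7,
   "slope_phi": -2.5384615384615383,
   "slope_psi": 2.5384615384615383
  },
  {
   "residue": "T",
   "atom": "CO",
   "basin": "beta",
   "shift": 173.5,
   "slope_phi": -2.5384615384615383,
   "slope_psi": 2.5384615384615383
  },
  {
   "residue": "T",
   "atom": "CO",
   "basin": "positive_phi",
   "shift": 174.0,
   "slope_phi": -2.5,
   "slope_psi": 2.5
  }
 ]
}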