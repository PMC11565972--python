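{
 "A": [
  {
   "label": "alpha",
   "center": [
    -63.0,
    -43.0
   ],
   "spread": [
    15.0,
    15.0
   ],
   "weight": 16
  },
  {
   "label": "ppii_coil",
   "center": [
    -70.0,
    145.0
   ],
   "spread": [
    13.0,
    13.0
   ],
   "weight": 60
  },
  {
   "label": "beta",
   "center": [
    -150.0,
    125.0
   ],
   "spread": [
    13.0,
    13.0
   ],
   "weight": 15
  },
  {
   "label": "positive_phi",
   "center": [
    60.0,
    45.0
   ],
   "spread": [
    13.0,
    13.0
   ],
   "weight": 8
  }
 ],
 "L": [
  {
   "label": "alpha",
   "center": [
    -63.0,
    -43.0
   ],
   "spread": [
    15.0,
    15.0
   ],
   "weight": 8
  },
  {
   "label": "ppii_coil",
   "center": [
    -70.0,
    145.0
   ],
   "spread": [
    13.0,
    13.0
   ],
   "weight": 64
  },
  {
   "label": "beta",
   "center": [
    -150.0,
    125.0
   ],
   "spread": [
    13.0,
    13.0
   ],
   "weight": 21
  },
  {
   "label": "positive_phi",
   "center": [
    60.0,
    45.0
   ],
   "spread": [
    13.0,
    13.0
   ],
   "weight": 7
  }
 ],
 "G": [
  {
   "label": "alpha",
   "center": [
    -63.0,
    -43.0
   ],
   "spread": [
    18.0,
    18.0
   ],
   "weight": 25
  },
  {
   "label": "ppii_coil",
   "center": [
    -70.0,
    145.0
   ],
   "spread": [
    18.0,
    18.0
   ],
   "weight": 35
  },
  {
   "label": "beta",
   "center": [
    -150.0,
    125.0
   ],
   "spread": [
    18.0,
    18.0
   ],
   "weight": 15
  },
  {
   "label": "positive_phi",
   "center": [
    75.0,
    30.0
   ],
   "spread": [
    18.0,
    18.0
   ],
   "weight": 25
  }
 ],
 "S": [
  {
   "label": "alpha",
   "center": [
    -63.0,
    -43.0
   ],
   "spread": [
    15.0,
    15.0
   ],
   "weight": 12
  },
  {
   "label": "ppii_coil",
   "center": [
    -70.0,
    145.0
   ],
   "spread": [
    13.0,
    13.0
   ],
   "weight": 58
  },
  {
   "label": "beta",
   "center": [
    -150.0,
    125.0
   ],
   "spread": [
    13.0,
    13.0
   ],
   "weight": 22
  },
  {
   "label": "positive_phi",
   "center": [
    60.0,
    45.0
   ],
   "spread": [
    13.0,
    13.0
   ],
   "weight": 8
  }
 ],
 "T": [
  {
   "label": "alpha",
   "center": [
    -63.0,
    -43.0
   ],
   "spread": [
    15.0,
    15.0
   ],
   "weight": 10
  },
  {
   "label": "ppii_coil",
   "center": [
    -70.0,
    145.0
   ],
   "spread": [
    13.0,
    13.0
   ],
   "weight": 55
  },
  {
   "label": "beta",
   "center": [
    -150.0,
    125.0
   ],
   "spread": [
    13.0,
    13.0
   ],
   "weight": 28
  },
  {
   "label": "positive_phi",
   "center": [
    60.0,
    45.0
   ],
   "spread": [
    13.0,
    13.0
   ],
   "weight": 7
  }
 ]
}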