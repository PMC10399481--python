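{
  "name": "carm1-like-4-feature",
  "features": [
    {"kind": "donor", "center": [0.0, 0.0, 0.0], "radius": 1.0},
    {"kind": "aromatic", "center": [6.0, 0.0, 0.0], "radius": 1.0},
    {"kind": "aromatic", "center": [3.0, 5.0, 0.0], "radius": 1.0},
    {"kind": "hydrophobic", "center": [3.0, 1.8, 4.8], "radius": 1.0}
  ]
}
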