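{
  "description": "Experimentally derived per-position mismatch penalty weights for SpCas9 off-target scoring (MIT/Hsu matrix). Index 1 is the PAM-distal protospacer position, index 20 is PAM-proximal.",
  "weights": [0.0, 0.0, 0.014, 0.0, 0.0, 0.395, 0.317, 0.0, 0.389, 0.079,
              0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583]
}
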