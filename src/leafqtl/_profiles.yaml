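# Default spectral profiles for the synthetic-scene generator.
# Mean reflectances per band (445..800 nm, ascending) on the [0, 1] scale.
# green_leaf: green-peaked visible spectrum with a strong NIR plateau.
# dormant_leaf: red-shifted (anthocyanic) visible spectrum, NIR still above red.
# background: pot/soil — flat visible, NIR at or below red (no red edge).
green_leaf:
  means: [0.08, 0.10, 0.25, 0.30, 0.24, 0.09, 0.09, 0.18, 0.60]
  noise_sd: 0.01
dormant_leaf:
  means: [0.10, 0.13, 0.14, 0.15, 0.16, 0.24, 0.25, 0.30, 0.52]
  noise_sd: 0.01
background:
  means: [0.20, 0.21, 0.22, 0.22, 0.23, 0.24, 0.24, 0.23, 0.18]
  noise_sd: 0.01
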