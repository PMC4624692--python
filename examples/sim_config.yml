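# Example simulation configuration: the full 5 tissue x 2 gene study design
# (7 sampling times at 4-h spacing, 6 fish per time, additive noise sd 1.0).
series:
  - {tissue: hypothalamus, gene: preproghrelin, mesor: 2.7, amplitude: 1.2, acrophase_h: 16.3}
  - {tissue: pituitary, gene: preproghrelin, mesor: 2.2, amplitude: 1.0, acrophase_h: 20.0}
  - {tissue: gastrointestinal_tract, gene: preproghrelin, mesor: 3.9, amplitude: 3.3, acrophase_h: 17.4}
  - {tissue: hypothalamus, gene: ghs-r1, mesor: 1.5, amplitude: 0.9, acrophase_h: 16.9}
  - {tissue: pituitary, gene: ghs-r1, mesor: 2.7, amplitude: 1.4, acrophase_h: 19.4}
  - {tissue: forebrain, gene: preproghrelin, mesor: 1.5, amplitude: 0.0}
  - {tissue: hindbrain, gene: preproghrelin, mesor: 1.5, amplitude: 0.0}
  - {tissue: forebrain, gene: ghs-r1, mesor: 1.5, amplitude: 0.0}
  - {tissue: hindbrain, gene: ghs-r1, mesor: 1.5, amplitude: 0.0}
  - {tissue: gastrointestinal_tract, gene: ghs-r1, mesor: 1.5, amplitude: 0.0}
timepoints_h: [0, 4, 8, 12, 16, 20, 24]
n_per_timepoint: 6
noise_sd: 1.0
noise_scale: additive
seed: 42
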