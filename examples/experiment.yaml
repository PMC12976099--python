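# Reference ward-simulation experiment: naive benchmark plus confusion
# emulators of the three fitted LOS classifiers.
runs: 1000
horizon: 10
beds: 50
reference_capacity: 60
seed: 1
class_counts: [18629, 6722, 2623, 5931]
models:
  - {type: naive, name: NP}
  - {type: emulator, reference: LRs}
  - {type: emulator, reference: LRc}
  - {type: emulator, reference: XGB}
  # custom emulator example:
  # - type: emulator
  #   name: my-model
  #   sensitivity: [0.6, 0.7, 0.9]
  #   specificity: [0.8, 0.6, 0.2]
  # real out-of-fold predictions:
  # - {type: table, path: predictions.csv, threshold: 0.5}
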