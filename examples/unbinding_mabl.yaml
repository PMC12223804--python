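# Surrogate ligand-unbinding run with the binless (MABL) resampler:
# 40 walkers, N = 5 split/merge per iteration, three-coordinate
# progress score with a 0.8 backward-progress window on rmsd 10-13.
system:
  kind: surrogate_unbinding_2d
  parameters: {}
resampler:
  type: mabl
  n_split_merge: 5
walker_count: 40
tau: 1.0
iterations: 400
seed: 1
score:
  balance: inverse_neg_log
  coordinates:
  - name: rmsd
    initial: 0.0
    target: 25.0
    regions:
    - - 10.0
      - 13.0
      - 0.8
  - name: energy
    initial: 350.0
    target: -200.0
  - name: distance
    initial: 0.0
    target: 10.0
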