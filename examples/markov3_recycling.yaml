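# 3-state Markov chain with recycling at the 'unbound' state:
# the mean recycled flux estimates 1/MFPT (= 1/30 per iteration
# for the built-in chain), checkable against the exact
# fundamental-matrix oracle.
system:
  kind: markov_chain
resampler:
  type: mabl
  n_split_merge: 3
walker_count: 20
tau: 1.0
iterations: 600
seed: 1
recycling:
  enabled: true
  target: unbound
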