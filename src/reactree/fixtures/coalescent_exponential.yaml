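# Single-type coalescent under exponential growth N(t) = 10 exp(0.5 t)
# (forward time, reference time 10 = the sampling time), ten
# contemporaneous leaves.
model: coalescent
types: [L]
coalescent_reactions:
  - reaction: "2L -> L"
    population: {kind: exponential, N0: 10.0, r: 0.5, t_ref: 10.0}
leaves:
  - {time: 10.0, type: L, count: 10}
replicates: 5
seed: 1
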