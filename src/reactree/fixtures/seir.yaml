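# SEIR epidemic with two sampling schemes:
#  - serial sampling of infectious individuals, rate 0 before t=5 and 1 after
#    (non-removing, so sampled ancestors can occur);
#  - punctual sampling-with-removal of each infectious individual with
#    probability 0.1 at times 5 and 10.
populations:
  - {name: S, initial: 99}
  - {name: E, initial: 0}
  - {name: I, initial: 1}
  - {name: R, initial: 0}
  - {name: sample, sample: true}
reactions:
  - {reaction: "I + S -> I + E", rate: "0.1"}
  - {reaction: "E -> I", rate: "1.0"}
  - {reaction: "I -> R", rate: "0.5"}
  - {reaction: "I -> I + sample", rate: "0 1", changeTimes: "5"}
punctual_reactions:
  - {reaction: "I -> sample", p: "0.1", times: "5 10"}
t_end: 10
conditions: {min_samples: 1, max_retries: 10000}
replicates: 3
seed: 1
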