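# Pure-birth (Yule) process run for 2 time units, then every extant
# individual is sampled at once.  Try:
#   reactree simulate examples/configs/yule_complete_sampling.yaml \
#       --seed 1 --out-trees yule.nexus --out-traj yule.tsv
populations:
  - {name: A, initial: 1}
  - {name: sample, sample: true}
reactions:
  - {reaction: "A -> 2A", rate: "1.0"}
punctual_reactions:
  - {reaction: "A -> sample", p: 1.0, times: "2"}
t_end: 2
replicates: 5
seed: 1
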