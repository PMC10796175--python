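# Stochastic logistic growth: birth X -> 2X at rate 1, density-dependent
# death 2X -> X at rate 1/K per ordered pair (K = 200 here), with 100
# individuals sampled contemporaneously at the end of the run.
populations:
  - {name: X, initial: 1}
  - {name: sample, sample: true}
reactions:
  - {reaction: "X -> 2X", rate: "1.0"}
  - {reaction: "2X -> X", rate: "0.005"}
punctual_reactions:
  - {reaction: "X -> sample", n: 100, times: "20"}
t_end: 20
conditions: {min_samples: 100, max_retries: 10000}
replicates: 1
seed: 1
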