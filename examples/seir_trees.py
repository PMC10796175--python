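"""Simulate transmission trees from the packaged SEIR epidemic model.

The model has compartments S, E, I, R, transmission at rate 0.1 per
infectious-susceptible pair, progression E->I at rate 1, removal at rate
0.5, serial (non-removing) sampling of infectious individuals at rate 1
after time 5, and punctual sampling-with-removal (p = 0.1) at times 5 and
10.  Each replicate yields a population trajectory and the phylogeny of
its samples.
"""

import importlib.resources as res

import reactree as rt
from reactree.config import load_config
from reactree.jobs import run_job

with res.as_file(res.files("reactree") / "fixtures" / "seir.yaml") as p:
    job = load_config(p)

result = run_job(job, out_trees="seir_trees.nexus",
                 out_trajectory="seir_trajectories.tsv")

for rep, forest in enumerate(result.forests):
    root = forest[0]
    print(f"replicate {rep}: {rt.leaf_count(root)} sampled leaves, "
          f"{rt.sampled_ancestor_count(root)} sampled ancestors, "
          f"tree height {rt.tree_height(root):.2f} time units")
print("Leaves are sampling events; height is the span from the root of the")
print("sampled outbreak to the last sample. Outputs: seir_trees.nexus,")
print("seir_trajectories.tsv (one row per grid time point per replicate).")
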