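import numpy as np
import pytest

import reactree as rt

SAMPLE = frozenset({"sample"})


def make_model(reactions=(), punctual=(), pops=(), t_end=1.0, min_samples=1):
    return rt.Model(
        populations=tuple(pops),
        reactions=tuple(reactions),
        punctual_reactions=tuple(punctual),
        t_end=t_end,
        conditions=rt.Conditions(min_samples=min_samples),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def yule_model():
    """Pure birth A -> 2A at rate 1 from a single founder."""
    return make_model(
        reactions=[rt.Reaction.from_string("A -> 2A", 1.0)],
        pops=[rt.Population("A", 1)],
        t_end=1.0,
    )


@pytest.fixture
def yule_sampled_model():
    """Yule run to t=2, then every extant individual sampled (p=1)."""
    return make_model(
        reactions=[rt.Reaction.from_string("A -> 2A", 1.0, SAMPLE)],
        punctual=[rt.PunctualReaction.from_string(
            "A -> sample", times=(2.0,), p=1.0, sample_populations=SAMPLE)],
        pops=[rt.Population("A", 1), rt.Population("sample", is_sample=True)],
        t_end=2.0,
    )


@pytest.fixture
def bd_sampling_model():
    """Linear birth-death with non-removing serial sampling, so sampled
    ancestors occur: lambda=2, mu=1, psi=0.5 over [0, 2]."""
    return make_model(
        reactions=[
            rt.Reaction.from_string("I -> 2I", 2.0, SAMPLE),
            rt.Reaction.from_string("I -> 0", 1.0, SAMPLE),
            rt.Reaction.from_string("I -> I + sample", 0.5, SAMPLE),
        ],
        pops=[rt.Population("I", 1), rt.Population("sample", is_sample=True)],
        t_end=2.0,
    )


@pytest.fixture
def two_type_model():
    """Two infectious types with symmetric migration and removal sampling."""
    sp = frozenset({"s1", "s2"})
    return make_model(
        reactions=[
            rt.Reaction.from_string("I1 -> 2I1", 1.5, sp),
            rt.Reaction.from_string("I2 -> 2I2", 1.5, sp),
            rt.Reaction.from_string("I1 -> I2", 0.5, sp),
            rt.Reaction.from_string("I2 -> I1", 0.5, sp),
            rt.Reaction.from_string("I1 -> 0", 0.5, sp),
            rt.Reaction.from_string("I2 -> 0", 0.5, sp),
            rt.Reaction.from_string("I1 -> s1", 0.4, sp),
            rt.Reaction.from_string("I2 -> s2", 0.4, sp),
        ],
        pops=[rt.Population("I1", 1), rt.Population("I2", 0),
              rt.Population("s1", is_sample=True),
              rt.Population("s2", is_sample=True)],
        t_end=2.5,
    )


@pytest.fixture
def immigration_death_model():
    """0 -> A at rate 1, A -> 0 at rate 1: Poisson stationary law."""
    return make_model(
        reactions=[rt.Reaction.from_string("0 -> A", 1.0),
                   rt.Reaction.from_string("A -> 0", 1.0)],
        pops=[rt.Population("A", 0)],
        t_end=2.0,
    )


@pytest.fixture
def seir_model():
    """SEIR epidemic with serial and punctual sampling."""
    from reactree.config import load_config
    import importlib.resources as res

    with res.as_file(res.files("reactree") / "fixtures" / "seir.yaml") as p:
        return load_config(p).model


def collect_tree_stats(model, n, seed, engine="backward", require_single_root=True):
    """Summary statistics over replicate reconstructed trees, from either
    the backward engine or the simulate-full-then-prune oracle."""
    from reactree.oracles import prune_to_reconstructed, simulate_full_tree

    heights, lengths, leaves, sa = [], [], [], []
    i, done = 0, 0
    while done < n:
        gen = rt.replicate_rng(seed, i)
        i += 1
        if engine == "backward":
            try:
                traj = rt.simulate_trajectory(model, gen)
            except rt.trajectory.ConditionError:
                continue
            forest = rt.reconstruct_tree(traj, model, gen)
        else:
            ft = simulate_full_tree(model, gen)
            if ft.n_samples < model.conditions.min_samples:
                continue
            forest = prune_to_reconstructed(ft)
        if require_single_root and len(forest) != 1:
            continue
        root = forest[0].copy_suppressed()
        heights.append(rt.tree_height(root))
        lengths.append(rt.total_branch_length(root))
        leaves.append(rt.leaf_count(root))
        sa.append(rt.sampled_ancestor_count(root))
        done += 1
    return (np.asarray(heights), np.asarray(lengths),
            np.asarray(leaves), np.asarray(sa))
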