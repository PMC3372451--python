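import numpy as np
import pytest

from spliceforest import (
    Costs,
    ExonColumn,
    GeneTree,
    Instance,
    SimulationConfig,
    Transcript,
    make_caterpillar,
    simulate,
)


@pytest.fixture
def cherry():
    return GeneTree.from_newick("(D,E)A;")


@pytest.fixture
def cat3():
    return make_caterpillar(3)


@pytest.fixture
def balanced4():
    return GeneTree.from_newick("((l1,l2)x,(l3,l4)y)r;")


def build_instance(tree, per_gene_vectors, n_states=None):
    """Instance from a {gene: [vector, ...]} dict of integer tuples."""
    n_cols = len(next(iter(per_gene_vectors.values()))[0])
    columns = [
        ExonColumn(f"e{i + 1}", 1 if n_states is None else n_states[i])
        for i in range(n_cols)
    ]
    transcripts = {
        g: [
            Transcript(f"{g}.t{j + 1}", g, tuple(vec))
            for j, vec in enumerate(vectors)
        ]
        for g, vectors in per_gene_vectors.items()
    }
    return Instance(tree, transcripts, columns)


def small_random_instances(
    n_instances,
    seed,
    *,
    max_leaves=3,
    max_transcripts=3,
    n_exons=20,
    one_transcript=False,
    min_leaves=2,
):
    """Seeded stream of simulated instances within the given size limits
    (instances exceeding the transcript cap are redrawn)."""
    rng = np.random.default_rng(seed)
    out = []
    attempts = 0
    while len(out) < n_instances and attempts < n_instances * 50:
        attempts += 1
        s = int(rng.integers(2**31))
        n_leaves = int(rng.integers(min_leaves, max_leaves + 1))
        tree = make_caterpillar(n_leaves)
        if one_transcript:
            cfg = SimulationConfig(
                n_exons=n_exons,
                n_transcripts=1,
                p_transcript_birth=0.0,
                seed=s,
            )
        else:
            cfg = SimulationConfig(
                n_exons=n_exons,
                n_transcripts=int(rng.integers(1, max_transcripts + 1)),
                seed=s,
            )
        sim = simulate(tree, cfg)
        if max(sim.instance.leaf_counts().values()) > max_transcripts:
            continue
        out.append(sim)
    assert len(out) == n_instances
    return out


@pytest.fixture
def unit_costs():
    return Costs(1, 1, 1)
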