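"""Scoring, bounds, sampling, the full search and the extended model."""

import math

import pytest

from spliceforest import (
    Costs,
    ScoringContext,
    SearchOptions,
    Topology,
    TreeShape,
    infer_transcript_phylogenies,
    leaf_exon_states,
    reconstruct_ancestral_exon_states,
    sample_initial_upper_bound,
    score_solution,
    similarity_index,
    topology_lower_bound,
)
from spliceforest.simulate import _oracle_topology_sf, enumerate_all_topologies

from conftest import build_instance, small_random_instances


def make_ctx(instance, costs):
    rows = leaf_exon_states(instance.transcripts, len(instance.columns))
    ancestral = reconstruct_ancestral_exon_states(instance.tree, rows)
    return (
        ScoringContext(
            instance.tree, instance.transcripts, instance.columns, ancestral, costs
        ),
        ancestral,
    )


class TestScore:
    def test_linear_combination(self):
        assert score_solution(2, 1, 3, Costs(1, 1, 1)) == 6
        assert score_solution(1, 0, 0, Costs(2.5, 1, 1)) == 2.5

    def test_infinite_parsimony_propagates(self):
        assert math.isinf(score_solution(1, 0, math.inf, Costs(1, 1, 1)))


class TestSimilarityIndex:
    def test_shared_exons_give_one(self):
        assert similarity_index([(1, 1, 0), (1, 1, 0)]) == 1.0

    def test_private_exons_give_zero(self):
        assert similarity_index([(1, 0), (0, 1)]) == 0.0

    def test_half_shared(self):
        assert similarity_index([(1, 1), (1, 0)]) == 0.5

    def test_empty_vectors_default_to_one(self):
        assert similarity_index([(0, 0), (0, 0)]) == 1.0

    def test_requires_a_leaf(self):
        with pytest.raises(ValueError):
            similarity_index([])


class TestLowerBound:
    def test_structural_part_alone_is_a_bound(self, cherry, unit_costs):
        inst = build_instance(cherry, {"D": [(1, 0)], "E": [(0, 1)]})
        ctx, _ = make_ctx(inst, unit_costs)
        topo = Topology(cherry, [TreeShape("A", ("D", "E"))])
        lb = topology_lower_bound(topo, unit_costs, ctx)
        assert lb >= unit_costs.birth * topo.n_tree + unit_costs.death * topo.n_death

    def test_single_tree_bound_is_exact(self, cherry, unit_costs):
        from spliceforest import assign_leaves

        inst = build_instance(cherry, {"D": [(1, 0, 1)], "E": [(0, 1, 1)]})
        ctx, anc = make_ctx(inst, unit_costs)
        topo = Topology(cherry, [TreeShape("A", ("D", "E"))])
        lb = topology_lower_bound(topo, unit_costs, ctx)
        res = assign_leaves(
            topo, cherry, inst.transcripts, anc, unit_costs, ctx=ctx
        )
        assert lb == score_solution(topo.n_tree, topo.n_death, res.s_f, unit_costs)

    @pytest.mark.parametrize("seed", range(10))
    def test_never_exceeds_topology_optimum(self, seed, unit_costs):
        sim = small_random_instances(1, seed, max_transcripts=2, n_exons=10)[0]
        inst = sim.instance
        ctx, _ = make_ctx(inst, unit_costs)
        for topo in enumerate_all_topologies(inst.tree, inst.leaf_counts()):
            lb = topology_lower_bound(topo, unit_costs, ctx)
            opt = score_solution(
                topo.n_tree,
                topo.n_death,
                _oracle_topology_sf(topo, ctx, inst.transcripts),
                unit_costs,
            )
            assert lb <= opt + 1e-9


class TestSampling:
    def test_deterministic_given_seed(self, unit_costs):
        sim = small_random_instances(1, 3, n_exons=10)[0]
        inst = sim.instance
        ctx, _ = make_ctx(inst, unit_costs)
        a = sample_initial_upper_bound(
            inst.tree, inst.transcripts, unit_costs, ctx, 5, seed=11
        )
        b = sample_initial_upper_bound(
            inst.tree, inst.transcripts, unit_costs, ctx, 5, seed=11
        )
        assert a == b

    def test_bound_dominates_optimum(self, unit_costs):
        from spliceforest import brute_force_optimal

        sim = small_random_instances(1, 5, max_transcripts=2, n_exons=10)[0]
        inst = sim.instance
        ctx, _ = make_ctx(inst, unit_costs)
        ub = sample_initial_upper_bound(
            inst.tree, inst.transcripts, unit_costs, ctx, 8, seed=0
        )
        assert ub >= brute_force_optimal(inst, unit_costs).score

    def test_rejects_zero_samples(self, cherry, unit_costs):
        inst = build_instance(cherry, {"D": [(1,)], "E": [(1,)]})
        ctx, _ = make_ctx(inst, unit_costs)
        with pytest.raises(ValueError):
            sample_initial_upper_bound(
                inst.tree, inst.transcripts, unit_costs, ctx, 0, seed=0
            )


class TestSearch:
    def test_identical_singletons_give_one_tree_costing_birth(
        self, cherry, unit_costs
    ):
        inst = build_instance(cherry, {"D": [(1, 1)], "E": [(1, 1)]})
        res = infer_transcript_phylogenies(
            inst.tree, inst.transcripts, inst.columns, unit_costs
        )
        assert res.score == unit_costs.birth
        assert res.n_solutions == 1
        assert res.solutions[0].n_tree == 1

    def test_all_solutions_share_the_minimum_score(self, unit_costs):
        sim = small_random_instances(1, 7, n_exons=10)[0]
        inst = sim.instance
        res = infer_transcript_phylogenies(
            inst.tree, inst.transcripts, inst.columns, unit_costs
        )
        assert {s.score for s in res.solutions} == {res.score}

    def test_pruning_does_not_change_the_result(self, unit_costs):
        for seed in (2, 9, 14):
            sim = small_random_instances(1, seed, max_transcripts=2, n_exons=10)[0]
            inst = sim.instance
            kw = dict(seed=seed, samples_per_tree_count=5)
            on = infer_transcript_phylogenies(
                inst.tree, inst.transcripts, inst.columns, unit_costs,
                SearchOptions(prune=True, **kw),
            )
            off = infer_transcript_phylogenies(
                inst.tree, inst.transcripts, inst.columns, unit_costs,
                SearchOptions(prune=False, **kw),
            )
            assert on.score == off.score
            key = lambda s: (s.topology.canonical_key, s.assignment.key())
            assert {key(s) for s in on.solutions} == {key(s) for s in off.solutions}

    def test_score_never_exceeds_sampling_bound(self, unit_costs):
        sim = small_random_instances(1, 4, n_exons=10)[0]
        inst = sim.instance
        ctx, _ = make_ctx(inst, unit_costs)
        ub = sample_initial_upper_bound(
            inst.tree, inst.transcripts, unit_costs, ctx, 10, seed=4
        )
        res = infer_transcript_phylogenies(
            inst.tree, inst.transcripts, inst.columns, unit_costs,
            SearchOptions(seed=4),
        )
        assert res.score <= ub

    def test_infinite_exon_cost_can_make_instances_infeasible(self, cherry):
        costs = Costs(1, 1, math.inf)
        # matching identical transcripts pairwise stays feasible
        inst = build_instance(
            cherry, {"D": [(1,), (0,)], "E": [(1,), (0,)]}
        )
        res = infer_transcript_phylogenies(
            inst.tree, inst.transcripts, inst.columns, costs
        )
        assert not res.no_solution
        # both D transcripts carry an exon that is absent at the ancestor and
        # gained as *alternative* (not free), so every tree spanning the A-D
        # edge needs a transcript-level flip: with c_E = inf, no solution
        inst2 = build_instance(
            cherry, {"D": [(1, 0), (0, 1)], "E": [(0, 0)]}
        )
        res2 = infer_transcript_phylogenies(
            inst2.tree, inst2.transcripts, inst2.columns, costs
        )
        assert res2.no_solution
        assert math.isinf(res2.score)
        assert res2.solutions == []

    def test_ranking_is_deterministic(self, unit_costs):
        sim = small_random_instances(1, 12, n_exons=10)[0]
        inst = sim.instance
        a = infer_transcript_phylogenies(
            inst.tree, inst.transcripts, inst.columns, unit_costs
        )
        b = infer_transcript_phylogenies(
            inst.tree, inst.transcripts, inst.columns, unit_costs
        )
        key = lambda s: (s.topology.canonical_key, s.assignment.key())
        assert [key(s) for s in a.solutions] == [key(s) for s in b.solutions]
        sims = [s.mean_similarity for s in a.solutions]
        events = [s.n_events for s in a.solutions]
        assert events == sorted(events)
        for e in set(events):
            group = [s for ev, s in zip(events, sims) if ev == e]
            assert group == sorted(group, reverse=True)


class TestExtendedModel:
    def test_newborn_identical_to_ancestor_costs_nothing(self, cherry):
        # two transcripts at D, one at E; the extra D transcript is a copy
        inst = build_instance(
            cherry, {"D": [(1, 1), (1, 1)], "E": [(1, 1)]}
        )
        costs = Costs(5, 1, 1)
        res = infer_transcript_phylogenies(
            inst.tree, inst.transcripts, inst.columns, costs,
            SearchOptions(extended=True),
        )
        assert not res.no_solution
        best = res.solutions[0]
        assert best.birth_costs is not None
        assert min(best.birth_costs) == 0.0

    def test_single_flip_newborn_costs_one(self, cherry):
        inst = build_instance(
            cherry, {"D": [(1, 1), (1, 0)], "E": [(1, 1)]}
        )
        costs = Costs(5, 1, 1)
        res = infer_transcript_phylogenies(
            inst.tree, inst.transcripts, inst.columns, costs,
            SearchOptions(extended=True),
        )
        best = res.solutions[0]
        assert sorted(best.birth_costs)[0] <= 1.0
        assert res.score < 2 * costs.birth  # dynamic births beat two constants

    def test_extended_search_visits_every_topology(self, cherry):
        inst = build_instance(cherry, {"D": [(1,)], "E": [(1,)]})
        res = infer_transcript_phylogenies(
            inst.tree, inst.transcripts, inst.columns, Costs(1, 1, 1),
            SearchOptions(extended=True),
        )
        total = len(enumerate_all_topologies(cherry, {"D": 1, "E": 1}))
        assert sum(s["refined"] for s in res.stats) == total

    def test_instance_size_guard(self, unit_costs):
        from spliceforest import ValidationError, make_caterpillar

        tree = make_caterpillar(4)
        inst = build_instance(
            tree, {g: [(1,), (1,), (1,), (1,)] for g in tree.leaves}
        )
        with pytest.raises(ValidationError):
            infer_transcript_phylogenies(
                inst.tree, inst.transcripts, inst.columns, unit_costs,
                SearchOptions(extended=True, extended_guard=12),
            )
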