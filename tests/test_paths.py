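import numpy as np
import pytest

from causal_emergence import (
    InconsistentEndpointError,
    Partition,
    apportion,
    build_path,
    ce_upper_bound,
    consistency_check,
    enumerate_partitions,
    find_endpoint_exhaustive,
    find_endpoint_greedy,
    make_block_model,
    make_cycle_plus_block,
    make_mesoscale_variant,
    make_permutation,
    parse_partition,
    scale_scores,
)


class TestExhaustiveEndpoint:
    def test_permutation_keeps_microscale(self, perm8):
        ep = find_endpoint_exhaustive(perm8)
        assert ep.partition == Partition.discrete(8)
        assert ep.cp == pytest.approx(1.0)

    def test_block_model(self, block_model):
        ep = find_endpoint_exhaustive(block_model)
        assert ep.partition.label == "(0,1,2,3),(4,5,6,7)"
        assert ep.cp == pytest.approx(1.0)

    def test_cycle_block_prefers_least_reduction(self, cycle_block):
        ep = find_endpoint_exhaustive(cycle_block)
        assert ep.partition.label == "(0),(1),(2),(3),(4,5,6,7)"
        assert ep.n_macro_states == 5
        assert ep.cp == pytest.approx(1.0)

    def test_no_consistent_partition_beats_endpoint(self, cycle_block):
        ep = find_endpoint_exhaustive(cycle_block)
        for part in enumerate_partitions(8):
            if not consistency_check(cycle_block, part).consistent:
                continue
            cp = scale_scores(cycle_block, part).cp_info
            assert cp <= ep.cp + 1e-9


class TestBuildPath:
    def test_endpoint_equals_micro_gives_flat_path(self, perm8):
        path = build_path(perm8, Partition.discrete(8))
        assert path.L == 0
        assert path.total_ce == 0.0

    def test_cycle_block_walkthrough(self, cycle_block):
        endpoint = parse_partition("(0),(1),(2),(3),(4,5,6,7)", 8)
        path = build_path(cycle_block, endpoint)
        assert len(path.scales) == 4  # micro + two pairwise merges + endpoint
        assert path.cp_values[0] == pytest.approx(2 / 3)
        assert path.cp_values[-1] == pytest.approx(1.0)
        assert path.total_ce == pytest.approx(1 / 3)
        assert all(c.consistent for c in path.consistency)
        # gains cease past the full-block merge: every coarser scale loses CP
        coarser = parse_partition("(0),(1,2,3),(4,5,6,7)", 8)
        # not consistent, hence never on an automated path
        assert not consistency_check(cycle_block, coarser).consistent

    def test_telescoping_identity(self, cycle_block, block_model, mesoscale_model):
        for tm in (cycle_block, block_model, mesoscale_model):
            ep = find_endpoint_exhaustive(tm)
            path = build_path(tm, ep.partition)
            assert abs(path.total_ce - (path.cp_values[-1] - path.cp_values[0])) < 1e-12
            assert abs(sum(path.deltas) - path.total_ce) < 1e-12

    def test_path_length_counts_merges(self, block_model):
        path = build_path(block_model, parse_partition("(0,1,2,3),(4,5,6,7)", 8))
        assert path.L == 6  # 8 states to 2 blocks, one merge per step

    def test_consecutive_scales_refinement_related(self, mesoscale_model):
        from causal_emergence import is_refinement

        ep = find_endpoint_exhaustive(mesoscale_model)
        path = build_path(mesoscale_model, ep.partition)
        for finer, coarser in zip(path.scales, path.scales[1:]):
            assert is_refinement(finer, coarser)
            assert coarser.n_blocks == finer.n_blocks - 1

    def test_inconsistent_endpoint_rejected(self, cycle_block):
        with pytest.raises(InconsistentEndpointError):
            build_path(cycle_block, parse_partition("(0,1),(2),(3),(4,5,6,7)", 8))


class TestApportion:
    def test_permutation_all_at_microscale(self, perm8):
        path = build_path(perm8, Partition.discrete(8))
        contributions = apportion(path)
        assert contributions[0][1] == pytest.approx(1.0)
        assert len(contributions) == 1

    def test_contributions_sum_to_endpoint_cp(self, cycle_block):
        endpoint = parse_partition("(0),(1),(2),(3),(4,5,6,7)", 8)
        path = build_path(cycle_block, endpoint)
        total = sum(v for _, v in apportion(path))
        assert total == pytest.approx(path.cp_values[-1], abs=1e-12)

    def test_microscale_contribution_is_its_cp(self, block_model):
        path = build_path(block_model, parse_partition("(0,1,2,3),(4,5,6,7)", 8))
        assert apportion(path)[0] == (Partition.discrete(8).label, path.cp_values[0])


class TestUpperBound:
    def test_permutation_zero(self, perm8):
        assert ce_upper_bound(perm8) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_one(self, uniform4):
        assert ce_upper_bound(uniform4) == pytest.approx(1.0, abs=1e-12)

    def test_cycle_block_bound_attained(self, cycle_block):
        bound = ce_upper_bound(cycle_block)
        ep = find_endpoint_exhaustive(cycle_block)
        path = build_path(cycle_block, ep.partition)
        assert bound == pytest.approx(1 / 3)
        assert path.total_ce == pytest.approx(bound)


class TestGreedyEndpoint:
    def test_permutation_stops_at_microscale(self, perm8):
        ep = find_endpoint_greedy(perm8, epsilon=1e-6)
        assert ep.partition == Partition.discrete(8)

    @pytest.mark.parametrize(
        "factory",
        [
            lambda: make_block_model([4, 4]),
            lambda: make_block_model([2, 2]),
            lambda: make_block_model([2, 3, 3]),
            lambda: make_cycle_plus_block(4, 4),
            lambda: make_cycle_plus_block(1, 2),
            lambda: make_cycle_plus_block(2, 3),
            lambda: make_mesoscale_variant([4, 4], [0.7, 0.1, 0.1, 0.1]),
            lambda: make_mesoscale_variant([2, 2], [0.9, 0.1]),
            lambda: make_permutation(8, [1, 2, 3, 4, 5, 6, 7, 0]),
        ],
    )
    def test_agrees_with_exhaustive_on_fixture_families(self, factory):
        tm = factory()
        exhaustive = find_endpoint_exhaustive(tm)
        greedy = find_endpoint_greedy(tm)
        assert greedy.cp == pytest.approx(exhaustive.cp, abs=1e-9)

    def test_rejects_bad_parameters(self, block_model):
        with pytest.raises(ValueError):
            find_endpoint_greedy(block_model, epsilon=0.0)
        with pytest.raises(ValueError):
            find_endpoint_greedy(block_model, window=0)


def test_permutation_coarse_grains_never_gain(perm8):
    """Every coarse grain of a permutation microscale has non-positive gain."""
    micro_cp = scale_scores(perm8, Partition.discrete(8)).cp_info
    for part in enumerate_partitions(8):
        cp = scale_scores(perm8, part).cp_info
        assert cp <= micro_cp + 1e-9
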