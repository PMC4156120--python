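"""Growth-unit succession, HSMC branching and multi-year topology."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from malustar.io import tree_to_json
from malustar.topology import (
    BranchingSequence,
    GUType,
    HsmcClassParams,
    HsmcParams,
    LateralFate,
    MarkovParams,
    SYLLEPTIC_FATES,
    Tree,
    ZoneSpec,
    count_gus,
    grow_year,
    init_trunk_from_sequence,
    sample_branching_zones,
    sample_gu_succession,
)

L = LateralFate


def degenerate_markov(row):
    T = np.tile(np.asarray(row, dtype=float), (4, 1))
    return MarkovParams(T, np.array([1.0, 0, 0, 0]))


class TestGuSuccession:
    @pytest.mark.parametrize(
        "row,expected",
        [((1, 0, 0, 0), GUType.LONG), ((0, 0, 0, 1), GUType.FLORAL)],
    )
    def test_degenerate_rows(self, rng, row, expected):
        params = degenerate_markov(row)
        assert all(
            sample_gu_succession(GUType.LONG, params, rng) == expected
            for _ in range(20)
        )

    def test_uniform_row_frequencies(self, rng):
        params = degenerate_markov((0.25, 0.25, 0.25, 0.25))
        draws = [sample_gu_succession(GUType.SHORT, params, rng) for _ in range(40_000)]
        for t in GUType:
            freq = sum(d == t for d in draws) / 40_000
            assert freq == pytest.approx(0.25, abs=0.01)

    def test_non_stochastic_row_rejected_at_load(self):
        with pytest.raises(ValueError):
            MarkovParams(np.full((4, 4), 0.3), np.array([1.0, 0, 0, 0]))


def single_zone_params(fate_probs, occupancy=("rest", ())):
    return HsmcParams(
        {"long": HsmcClassParams([ZoneSpec("only", occupancy, fate_probs)])}
    )


class TestBranchingZones:
    def test_single_latent_zone(self, rng):
        params = single_zone_params({L.LATENT: 1.0})
        out = sample_branching_zones("long", 10, params, rng)
        assert out == [(0, L.LATENT)] * 10

    def test_deterministic_two_zones(self, rng):
        params = HsmcParams(
            {
                "long": HsmcClassParams(
                    [
                        ZoneSpec("base", ("fixed", (3,)), {L.LATENT: 1.0}),
                        ZoneSpec("rest", ("rest", ()), {L.SYLLEPTIC_SHORT: 1.0}),
                    ]
                )
            }
        )
        out = sample_branching_zones("long", 8, params, rng)
        assert [z for z, _ in out] == [0, 0, 0, 1, 1, 1, 1, 1]

    def test_unknown_parent_class_is_config_error(self, rng):
        params = single_zone_params({L.LATENT: 1.0})
        with pytest.raises(ValueError):
            sample_branching_zones("medium", 5, params, rng)

    def test_zone_length_means_match_occupancies(self, rng):
        """Monte-Carlo zone lengths vs configured occupancy means (3 zones)."""
        zones = [
            ZoneSpec("a", ("shifted_poisson", (4.0, 2)), {L.LATENT: 1.0}),
            ZoneSpec("b", ("shifted_negbin", (4, 0.5, 3)), {L.PROLEPTIC_SHORT: 1.0}),
            ZoneSpec("c", ("rest", ()), {L.SYLLEPTIC_SHORT: 1.0}),
        ]
        params = HsmcParams({"long": HsmcClassParams(zones)})
        lengths = {0: [], 1: []}
        for _ in range(10_000):
            out = sample_branching_zones("long", 200, params, rng)
            ids = np.array([z for z, _ in out])
            for zid in (0, 1):
                lengths[zid].append(int(np.sum(ids == zid)))
        for zid, spec in [(0, zones[0]), (1, zones[1])]:
            got = np.mean(lengths[zid])
            assert got == pytest.approx(spec.mean_occupancy(), rel=0.05)

    @given(n_nodes=st.integers(1, 150), seed=st.integers(0, 1000))
    def test_zone_ids_non_decreasing(self, toy_params, n_nodes, seed):
        _, hsmc = toy_params
        rng = np.random.default_rng(seed)
        out = sample_branching_zones("long", n_nodes, hsmc, rng)
        ids = [z for z, _ in out]
        assert len(out) == n_nodes
        assert all(a <= b for a, b in zip(ids, ids[1:]))


class TestTrunkInit:
    def test_all_latent_single_gu(self):
        seq = BranchingSequence([L.LATENT] * 30, 1.0)
        tree = init_trunk_from_sequence(seq)
        assert len(tree.gus) == 1
        assert tree.gus[tree.root_id].n_metamers == 30

    def test_sylleptic_fates_instantiate_laterals(self, rng):
        fates = [L.LATENT] * 10 + [L.SYLLEPTIC_LONG] * 4
        tree = init_trunk_from_sequence(BranchingSequence(fates, 1.0), rng)
        assert len(tree.gus) == 5
        laterals = [g for g in tree.gus.values() if g.gu_id != tree.root_id]
        assert all(g.gu_type == GUType.LONG and g.year == 1 for g in laterals)

    def test_gu_count_matches_sylleptic_count(self, rng):
        from malustar.synthetic import SequenceGenSpec, generate_trunk_sequences

        seqs = generate_trunk_sequences(SequenceGenSpec(n_sequences=20, seed=4))
        for seq in seqs:
            tree = init_trunk_from_sequence(seq, np.random.default_rng(0))
            n_syl = sum(1 for f in seq.node_fates if f in SYLLEPTIC_FATES)
            assert len(tree.gus) == 1 + n_syl

    def test_proleptic_fates_become_pending_buds(self, rng):
        fates = [L.PROLEPTIC_SHORT, L.LATENT, L.PROLEPTIC_LONG]
        tree = init_trunk_from_sequence(BranchingSequence(fates, 0.5), rng)
        assert len(tree.gus) == 1
        assert len(tree.pending_buds) == 2

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            BranchingSequence([], 1.0)


def all_short_tree(n_gus=4):
    tree = Tree(age_years=1)
    root = tree.add_gu(GUType.SHORT, 1, 5)
    tree.root_id = root.gu_id
    for i in range(n_gus - 1):
        tree.add_gu(GUType.SHORT, 1, 5, parent_gu=root.gu_id, parent_rank=i + 1)
    return tree


class TestGrowYear:
    def test_total_mortality_stops_short_trees(self, toy_params, rng):
        markov, hsmc = toy_params
        tree = all_short_tree()
        n0 = len(tree.gus)
        grow_year(tree, markov, hsmc, mortality_short=1.0, rng=rng)
        assert len(tree.gus) == n0

    def test_degenerate_chain_growth(self, rng):
        """long->long succession with a zero-branching HSMC: one new GU per
        terminal, so an unbranched trunk stays a chain: GU count == years."""
        markov = degenerate_markov((1, 0, 0, 0))
        hsmc = single_zone_params({L.LATENT: 1.0})
        tree = init_trunk_from_sequence(BranchingSequence([L.LATENT] * 20, 1.0))
        for year in range(2, 7):
            grow_year(tree, markov, hsmc, 0.0, rng)
            assert len(tree.gus) == year

    def test_gu_count_non_decreasing_without_mortality(self, toy_params, rng):
        markov, hsmc = toy_params
        tree = init_trunk_from_sequence(
            BranchingSequence([L.LATENT] * 50, 1.0), rng
        )
        prev = 1
        for _ in range(4):
            grow_year(tree, markov, hsmc, 0.0, rng)
            assert len(tree.gus) >= prev
            prev = len(tree.gus)

    def test_reproducibility_bitwise(self, toy_params):
        markov, hsmc = toy_params
        docs = []
        for _rep in range(2):
            rng = np.random.default_rng(777)
            tree = init_trunk_from_sequence(
                BranchingSequence([L.LATENT] * 60, 1.0), rng
            )
            for _ in range(3):
                grow_year(tree, markov, hsmc, 0.1, rng)
            docs.append(tree_to_json(tree))
        assert docs[0] == docs[1]

    def test_golden_run_gu_counts(self, toy_params):
        """Regression fixture: per-year GU counts of a fixed-seed run."""
        markov, hsmc = toy_params
        rng = np.random.default_rng(2024)
        tree = init_trunk_from_sequence(
            BranchingSequence([L.LATENT] * 60, 1.0), rng
        )
        counts = [len(tree.gus)]
        for _ in range(4):
            grow_year(tree, markov, hsmc, 0.1, rng)
            counts.append(len(tree.gus))
        assert counts == GOLDEN_GU_COUNTS


# frozen from the run above (seed 2024, 60-node all-latent trunk, defaults)
GOLDEN_GU_COUNTS = [1, 2, 4, 9, 14]


class TestCountGus:
    def test_single_gu(self):
        seq = BranchingSequence([L.LATENT] * 10, 1.0)
        tree = init_trunk_from_sequence(seq)
        assert count_gus(tree) == {(1, GUType.LONG): 1}

    def test_counts_match_brute_force_traversal(self, toy_params):
        markov, hsmc = toy_params
        rng = np.random.default_rng(5)
        tree = init_trunk_from_sequence(BranchingSequence([L.LATENT] * 70, 1.0), rng)
        for _ in range(3):
            grow_year(tree, markov, hsmc, 0.1, rng)
        counts = count_gus(tree)
        # independent recount by walking parent links from every GU
        seen = {}
        stack = [tree.root_id]
        children = {}
        for g in tree.gus.values():
            if g.parent_gu is not None:
                children.setdefault(g.parent_gu, []).append(g.gu_id)
        while stack:
            gid = stack.pop()
            g = tree.gus[gid]
            key = (g.year, g.gu_type)
            seen[key] = seen.get(key, 0) + 1
            stack.extend(children.get(gid, []))
        assert counts == seen
        assert sum(counts.values()) == len(tree.gus)
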