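"""Sampling, clone-tree tracing, coalescent resolution, passengers."""

import numpy as np
import pytest

from oncosim.engine import Clone, SimulationRecord
from oncosim.genome import (
    GenomeLayout,
    MutationEvent,
    apply_event,
    copy_number_profile,
    init_diploid_genome,
)
from oncosim.lineage import (
    LineageNode,
    PassengerRates,
    add_passenger_mutations,
    build_clone_tree,
    realize_leaf_genomes,
    resolve_lineage,
    resolve_within_clone,
    sample_observed_cells,
)


def make_record(layout, chain_events, extra_children=(), final_counts=None,
                generations=20):
    """Synthetic registry: a founder, a chain of clones, optional side branches.

    chain_events: list of (clone_id, parent_id, birth_gen, event_kind_stub).
    final_counts: {site: {clone: n}} at the last generation; sizes are held
    constant over the whole history for simplicity.
    """
    clones = {0: Clone(clone_id=0, parent_clone_id=None, founding_event=None,
                       birth_generation=0, birth_site=0,
                       genome=init_diploid_genome(layout))}
    for cid, parent, gen in chain_events:
        genome = clones[parent].genome.copy()
        ev = MutationEvent(kind="snv", generation=gen, strand_id=0,
                           region=cid % layout.n_regions, offset=cid,
                           origin="driver")
        apply_event(genome, ev)
        clones[cid] = Clone(clone_id=cid, parent_clone_id=parent,
                            founding_event=ev, birth_generation=gen,
                            birth_site=0, genome=genome)
    final_counts = final_counts or {0: {max(clones): 100}}
    n_sites = max(final_counts) + 1
    snap = [dict(final_counts.get(s, {})) for s in range(n_sites)]
    history = []
    for t in range(generations + 1):
        gen_snap = [
            {c: n for c, n in snap[s].items()
             if clones[c].birth_generation <= t}
            for s in range(n_sites)
        ]
        history.append(gen_snap)
    return SimulationRecord(clones=clones, size_history=history,
                            migration_events=[], rng_seed=0, layout=layout,
                            generations_elapsed=generations)


class TestSampling:
    def test_single_surviving_clone_takes_all_samples(self, layout, rng):
        record = make_record(layout, [(1, 0, 3)], final_counts={0: {1: 500}})
        sample = sample_observed_cells(record, {0: 40}, rng)
        assert len(sample.cells) == 40
        assert {c.clone_id for c in sample.cells} == {1}
        assert len({c.cell_id for c in sample.cells}) == 40

    def test_empty_request_gives_empty_sample(self, layout, rng):
        record = make_record(layout, [(1, 0, 3)])
        assert sample_observed_cells(record, {0: 0}, rng).cells == []

    def test_oversampling_names_the_site(self, layout, rng):
        record = make_record(layout, [(1, 0, 3)], final_counts={0: {1: 10}})
        with pytest.raises(ValueError, match="site 0"):
            sample_observed_cells(record, {0: 11}, rng)

    def test_multinomial_proportions_follow_clone_sizes(self, layout, rng):
        record = make_record(layout, [(1, 0, 3), (2, 0, 4)],
                             final_counts={0: {1: 9000, 2: 1000}})
        sample = sample_observed_cells(record, {0: 1000}, rng)
        frac = sum(c.clone_id == 1 for c in sample.cells) / 1000
        se = np.sqrt(0.9 * 0.1 / 1000)
        assert abs(frac - 0.9) < 3 * se


class TestCloneTree:
    def test_single_observed_clone_contracts_to_one_node(self, layout, rng):
        record = make_record(layout, [(1, 0, 2), (2, 1, 5), (3, 2, 9)],
                             final_counts={0: {3: 100}})
        sample = sample_observed_cells(record, {0: 10}, rng)
        tree = build_clone_tree(sample, record)
        assert tree.root.clone_id == 0
        assert len(tree.root.children) == 1
        (node,) = tree.root.children
        assert node.clone_id == 3
        # the contracted edge concatenates the skipped events in birth order
        assert [e.generation for e in node.edge_events] == [2, 5, 9]
        assert node.edge_length == 9

    def test_sibling_clones_share_the_root(self, layout, rng):
        record = make_record(layout, [(1, 0, 2), (2, 0, 4)],
                             final_counts={0: {1: 50, 2: 50}})
        sample = sample_observed_cells(record, {0: 20}, rng)
        tree = build_clone_tree(sample, record)
        assert {c.clone_id for c in tree.root.children} == {1, 2}

    def test_branching_unobserved_ancestor_is_kept(self, layout, rng):
        # 0 -> 1 -> {2, 3}; only 2 and 3 observed: 1 must stay as a fork
        record = make_record(layout, [(1, 0, 2), (2, 1, 5), (3, 1, 7)],
                             final_counts={0: {2: 60, 3: 40}})
        sample = sample_observed_cells(record, {0: 30}, rng)
        tree = build_clone_tree(sample, record)
        assert set(tree.nodes) == {0, 1, 2, 3}
        fork = tree.nodes[1]
        assert not fork.sampled_cells
        assert {c.clone_id for c in fork.children} == {2, 3}

    def test_leaf_weights_count_samples_per_site_and_clone(self, layout, rng):
        record = make_record(layout, [(1, 0, 2)],
                             final_counts={0: {1: 100}, 1: {1: 100}})
        sample = sample_observed_cells(record, {0: 7, 1: 3}, rng)
        tree = build_clone_tree(sample, record)
        assert tree.leaf_weights() == {(0, 1): 7, (1, 1): 3}


class TestCoalescentResolution:
    def test_single_entering_lineage_passes_through(self, rng):
        leaf = LineageNode(name="cell", time=50, clone_id=1)
        out = resolve_within_clone([(leaf, 50)], np.full(51, 100), 0, rng)
        assert out is leaf

    def test_star_entry_at_birth_merges_at_the_founding_cell(self, rng):
        leaves = [LineageNode(name=f"c{i}", time=10, clone_id=1)
                  for i in range(5)]
        root = resolve_within_clone([(lf, 10) for lf in leaves],
                                    np.full(11, 1000), 10, rng)
        for node in _preorder(root):
            if node.children:
                assert node.time == 10

    def test_pairwise_time_is_geometric_with_mean_n(self):
        rng = np.random.default_rng(8)
        N, reps, span = 200, 600, 6000
        sizes = np.full(span + 1, N)
        times = []
        for _ in range(reps):
            a = LineageNode(name="a", time=span, clone_id=1)
            b = LineageNode(name="b", time=span, clone_id=1)
            root = resolve_within_clone([(a, span), (b, span)], sizes, 0, rng)
            times.append(span - root.time + 1)
        mean = np.mean(times)
        assert abs(mean - N) / N < 3 * (1 / np.sqrt(reps)) + 0.02

    def test_forced_merges_when_lineages_exceed_population(self, rng):
        # N=1 through the whole lifetime: everything must merge immediately
        leaves = [LineageNode(name=f"c{i}", time=30, clone_id=1)
                  for i in range(6)]
        root = resolve_within_clone([(lf, 30) for lf in leaves],
                                    np.ones(31, dtype=int), 0, rng)
        assert root.time == 30

    def test_resolved_tree_is_binary_with_all_leaves(self, layout, rng):
        record = make_record(layout, [(1, 0, 2), (2, 1, 5), (3, 1, 7)],
                             final_counts={0: {2: 600, 3: 400}})
        sample = sample_observed_cells(record, {0: 50}, rng)
        tree = resolve_lineage(build_clone_tree(sample, record), record, rng)
        leaves = tree.leaves()
        assert len(leaves) == 50
        assert {l.name for l in leaves} == {c.cell_id for c in sample.cells}
        for node in tree.preorder():
            assert len(node.children) in (0, 2)
            for child in node.children:
                assert child.time >= node.time

    def test_leaves_are_ultrametric_at_final_generation(self, layout, rng):
        record = make_record(layout, [(1, 0, 2), (2, 0, 4)],
                             final_counts={0: {1: 300, 2: 700}})
        sample = sample_observed_cells(record, {0: 30}, rng)
        tree = resolve_lineage(build_clone_tree(sample, record), record, rng)
        assert {l.time for l in tree.leaves()} == {record.generations_elapsed}

    def test_contracting_by_clone_recovers_clone_tree(self, layout, rng):
        record = make_record(layout, [(1, 0, 2), (2, 1, 5), (3, 1, 7)],
                             final_counts={0: {1: 100, 2: 600, 3: 300}})
        sample = sample_observed_cells(record, {0: 60}, rng)
        clone_tree = build_clone_tree(sample, record)
        tree = resolve_lineage(clone_tree, record, rng)
        # map every leaf up to the set of clones it passes through
        def clone_children(cid):
            return {c.clone_id for c in clone_tree.nodes[cid].children}
        for node in tree.preorder():
            for child in node.children:
                if child.clone_id != node.clone_id:
                    assert child.clone_id in clone_children(node.clone_id)


def _preorder(root):
    out, stack = [], [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


class TestPassengers:
    def _tree(self, layout, rng, counts=None):
        record = make_record(layout, [(1, 0, 2), (2, 0, 4)],
                             final_counts=counts or {0: {1: 500, 2: 500}})
        sample = sample_observed_cells(record, {0: 40}, rng)
        tree = resolve_lineage(build_clone_tree(sample, record), record, rng)
        return record, tree

    def test_zero_rate_leaves_tree_and_genomes_unchanged(self, layout, rng):
        record, tree = self._tree(layout, rng)
        add_passenger_mutations(tree, PassengerRates(snv=0, segmental=0),
                                record, rng)
        genomes = realize_leaf_genomes(tree, record)
        for leaf in tree.leaves():
            clone = record.clones[leaf.clone_id]
            assert copy_number_profile(genomes[leaf.name]) == clone.profile
            assert genomes[leaf.name].snvs == clone.genome.snvs

    def test_total_count_matches_poisson_expectation(self, layout):
        rng = np.random.default_rng(77)
        record, tree = self._tree(layout, rng)
        rate = PassengerRates(snv=0.05, segmental=0.0)
        add_passenger_mutations(tree, rate, record, rng)
        total_len = sum(n.time - n.parent.time for n in tree.preorder()
                        if n.parent is not None)
        expected = rate.total * total_len
        observed = sum(len(n.passenger_events) for n in tree.preorder())
        assert abs(observed - expected) < 3 * np.sqrt(expected) + 1
        # passengers are annotated as such and never touch the record
        for node in tree.preorder():
            for ev in node.passenger_events:
                assert ev.origin == "passenger"

    def test_same_clone_leaves_differ_only_below_their_mrca(self, layout):
        rng = np.random.default_rng(3)
        record, tree = self._tree(layout, rng, counts={0: {1: 1000}})
        add_passenger_mutations(tree, PassengerRates(snv=0.1, segmental=0.0),
                                record, rng)
        genomes = realize_leaf_genomes(tree, record)
        driver_snvs = record.clones[1].genome.snvs
        for g in genomes.values():
            assert driver_snvs <= g.snvs  # drivers shared by every leaf

    def test_realization_is_deterministic_given_the_tree(self, layout):
        rng = np.random.default_rng(11)
        record, tree = self._tree(layout, rng)
        add_passenger_mutations(tree, PassengerRates(), record,
                                np.random.default_rng(5))
        g1 = realize_leaf_genomes(tree, record)
        g2 = realize_leaf_genomes(tree, record)
        assert set(g1) == set(g2)
        for cell in g1:
            assert g1[cell].snvs == g2[cell].snvs
            assert copy_number_profile(g1[cell]) == copy_number_profile(g2[cell])
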