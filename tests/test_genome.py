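"""Genome representation, mutation mechanisms, replay, and viability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_event_sequence
from oncosim.genome import (
    DuplicateSnvError,
    GeneClass,
    GenomeConsistencyError,
    GenomeLayout,
    ConfigurationError,
    Snv,
    ViabilityLimits,
    apply_missegregation,
    apply_segmental_event,
    apply_snv,
    apply_wgd,
    check_viability,
    copy_number_profile,
    init_diploid_genome,
    replay_events,
)


class TestLayout:
    def test_region_ids_partition_into_chromosomes_and_arms(self, layout):
        seen = []
        for chrom in range(layout.n_chromosomes):
            for arm in ("p", "q"):
                regions = list(layout.regions_of_arm(chrom, arm))
                assert len(regions) == layout.regions_per_arm
                for r in regions:
                    assert layout.chromosome_of(r) == chrom
                    assert layout.arm_of(r) == arm
                seen.extend(regions)
        assert seen == list(range(layout.n_regions))

    @pytest.mark.parametrize("bad", [dict(n_chromosomes=0, regions_per_arm=3),
                                     dict(n_chromosomes=2, regions_per_arm=0)])
    def test_degenerate_layout_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            GenomeLayout(**bad)


class TestDiploidFounder:
    def test_two_strands_per_chromosome_and_all_two_profile(self, layout):
        g = init_diploid_genome(layout)
        assert len(g.strands) == 2 * layout.n_chromosomes
        prof = copy_number_profile(g)
        assert np.array_equal(prof.maternal, np.ones(layout.n_regions, dtype=int))
        assert np.array_equal(prof.paternal, np.ones(layout.n_regions, dtype=int))
        assert not g.snvs and g.wgd_count == 0

    def test_empty_event_log_replays_to_identity(self, layout):
        g = replay_events(layout, [])
        assert copy_number_profile(g) == copy_number_profile(init_diploid_genome(layout))


class TestSegmentalEvents:
    def test_gain_is_tandem_duplication(self, layout):
        g = init_diploid_genome(layout)
        sid = next(iter(g.strands))
        original = list(g.strands[sid].regions)
        apply_segmental_event(g, sid, start_index=1, length=1, kind="gain")
        expected = original[:2] + [original[1]] + original[2:]
        assert g.strands[sid].regions == expected

    def test_full_loss_removes_strand(self, layout):
        g = init_diploid_genome(layout)
        sid = next(iter(g.strands))
        n = len(g.strands[sid].regions)
        apply_segmental_event(g, sid, 0, n, kind="loss")
        assert sid not in g.strands

    def test_length_truncated_at_strand_end(self, layout):
        g = init_diploid_genome(layout)
        sid = next(iter(g.strands))
        apply_segmental_event(g, sid, 2, 10_000, kind="loss")
        assert len(g.strands[sid].regions) == 2

    def test_gain_then_loss_of_same_slice_restores_profile(self, layout):
        g = init_diploid_genome(layout)
        before = copy_number_profile(g)
        sid = next(iter(g.strands))
        apply_segmental_event(g, sid, 1, 2, kind="gain")
        apply_segmental_event(g, sid, 1, 2, kind="loss")
        assert copy_number_profile(g) == before

    def test_unknown_strand_is_consistency_error(self, layout):
        g = init_diploid_genome(layout)
        with pytest.raises(GenomeConsistencyError):
            apply_segmental_event(g, 999, 0, 1, kind="gain")


class TestMissegregation:
    def test_chromosome_gain_adds_strand_and_raises_cn(self, layout):
        g = init_diploid_genome(layout)
        maternal = [s for s in g.strands.values()
                    if s.chromosome == 0 and s.allele_of_origin == "maternal"]
        apply_missegregation(g, "chromosome", maternal[0].strand_id, "gain")
        prof = copy_number_profile(g)
        chr0 = list(layout.regions_of_chromosome(0))
        assert np.all(prof.total[chr0] == 3)
        assert np.all(prof.maternal[chr0] == 2)
        assert len([s for s in g.strands.values() if s.chromosome == 0]) == 3

    def test_arm_loss_removes_only_that_arm(self, layout):
        g = init_diploid_genome(layout)
        sid = next(iter(g.strands))
        apply_missegregation(g, "arm", sid, "loss", arm="p")
        prof = copy_number_profile(g)
        assert np.all(prof.total[list(layout.regions_of_arm(0, "p"))] == 1)
        assert np.all(prof.total[list(layout.regions_of_arm(0, "q"))] == 2)

    def test_gain_then_loss_of_new_strand_restores_diploid(self, layout):
        g = init_diploid_genome(layout)
        before = copy_number_profile(g)
        sid = next(iter(g.strands))
        apply_missegregation(g, "chromosome", sid, "gain")
        new_sid = max(g.strands)
        apply_missegregation(g, "chromosome", new_sid, "loss")
        assert copy_number_profile(g) == before


class TestWgd:
    def test_doubles_diploid(self, layout):
        g = init_diploid_genome(layout)
        n_strands = len(g.strands)
        apply_wgd(g)
        assert len(g.strands) == 2 * n_strands
        assert np.all(copy_number_profile(g).total == 4)

    def test_doubles_arbitrary_profile(self, layout):
        g = init_diploid_genome(layout)
        sids = list(g.strands)
        apply_missegregation(g, "chromosome", sids[0], "gain")  # chr0: 3 copies
        apply_missegregation(g, "chromosome", sids[2], "loss")  # chr1: 1 copy
        before = copy_number_profile(g).total.copy()
        apply_wgd(g)
        assert np.array_equal(copy_number_profile(g).total, 2 * before)

    def test_two_wgds_reach_octoploid(self, layout):
        g = init_diploid_genome(layout)
        apply_wgd(g)
        apply_wgd(g)
        assert np.all(copy_number_profile(g).total == 8)
        assert g.wgd_count == 2


class TestSnvs:
    def test_snv_has_multiplicity_one_and_leaves_profile_unchanged(self, layout):
        g = init_diploid_genome(layout)
        before = copy_number_profile(g)
        sid = next(iter(g.strands))
        apply_snv(g, region=5, offset=10, strand_id=sid)
        snv = next(iter(g.snvs))
        assert g.snv_multiplicity(snv) == 1
        assert copy_number_profile(g) == before

    def test_wgd_doubles_snv_multiplicity(self, layout):
        g = init_diploid_genome(layout)
        sid = next(iter(g.strands))
        apply_snv(g, 5, 10, sid)
        apply_wgd(g)
        total_mult = sum(g.snv_multiplicity(s) for s in g.snvs)
        assert total_mult == 2
        assert copy_number_profile(g).total[5] == 4

    def test_snv_dropped_with_lost_strand(self, layout):
        g = init_diploid_genome(layout)
        sid = next(iter(g.strands))
        apply_snv(g, 5, 10, sid)
        apply_missegregation(g, "chromosome", sid, "loss")
        assert not g.snvs

    def test_duplicate_site_signals_redraw(self, layout):
        g = init_diploid_genome(layout)
        sid = next(iter(g.strands))
        apply_snv(g, 5, 10, sid)
        with pytest.raises(DuplicateSnvError):
            apply_snv(g, 5, 10, sid)


class TestViability:
    def test_diploid_is_viable(self, classed_layout):
        assert check_viability(init_diploid_genome(classed_layout))

    def test_homozygous_essential_deletion_is_lethal(self, classed_layout):
        g = init_diploid_genome(classed_layout)
        essential = classed_layout.regions_of_class(GeneClass.ESSENTIAL)[0]
        for strand in list(g.strands.values()):
            if essential in strand.regions:
                idx = strand.regions.index(essential)
                apply_segmental_event(g, strand.strand_id, idx, 1, "loss")
        assert copy_number_profile(g).total[essential] == 0
        assert not check_viability(g)

    def test_wgd_budget_enforced(self, classed_layout):
        g = init_diploid_genome(classed_layout)
        limits = ViabilityLimits(max_wgd=2, max_mean_cn=100, max_region_cn=100)
        apply_wgd(g)
        apply_wgd(g)
        assert check_viability(g, limits)
        apply_wgd(g)
        assert not check_viability(g, limits)

    def test_region_copy_cap_enforced(self, layout):
        g = init_diploid_genome(layout)
        sid = next(iter(g.strands))
        for _ in range(10):
            apply_segmental_event(g, sid, 0, 1, "gain")
        assert copy_number_profile(g).total[0] == 12
        assert not check_viability(g, ViabilityLimits(max_region_cn=10,
                                                      max_mean_cn=1000))


class TestReplayOracle:
    """Replaying a logged event sequence must reproduce the genome exactly."""

    def test_replay_reproduces_profile_and_snvs(self, layout):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            g, events = random_event_sequence(layout, rng, max_len=30)
            replayed = replay_events(layout, events)
            assert copy_number_profile(replayed) == copy_number_profile(g)
            assert replayed.snvs == g.snvs
            assert replayed.wgd_count == g.wgd_count
            assert replayed.next_strand_id == g.next_strand_id

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_wgd_doubling_on_arbitrary_genomes(self, seed):
        layout = GenomeLayout(n_chromosomes=2, regions_per_arm=3,
                              region_length=1000)
        g, _ = random_event_sequence(layout, np.random.default_rng(seed))
        before = copy_number_profile(g)
        apply_wgd(g)
        after = copy_number_profile(g)
        assert np.array_equal(after.maternal, 2 * before.maternal)
        assert np.array_equal(after.paternal, 2 * before.paternal)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_allele_conservation_and_snv_multiplicity_bound(self, seed):
        layout = GenomeLayout(n_chromosomes=2, regions_per_arm=3,
                              region_length=1000)
        g, _ = random_event_sequence(layout, np.random.default_rng(seed))
        prof = copy_number_profile(g)
        assert np.all(prof.maternal >= 0) and np.all(prof.paternal >= 0)
        occurrences = np.zeros(layout.n_regions, dtype=int)
        for strand in g.strands.values():
            for r in strand.regions:
                occurrences[r] += 1
        assert np.array_equal(prof.total, occurrences)
        for snv in g.snvs:
            assert 1 <= g.snv_multiplicity(snv) <= prof.total[snv.region]
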