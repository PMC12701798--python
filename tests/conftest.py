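"""Shared fixtures and helpers for the oncosim test suite."""

from __future__ import annotations

import numpy as np
import pytest

from oncosim.genome import (
    DuplicateSnvError,
    GeneClass,
    Genome,
    GenomeLayout,
    MutationEvent,
    apply_event,
    draw_random_event,
    init_diploid_genome,
)

MECH_MENU = ("snv", "segmental", "arm_misseg", "chrom_misseg", "wgd")
# WGD kept rare so random genomes stay small
MECH_WEIGHTS = np.array([0.3, 0.3, 0.17, 0.17, 0.06])


@pytest.fixture
def layout() -> GenomeLayout:
    """Two chromosomes, three regions per arm, short regions."""
    return GenomeLayout(n_chromosomes=2, regions_per_arm=3, region_length=1000)


@pytest.fixture
def classed_layout() -> GenomeLayout:
    """Layout with one OG, one TSG and one essential region per chromosome."""
    gc = np.zeros(24, dtype=np.int8)
    gc[[0, 12]] = GeneClass.OG
    gc[[3, 15]] = GeneClass.TSG
    gc[[6, 18]] = GeneClass.ESSENTIAL
    return GenomeLayout(n_chromosomes=2, regions_per_arm=6, region_length=1000,
                        gene_class=gc)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_event_sequence(
    layout: GenomeLayout,
    rng: np.random.Generator,
    max_len: int = 30,
) -> tuple[Genome, list[MutationEvent]]:
    """Mutate a diploid founder with a random event sequence, logging events.

    Viability is deliberately not enforced so arbitrary genomes (including
    near-empty ones) are covered.
    """
    g = init_diploid_genome(layout)
    events: list[MutationEvent] = []
    n_events = int(rng.integers(0, max_len + 1))
    for _ in range(n_events):
        if not g.strands:
            break
        mech = MECH_MENU[rng.choice(len(MECH_MENU), p=MECH_WEIGHTS)]
        ev = draw_random_event(g, mech, rng, generation=len(events))
        if ev is None:
            continue
        try:
            apply_event(g, ev)
        except DuplicateSnvError:
            continue
        events.append(ev)
    return g, events
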