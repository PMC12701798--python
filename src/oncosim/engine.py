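"""Clone-level agent-based forward simulation (stage 1).

Tumor cell populations at one or more anatomical sites evolve over discrete
generations through a birth-death-mutation-migration process.  Because every
cell of a clone (the set of cells sharing an identical ordered sequence of
driver mutations) has the same replication, mutation and migration
probabilities, the agents are clones rather than individual cells: per
generation and site each clone's cell count is updated with vectorized
binomial draws, which keeps multi-million-cell populations tractable.

One generation at a site with population N and mean fitness fbar proceeds,
for a clone with n cells and fitness f:

1. lifespan completions  m ~ Binomial(n, tau);
2. divisions             b ~ Binomial(m, p_div) with
                         p_div = clamp((f/fbar)(1 + r(1 - N/K))/2, 0, 1);
                         the m - b non-dividers die;
3. mutant daughters      k ~ Binomial(2b, mu_total); each drawn mutant
                         founds a singleton clone via one driver event drawn
                         proportional to the per-mechanism rates, subject to
                         viability checkpoints (an inviable daughter dies);
4. count update          n' = n - m + 2b - k;
5. migration             per surviving clone and target site, binomial
                         thinning at the migration-model probability;
6. a per-generation snapshot of every clone's size at every site is
   appended to the simulation record (the coalescent in stage 2 runs over
   these recorded sizes).

The run terminates once every site that has ever been colonized
simultaneously holds at least ``n_min_detectable`` cells.  Total extinction
triggers a restart with a derived seed, up to a configured attempt limit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import (
    CNProfile,
    ConfigurationError,
    DuplicateSnvError,
    Genome,
    GenomeConsistencyError,
    GenomeLayout,
    MutationEvent,
    ViabilityLimits,
    check_viability,
    copy_number_profile,
    draw_random_event,
    init_diploid_genome,
    replay_events,
)
from .migration import MigrationEvent, SiteNetwork
from .selection import GrowthParams, SelectionLandscape, fitness_of

__all__ = [
    "DriverRates",
    "Clone",
    "EngineConfig",
    "SimulationState",
    "SimulationRecord",
    "SimulationExtinctError",
    "SimulationTimeoutError",
    "step_generation",
    "spawn_driver_clone",
    "run_forward",
]

logger = logging.getLogger(__name__)

MECHANISMS = ("snv", "segmental", "arm_misseg", "chrom_misseg", "wgd")


class SimulationExtinctError(RuntimeError):
    """Every restart attempt went extinct before detection."""


class SimulationTimeoutError(RuntimeError):
    """max_generations elapsed before every colonized site was detectable."""


@dataclass(frozen=True)
class DriverRates:
    """Per-division, per-daughter probabilities of each driver mechanism."""

    snv: float = 2e-3
    segmental: float = 1e-3
    arm_misseg: float = 5e-4
    chrom_misseg: float = 5e-4
    wgd: float = 1e-4
    segment_mean_length: float = 5.0

    def __post_init__(self) -> None:
        for mech in MECHANISMS:
            rate = getattr(self, mech)
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"rate for {mech} must lie in [0, 1]")
        if self.total > 1:
            raise ConfigurationError("summed driver rates exceed 1")

    @property
    def total(self) -> float:
        return self.snv + self.segmental + self.arm_misseg + self.chrom_misseg + self.wgd

    def mechanism_probs(self) -> np.ndarray:
        rates = np.array([getattr(self, m) for m in MECHANISMS], dtype=float)
        return rates / rates.sum() if rates.sum() > 0 else rates


@dataclass
class Clone:
    """Agent: the set of cells sharing one ordered driver-event sequence."""

    clone_id: int
    parent_clone_id: int | None
    founding_event: MutationEvent | None  # None only for the founder
    birth_generation: int
    birth_site: int
    genome: Genome
    profile: CNProfile = None  # cached allele-specific CNP
    driver_snv_regions: frozenset = frozenset()
    fitness_by_site: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.profile is None:
            self.profile = copy_number_profile(self.genome)
            self.driver_snv_regions = frozenset(self.genome.driver_snv_regions())


@dataclass
class EngineConfig:
    """Everything the forward simulation needs."""

    layout: GenomeLayout
    landscapes: list[SelectionLandscape]
    growth: list[GrowthParams]          # one per site
    rates: DriverRates = DriverRates()
    net: SiteNetwork | None = None      # None => single site, no migration
    selection_model: str = "region"
    viability: ViabilityLimits = ViabilityLimits()
    n_min_detectable: int = 50_000
    max_generations: int = 5_000
    max_restart_attempts: int = 50

    @property
    def n_sites(self) -> int:
        return self.net.n_sites if self.net is not None else 1

    def __post_init__(self) -> None:
        if len(self.growth) == 1 and self.n_sites > 1:
            self.growth = list(self.growth) * self.n_sites
        if len(self.growth) != self.n_sites:
            raise ConfigurationError("need one GrowthParams per site")
        if len(self.landscapes) != self.n_sites:
            raise ConfigurationError("need one landscape per site")
        if self.n_min_detectable < 1:
            raise ConfigurationError("n_min_detectable must be >= 1")


class SimulationState:
    """Mutable state of one forward run."""

    def __init__(self, cfg: EngineConfig):
        self.cfg = cfg
        self.clones: dict[int, Clone] = {}
        self.counts: list[dict[int, int]] = [dict() for _ in range(cfg.n_sites)]
        self.generation = 0
        self.colonized: set[int] = set()
        self.next_clone_id = 0

    @classmethod
    def founder(cls, cfg: EngineConfig, n_cells: int = 1) -> "SimulationState":
        state = cls(cfg)
        clone = Clone(
            clone_id=state.next_clone_id,
            parent_clone_id=None,
            founding_event=None,
            birth_generation=0,
            birth_site=0,
            genome=init_diploid_genome(cfg.layout),
        )
        state.next_clone_id += 1
        state.clones[clone.clone_id] = clone
        state.counts[0][clone.clone_id] = n_cells
        state.colonized.add(0)
        return state

    def register(self, clone: Clone) -> None:
        self.clones[clone.clone_id] = clone

    def total_cells(self) -> int:
        return sum(sum(site.values()) for site in self.counts)

    def site_total(self, site: int) -> int:
        return sum(self.counts[site].values())

    def fitness(self, clone: Clone, site: int) -> float:
        f = clone.fitness_by_site.get(site)
        if f is None:
            f = fitness_of(
                clone.profile,
                set(clone.driver_snv_regions),
                self.cfg.landscapes[site],
                self.cfg.selection_model,
            )
            clone.fitness_by_site[site] = f
        return f


@dataclass
class SimulationRecord:
    """Ground truth of a forward run, consumed by stage-2 lineage resolution.

    ``size_history[t][s]`` maps clone id to its cell count at site ``s`` at
    generation ``t`` (sparse: absent means zero); index 0 is the initial
    state.  The clone registry includes extinct clones.
    """

    clones: dict[int, Clone]
    size_history: list[list[dict[int, int]]]
    migration_events: list[MigrationEvent]
    rng_seed: int
    layout: GenomeLayout
    generations_elapsed: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.size_history[0])

    def final_counts(self) -> list[dict[int, int]]:
        return self.size_history[-1]

    def clone_size_series(self, clone_id: int, t0: int, t1: int) -> np.ndarray:
        """Total cells of a clone (summed over sites) at generations t0..t1."""
        out = np.zeros(t1 - t0 + 1, dtype=np.int64)
        for t in range(t0, t1 + 1):
            out[t - t0] = sum(site.get(clone_id, 0) for site in self.size_history[t])
        return out

    def driver_path(self, clone_id: int) -> list[MutationEvent]:
        """Founding events from the founder down to this clone, oldest first."""
        events: list[MutationEvent] = []
        cid: int | None = clone_id
        while cid is not None:
            clone = self.clones[cid]
            if clone.founding_event is not None:
                events.append(clone.founding_event)
            cid = clone.parent_clone_id
        events.reverse()
        return events

    # -- JSON (de)serialization; genomes are rebuilt by event replay ---------

    def to_dict(self) -> dict:
        def ev(e: MutationEvent | None):
            if e is None:
                return None
            return {k: v for k, v in vars(e).items() if v is not None}

        return {
            "rng_seed": self.rng_seed,
            "generations_elapsed": self.generations_elapsed,
            "layout": {
                "n_chromosomes": self.layout.n_chromosomes,
                "regions_per_arm": self.layout.regions_per_arm,
                "region_length": self.layout.region_length,
                "gene_class": self.layout.gene_class.tolist(),
            },
            "clones": {
                str(c.clone_id): {
                    "parent": c.parent_clone_id,
                    "event": ev(c.founding_event),
                    "birth_generation": c.birth_generation,
                    "birth_site": c.birth_site,
                }
                for c in self.clones.values()
            },
            "size_history": [
                [{str(k): v for k, v in site.items()} for site in gen]
                for gen in self.size_history
            ],
            "migration_events": [vars(m) for m in self.migration_events],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationRecord":
        layout = GenomeLayout(
            n_chromosomes=d["layout"]["n_chromosomes"],
            regions_per_arm=d["layout"]["regions_per_arm"],
            region_length=d["layout"]["region_length"],
            gene_class=np.array(d["layout"]["gene_class"], dtype=np.int8),
        )
        clones: dict[int, Clone] = {}
        raw = {int(k): v for k, v in d["clones"].items()}
        for cid in sorted(raw):  # parents precede children by id order
            info = raw[cid]
            parent = info["parent"]
            event = MutationEvent(**info["event"]) if info["event"] else None
            if parent is None:
                genome = init_diploid_genome(layout)
            else:
                genome = clones[parent].genome.copy()
                from .genome import apply_event

                apply_event(genome, event)
            clones[cid] = Clone(
                clone_id=cid,
                parent_clone_id=parent,
                founding_event=event,
                birth_generation=info["birth_generation"],
                birth_site=info["birth_site"],
                genome=genome,
            )
        return cls(
            clones=clones,
            size_history=[
                [{int(k): v for k, v in site.items()} for site in gen]
                for gen in d["size_history"]
            ],
            migration_events=[MigrationEvent(**m) for m in d["migration_events"]],
            rng_seed=d["rng_seed"],
            layout=layout,
            generations_elapsed=d["generations_elapsed"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "SimulationRecord":
        return cls.from_dict(json.loads(Path(path).read_text()))


def spawn_driver_clone(
    parent: Clone,
    site: int,
    generation: int,
    cfg: EngineConfig,
    rng: np.random.Generator,
    state: SimulationState,
) -> Clone | None:
    """Attempt to found a mutant daughter clone; None means the daughter died.

    The mechanism is drawn proportional to the configured driver rates, its
    coordinates uniformly over valid targets; the event is applied to a copy
    of the parent genome and the daughter is rejected if it fails a
    viability checkpoint or no valid target exists.
    """
    probs = cfg.rates.mechanism_probs()
    mech = MECHANISMS[rng.choice(len(MECHANISMS), p=probs)]
    event = draw_random_event(
        parent.genome, mech, rng, generation, cfg.rates.segment_mean_length
    )
    if event is None:
        return None
    genome = parent.genome.copy()
    try:
        from .genome import apply_event

        apply_event(genome, event)
    except (DuplicateSnvError, GenomeConsistencyError):
        return None
    if not check_viability(genome, cfg.viability):
        return None
    clone = Clone(
        clone_id=state.next_clone_id,
        parent_clone_id=parent.clone_id,
        founding_event=event,
        birth_generation=generation,
        birth_site=site,
        genome=genome,
    )
    state.next_clone_id += 1
    state.register(clone)
    return clone


def step_generation(
    state: SimulationState,
    rng: np.random.Generator,
    record: SimulationRecord | None = None,
) -> SimulationState:
    """Advance every site by one generation (birth/death, mutation, migration)."""
    cfg = state.cfg
    gen_next = state.generation + 1
    mu_total = cfg.rates.total

    for site in range(cfg.n_sites):
        counts = state.counts[site]
        if not counts:
            continue
        ids = list(counts)
        n = np.array([counts[c] for c in ids], dtype=np.int64)
        f = np.array([state.fitness(state.clones[c], site) for c in ids])
        total = int(n.sum())
        f_mean = float(np.dot(n, f)) / total
        gp = cfg.growth[site]
        logistic = 1.0 + gp.growth_rate * (1.0 - total / gp.carrying_capacity)
        p_div = np.clip((f / f_mean) * logistic / 2.0, 0.0, 1.0)

        m = rng.binomial(n, gp.turnover_rate)
        b = rng.binomial(m, p_div)
        daughters = 2 * b
        k = rng.binomial(daughters, mu_total) if mu_total > 0 else np.zeros_like(n)
        new_n = n - m + daughters - k

        new_counts = {cid: int(c) for cid, c in zip(ids, new_n) if c > 0}
        n_viable = 0
        for cid, k_i in zip(ids, k):
            parent = state.clones[cid]
            for _ in range(int(k_i)):
                child = spawn_driver_clone(parent, site, gen_next, cfg, rng, state)
                if child is not None:
                    new_counts[child.clone_id] = new_counts.get(child.clone_id, 0) + 1
                    n_viable += 1
        # bookkeeping identity: survivors + net births + viable mutants
        assert sum(new_counts.values()) == int(new_n.sum()) + n_viable
        state.counts[site] = new_counts

    _migration_pass(state, gen_next, rng, record)

    state.generation = gen_next
    if record is not None:
        record.size_history.append([dict(site) for site in state.counts])
        record.generations_elapsed = gen_next
    return state


def _migration_pass(
    state: SimulationState,
    generation: int,
    rng: np.random.Generator,
    record: SimulationRecord | None,
) -> None:
    cfg = state.cfg
    net = cfg.net
    if net is None or net.n_sites < 2 or net.base_migration_prob == 0:
        return
    for a in range(cfg.n_sites):
        counts = state.counts[a]
        if not counts:
            continue
        ids = list(counts)
        remaining = np.array([counts[c] for c in ids], dtype=np.int64)
        for b in range(cfg.n_sites):
            if b == a:
                continue
            if net.model == "static":
                p = min(1.0, net.base_migration_prob / net.base_distance[a, b])
                p_vec = np.full(len(ids), p)
            else:
                f_b = np.array(
                    [state.fitness(state.clones[c], b) for c in ids]
                )
                d_eff = net.base_distance[a, b] * np.maximum(
                    net.genotype_floor, 1.0 / f_b
                )
                p_vec = np.minimum(1.0, net.base_migration_prob / d_eff)
            migrants = rng.binomial(remaining, p_vec)
            if not migrants.any():
                continue
            for cid, cnt in zip(ids, migrants):
                if cnt == 0:
                    continue
                counts[cid] -= int(cnt)
                if counts[cid] == 0:
                    del counts[cid]
                dest = state.counts[b]
                dest[cid] = dest.get(cid, 0) + int(cnt)
                state.colonized.add(b)
                if record is not None:
                    record.migration_events.append(
                        MigrationEvent(generation, cid, a, b, int(cnt))
                    )
            remaining = remaining - migrants


def run_forward(cfg: EngineConfig, seed: int) -> SimulationRecord:
    """Stage 1: run the branching process to detectable size at every site.

    Starts one diploid founder cell at site 0 and iterates generations until
    every ever-colonized site simultaneously holds ``n_min_detectable``
    cells.  Total extinction restarts the run with seed + attempt index.
    """
    for attempt in range(cfg.max_restart_attempts):
        rng = np.random.default_rng(seed + attempt)
        state = SimulationState.founder(cfg)
        record = SimulationRecord(
            clones=state.clones,
            size_history=[[dict(site) for site in state.counts]],
            migration_events=[],
            rng_seed=seed,
            layout=cfg.layout,
        )
        extinct = False
        for _ in range(cfg.max_generations):
            step_generation(state, rng, record)
            if state.total_cells() == 0:
                extinct = True
                break
            if state.generation % 100 == 0:
                sizes = " ".join(
                    f"site{s}={state.site_total(s)}" for s in range(cfg.n_sites)
                )
                logger.info(
                    "generation=%d clones=%d %s",
                    state.generation, len(state.clones), sizes,
                )
            if all(
                state.site_total(s) >= cfg.n_min_detectable
                for s in state.colonized
            ):
                return record
        if extinct:
            logger.info("attempt %d went extinct; restarting", attempt)
            continue
        lagging = [
            s for s in state.colonized
            if state.site_total(s) < cfg.n_min_detectable
        ]
        raise SimulationTimeoutError(
            f"max_generations={cfg.max_generations} reached; "
            f"sites below threshold: {lagging}"
        )
    raise SimulationExtinctError(
        f"population went extinct in all {cfg.max_restart_attempts} attempts"
    )
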