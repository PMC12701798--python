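"""Region-resolved cancer genome representation and mutation mechanisms.

A cell genome is modeled as a multiset of chromosome *strands*.  Each strand
is an ordered list of fixed-length region identifiers (bins), tagged with the
parental allele it descends from.  Somatic copy-number aberrations (CNAs)
rearrange, duplicate or delete region slices and whole strands; single
nucleotide variants (SNVs) are point mutations pinned to a (strand, region,
offset) coordinate and physically ride along with the DNA they sit on: a
duplicated segment co-duplicates its SNVs and a deleted segment drops them.

Five mutation mechanisms are implemented:

* SNV — a point substitution at a uniform position on one strand,
* segmental gain/loss — tandem duplication or deletion of a contiguous
  slice of regions on one strand,
* chromosome-arm missegregation — gain (new strand holding a copy of one
  arm) or loss of one arm of a strand,
* whole-chromosome missegregation — gain (full strand copy on a fresh
  strand id) or loss of a strand,
* whole-genome duplication (WGD) — every strand duplicated at once.

The last three mechanisms create new chromosomal strands.  Strand ids are
allocated from a per-genome monotonic counter, so replaying a logged event
sequence on a fresh diploid founder deterministically reproduces the genome,
including the ids of event-created strands.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GeneClass",
    "GenomeLayout",
    "ChromosomeStrand",
    "Snv",
    "MutationEvent",
    "Genome",
    "CNProfile",
    "ViabilityLimits",
    "ConfigurationError",
    "GenomeConsistencyError",
    "DuplicateSnvError",
    "init_diploid_genome",
    "apply_segmental_event",
    "apply_missegregation",
    "apply_wgd",
    "apply_snv",
    "apply_event",
    "replay_events",
    "draw_random_event",
    "assign_gene_classes",
    "copy_number_profile",
    "check_viability",
]

MATERNAL = "maternal"
PATERNAL = "paternal"
ARMS = ("p", "q")


class ConfigurationError(ValueError):
    """Invalid user-supplied configuration."""


class GenomeConsistencyError(RuntimeError):
    """An operation referenced genome state that does not exist."""


class DuplicateSnvError(ValueError):
    """Signal to the caller that a drawn SNV site is already occupied."""


class GeneClass(IntEnum):
    NEUTRAL = 0
    OG = 1       # oncogene: amplification raises fitness
    TSG = 2      # tumor suppressor: deletion raises fitness
    ESSENTIAL = 3  # homozygous loss is lethal


@dataclass(frozen=True)
class GenomeLayout:
    """Static genome coordinate system shared by every cell in a simulation.

    Regions are fixed-length bins.  Global region ids are contiguous
    integers: chromosome ``c`` occupies ids ``[c*2k, (c+1)*2k)`` where ``k``
    is ``regions_per_arm``; within a chromosome the p-arm precedes the q-arm.
    """

    n_chromosomes: int
    regions_per_arm: int
    region_length: int = 1_000_000
    gene_class: np.ndarray | None = None  # int8 array of GeneClass, len n_regions

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.regions_per_arm < 1:
            raise ConfigurationError(
                "layout needs at least one chromosome and one region per arm"
            )
        if self.region_length < 1:
            raise ConfigurationError("region_length must be positive")
        if self.gene_class is None:
            object.__setattr__(
                self, "gene_class", np.zeros(self.n_regions, dtype=np.int8)
            )
        else:
            gc = np.asarray(self.gene_class, dtype=np.int8)
            if gc.shape != (self.n_regions,):
                raise ConfigurationError(
                    f"gene_class must have length {self.n_regions}"
                )
            object.__setattr__(self, "gene_class", gc)

    @property
    def n_regions(self) -> int:
        return self.n_chromosomes * 2 * self.regions_per_arm

    def chromosome_of(self, region: int) -> int:
        return region // (2 * self.regions_per_arm)

    def arm_of(self, region: int) -> str:
        return ARMS[(region // self.regions_per_arm) % 2]

    def regions_of_chromosome(self, chromosome: int) -> range:
        k = 2 * self.regions_per_arm
        return range(chromosome * k, (chromosome + 1) * k)

    def regions_of_arm(self, chromosome: int, arm: str) -> range:
        k = self.regions_per_arm
        base = chromosome * 2 * k + (k if arm == "q" else 0)
        return range(base, base + k)

    def arms(self) -> Iterator[tuple[int, str]]:
        return itertools.product(range(self.n_chromosomes), ARMS)

    def regions_of_class(self, cls: GeneClass) -> np.ndarray:
        return np.flatnonzero(self.gene_class == int(cls))


def assign_gene_classes(
    layout: GenomeLayout,
    frac_og: float,
    frac_tsg: float,
    frac_essential: float,
    rng: np.random.Generator,
) -> GenomeLayout:
    """Return a copy of *layout* with gene classes assigned uniformly at random.

    Fractions are of the total region count; the remainder is neutral.
    """
    total = frac_og + frac_tsg + frac_essential
    if min(frac_og, frac_tsg, frac_essential) < 0 or total > 1:
        raise ConfigurationError("gene-class fractions must be >=0 and sum to <=1")
    n = layout.n_regions
    n_og = int(round(frac_og * n))
    n_tsg = int(round(frac_tsg * n))
    n_ess = int(round(frac_essential * n))
    perm = rng.permutation(n)
    gc = np.zeros(n, dtype=np.int8)
    gc[perm[:n_og]] = GeneClass.OG
    gc[perm[n_og : n_og + n_tsg]] = GeneClass.TSG
    gc[perm[n_og + n_tsg : n_og + n_tsg + n_ess]] = GeneClass.ESSENTIAL
    return replace(layout, gene_class=gc)


@dataclass
class ChromosomeStrand:
    strand_id: int
    chromosome: int
    allele_of_origin: str  # MATERNAL or PATERNAL
    regions: list[int]


@dataclass(frozen=True)
class Snv:
    region: int
    offset: int
    strand_id: int
    origin: str = "driver"  # driver | passenger

    def locus(self) -> tuple[int, int]:
        return (self.region, self.offset)


@dataclass(frozen=True)
class MutationEvent:
    """A replayable mutation.  Fields irrelevant to ``kind`` are None.

    kinds: snv, segmental_gain, segmental_loss, arm_misseg_gain,
    arm_misseg_loss, chrom_misseg_gain, chrom_misseg_loss, wgd.
    """

    kind: str
    generation: int = 0
    strand_id: int | None = None
    arm: str | None = None
    start: int | None = None
    length: int | None = None
    region: int | None = None
    offset: int | None = None
    origin: str | None = None


@dataclass
class Genome:
    """Mutable genome of a single cell or clone."""

    layout: GenomeLayout
    strands: dict[int, ChromosomeStrand] = field(default_factory=dict)
    snvs: set[Snv] = field(default_factory=set)
    wgd_count: int = 0
    next_strand_id: int = 0

    def copy(self) -> "Genome":
        return Genome(
            layout=self.layout,
            strands={
                sid: ChromosomeStrand(
                    s.strand_id, s.chromosome, s.allele_of_origin, list(s.regions)
                )
                for sid, s in self.strands.items()
            },
            snvs=set(self.snvs),
            wgd_count=self.wgd_count,
            next_strand_id=self.next_strand_id,
        )

    def _new_strand_id(self) -> int:
        sid = self.next_strand_id
        self.next_strand_id += 1
        return sid

    def snvs_on_strand(self, strand_id: int) -> list[Snv]:
        return [s for s in self.snvs if s.strand_id == strand_id]

    def snv_multiplicity(self, snv: Snv) -> int:
        """Copies of the mutated base: occurrences of the region on its strand."""
        strand = self.strands.get(snv.strand_id)
        if strand is None:
            return 0
        return strand.regions.count(snv.region)

    def driver_snv_regions(self) -> set[int]:
        return {s.region for s in self.snvs if s.origin == "driver"}


@dataclass(frozen=True)
class CNProfile:
    """Allele-specific copy-number profile over the whole region set."""

    maternal: np.ndarray
    paternal: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.maternal + self.paternal

    def __eq__(self, other: object) -> bool:  # value semantics for tests
        if not isinstance(other, CNProfile):
            return NotImplemented
        return bool(
            np.array_equal(self.maternal, other.maternal)
            and np.array_equal(self.paternal, other.paternal)
        )


def init_diploid_genome(layout: GenomeLayout) -> Genome:
    """Found the simulation: one maternal and one paternal copy per chromosome."""
    g = Genome(layout=layout)
    for chrom in range(layout.n_chromosomes):
        for allele in (MATERNAL, PATERNAL):
            sid = g._new_strand_id()
            g.strands[sid] = ChromosomeStrand(
                sid, chrom, allele, list(layout.regions_of_chromosome(chrom))
            )
    return g


def _drop_orphan_snvs(g: Genome, strand_id: int) -> None:
    """Remove SNVs whose region no longer occurs on their strand."""
    strand = g.strands.get(strand_id)
    present = set(strand.regions) if strand is not None else set()
    g.snvs = {
        s
        for s in g.snvs
        if s.strand_id != strand_id or s.region in present
    }


def apply_segmental_event(
    g: Genome,
    strand_id: int,
    start_index: int,
    length: int,
    kind: str,
) -> Genome:
    """Tandem-duplicate (gain) or delete (loss) a contiguous region slice.

    The slice is ``regions[start : start+length]``, truncated at the strand
    end.  A gained slice is inserted immediately after the original; its SNVs
    ride along automatically since multiplicity is occurrence-counted.  A
    fully deleted strand is removed from the genome.
    """
    strand = g.strands.get(strand_id)
    if strand is None:
        raise GenomeConsistencyError(f"unknown strand {strand_id}")
    n = len(strand.regions)
    if not (0 <= start_index < n):
        raise GenomeConsistencyError(
            f"start index {start_index} outside strand of length {n}"
        )
    if length < 1:
        raise GenomeConsistencyError("segment length must be >= 1")
    stop = min(start_index + length, n)
    if kind == "gain":
        slice_ = strand.regions[start_index:stop]
        strand.regions[stop:stop] = slice_
    elif kind == "loss":
        del strand.regions[start_index:stop]
        if not strand.regions:
            del g.strands[strand_id]
        _drop_orphan_snvs(g, strand_id)
    else:
        raise GenomeConsistencyError(f"unknown segmental kind {kind!r}")
    return g


def apply_missegregation(
    g: Genome, scope: str, strand_id: int, kind: str, arm: str | None = None
) -> Genome:
    """Gain or lose a whole strand (chromosome scope) or one arm of a strand.

    Gains create a fresh strand carrying a copy of the target regions and
    their SNVs (re-keyed to the new strand id).
    """
    strand = g.strands.get(strand_id)
    if strand is None:
        raise GenomeConsistencyError(f"unknown strand {strand_id}")
    if scope == "chromosome":
        target_regions = list(strand.regions)
    elif scope == "arm":
        if arm not in ARMS:
            raise GenomeConsistencyError(f"unknown arm {arm!r}")
        arm_set = set(g.layout.regions_of_arm(strand.chromosome, arm))
        target_regions = [r for r in strand.regions if r in arm_set]
        if not target_regions:
            raise GenomeConsistencyError(
                f"strand {strand_id} carries no {arm}-arm regions"
            )
    else:
        raise GenomeConsistencyError(f"unknown missegregation scope {scope!r}")

    if kind == "gain":
        new_id = g._new_strand_id()
        g.strands[new_id] = ChromosomeStrand(
            new_id, strand.chromosome, strand.allele_of_origin, list(target_regions)
        )
        carried = set(target_regions)
        for snv in list(g.snvs):
            if snv.strand_id == strand_id and snv.region in carried:
                g.snvs.add(replace(snv, strand_id=new_id))
    elif kind == "loss":
        if scope == "chromosome":
            del g.strands[strand_id]
        else:
            keep = set(target_regions)
            strand.regions = [r for r in strand.regions if r not in keep]
            if not strand.regions:
                del g.strands[strand_id]
        _drop_orphan_snvs(g, strand_id)
    else:
        raise GenomeConsistencyError(f"unknown missegregation kind {kind!r}")
    return g


def apply_wgd(g: Genome) -> Genome:
    """Duplicate every strand (fresh ids, SNVs copied); doubles every copy number."""
    for sid in list(g.strands):
        strand = g.strands[sid]
        new_id = g._new_strand_id()
        g.strands[new_id] = ChromosomeStrand(
            new_id, strand.chromosome, strand.allele_of_origin, list(strand.regions)
        )
        for snv in list(g.snvs):
            if snv.strand_id == sid:
                g.snvs.add(replace(snv, strand_id=new_id))
    g.wgd_count += 1
    return g


def apply_snv(
    g: Genome, region: int, offset: int, strand_id: int, origin: str = "driver"
) -> Genome:
    """Place a point mutation; raises DuplicateSnvError if the site is taken."""
    strand = g.strands.get(strand_id)
    if strand is None or region not in strand.regions:
        raise GenomeConsistencyError(
            f"strand {strand_id} does not carry region {region}"
        )
    if not (0 <= offset < g.layout.region_length):
        raise GenomeConsistencyError(f"offset {offset} outside region")
    snv = Snv(region, offset, strand_id, origin)
    if any(
        s.region == region and s.offset == offset and s.strand_id == strand_id
        for s in g.snvs
    ):
        raise DuplicateSnvError(f"site {(region, offset, strand_id)} already mutated")
    g.snvs.add(snv)
    return g


def apply_event(g: Genome, ev: MutationEvent) -> Genome:
    """Dispatch one logged event onto the genome (the replay primitive)."""
    if ev.kind == "snv":
        return apply_snv(g, ev.region, ev.offset, ev.strand_id, ev.origin or "driver")
    if ev.kind in ("segmental_gain", "segmental_loss"):
        return apply_segmental_event(
            g, ev.strand_id, ev.start, ev.length, ev.kind.removeprefix("segmental_")
        )
    if ev.kind in ("arm_misseg_gain", "arm_misseg_loss"):
        return apply_missegregation(
            g, "arm", ev.strand_id,
            "gain" if ev.kind.endswith("gain") else "loss",
            arm=ev.arm,
        )
    if ev.kind in ("chrom_misseg_gain", "chrom_misseg_loss"):
        return apply_missegregation(
            g, "chromosome", ev.strand_id,
            "gain" if ev.kind.endswith("gain") else "loss",
        )
    if ev.kind == "wgd":
        return apply_wgd(g)
    raise GenomeConsistencyError(f"unknown event kind {ev.kind!r}")


def replay_events(layout: GenomeLayout, events: Iterable[MutationEvent]) -> Genome:
    """Rebuild a genome by applying an event log to a fresh diploid founder."""
    g = init_diploid_genome(layout)
    for ev in events:
        apply_event(g, ev)
    return g


def copy_number_profile(g: Genome) -> CNProfile:
    """Count region occurrences over strands, split by parental allele."""
    mat = np.zeros(g.layout.n_regions, dtype=np.int64)
    pat = np.zeros(g.layout.n_regions, dtype=np.int64)
    for strand in g.strands.values():
        target = mat if strand.allele_of_origin == MATERNAL else pat
        for r in strand.regions:
            target[r] += 1
    return CNProfile(maternal=mat, paternal=pat)


def draw_random_event(
    g: Genome,
    mechanism: str,
    rng: np.random.Generator,
    generation: int = 0,
    seg_mean_length: float = 5.0,
    origin: str = "driver",
    max_tries: int = 8,
) -> MutationEvent | None:
    """Draw uniform coordinates for one mutation mechanism on the current genome.

    Strands are weighted by their region count for SNVs and segmental events
    (breakpoints are uniform over the genome); missegregations pick a strand
    (and arm) uniformly.  Segmental lengths are geometric with the given
    mean.  Returns None when the genome offers no valid target (e.g. empty
    genome, or an SNV redraw limit is hit).
    """
    if not g.strands:
        return None
    sids = list(g.strands)
    if mechanism == "wgd":
        return MutationEvent(kind="wgd", generation=generation)
    if mechanism == "chrom_misseg":
        sid = sids[rng.integers(len(sids))]
        kind = "chrom_misseg_gain" if rng.random() < 0.5 else "chrom_misseg_loss"
        return MutationEvent(kind=kind, generation=generation, strand_id=sid)
    if mechanism == "arm_misseg":
        targets = []
        for sid in sids:
            strand = g.strands[sid]
            for arm in ARMS:
                arm_set = set(g.layout.regions_of_arm(strand.chromosome, arm))
                if any(r in arm_set for r in strand.regions):
                    targets.append((sid, arm))
        if not targets:
            return None
        sid, arm = targets[rng.integers(len(targets))]
        kind = "arm_misseg_gain" if rng.random() < 0.5 else "arm_misseg_loss"
        return MutationEvent(kind=kind, generation=generation, strand_id=sid, arm=arm)

    lengths = np.array([len(g.strands[s].regions) for s in sids], dtype=float)
    weights = lengths / lengths.sum()
    if mechanism == "segmental":
        sid = sids[rng.choice(len(sids), p=weights)]
        n = len(g.strands[sid].regions)
        start = int(rng.integers(n))
        length = int(rng.geometric(1.0 / max(seg_mean_length, 1.0)))
        kind = "segmental_gain" if rng.random() < 0.5 else "segmental_loss"
        return MutationEvent(
            kind=kind, generation=generation, strand_id=sid, start=start, length=length
        )
    if mechanism == "snv":
        for _ in range(max_tries):
            sid = sids[rng.choice(len(sids), p=weights)]
            strand = g.strands[sid]
            region = strand.regions[rng.integers(len(strand.regions))]
            offset = int(rng.integers(g.layout.region_length))
            taken = any(
                s.region == region and s.offset == offset and s.strand_id == sid
                for s in g.snvs
            )
            if not taken:
                return MutationEvent(
                    kind="snv", generation=generation, strand_id=sid,
                    region=region, offset=offset, origin=origin,
                )
        return None
    raise ConfigurationError(f"unknown mutation mechanism {mechanism!r}")


@dataclass(frozen=True)
class ViabilityLimits:
    """Checkpoint thresholds beyond which a newly mutated cell dies.

    A cell is inviable if an essential region is homozygously deleted, the
    genome-wide mean copy number exceeds ``max_mean_cn``, any single region
    exceeds ``max_region_cn`` copies, or more than ``max_wgd`` whole-genome
    duplications have occurred.
    """

    max_mean_cn: float = 8.0
    max_region_cn: int = 10
    max_wgd: int = 2


def check_viability(
    g: Genome, limits: ViabilityLimits = ViabilityLimits()
) -> bool:
    if g.wgd_count > limits.max_wgd:
        return False
    prof = copy_number_profile(g)
    total = prof.total
    essential = g.layout.regions_of_class(GeneClass.ESSENTIAL)
    if essential.size and np.any(total[essential] == 0):
        return False
    if total.mean() > limits.max_mean_cn:
        return False
    if total.max(initial=0) > limits.max_region_cn:
        return False
    return True
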