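"""Metastatic migration between anatomical sites.

The probability that a cell migrates from site ``a`` to site ``b`` in one
generation is the baseline per-generation migration probability divided by
an abstract site-to-site distance:

    p(a -> b) = min(1, p_base / d_eff(a, b))

Two distance models are provided.  The *static* model uses a fixed (supplied
or randomly generated) distance matrix — an organotropism prior that is
constant across cells and generations.  The *genotype* model additionally
rescales the distance per cell by the inverse of the cell's fitness under
the *target* site's landscape, floored at a configurable fraction of the
static distance, so cells whose mutations are advantageous in the target
site migrate there more readily.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import ConfigurationError, Genome
from .selection import SelectionLandscape, cell_fitness

__all__ = [
    "SiteNetwork",
    "random_distances",
    "effective_distance",
    "migration_probability",
    "sample_migrants",
]

MIGRATION_MODELS = ("static", "genotype")


def random_distances(
    n_sites: int, d_max: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw pairwise distances Uniform(1, d_max); diagonal is unused (0)."""
    if d_max < 1:
        raise ConfigurationError("d_max must be >= 1")
    d = rng.uniform(1.0, d_max, size=(n_sites, n_sites))
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class SiteNetwork:
    """Anatomical-site graph with distances and the migration model."""

    n_sites: int
    base_distance: np.ndarray  # (n_sites, n_sites), positive off-diagonal
    base_migration_prob: float = 1e-6
    model: str = "static"
    genotype_floor: float = 0.1

    def __post_init__(self) -> None:
        self.base_distance = np.asarray(self.base_distance, dtype=float)
        if self.base_distance.shape != (self.n_sites, self.n_sites):
            raise ConfigurationError("distance matrix must be n_sites x n_sites")
        off = ~np.eye(self.n_sites, dtype=bool)
        if self.n_sites > 1 and np.any(self.base_distance[off] <= 0):
            raise ConfigurationError("off-diagonal distances must be positive")
        if not 0 <= self.base_migration_prob <= 1:
            raise ConfigurationError("base_migration_prob must lie in [0, 1]")
        if self.model not in MIGRATION_MODELS:
            raise ConfigurationError(f"unknown migration model {self.model!r}")
        if not 0 < self.genotype_floor <= 1:
            raise ConfigurationError("genotype_floor must lie in (0, 1]")


def effective_distance(
    net: SiteNetwork,
    a: int,
    b: int,
    genome: Genome | None = None,
    landscapes: list[SelectionLandscape] | None = None,
    selection_model: str = "region",
    target_fitness: float | None = None,
) -> float:
    """Distance the migrating cell experiences from ``a`` to ``b``.

    Static model: the matrix entry, genome-independent.  Genotype model:
    the matrix entry times max(genotype_floor, 1 / f_b) where f_b is the
    cell's fitness under the target site's landscape (precomputed
    ``target_fitness`` may be passed to avoid recomputation).
    """
    if a == b:
        raise ValueError("migration requires distinct source and target sites")
    d = float(net.base_distance[a, b])
    if net.model == "static":
        return d
    if target_fitness is None:
        if genome is None or landscapes is None:
            raise ValueError("genotype model needs a genome or target fitness")
        target_fitness = cell_fitness(genome, landscapes[b], selection_model)
    return d * max(net.genotype_floor, 1.0 / target_fitness)


def migration_probability(net: SiteNetwork, d_eff: float) -> float:
    """p = min(1, p_base / d_eff)."""
    if d_eff <= 0:
        raise ValueError("effective distance must be positive")
    return min(1.0, net.base_migration_prob / d_eff)


def sample_migrants(
    clone_count: int, p: float, rng: np.random.Generator
) -> int:
    """Binomial thinning: number of a clone's cells that migrate this generation."""
    if clone_count < 0:
        raise ValueError("clone_count must be non-negative")
    if clone_count == 0 or p == 0:
        return 0
    return int(rng.binomial(clone_count, p))


@dataclass(frozen=True)
class MigrationEvent:
    """One realized clone-level migration (possibly several cells at once)."""

    generation: int
    clone_id: int
    source: int
    target: int
    n_cells: int
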