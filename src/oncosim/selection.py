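"""Multiplicative fitness landscapes and logistic growth scaling.

Each anatomical site carries its own fitness landscape: a selection
coefficient delta per region (and, derived from it, per chromosome arm).
Deltas multiply: delta > 1 marks an oncogene (OG) whose amplification raises
fitness, delta < 1 a tumor suppressor (TSG) whose loss raises fitness, and
delta = 1 is neutral.  Three models convert a genome into a relative fitness
``f`` (diploid baseline f = 1):

* region model      f = prod_r delta_r ** (c_r - 2), with c_r the total
                    copy number of region r;
* chromosome-arm    f = prod_A delta_A ** (cbar_A - 2), with cbar_A the mean
  model             copy number over the arm's regions and delta_A the
                    geometric mean of the arm's per-region deltas, so the arm
                    coefficient reflects the OG/TSG balance of the arm;
* hybrid model      the region model times one extra multiplier per region
                    carrying at least one driver SNV: delta_r for an OG
                    (activation), 1/delta_r for a TSG (inactivation), a
                    penalty epsilon for an essential-class region, 1
                    otherwise.

Fitness enters the birth-death process through the division probability

    p = clamp( (f / fbar) * (1 + r * (1 - N/K)) / 2, 0, 1 )

where fbar is the population mean fitness at the site, N the site population
and K its carrying capacity.  For a neutral population this reduces to the
deterministic logistic recursion E[N'] = N * (1 + r(1 - N/K)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import (
    ARMS,
    ConfigurationError,
    CNProfile,
    GeneClass,
    Genome,
    GenomeLayout,
    copy_number_profile,
)

__all__ = [
    "SelectionLandscape",
    "LandscapeParams",
    "GrowthParams",
    "build_landscapes",
    "region_fitness",
    "arm_fitness",
    "hybrid_fitness",
    "cell_fitness",
    "division_probability",
]

SELECTION_MODELS = ("region", "arm", "hybrid")


@dataclass
class SelectionLandscape:
    """Per-site map from genomic units to selection coefficients."""

    site: int
    layout: GenomeLayout
    region_delta: np.ndarray  # float, len n_regions, all > 0
    snv_essential_penalty: float = 0.95
    arm_delta: dict[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.region_delta = np.asarray(self.region_delta, dtype=float)
        if self.region_delta.shape != (self.layout.n_regions,):
            raise ConfigurationError("region_delta must cover every region")
        # a stored 0 is the "no effect" sentinel; map it to neutral 1
        self.region_delta = np.where(self.region_delta == 0, 1.0, self.region_delta)
        if np.any(self.region_delta <= 0):
            raise ConfigurationError("selection coefficients must be positive")
        if not 0 < self.snv_essential_penalty <= 1:
            raise ConfigurationError("snv_essential_penalty must lie in (0, 1]")
        if not self.arm_delta:
            self.arm_delta = {
                (c, a): float(
                    np.exp(np.mean(np.log(self.region_delta[list(
                        self.layout.regions_of_arm(c, a))])))
                )
                for c, a in self.layout.arms()
            }

    @property
    def log_region_delta(self) -> np.ndarray:
        return np.log(self.region_delta)


@dataclass(frozen=True)
class LandscapeParams:
    """Generator settings for random site-specific landscapes.

    ``s_max`` bounds the per-region effect size: OG deltas are drawn
    Uniform(1, 1+s_max) and TSG deltas Uniform(1-s_max, 1).  ``divergence``
    controls how much the non-neutral coefficients differ from site to site:
    each site multiplies the shared base delta by 1 + divergence * U(-1.5, 1.5),
    scaled so the expected absolute site-to-site difference relative to the
    mean coefficient equals ``divergence``.
    """

    frac_og: float = 0.1
    frac_tsg: float = 0.1
    frac_essential: float = 0.05
    s_max: float = 0.1
    divergence: float = 0.0
    snv_essential_penalty: float = 0.95

    def __post_init__(self) -> None:
        if self.frac_og + self.frac_tsg + self.frac_essential > 1:
            raise ConfigurationError("gene-class fractions sum to more than 1")
        if not 0 < self.s_max < 1:
            raise ConfigurationError("s_max must lie in (0, 1)")
        if self.divergence < 0:
            raise ConfigurationError("divergence must be non-negative")


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth settings for one site.

    ``growth_rate`` r and ``carrying_capacity`` K define the recursion
    N' = N(1 + r(1 - N/K)); ``turnover_rate`` tau is the per-generation
    probability that a cell completes its lifespan (tau = 1 recovers fixed
    one-generation lifespans; tau < 1 is the memoryless discretization of an
    exponential lifespan).
    """

    growth_rate: float = 0.4
    carrying_capacity: float = 100_000.0
    turnover_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.growth_rate <= 0:
            raise ConfigurationError("growth_rate must be positive")
        if self.carrying_capacity < 1:
            raise ConfigurationError("carrying_capacity must be >= 1")
        if not 0 < self.turnover_rate <= 1:
            raise ConfigurationError("turnover_rate must lie in (0, 1]")


def build_landscapes(
    layout: GenomeLayout,
    n_sites: int,
    params: LandscapeParams,
    rng: np.random.Generator,
) -> list[SelectionLandscape]:
    """Draw one fitness landscape per site over a shared gene-class layout.

    Gene classes must already be assigned on the layout (see
    :func:`oncosim.genome.assign_gene_classes`); classes are shared across
    sites while coefficients are perturbed per site by ``divergence``.
    """
    if n_sites < 1:
        raise ConfigurationError("need at least one site")
    base = np.ones(layout.n_regions, dtype=float)
    og = layout.regions_of_class(GeneClass.OG)
    tsg = layout.regions_of_class(GeneClass.TSG)
    base[og] = rng.uniform(1.0, 1.0 + params.s_max, size=og.size)
    base[tsg] = rng.uniform(1.0 - params.s_max, 1.0, size=tsg.size)

    landscapes = []
    for site in range(n_sites):
        delta = base.copy()
        if params.divergence > 0:
            nonneutral = np.concatenate([og, tsg])
            factor = 1.0 + params.divergence * rng.uniform(
                -1.5, 1.5, size=nonneutral.size
            )
            delta[nonneutral] = delta[nonneutral] * np.maximum(factor, 0.05)
            # keep every coefficient on its class's side of neutral
            delta[og] = np.maximum(delta[og], 1.0 + 1e-9)
            delta[tsg] = np.clip(delta[tsg], 1e-9, 1.0 - 1e-9)
        landscapes.append(
            SelectionLandscape(
                site=site,
                layout=layout,
                region_delta=delta,
                snv_essential_penalty=params.snv_essential_penalty,
            )
        )
    return landscapes


def region_fitness(profile: CNProfile, landscape: SelectionLandscape) -> float:
    """f = prod_r delta_r ** (c_r - 2); diploid genomes score exactly 1."""
    exponents = profile.total.astype(float) - 2.0
    return float(np.exp(np.dot(exponents, landscape.log_region_delta)))


def arm_fitness(profile: CNProfile, landscape: SelectionLandscape) -> float:
    """f = prod_A delta_A ** (cbar_A - 2) with cbar_A the arm-mean copy number."""
    total = profile.total.astype(float)
    log_f = 0.0
    for (c, a), delta in landscape.arm_delta.items():
        cbar = total[list(landscape.layout.regions_of_arm(c, a))].mean()
        log_f += (cbar - 2.0) * math.log(delta)
    return float(math.exp(log_f))


def hybrid_fitness(
    profile: CNProfile,
    driver_snv_regions: set[int],
    landscape: SelectionLandscape,
) -> float:
    """Region-model fitness times one SNV multiplier per mutated region.

    The multiplier for a region holding at least one driver SNV is delta_r
    for an OG, 1/delta_r for a TSG, the essential-gene penalty epsilon for an
    essential-class region, and 1 otherwise; multiple SNVs in one region
    count once.
    """
    f = region_fitness(profile, landscape)
    gc = landscape.layout.gene_class
    for r in driver_snv_regions:
        delta = landscape.region_delta[r]
        if delta > 1.0:
            f *= delta
        elif delta < 1.0:
            f /= delta
        elif gc[r] == GeneClass.ESSENTIAL:
            f *= landscape.snv_essential_penalty
    return float(f)


def fitness_of(
    profile: CNProfile,
    driver_snv_regions: set[int],
    landscape: SelectionLandscape,
    model: str,
) -> float:
    """Evaluate the configured selection model on a precomputed profile."""
    if model == "region":
        return region_fitness(profile, landscape)
    if model == "arm":
        return arm_fitness(profile, landscape)
    if model == "hybrid":
        return hybrid_fitness(profile, driver_snv_regions, landscape)
    raise ConfigurationError(f"unknown selection model {model!r}")


def cell_fitness(
    genome: Genome, landscape: SelectionLandscape, model: str
) -> float:
    """Dispatch to the configured selection model."""
    return fitness_of(
        copy_number_profile(genome), genome.driver_snv_regions(), landscape, model
    )


def division_probability(
    f: float, f_mean: float, n_cells: float, gp: GrowthParams
) -> float:
    """Per-lifespan-completion division probability under logistic scaling.

    p = clamp((f/fbar) * (1 + r(1 - N/K)) / 2, 0, 1).  With f = fbar and
    N = K this is exactly 1/2 (stationary); a neutral population follows the
    logistic recursion in expectation.
    """
    if f <= 0 or f_mean <= 0:
        raise RuntimeError("non-positive fitness reached the growth step")
    if n_cells < 1:
        raise RuntimeError("division probability queried for an empty population")
    logistic = 1.0 + gp.growth_rate * (1.0 - n_cells / gp.carrying_capacity)
    return float(min(max((f / f_mean) * logistic / 2.0, 0.0), 1.0))
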