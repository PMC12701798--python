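"""End-to-end orchestration: forward simulation through data generation.

A run proceeds through named stages — setup, forward, sample, resolve,
passengers, profiles, counts, sequences — each drawing randomness from its
own substream derived from the master seed, so disabling or re-running a
late stage never perturbs an earlier one.  Any stage error aborts the run
with the stage name; outputs written by earlier stages are preserved.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io as oio
from .config import RunConfig, save_config
from .datagen import (
    CoverageModel,
    emit_profiles,
    invoke_read_simulator,
    realize_sequences,
    simulate_read_counts,
)
from .engine import DriverRates, EngineConfig, SimulationRecord, run_forward
from .genome import GenomeLayout, ViabilityLimits, assign_gene_classes
from .lineage import (
    PassengerRates,
    add_passenger_mutations,
    build_clone_tree,
    realize_leaf_genomes,
    resolve_lineage,
    sample_observed_cells,
)
from .migration import SiteNetwork, random_distances
from .selection import GrowthParams, LandscapeParams, build_landscapes

__all__ = ["PipelineError", "build_engine_config", "run_pipeline"]

logger = logging.getLogger(__name__)

READ_LENGTH = 150  # bases, paired-end: used only to convert reads to coverage


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def build_engine_config(
    cfg: RunConfig, rng: np.random.Generator
) -> EngineConfig:
    """Materialize layout, landscapes and site network from the run config."""
    layout = GenomeLayout(
        n_chromosomes=cfg.genome.n_chromosomes,
        regions_per_arm=cfg.genome.regions_per_arm,
        region_length=cfg.genome.region_length,
    )
    layout = assign_gene_classes(
        layout,
        cfg.genome.frac_og,
        cfg.genome.frac_tsg,
        cfg.genome.frac_essential,
        rng,
    )
    n_sites = cfg.migration.n_sites
    landscapes = build_landscapes(
        layout,
        n_sites,
        LandscapeParams(
            frac_og=cfg.genome.frac_og,
            frac_tsg=cfg.genome.frac_tsg,
            frac_essential=cfg.genome.frac_essential,
            s_max=cfg.selection.s_max,
            divergence=cfg.selection.divergence,
            snv_essential_penalty=cfg.selection.snv_essential_penalty,
        ),
        rng,
    )
    net = None
    if n_sites > 1:
        if cfg.migration.distance_matrix is not None:
            d = np.asarray(cfg.migration.distance_matrix, dtype=float)
        else:
            d = random_distances(n_sites, cfg.migration.d_max, rng)
        net = SiteNetwork(
            n_sites=n_sites,
            base_distance=d,
            base_migration_prob=cfg.migration.p_base,
            model=cfg.migration.model,
            genotype_floor=cfg.migration.genotype_floor,
        )
    return EngineConfig(
        layout=layout,
        landscapes=landscapes,
        growth=[
            GrowthParams(
                growth_rate=cfg.growth.growth_rate,
                carrying_capacity=cfg.growth.carrying_capacity,
                turnover_rate=cfg.growth.turnover_rate,
            )
        ]
        * n_sites,
        rates=DriverRates(
            snv=cfg.rates.snv,
            segmental=cfg.rates.segmental,
            arm_misseg=cfg.rates.arm_misseg,
            chrom_misseg=cfg.rates.chrom_misseg,
            wgd=cfg.rates.wgd,
            segment_mean_length=cfg.rates.segment_mean_length,
        ),
        net=net,
        selection_model=cfg.selection.model,
        viability=ViabilityLimits(
            max_mean_cn=cfg.viability.max_mean_cn,
            max_region_cn=cfg.viability.max_region_cn,
            max_wgd=cfg.viability.max_wgd,
        ),
        n_min_detectable=cfg.engine.n_min_detectable,
        max_generations=cfg.engine.max_generations,
        max_restart_attempts=cfg.engine.max_restart_attempts,
    )


def resolve_record(
    cfg: RunConfig, record: SimulationRecord, outdir: Path
):
    """Stage 2: sample cells, build trees, add passengers, realize genomes."""
    sample_rng = _stage_rng(cfg.seed, 2)
    final = record.final_counts()
    n_per_site = {
        s: min(cfg.sampling.n_per_site, sum(final[s].values()))
        for s in range(record.n_sites)
        if final[s]
    }
    sample = sample_observed_cells(record, n_per_site, sample_rng)

    clone_tree = build_clone_tree(sample, record)
    (outdir / "clone_tree.nwk").write_text(oio.clone_tree_to_newick(clone_tree))

    tree = resolve_lineage(clone_tree, record, _stage_rng(cfg.seed, 3))
    tree = add_passenger_mutations(
        tree,
        PassengerRates(
            snv=cfg.passengers.snv,
            segmental=cfg.passengers.segmental,
            segment_mean_length=cfg.passengers.segment_mean_length,
        ),
        record,
        _stage_rng(cfg.seed, 4),
    )
    (outdir / "cell_lineage.nwk").write_text(oio.lineage_tree_to_newick(tree))
    oio.write_edge_annotations_tsv(tree, outdir / "edge_events.tsv")
    genomes = realize_leaf_genomes(tree, record)
    return sample, clone_tree, tree, genomes


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full simulation pipeline; returns the output directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("oncosim")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        save_config(cfg, outdir / "config_echo.yaml")

        stage = "setup"
        try:
            engine_cfg = build_engine_config(cfg, _stage_rng(cfg.seed, 0))
            oio.write_landscapes_tsv(
                engine_cfg.landscapes, outdir / "landscapes.tsv"
            )
            if engine_cfg.net is not None:
                oio.write_distance_matrix(
                    engine_cfg.net.base_distance, outdir / "distances.tsv"
                )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "forward"
        try:
            forward_seed = int(_stage_rng(cfg.seed, 1).integers(2**31))
            record = run_forward(engine_cfg, forward_seed)
            record.save(outdir / "record.json")
            oio.write_events_tsv(record, outdir / "events.tsv")
            oio.write_migration_events_tsv(
                record.migration_events, outdir / "migration_events.tsv"
            )
            oio.write_migration_graph(
                record.migration_events, engine_cfg.n_sites,
                outdir / "migration_graph.tsv",
            )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "resolve"
        try:
            sample, clone_tree, tree, genomes = resolve_record(
                cfg, record, outdir
            )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "profiles"
        try:
            cnp, snv, loci = emit_profiles(genomes, engine_cfg.layout)
            cnp.to_csv(outdir / "cnp.tsv", sep="\t")
            snv.to_csv(outdir / "snv.tsv", sep="\t")
            loci.to_csv(outdir / "snv_loci.tsv", sep="\t", index=False)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "counts"
        try:
            cm = CoverageModel(
                mean_reads_per_cell=cfg.coverage.mean_reads_per_cell,
                total_depth=cfg.coverage.total_depth,
                sigma_bias=cfg.coverage.sigma_bias,
                overdispersion=cfg.coverage.overdispersion_value,
                normal_fraction=cfg.coverage.normal_fraction,
            )
            counts = simulate_read_counts(
                cnp, cm, cfg.coverage.mode, _stage_rng(cfg.seed, 5)
            )
            counts.to_csv(outdir / "counts.tsv", sep="\t")
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        if cfg.reference is not None:
            stage = "sequences"
            try:
                _generate_sequences(cfg, engine_cfg.layout, genomes, outdir)
            except Exception as exc:
                raise PipelineError(stage, exc) from exc

        logger.info("pipeline complete: %s", outdir)
        return outdir
    finally:
        root.removeHandler(handler)
        handler.close()


def _generate_sequences(cfg, layout, genomes, outdir: Path) -> None:
    import pyfaidx

    fasta = pyfaidx.Fasta(cfg.reference)
    names = list(fasta.keys())
    if len(names) < layout.n_chromosomes:
        raise ValueError(
            f"reference has {len(names)} sequences; layout needs "
            f"{layout.n_chromosomes}"
        )
    reference = {
        c: str(fasta[names[c]][:]) for c in range(layout.n_chromosomes)
    }
    sequences = {
        cell: realize_sequences(g, reference, layout, cell_id=cell)
        for cell, g in sorted(genomes.items())
    }
    diploid_len = 2 * layout.n_regions * layout.region_length
    coverage = cfg.coverage.mean_reads_per_cell * 2 * READ_LENGTH / diploid_len
    invoke_read_simulator(
        sequences, coverage, outdir / "reads", cfg.read_simulator
    )
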