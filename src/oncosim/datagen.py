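"""Mutation profiles, read counts, and mutated reference sequences.

From the realized per-cell genomes this module emits the standard
derivatives of a single-cell DNA-seq experiment:

* allele-specific copy-number profile (CNP) and SNV-multiplicity matrices;
* single-cell or pseudobulk read-count matrices under a negative-binomial
  model with a shared lognormal per-region bias (Poisson in the
  infinite-dispersion limit) — the expected count of cell i in region j is
  proportional to the cell's copy number there:
      lambda_ij = R_i * c_ij * bias_j / sum_k c_ik * bias_k;
* per-strand mutated reference sequences assembled from a user-supplied
  reference FASTA, with SNVs substituted as transitions;
* an interface to a third-party short-read simulator, degrading to a
  per-cell FASTA plus coverage manifest when no tool is configured.
"""

from __future__ import annotations

import shlex
import subprocess
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import ConfigurationError, Genome, GenomeLayout, copy_number_profile

__all__ = [
    "CoverageModel",
    "emit_profiles",
    "simulate_read_counts",
    "realize_sequences",
    "invoke_read_simulator",
]

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class CoverageModel:
    """Noise model for read-count generation.

    ``overdispersion`` is the negative-binomial shape (variance =
    mean + mean^2/overdispersion); ``inf`` gives Poisson counts.
    ``sigma_bias`` is the standard deviation of the shared lognormal
    per-region bias.  ``normal_fraction`` mixes diploid normal cells into
    bulk profiles.
    """

    mean_reads_per_cell: float = 500_000.0
    total_depth: float = 5_000_000.0
    sigma_bias: float = 0.2
    overdispersion: float = float("inf")
    normal_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_reads_per_cell <= 0 or self.total_depth <= 0:
            raise ConfigurationError("read depths must be positive")
        if self.sigma_bias < 0:
            raise ConfigurationError("sigma_bias must be non-negative")
        if self.overdispersion <= 0:
            raise ConfigurationError("overdispersion must be positive")
        if not 0 <= self.normal_fraction < 1:
            raise ConfigurationError("normal_fraction must lie in [0, 1)")


def emit_profiles(
    genomes: dict[str, Genome], layout: GenomeLayout
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build CNP and SNV matrices over all cells.

    Returns ``(cnp, snv, loci)``: *cnp* has one row per cell and one
    ``region_<r>`` column per region holding ``"maternal|paternal"`` count
    pairs; *snv* has one column per distinct SNV locus holding the
    mutated-copy multiplicity (0 = absent); *loci* catalogs each locus
    (region, offset).
    """
    if not genomes:
        raise ValueError("no genomes to profile")
    cells = sorted(genomes)
    region_cols = [f"region_{r}" for r in range(layout.n_regions)]
    cnp_rows = []
    loci: dict[tuple[int, int], str] = {}
    mult_by_cell: dict[str, dict[tuple[int, int], int]] = {}
    for cell in cells:
        g = genomes[cell]
        prof = copy_number_profile(g)
        cnp_rows.append(
            [f"{m}|{p}" for m, p in zip(prof.maternal, prof.paternal)]
        )
        mults: dict[tuple[int, int], int] = {}
        for snv in g.snvs:
            mults[snv.locus()] = mults.get(snv.locus(), 0) + g.snv_multiplicity(snv)
        mult_by_cell[cell] = mults
        for locus in mults:
            loci.setdefault(locus, f"snv_r{locus[0]}_{locus[1]}")
    cnp = pd.DataFrame(cnp_rows, index=cells, columns=region_cols)
    cnp.index.name = "cell"

    locus_keys = sorted(loci)
    snv = pd.DataFrame(
        [
            [mult_by_cell[cell].get(locus, 0) for locus in locus_keys]
            for cell in cells
        ],
        index=cells,
        columns=[loci[k] for k in locus_keys],
        dtype=np.int64,
    )
    snv.index.name = "cell"
    loci_df = pd.DataFrame(
        {
            "locus": [loci[k] for k in locus_keys],
            "region": [k[0] for k in locus_keys],
            "offset": [k[1] for k in locus_keys],
        }
    )
    return cnp, snv, loci_df


def total_cn_matrix(cnp: pd.DataFrame) -> np.ndarray:
    """Decode the "a|b" CNP matrix into total copy numbers (cells x regions)."""
    def tot(entry: str) -> int:
        a, b = entry.split("|")
        return int(a) + int(b)

    return cnp.map(tot).to_numpy(dtype=np.int64)


def _nb_counts(
    lam: np.ndarray, overdispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if np.isinf(overdispersion):
        return rng.poisson(lam)
    shape = overdispersion
    return rng.poisson(rng.gamma(shape, lam / shape))


def simulate_read_counts(
    cnp: pd.DataFrame,
    cm: CoverageModel,
    mode: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw a read-count matrix from the copy-number profiles.

    single_cell: one row per cell at ``mean_reads_per_cell`` expected reads;
    bulk: one pseudobulk row at ``total_depth``, mixing the mean tumor
    profile with a ``normal_fraction`` of diploid cells.
    """
    total = total_cn_matrix(cnp).astype(float)
    if np.any(total.sum(axis=1) == 0):
        raise ValueError("a cell has an all-zero copy-number profile")
    n_regions = total.shape[1]
    bias = (
        rng.lognormal(0.0, cm.sigma_bias, size=n_regions)
        if cm.sigma_bias > 0
        else np.ones(n_regions)
    )
    if mode == "single_cell":
        weighted = total * bias
        lam = cm.mean_reads_per_cell * weighted / weighted.sum(axis=1, keepdims=True)
        counts = _nb_counts(lam, cm.overdispersion, rng)
        out = pd.DataFrame(counts, index=cnp.index, columns=cnp.columns)
    elif mode == "bulk":
        mean_profile = (
            (1.0 - cm.normal_fraction) * total.mean(axis=0)
            + cm.normal_fraction * 2.0
        )
        weighted = mean_profile * bias
        lam = cm.total_depth * weighted / weighted.sum()
        counts = _nb_counts(lam[None, :], cm.overdispersion, rng)
        out = pd.DataFrame(counts, index=["bulk"], columns=cnp.columns)
    else:
        raise ConfigurationError(f"unknown read-count mode {mode!r}")
    out.index.name = "cell"
    return out


def realize_sequences(
    genome: Genome,
    reference: dict[int, str],
    layout: GenomeLayout,
    cell_id: str = "cell",
) -> list[tuple[str, str]]:
    """Assemble each strand's nucleotide sequence from the reference.

    Regions map to contiguous reference intervals from each chromosome's
    start; SNVs substitute the transition base at (region start + offset) in
    every occurrence of their region on their strand.  Returns
    ``(record_id, sequence)`` pairs, one per strand.
    """
    starts = {}
    for chrom in range(layout.n_chromosomes):
        regions = layout.regions_of_chromosome(chrom)
        need = len(regions) * layout.region_length
        if chrom not in reference or len(reference[chrom]) < need:
            raise ConfigurationError(
                f"reference chromosome {chrom} shorter than layout "
                f"({need} bases needed)"
            )
        starts[chrom] = {r: i * layout.region_length for i, r in enumerate(regions)}

    records = []
    for m, sid in enumerate(sorted(genome.strands)):
        strand = genome.strands[sid]
        ref = reference[strand.chromosome]
        region_start = starts[strand.chromosome]
        snvs_here: dict[int, list[int]] = {}
        for snv in genome.snvs:
            if snv.strand_id == sid:
                snvs_here.setdefault(snv.region, []).append(snv.offset)
        parts = []
        L = layout.region_length
        for r in strand.regions:
            s = region_start[r]
            seg = ref[s : s + L]
            for offset in snvs_here.get(r, ()):
                base = seg[offset]
                seg = seg[:offset] + TRANSITION.get(base.upper(), "A") + seg[offset + 1 :]
            parts.append(seg)
        records.append(
            (f"{cell_id}_chr{strand.chromosome}_strand{m}", "".join(parts))
        )
    return records


def invoke_read_simulator(
    sequences_by_cell: dict[str, list[tuple[str, str]]],
    coverage_per_cell: float,
    outdir: str | Path,
    tool_command: str | None = None,
) -> dict[str, list[Path]]:
    """Write per-cell FASTA and either call the configured read simulator or
    fall back to a coverage manifest.

    ``tool_command`` is a shell template with ``{fasta}``, ``{coverage}``
    and ``{prefix}`` placeholders, invoked once per cell.  Total cell
    coverage is apportioned to strands by length (uniform per-base coverage).
    Without a tool the FASTA plus a TSV manifest of (strand, length, target
    coverage) per cell is produced.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[Path]] = {}
    for cell, records in sorted(sequences_by_cell.items()):
        fasta = outdir / f"{cell}.fasta"
        with open(fasta, "w") as fh:
            for name, seq in records:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        outputs[cell] = [fasta]
        if tool_command is None:
            manifest = outdir / f"{cell}.coverage.tsv"
            with open(manifest, "w") as fh:
                fh.write("strand\tlength\ttarget_coverage\n")
                for name, seq in records:
                    # per-base coverage is uniform, so each strand's target
                    # coverage equals the cell coverage
                    fh.write(f"{name}\t{len(seq)}\t{coverage_per_cell:.6g}\n")
            outputs[cell].append(manifest)
        else:
            prefix = outdir / f"{cell}_reads"
            cmd = tool_command.format(
                fasta=shlex.quote(str(fasta)),
                coverage=coverage_per_cell,
                prefix=shlex.quote(str(prefix)),
            )
            proc = subprocess.run(
                cmd, shell=True, capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise RuntimeError(
                    f"read simulator failed for {cell} "
                    f"(exit {proc.returncode}): {proc.stderr.strip()}"
                )
            outputs[cell].extend(sorted(outdir.glob(f"{cell}_reads*")))
    return outputs
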