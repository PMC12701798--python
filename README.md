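# oncosim

Agent-based simulation of tumor evolution, metastatic cell migration, and
single-cell DNA sequencing data under genotype-driven selection.

Most tumor-sequencing simulators generate cell lineages under the neutral
coalescent or a plain birth–death process, which cannot express the clonal
selection that drives real tumor progression and metastasis. `oncosim` is
aimed at developers and benchmarkers of tumor-phylogeny, copy-number and
migration-inference methods who need ground truth generated *under
selection*: it simulates tumor cell populations forward in time as competing
clone-level agents with site-specific fitness landscapes, then resolves
exact single-cell lineages backward, and finally emits the derivatives a
DNA-seq analysis pipeline consumes — copy-number and SNV profiles, read
counts, and mutated reference sequences — together with the true cell
lineage tree, clone tree, and migration graph.

## Model

Cells carry an anatomical site `a` and a genome `G`: allele-specific
copy-number profiles over fixed-length regions (bins) on chromosome strands,
plus a set of SNVs. Five mutation mechanisms act on `G` — SNVs, segmental
gains/losses, chromosome-arm missegregation, whole-chromosome
missegregation, and whole-genome duplication (WGD) — with new strands
created by the latter three. Every new mutant passes viability checkpoints
(essential-gene loss, ploidy and copy caps, WGD budget) or dies.

Selection is a multiplicative fitness landscape per site. Each region `r`
has a coefficient δ_r (δ > 1: oncogene, δ < 1: tumor suppressor, δ = 1:
neutral), and three models map a genome to relative fitness `f`:

- **region**: `f = Π_r δ_r^(c_r − 2)` with `c_r` the total copy number;
- **chromosome-arm**: `f = Π_A δ_A^(c̄_A − 2)` with `c̄_A` the arm-mean copy
  number and `δ_A` the geometric mean of the arm's region coefficients;
- **hybrid**: the region model times one multiplier per region carrying a
  driver SNV (δ_r for an oncogene, 1/δ_r for a tumor suppressor, a penalty
  ε for essential genes).

Fitness enters a discrete-generation birth–death process through

```
p_divide = clamp( (f / f̄) · (1 + r·(1 − N/K)) / 2 , 0, 1 )
```

so a neutral population follows the logistic recursion
`N' = N(1 + r(1 − N/K))` in expectation, and fitter clones divide
proportionally more often. Each generation, every surviving cell may also
migrate from site `a` to site `b` with probability
`min(1, p_base / d(a,b))`, where the distance `d` is either a fixed
organotropism matrix ("static") or additionally shrinks with the cell's
fitness under the *target* site's landscape ("genotype").

Because all cells of a clone (the set sharing one ordered driver-mutation
sequence) behave identically, agents are clones, not cells — populations of
millions simulate in seconds. After every colonized site reaches a
detectable size, sampled cells are traced back through the clone registry
into a clone tree, multifurcations are resolved by a discrete coalescent
whose per-generation merge probability `C(j,2)/N_c(t)` follows the clone
sizes recorded each generation, and neutral passenger mutations are placed
Poisson-per-branch in a top-down pass.

## Worked example

Simulate three anatomical sites to 10,000 detectable cells each, sampling
30 cells per site:

```python
from oncosim import RunConfig, run_pipeline

cfg = RunConfig()
cfg.outdir = "demo"
cfg.seed = 17
cfg.migration.n_sites = 3
cfg.migration.p_base = 5e-3
cfg.growth.carrying_capacity = 20_000
cfg.engine.n_min_detectable = 10_000
cfg.sampling.n_per_site = 30
run_pipeline(cfg)
```

(equivalently `oncosim run --config demo.yaml --seed 17` from a shell).
This run finishes in about a second: 45 generations, 1,985 clones ever
created, 200 realized migration events. `demo/migration_graph.tsv` holds the
true migration graph —

```
source  target  n_cells n_events  clones
0       1       352     69        0,2,4,5,8,11,...
0       2       216     42        0,2,4,5,11,12,...
1       0       127     23        0,121,126,154,...
...
```

— i.e. 352 cells migrated from site 0 to site 1 across 69 clone-level
events. `demo/clone_tree.nwk` is the true clone tree with branch lengths in
generations and clone-id labels,

```
((clone_17:2,clone_127:8)clone_11:19,clone_21:22,...)clone_0:0;
```

`demo/cell_lineage.nwk` the fully binary 90-leaf single-cell lineage, and
`demo/cnp.tsv` the 90 × 100 allele-specific copy-number matrix whose entries
read `maternal|paternal` (diploid regions are `1|1`). `counts.tsv` holds the
simulated per-cell read counts, `snv.tsv` the SNV multiplicity matrix, and
`record.json` the complete generation-by-generation ground truth. Passing
`--reference genome.fa` additionally writes per-cell mutated FASTA plus a
coverage manifest (or paired FASTQ via a configured external read
simulator).

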