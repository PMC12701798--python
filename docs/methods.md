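# Methods

This note records the model as implemented, the defaults and why they were
chosen, and the places where the design was genuinely open.

## Genome representation

A genome is a multiset of chromosome strands; a strand is an ordered list of
region identifiers tagged with its parental allele of origin. Regions are
fixed-length bins (default 1 Mb) — the unit of the copy-number profile is
the region, not the base pair, which keeps profiles array-shaped and scales
to thousands of clones. Default layout: 10 chromosomes × 2 arms × 5 regions
(100 regions).

Mutation semantics:

- **Segmental gains** are tandem (the duplicated slice is inserted
  immediately after the original) and add one copy per event; multi-copy
  amplifications arise from repeated events. Segment lengths are geometric
  (mean 5 regions, configurable); breakpoints are uniform over the genome.
- **SNVs** are pinned to (strand, region, offset). Multiplicity is the
  occurrence count of the region on the carrying strand, so duplicating a
  segment co-duplicates its SNVs and deleting the last occurrence drops
  them. Phase is tracked per strand (finer than per allele; collapsible).
- **Missegregations** (arm or whole-chromosome) and **WGD** create new
  strands with fresh ids; SNVs are copied onto the new strands.
- Strand ids come from a per-genome monotonic counter, which makes any
  logged event sequence *replayable*: applying a clone's driver-event path
  to a fresh diploid founder reproduces its genome exactly, including the
  ids of event-created strands. This replay identity is the correctness
  oracle for the whole mutation layer and is what lets the saved simulation
  record omit genomes entirely.

**Viability checkpoints** (all configurable): a mutant dies immediately if
any essential-class region reaches zero total copies, genome-wide mean copy
number exceeds 8, any region exceeds 10 copies, or more than 2 WGDs have
occurred. These caps keep the fitness landscape stable and bound genome
sizes; they are package defaults, chosen to be permissive enough that
typical aneuploid karyotypes (including one or two WGDs) survive.

## Selection

Coefficients multiply and the diploid founder scores exactly 1 in all three
models, which makes fitness directly comparable across sites and
generations. δ is interpreted as a per-extra-copy multiplier with neutral
δ = 1; a stored coefficient of 0 is accepted as a "no effect" sentinel and
mapped to 1, since 0 as a multiplicative base would contradict deletions of
tumor suppressors being advantageous. In the hybrid model a region
contributes its SNV multiplier once regardless of how many driver SNVs it
holds (activation/inactivation is a binary state); passenger SNVs never
contribute.

The chromosome-arm model uses the geometric mean of an arm's region
coefficients with the arm-mean copy number as exponent. This reflects the
arm's oncogene/tumor-suppressor balance and treats sub-arm events by
averaging rather than ignoring them; it intentionally compresses the effect
of a whole-arm event relative to the region model (one arm-level coefficient
per arm, not one per region). The two models coincide exactly when arms
contain a single region.

**Random landscapes.** Gene classes (default 10% oncogene, 10% tumor
suppressor, 5% essential) are assigned uniformly and shared across sites.
Oncogene coefficients are drawn Uniform(1, 1+s_max) and tumor-suppressor
coefficients Uniform(1−s_max, 1), with s_max = 0.1. Site divergence `d`
multiplies each non-neutral coefficient per site by `1 + d·U(−1.5, 1.5)`
(clipped to keep each class on its side of neutral); the U(−1.5, 1.5) width
is chosen so the expected absolute site-to-site difference relative to the
mean coefficient equals `d`. The default d = 0.2 gives sites whose
landscapes differ by roughly 20%.

## Growth and lifecycle

The division probability `p = clamp((f/f̄)·(1 + r(1−N/K))/2, 0, 1)` is the
simplest mapping that (i) yields exact logistic growth `N' = N(1+r(1−N/K))`
in expectation for a neutral population, (ii) is stationary (p = ½) at
carrying capacity, and (iii) scales selection proportionally through f/f̄,
with f̄ recomputed exactly each generation from clone sizes. Defaults
r = 0.4 per generation and K = 10⁵ cells per site; each site's logistic
term uses its own population from first colonization.

Exponential lifespans are discretized geometrically: each generation a cell
completes its lifespan with probability τ (default 1, i.e. fixed
one-generation lifespans); non-completing cells persist unchanged. This is
the memoryless discrete analogue of an exponential lifespan and is
compatible with clone-level binomial bookkeeping.

Driver rates are per division per daughter (defaults: SNV 2×10⁻³,
segmental 10⁻³, arm missegregation 5×10⁻⁴, chromosome missegregation
5×10⁻⁴, WGD 10⁻⁴). The mechanism of a mutant daughter is drawn by
normalized rates; at these magnitudes the probability of two mutations in
one division is second-order and is ignored, so every mutant daughter
founds a singleton clone differing from its parent by exactly one driver
event. An inviable daughter counts as a dead daughter in the parent's
bookkeeping.

A run starts from one diploid founder cell at site 0 and terminates when
every site ever colonized simultaneously holds the detectable threshold
(default 50,000 cells). Total extinction — likely when the founder's
survival probability is well below 1 — restarts the run with seed + attempt
index, keeping runs reproducible.

## Migration

`p(a→b) = min(1, p_base/d_eff(a,b))` per cell per generation. The static
model uses the supplied or randomly generated (Uniform(1, d_max)) distance
matrix, constant for all cells. The genotype model multiplies the matrix
entry by `max(floor, 1/f_b(G))` with `f_b` the cell's fitness under the
target landscape — the minimal per-cell form that decreases with
target-site advantage and reduces to the static model for the founder; the
floor (default 0.1) prevents distances collapsing to zero. Clone-level
migration is binomial thinning per target processed sequentially against
the remaining count, the clone-level equivalent of each cell attempting at
most one migration per generation. Migrants keep their genome and are
re-evaluated under the destination landscape; seeding an empty site and
migrating to an occupied one are mechanically identical.

## Lineage resolution

Sampling is end-point: cells are drawn multinomially from each site's final
clone sizes. The clone tree is the ancestor closure of observed clones with
unobserved non-branching intermediates contracted into edges (their driver
events concatenated in birth order; edge lengths are birth-generation
differences).

Within a clone, lineages coalesce backwards over the *recorded* clone sizes:
at generation t with j active lineages, a pairwise merger occurs with
probability `min(1, C(j,2)/N_c(t))`, at most one merger per generation, with
forced sequential mergers whenever j exceeds N_c(t); lineages reaching the
clone's birth generation merge at its founding cell. Clone sizes are
recorded every generation (memory is bounded by occupied clone-generation
pairs; at the default scale this is tens of megabytes). A recorded zero at
a visited generation is treated as the single founding cell. A child
clone's founder lineage enters its parent's coalescent at the generation of
the first driver event on the connecting edge, which guarantees
time-consistent grafts; sampled cells enter at the final generation, so the
resolved tree is ultrametric in generations at the leaves. Clone sizes are
summed over sites, i.e. within-clone coalescence ignores which site a cell
occupies.

Passenger mutations (defaults: SNV 0.02 and segmental 0.002 per cell per
generation; no passenger missegregation or WGD, as whole-arm-and-larger
events are treated as fitness-relevant) are drawn Poisson per branch and
applied top-down. Coordinates are drawn on the branch's clone driver
genome; at leaf realization the clone's driver genome is materialized first
and the root-to-leaf passenger events are then replayed onto it. A
passenger whose carrying strand was later lost to a driver deletion is
dropped during replay — the same physical-loss semantics as for driver
SNVs. One consequence of the drivers-first replay order is that a WGD
below a passenger's branch does not double that passenger's multiplicity;
at the default rates this affects a negligible fraction of passenger
alleles.

## Data generation

Read counts follow a negative-binomial model with a lognormal per-region
bias shared across cells — the standard noise model for single-cell CNV
data — with expected counts proportional to copy number:
`λ_ij = R_i·c_ij·bias_j / Σ_k c_ik·bias_k`. Infinite dispersion (the
default) gives Poisson counts; σ_bias defaults to 0.2. Bulk mode is
pseudobulk over the sampled cells' mean profile mixed with a configurable
diploid normal fraction. Sequences are realized by concatenating each
strand's region intervals from a user reference (regions map contiguously
from each chromosome's start; unused reference tail ignored) and
substituting SNVs deterministically as transitions, so sequences are
reproducible without storing alternate alleles. Read simulation itself is
delegated to an external tool via a command template; without one the
per-cell FASTA and a per-strand coverage manifest are written.

## Determinism

One master seed; every stage (setup, forward, sampling, coalescent,
passengers, counts) draws from its own substream derived from the master
seed, so re-running or toggling a late stage never perturbs an earlier one.
Two runs with the same configuration and seed produce byte-identical trees,
matrices, and event logs.

## What the synthetic data does and does not emulate

The generator produces populations under logistic growth with multiplicative
selection, organotropism-biased migration, and CNV/SNV mutation at constant
rates. It does not model treatment effects, mutation interactions
(epistasis), microenvironment or immune interactions, intra-tumor spatial
structure, structural variants, indels, breakage–fusion–bridge cycles, or
RNA modalities. Tests passing against this generator therefore validate the
simulator's internal laws (branching survival, logistic recovery,
coalescent calibration, replay identity, count linearity), not the fidelity
of any particular real tumor cohort.

## Problem sizes used in the calibration checks

The acceptance checks use 10⁴ founder lineages over 50 generations for
branching survival; 20 replicates at K = 10⁴ for logistic recovery; 2,000
replicates at clone size 1,000 for coalescent calibration; 100 random event
sequences of length ≤ 30 for replay; 200 cells for count linearity; and a
3-site run to 50,000 detectable cells per site for migration accounting and
bit-level reproducibility. These sizes make each check's Monte-Carlo error
small relative to its tolerance while keeping the full calibration run
under a minute of compute for the statistical checks.
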