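"""Stage 2: sampling, clone-tree construction, and coalescent lineage resolution.

After the forward simulation, observed cells are sampled from each site's
final population in proportion to clone sizes.  A clone tree is obtained by
tracing the sampled clones back to the founder through the clone registry;
unobserved, non-branching intermediate clones are contracted into edges that
keep the intermediate driver events in birth order.  Multifurcations and
within-clone ancestry are then fully resolved into a binary single-cell
lineage tree by a discrete-generation coalescent run backwards over the
clone sizes recorded per generation in stage 1: with ``j`` lineages active
inside a clone of recorded size ``N(t)``, a pairwise merger happens at
generation ``t`` with probability C(j,2)/N(t) (at most one merger per
generation, with forced sequential mergers whenever j exceeds N(t)); any
lineages surviving back to the clone's birth generation merge at its
founding cell.  Finally, neutral passenger mutations are laid down in a
top-down traversal, Poisson per branch in its length in generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import SimulationRecord
from .genome import (
    ConfigurationError,
    DuplicateSnvError,
    Genome,
    GenomeConsistencyError,
    MutationEvent,
    apply_event,
    draw_random_event,
)

__all__ = [
    "SampledCell",
    "SampleAssignment",
    "CloneTreeNode",
    "CloneTree",
    "LineageNode",
    "CellLineageTree",
    "PassengerRates",
    "sample_observed_cells",
    "build_clone_tree",
    "resolve_within_clone",
    "resolve_lineage",
    "add_passenger_mutations",
    "realize_leaf_genomes",
]


@dataclass(frozen=True)
class SampledCell:
    cell_id: str
    site: int
    clone_id: int


@dataclass
class SampleAssignment:
    cells: list[SampledCell]

    def by_clone(self) -> dict[int, list[SampledCell]]:
        out: dict[int, list[SampledCell]] = {}
        for cell in self.cells:
            out.setdefault(cell.clone_id, []).append(cell)
        return out

    def counts(self) -> dict[tuple[int, int], int]:
        """(site, clone) -> number of sampled cells."""
        out: dict[tuple[int, int], int] = {}
        for cell in self.cells:
            key = (cell.site, cell.clone_id)
            out[key] = out.get(key, 0) + 1
        return out


def sample_observed_cells(
    record: SimulationRecord,
    n_per_site: dict[int, int],
    rng: np.random.Generator,
) -> SampleAssignment:
    """Draw cells from each site's final population, multinomial over clone sizes."""
    final = record.final_counts()
    cells: list[SampledCell] = []
    for site in sorted(n_per_site):
        n = n_per_site[site]
        if n == 0:
            continue
        counts = final[site]
        total = sum(counts.values())
        if n > total:
            raise ValueError(
                f"cannot sample {n} cells from site {site} holding {total}"
            )
        ids = sorted(counts)
        probs = np.array([counts[c] for c in ids], dtype=float) / total
        draw = rng.multinomial(n, probs)
        idx = 0
        for cid, k in zip(ids, draw):
            for _ in range(int(k)):
                cells.append(SampledCell(f"cell_{site}_{idx}", site, cid))
                idx += 1
    return SampleAssignment(cells=cells)


@dataclass
class CloneTreeNode:
    clone_id: int
    birth_generation: int
    parent: "CloneTreeNode | None" = None
    children: list["CloneTreeNode"] = field(default_factory=list)
    # driver events on the edge from the parent node, oldest first; the last
    # one is this clone's own founding event (empty only at the root)
    edge_events: list[MutationEvent] = field(default_factory=list)
    sampled_cells: list[SampledCell] = field(default_factory=list)

    @property
    def entry_generation(self) -> int:
        """Generation at which this node's lineage departs the parent clone."""
        return self.edge_events[0].generation if self.edge_events else self.birth_generation

    @property
    def edge_length(self) -> int:
        if self.parent is None:
            return 0
        return self.birth_generation - self.parent.birth_generation


@dataclass
class CloneTree:
    root: CloneTreeNode
    nodes: dict[int, CloneTreeNode]

    def leaf_weights(self) -> dict[tuple[int, int], int]:
        out: dict[tuple[int, int], int] = {}
        for node in self.nodes.values():
            for cell in node.sampled_cells:
                key = (cell.site, node.clone_id)
                out[key] = out.get(key, 0) + 1
        return out


def build_clone_tree(
    sample: SampleAssignment, record: SimulationRecord
) -> CloneTree:
    """Trace observed clones back to the founder and contract trivial paths.

    Kept nodes are the observed clones, the founder, and every ancestor at
    which the induced forest branches; other intermediate clones are
    contracted into edges, concatenating their founding events in birth
    order.
    """
    if not sample.cells:
        raise ValueError("cannot build a clone tree from an empty sample")
    observed = {c.clone_id for c in sample.cells}
    induced: set[int] = set()
    for cid in observed:
        cur: int | None = cid
        while cur is not None and cur not in induced:
            induced.add(cur)
            cur = record.clones[cur].parent_clone_id

    children_in: dict[int, list[int]] = {c: [] for c in induced}
    root_id = None
    for cid in induced:
        parent = record.clones[cid].parent_clone_id
        if parent is None:
            root_id = cid
        else:
            children_in[parent].append(cid)
    assert root_id is not None

    keep = {
        cid
        for cid in induced
        if cid in observed or cid == root_id or len(children_in[cid]) >= 2
    }

    by_clone = sample.by_clone()
    nodes: dict[int, CloneTreeNode] = {}

    def get_node(cid: int) -> CloneTreeNode:
        if cid in nodes:
            return nodes[cid]
        clone = record.clones[cid]
        node = CloneTreeNode(
            clone_id=cid,
            birth_generation=clone.birth_generation,
            sampled_cells=sorted(
                by_clone.get(cid, []), key=lambda c: c.cell_id
            ),
        )
        nodes[cid] = node
        if cid != root_id:
            # walk up through contracted clones to the nearest kept ancestor
            events = [clone.founding_event]
            cur = clone.parent_clone_id
            while cur not in keep:
                events.append(record.clones[cur].founding_event)
                cur = record.clones[cur].parent_clone_id
            events.reverse()
            parent_node = get_node(cur)
            node.parent = parent_node
            node.edge_events = events
            parent_node.children.append(node)
        return node

    for cid in sorted(keep):
        get_node(cid)
    for node in nodes.values():
        node.children.sort(key=lambda n: (n.birth_generation, n.clone_id))
    return CloneTree(root=nodes[root_id], nodes=nodes)


@dataclass
class LineageNode:
    name: str
    time: int  # generation
    clone_id: int
    children: list["LineageNode"] = field(default_factory=list)
    parent: "LineageNode | None" = None
    driver_events: list[MutationEvent] = field(default_factory=list)
    passenger_events: list[MutationEvent] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "LineageNode") -> None:
        child.parent = self
        self.children.append(child)


@dataclass
class CellLineageTree:
    root: LineageNode
    final_generation: int

    def leaves(self) -> list[LineageNode]:
        out: list[LineageNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def preorder(self) -> list[LineageNode]:
        out: list[LineageNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out


def resolve_within_clone(
    entering: list[tuple[LineageNode, int]],
    sizes: np.ndarray,
    birth_generation: int,
    rng: np.random.Generator,
    clone_id: int = -1,
    node_counter: list[int] | None = None,
) -> LineageNode:
    """Coalesce the entering lineages backwards over the clone's recorded sizes.

    ``entering`` pairs each lineage's subtree root with the generation at
    which it appears (walking backwards) inside this clone; ``sizes[i]`` is
    the clone's recorded cell count at generation ``birth_generation + i``.
    A recorded zero at a visited generation is treated as the single founding
    cell.  Lineages reaching the birth generation are merged there.
    Returns the root of the resolved binary subtree (time = merge time of
    the last coalescence, or the single lineage's own node).
    """
    if not entering:
        raise ValueError("no lineages entered the clone")
    if node_counter is None:
        node_counter = [0]

    def new_node(time: int) -> LineageNode:
        node_counter[0] += 1
        return LineageNode(name=f"n{node_counter[0]}", time=time, clone_id=clone_id)

    by_entry: dict[int, list[LineageNode]] = {}
    for node, t_in in entering:
        if t_in < birth_generation:
            raise ValueError("lineage enters before the clone was born")
        by_entry.setdefault(t_in, []).append(node)

    sizes = np.asarray(sizes, dtype=np.int64)

    def size_at(t: int) -> int:
        idx = t - birth_generation
        n = int(sizes[idx]) if idx < len(sizes) else int(sizes[-1])
        return max(n, 1)  # the founding cell always exists

    active: list[LineageNode] = []

    def merge_pair(time: int) -> None:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        parent = new_node(time)
        parent.add_child(active[i])
        parent.add_child(active[j])
        active[i] = parent
        del active[j]

    t = max(by_entry)
    while t > birth_generation:
        active.extend(by_entry.pop(t, ()))
        t_next = max(
            (x for x in by_entry if x > birth_generation), default=birth_generation
        )
        # scan generations t .. t_next+1 for the next merger; per generation the
        # merge probability is min(1, C(j,2)/N(t)), which realizes the forced
        # merger when j exceeds N(t)
        while t > t_next:
            j = len(active)
            if j < 2:
                t = t_next
                break
            gens = np.arange(t, t_next, -1)
            n_t = np.maximum(
                sizes[np.minimum(gens - birth_generation, len(sizes) - 1)], 1
            )
            p = np.minimum(1.0, (j * (j - 1) / 2.0) / n_t)
            hits = np.nonzero(rng.random(len(gens)) < p)[0]
            if hits.size == 0:
                t = t_next
                break
            t_merge = int(gens[hits[0]])
            merge_pair(t_merge)
            # forced sequential mergers within the same generation
            while len(active) > size_at(t_merge):
                merge_pair(t_merge)
            t = t_merge - 1
    active.extend(by_entry.pop(birth_generation, ()))
    while len(active) > 1:
        merge_pair(birth_generation)
    return active[0]


def resolve_lineage(
    clone_tree: CloneTree,
    record: SimulationRecord,
    rng: np.random.Generator,
) -> CellLineageTree:
    """Resolve the clone tree into a binary single-cell lineage tree.

    Sampled cells enter their clone's coalescent at the final generation;
    a child clone's founder lineage enters at the generation of the first
    driver event on its clone-tree edge.  Driver events are annotated on the
    edge entering each child subtree's root.
    """
    final_gen = record.generations_elapsed
    node_counter = [0]

    def resolve(ct_node: CloneTreeNode) -> LineageNode:
        entering: list[tuple[LineageNode, int]] = []
        for cell in ct_node.sampled_cells:
            leaf = LineageNode(
                name=cell.cell_id, time=final_gen, clone_id=ct_node.clone_id
            )
            entering.append((leaf, final_gen))
        for child in ct_node.children:
            sub_root = resolve(child)
            sub_root.driver_events = list(child.edge_events)
            entering.append((sub_root, child.entry_generation))
        sizes = record.clone_size_series(
            ct_node.clone_id, ct_node.birth_generation, final_gen
        )
        return resolve_within_clone(
            entering,
            sizes,
            ct_node.birth_generation,
            rng,
            clone_id=ct_node.clone_id,
            node_counter=node_counter,
        )

    root = resolve(clone_tree.root)
    for node in _preorder(root):
        for child in node.children:
            if child.time < node.time:
                raise RuntimeError("time inconsistency in assembled lineage tree")
    return CellLineageTree(root=root, final_generation=final_gen)


def _preorder(root: LineageNode) -> list[LineageNode]:
    out, stack = [], [root]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(reversed(node.children))
    return out


@dataclass(frozen=True)
class PassengerRates:
    """Per-cell per-generation rates of neutral (non-selected) mutations.

    Passengers default to SNVs and segmental CNAs only; whole-arm,
    whole-chromosome and WGD-scale events are treated as drivers.
    """

    snv: float = 0.02
    segmental: float = 0.002
    segment_mean_length: float = 5.0

    @property
    def total(self) -> float:
        return self.snv + self.segmental


def add_passenger_mutations(
    tree: CellLineageTree,
    rates: PassengerRates,
    record: SimulationRecord,
    rng: np.random.Generator,
) -> CellLineageTree:
    """Draw Poisson passenger events per branch in a top-down traversal.

    Event coordinates are drawn on the driver genome of the branch's clone;
    passenger events never feed back into fitness or the stage-1 record.
    """
    if rates.total == 0:
        return tree
    mech_p = np.array([rates.snv, rates.segmental]) / rates.total
    for node in tree.preorder():
        if node.parent is None:
            continue
        length = node.time - node.parent.time
        if length <= 0:
            continue
        n_events = rng.poisson(rates.total * length)
        if n_events == 0:
            continue
        clone_genome = record.clones[node.clone_id].genome
        events = []
        for _ in range(n_events):
            mech = ("snv", "segmental")[rng.choice(2, p=mech_p)]
            ev = draw_random_event(
                clone_genome,
                mech,
                rng,
                generation=node.parent.time,
                seg_mean_length=rates.segment_mean_length,
                origin="passenger",
            )
            if ev is not None:
                events.append(ev)
        node.passenger_events = events
    return tree


def _apply_passenger(genome: Genome, ev: MutationEvent) -> None:
    """Tolerantly replay a passenger event drawn on an ancestral genome.

    A passenger whose carrying strand (or region occurrence) was later lost
    to a driver deletion is itself lost, so such events are skipped; slice
    coordinates are clamped to the current strand extent.
    """
    if ev.kind == "snv":
        strand = genome.strands.get(ev.strand_id)
        if strand is None or ev.region not in strand.regions:
            return
        try:
            apply_event(genome, ev)
        except DuplicateSnvError:
            return
    elif ev.kind in ("segmental_gain", "segmental_loss"):
        strand = genome.strands.get(ev.strand_id)
        if strand is None or ev.start >= len(strand.regions):
            return
        apply_event(genome, ev)
    else:
        raise GenomeConsistencyError(
            f"unsupported passenger mechanism {ev.kind!r}"
        )


def realize_leaf_genomes(
    tree: CellLineageTree, record: SimulationRecord
) -> dict[str, Genome]:
    """Materialize each sampled cell's genome.

    The leaf genome is its clone's driver genome plus the passenger events
    accumulated on the root-to-leaf path, applied in order.
    """
    genomes: dict[str, Genome] = {}

    def walk(node: LineageNode, passengers: list[MutationEvent]) -> None:
        passengers = passengers + node.passenger_events
        if node.is_leaf:
            g = record.clones[node.clone_id].genome.copy()
            for ev in passengers:
                _apply_passenger(g, ev)
            genomes[node.name] = g
        else:
            for child in node.children:
                walk(child, passengers)

    walk(tree.root, [])
    return genomes
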