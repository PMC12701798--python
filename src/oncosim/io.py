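"""Writers for trees, matrices, event logs and the migration graph."""

from __future__ import annotations

from pathlib import Path

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .engine import SimulationRecord
from .genome import MutationEvent
from .lineage import CellLineageTree, CloneTree
from .migration import MigrationEvent
from .selection import SelectionLandscape

__all__ = [
    "clone_tree_to_newick",
    "lineage_tree_to_newick",
    "write_events_tsv",
    "write_edge_annotations_tsv",
    "migration_graph",
    "write_migration_graph",
    "write_landscapes_tsv",
    "write_distance_matrix",
]

_EVENT_COLS = [
    "kind", "generation", "strand_id", "arm", "start", "length",
    "region", "offset", "origin",
]


def clone_tree_to_newick(tree: CloneTree) -> str:
    """Clone tree with branch lengths in generations and clone-id labels."""
    dtree = dendropy.Tree()

    def build(node, dnode):
        dnode.label = f"clone_{node.clone_id}"
        dnode.edge.length = node.edge_length
        for child in node.children:
            build(child, dnode.new_child())

    build(tree.root, dtree.seed_node)
    return (
        dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_leaf_node_labels=False,
            unquoted_underscores=True,
        ).strip()
        + "\n"
    )


def lineage_tree_to_newick(tree: CellLineageTree) -> str:
    """Binary cell lineage tree; leaf labels are cell ids, lengths generations."""
    dtree = dendropy.Tree()

    def build(node, dnode):
        dnode.label = node.name
        if node.parent is not None:
            dnode.edge.length = node.time - node.parent.time
        for child in node.children:
            build(child, dnode.new_child())

    build(tree.root, dtree.seed_node)
    return (
        dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_leaf_node_labels=False,
            unquoted_underscores=True,
        ).strip()
        + "\n"
    )


def _event_row(ev: MutationEvent) -> dict:
    return {c: getattr(ev, c) for c in _EVENT_COLS}


def write_events_tsv(record: SimulationRecord, path: str | Path) -> None:
    """One row per clone-founding driver event."""
    rows = []
    for cid in sorted(record.clones):
        clone = record.clones[cid]
        if clone.founding_event is None:
            continue
        row = {"clone_id": cid, **_event_row(clone.founding_event)}
        rows.append(row)
    pd.DataFrame(rows, columns=["clone_id"] + _EVENT_COLS, dtype=object).to_csv(
        path, sep="\t", index=False
    )


def write_edge_annotations_tsv(tree: CellLineageTree, path: str | Path) -> None:
    """Driver and passenger events per lineage-tree edge, keyed by child node."""
    rows = []
    for node in tree.preorder():
        for origin, events in (
            ("driver", node.driver_events),
            ("passenger", node.passenger_events),
        ):
            for ev in events:
                rows.append({"node": node.name, "class": origin, **_event_row(ev)})
    pd.DataFrame(rows, columns=["node", "class"] + _EVENT_COLS, dtype=object).to_csv(
        path, sep="\t", index=False
    )


def migration_graph(events: list[MigrationEvent], n_sites: int) -> nx.DiGraph:
    """Directed site graph; edge attrs: n_cells, n_events, clone ids."""
    g = nx.DiGraph()
    g.add_nodes_from(range(n_sites))
    for ev in events:
        if g.has_edge(ev.source, ev.target):
            data = g.edges[ev.source, ev.target]
            data["n_cells"] += ev.n_cells
            data["n_events"] += 1
            data["clones"].add(ev.clone_id)
        else:
            g.add_edge(
                ev.source, ev.target,
                n_cells=ev.n_cells, n_events=1, clones={ev.clone_id},
            )
    return g


def write_migration_graph(
    events: list[MigrationEvent], n_sites: int, path: str | Path
) -> None:
    g = migration_graph(events, n_sites)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tn_cells\tn_events\tclones\n")
        for a, b in sorted(g.edges):
            data = g.edges[a, b]
            clones = ",".join(str(c) for c in sorted(data["clones"]))
            fh.write(f"{a}\t{b}\t{data['n_cells']}\t{data['n_events']}\t{clones}\n")


def write_migration_events_tsv(
    events: list[MigrationEvent], path: str | Path
) -> None:
    pd.DataFrame(
        [vars(ev) for ev in events],
        columns=["generation", "clone_id", "source", "target", "n_cells"],
    ).to_csv(path, sep="\t", index=False)


def write_landscapes_tsv(
    landscapes: list[SelectionLandscape], path: str | Path
) -> None:
    layout = landscapes[0].layout
    classes = ["neutral", "OG", "TSG", "essential"]
    df = pd.DataFrame(
        {
            "region": range(layout.n_regions),
            "gene_class": [classes[c] for c in layout.gene_class],
            **{
                f"delta_site{ls.site}": ls.region_delta for ls in landscapes
            },
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_distance_matrix(d: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(d).to_csv(path, sep="\t", header=True, index=True,
                           float_format="%.8g")
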