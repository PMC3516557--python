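"""First-degree binding-partner expansion over a binary interaction network.

Interactions (yeast-2-hybrid style, BIND-reported) are undirected regardless
of file order: physical binding is symmetric.  Node categories follow the
precedence pain > lethal > binding_partner — a screen hit stays a pain node
even if it is also a neighbor of another hit or carries a lethal phenotype.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import IntegrityError
from .io import INTERACTION_COLUMNS, read_tsv, write_tsv

logger = logging.getLogger(__name__)

__all__ = [
    "PAIN",
    "BINDING_PARTNER",
    "LETHAL",
    "FUNCTIONAL_CLASS",
    "CATEGORY_COLORS",
    "load_interactions",
    "first_degree_partners",
    "categorize_nodes",
    "write_node_table",
]

PAIN = "pain"
BINDING_PARTNER = "binding_partner"
LETHAL = "lethal"
FUNCTIONAL_CLASS = "functional_class"

# Fig-1 style display colors, exported as node attributes
CATEGORY_COLORS = {
    PAIN: "red",
    BINDING_PARTNER: "green",
    LETHAL: "blue",
    FUNCTIONAL_CLASS: "gold",
}


def load_interactions(path: str | Path) -> nx.Graph:
    """Load a binary interaction TSV as an undirected simple graph.

    Self-loops are dropped with a warning; duplicate edges (including
    reversed duplicates) collapse to one undirected edge.
    """
    frame = read_tsv(path, INTERACTION_COLUMNS)
    graph = nx.Graph()
    n_loops = 0
    for a, b in zip(frame["source_id"], frame["target_id"]):
        if a == b:
            n_loops += 1
            continue
        graph.add_edge(a, b)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    return graph


def first_degree_partners(hits: Iterable[str], network: nx.Graph) -> list[str]:
    """All neighbors of hit nodes that are not themselves hits, sorted."""
    hit_set = set(hits)
    partners: set[str] = set()
    for hit in hit_set:
        if hit in network:
            partners.update(network.neighbors(hit))
    return sorted(partners - hit_set)


def categorize_nodes(
    hits: Iterable[str],
    partners: Iterable[str],
    lethals: Iterable[str],
    nodes: Iterable[str] | None = None,
) -> dict[str, str]:
    """Assign each node exactly one category with precedence pain > lethal > binding_partner.

    *nodes* defaults to hits ∪ partners (the first-degree interaction map).
    A node outside all three lists cannot be categorized and raises
    IntegrityError; a hit that also appears in the lethal list is categorized
    pain with an integrity warning.
    """
    hit_set, partner_set, lethal_set = set(hits), set(partners), set(lethals)
    node_set = set(nodes) if nodes is not None else hit_set | partner_set
    overlap = hit_set & lethal_set & node_set
    if overlap:
        logger.warning(
            "%d gene(s) appear in both hit and lethal lists; categorized pain (precedence)",
            len(overlap),
        )
    categories: dict[str, str] = {}
    for node in sorted(node_set):
        if node in hit_set:
            categories[node] = PAIN
        elif node in lethal_set:
            categories[node] = LETHAL
        elif node in partner_set:
            categories[node] = BINDING_PARTNER
        else:
            raise IntegrityError(f"node {node!r} is not a hit, partner or lethal; cannot categorize")
    counts = {cat: sum(1 for c in categories.values() if c == cat) for cat in (PAIN, LETHAL, BINDING_PARTNER)}
    logger.info("categorized %d nodes: %s", len(categories), counts)
    return categories


def write_node_table(
    categories: dict[str, str],
    path: str | Path,
    species: str = "fly",
    header: Sequence[str] | None = None,
) -> None:
    """Write the categorized node table (gene_id, species, category)."""
    rows = [
        {"gene_id": gene, "species": species, "category": cat}
        for gene, cat in sorted(categories.items())
    ]
    write_tsv(pd.DataFrame(rows, columns=["gene_id", "species", "category"]), path, header=header)
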