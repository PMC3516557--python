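"""Assembly of the bipartite functional-class ↔ gene systems map.

Significant pathways / gene sets from all species and collections are pooled
into manually assigned functional classes; each class node connects to the
de-duplicated union of the query genes its member sets captured.  Genes are
unified across species by their fly anchor where one exists (a mouse or human
ortholog collapses onto its fly source gene), so one gene is one node no
matter how many species' analyses recovered it.

Two structural diagnostics are provided: the per-class fraction of members
that are direct screen hits (the ">50% representation" check) and the
connected-component comparison before/after removing all binding-partner
nodes (the "connectivity intact" check).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentResult
from .errors import IntegrityError
from .expansion import BINDING_PARTNER, CATEGORY_COLORS, FUNCTIONAL_CLASS, PAIN
from .io import write_tsv
from .orthology import GeneRef, OrthologTable

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_PREFIX",
    "fly_anchor_unifier",
    "pool_into_classes",
    "build_map",
    "class_hit_representation",
    "connectivity_without_partners",
    "write_graphml",
    "write_sif",
    "write_membership_table",
]

CLASS_PREFIX = "class::"


def fly_anchor_unifier(
    table: OrthologTable,
    anchor_species: str = "fly",
    prefer: set[str] | None = None,
) -> Callable[[str, str], str]:
    """Return a gene unifier that collapses orthologs onto their fly anchor.

    A mammalian gene maps to the lexicographically smallest fly gene that has
    it as an ortholog target; under many-to-many topology, anchors in
    *prefer* (typically the screen's hit/partner/lethal genes) win over other
    anchors, so a gene recovered through a hit's ortholog is keyed by the hit
    rather than an incidental co-ortholog.  Genes without a fly anchor keep a
    species-qualified ID.
    """
    reverse = table.reverse_index()
    prefer = prefer or set()

    def unify(species: str, gene_id: str) -> str:
        if species == anchor_species:
            return gene_id
        anchors = [s.id for s in reverse.get(GeneRef(species, gene_id), [])
                   if s.species == anchor_species]
        if anchors:
            preferred = [a for a in anchors if a in prefer]
            return min(preferred) if preferred else min(anchors)
        return f"{species}:{gene_id}"

    return unify


def pool_into_classes(
    runs: Sequence[tuple[str, Sequence[EnrichmentResult]]],
    class_map: Mapping[str, str],
    unify: Callable[[str, str], str] | None = None,
) -> tuple[dict[str, set[str]], dict[str, list[tuple[str, str]]], list[str]]:
    """Pool significant results across species/collections into functional classes.

    *runs* is a list of ``(species, results)`` pairs.  Returns
    ``(membership, provenance, unassigned)``: per-class member-gene unions
    (unified IDs), per-class contributing ``(species, set_name)`` pairs, and
    the significant set names missing from *class_map* (excluded from the map).
    Output is independent of the order of *runs*.
    """
    if unify is None:
        unify = lambda species, gene_id: gene_id  # noqa: E731 - identity default
    membership: dict[str, set[str]] = {}
    provenance: dict[str, list[tuple[str, str]]] = {}
    unassigned: set[str] = set()
    for species, results in runs:
        for res in results:
            if not res.significant:
                continue
            label = class_map.get(res.set_name)
            if label is None:
                unassigned.add(res.set_name)
                continue
            membership.setdefault(label, set()).update(
                unify(species, g) for g in res.member_hits
            )
            provenance.setdefault(label, []).append((species, res.set_name))
    for label in provenance:
        provenance[label] = sorted(set(provenance[label]))
    if unassigned:
        logger.warning("%d significant set(s) absent from class map; excluded", len(unassigned))
    if not membership:
        logger.warning("no significant sets to pool; systems map will be empty")
    return membership, provenance, sorted(unassigned)


def build_map(
    membership: Mapping[str, set[str]],
    categories: Mapping[str, str],
    provenance: Mapping[str, Sequence[tuple[str, str]]] | None = None,
) -> nx.Graph:
    """Build the bipartite class↔gene graph with category/color attributes.

    Every member gene must have a category (pain / binding_partner / lethal);
    a missing category is an integrity error.  Classes with no members are
    never created, and gene nodes only arise through membership, so every
    node has degree >= 1 by construction.
    """
    graph = nx.Graph()
    for label in sorted(membership):
        genes = membership[label]
        if not genes:
            continue
        class_node = CLASS_PREFIX + label
        sets = (provenance or {}).get(label, [])
        graph.add_node(
            class_node,
            category=FUNCTIONAL_CLASS,
            color=CATEGORY_COLORS[FUNCTIONAL_CLASS],
            label=label,
            bipartite=0,
            provenance=";".join(f"{sp}:{name}" for sp, name in sets),
        )
        for gene in sorted(genes):
            category = categories.get(gene)
            if category is None:
                raise IntegrityError(f"gene {gene!r} in class {label!r} has no category")
            graph.add_node(gene, category=category, color=CATEGORY_COLORS[category], bipartite=1)
            graph.add_edge(class_node, gene)
    n_classes = sum(1 for _, d in graph.nodes(data=True) if d["category"] == FUNCTIONAL_CLASS)
    logger.info(
        "systems map: %d classes, %d genes, %d edges",
        n_classes, graph.number_of_nodes() - n_classes, graph.number_of_edges(),
    )
    return graph


def _class_nodes(graph: nx.Graph) -> list[str]:
    return [node for node, d in graph.nodes(data=True) if d["category"] == FUNCTIONAL_CLASS]


def class_hit_representation(graph: nx.Graph) -> tuple[dict[str, float], int]:
    """Per-class fraction of member genes that are direct pain hits.

    Returns ``(fractions, n_at_or_below_half)`` where the count uses the
    boundary convention that exactly 50% does NOT qualify as majority-hit.
    """
    fractions: dict[str, float] = {}
    for class_node in _class_nodes(graph):
        members = list(graph.neighbors(class_node))
        n_pain = sum(1 for g in members if graph.nodes[g]["category"] == PAIN)
        fractions[graph.nodes[class_node].get("label", class_node)] = (
            n_pain / len(members) if members else 0.0
        )
    n_at_or_below_half = sum(1 for frac in fractions.values() if frac <= 0.5)
    return fractions, n_at_or_below_half


def connectivity_without_partners(graph: nx.Graph) -> tuple[int, int, bool]:
    """Connected components before/after removing all binding-partner nodes.

    Returns ``(components_full, components_pruned, intact)`` with
    ``intact ⇔ components_pruned <= components_full and no class node is
    isolated after removal``.
    """
    components_full = nx.number_connected_components(graph)
    pruned = graph.subgraph(
        [node for node, d in graph.nodes(data=True) if d["category"] != BINDING_PARTNER]
    )
    components_pruned = nx.number_connected_components(pruned)
    isolated_classes = [c for c in _class_nodes(graph) if c in pruned and pruned.degree(c) == 0]
    intact = components_pruned <= components_full and not isolated_classes
    return components_full, components_pruned, intact


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path), named_key_ids=True)


def write_sif(graph: nx.Graph, path: str | Path, header: Sequence[str] | None = None) -> None:
    """SIF export: ``class  member  gene`` per edge, class side first."""
    lines = []
    for a, b in sorted(graph.edges()):
        if graph.nodes[b]["category"] == FUNCTIONAL_CLASS:
            a, b = b, a
        lines.append(f"{a}\tmember\t{b}")
    text = "".join(f"# {line}\n" for line in (header or [])) + "".join(f"{l}\n" for l in lines)
    Path(path).write_text(text, encoding="utf-8", newline="\n")


def write_membership_table(
    membership: Mapping[str, set[str]],
    categories: Mapping[str, str],
    path: str | Path,
    header: Sequence[str] | None = None,
) -> None:
    """Class-membership TSV (class_label, gene_id, category), one row per pair."""
    rows = [
        {"class_label": label, "gene_id": gene, "category": categories[gene]}
        for label in sorted(membership)
        for gene in sorted(membership[label])
    ]
    write_tsv(pd.DataFrame(rows, columns=["class_label", "gene_id", "category"]), path, header=header)
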