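"""Multi-source ortholog tables and cross-species projection of gene lists.

Orthology predictions come as provenance-tagged tables (one per prediction
method, e.g. Compara / Homologene / Inparanoid / OrthoMCL).  Tables are merged
by set-union of mappings, each mapping keeping the set of methods that
predicted it.  Projection (`map_genes`) follows every mapping edge, so
one-to-one, one-to-many and many-to-many topologies are all honored; counts
downstream are always over de-duplicated target genes, never mapping edges.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import FormatError, IntegrityError, ParameterError
from .io import ORTHOLOG_COLUMNS, read_tsv, write_tsv

logger = logging.getLogger(__name__)

__all__ = ["GeneRef", "OrthologTable", "load_ortholog_table", "merge_tables", "map_genes"]


class GeneRef(NamedTuple):
    """A namespaced gene identifier: ``(species, id)`` is the unique key."""

    species: str
    id: str


# internal storage: {(source GeneRef, target GeneRef): frozenset of method labels}
_MappingDict = dict[tuple[GeneRef, GeneRef], frozenset[str]]


class OrthologTable:
    """Cross-species ortholog mappings with per-mapping method provenance."""

    def __init__(self, mappings: Mapping[tuple[GeneRef, GeneRef], Iterable[str]] | None = None):
        self._mappings: _MappingDict = {}
        if mappings:
            for (src, tgt), methods in mappings.items():
                self.add(src, tgt, methods)
        self._check_species_integrity()

    def add(self, source: GeneRef, target: GeneRef, methods: Iterable[str]) -> None:
        if not source.id or not target.id:
            raise ParameterError("gene IDs must be non-empty")
        key = (GeneRef(*source), GeneRef(*target))
        self._mappings[key] = self._mappings.get(key, frozenset()) | frozenset(methods)

    def _check_species_integrity(self) -> None:
        species_of: dict[str, str] = {}
        for src, tgt in self._mappings:
            for ref in (src, tgt):
                prior = species_of.setdefault(ref.id, ref.species)
                if prior != ref.species:
                    raise IntegrityError(
                        f"gene ID {ref.id!r} appears under two species labels "
                        f"({prior!r} and {ref.species!r})"
                    )

    # -- introspection -------------------------------------------------------
    def __len__(self) -> int:
        """Number of distinct (source, target) mappings."""
        return len(self._mappings)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, OrthologTable) and self._mappings == other._mappings

    @property
    def mappings(self) -> _MappingDict:
        return dict(self._mappings)

    def species(self) -> set[str]:
        out = set()
        for src, tgt in self._mappings:
            out.add(src.species)
            out.add(tgt.species)
        return out

    def forward_index(self) -> dict[GeneRef, list[GeneRef]]:
        """source gene -> sorted list of its targets (all species)."""
        index: dict[GeneRef, list[GeneRef]] = {}
        for src, tgt in self._mappings:
            index.setdefault(src, []).append(tgt)
        return {src: sorted(tgts) for src, tgts in index.items()}

    def reverse_index(self) -> dict[GeneRef, list[GeneRef]]:
        """target gene -> sorted list of sources mapping onto it."""
        index: dict[GeneRef, list[GeneRef]] = {}
        for src, tgt in self._mappings:
            index.setdefault(tgt, []).append(src)
        return {tgt: sorted(srcs) for tgt, srcs in index.items()}

    # -- serialization -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """One row per (source, target, method) triple, deterministically sorted."""
        rows = [
            {
                "source_species": src.species,
                "source_id": src.id,
                "target_species": tgt.species,
                "target_id": tgt.id,
                "method": method,
            }
            for (src, tgt), methods in self._mappings.items()
            for method in sorted(methods)
        ]
        frame = pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)
        return frame.sort_values(ORTHOLOG_COLUMNS, ignore_index=True)

    def write(self, path: str | Path, header: Sequence[str] | None = None) -> None:
        write_tsv(self.to_frame(), path, header=header)


def load_ortholog_table(path: str | Path, method_label: str | None = None) -> OrthologTable:
    """Load one ortholog TSV; ``method_label`` overrides the file's method column.

    Rows with empty IDs are malformed and reported with their line number;
    duplicate (source, target, method) triples are dropped with a warning.
    """
    frame = read_tsv(path, ORTHOLOG_COLUMNS if method_label is None else ORTHOLOG_COLUMNS[:4])
    table = OrthologTable()
    seen: set[tuple[GeneRef, GeneRef, str]] = set()
    n_dupes = n_bad = 0
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        if not row.source_id or not row.target_id or not row.source_species or not row.target_species:
            logger.warning("%s: line %d malformed (empty field); skipped", path, lineno)
            n_bad += 1
            continue
        method = method_label if method_label is not None else row.method
        src = GeneRef(row.source_species, row.source_id)
        tgt = GeneRef(row.target_species, row.target_id)
        if (src, tgt, method) in seen:
            n_dupes += 1
            continue
        seen.add((src, tgt, method))
        table.add(src, tgt, [method])
    if n_dupes:
        logger.warning("%s: %d duplicate (source, target, method) row(s) dropped", path, n_dupes)
    if n_bad:
        logger.warning("%s: %d malformed row(s) skipped", path, n_bad)
    table._check_species_integrity()
    return table


def merge_tables(tables: Sequence[OrthologTable]) -> OrthologTable:
    """Set-union of mappings; provenance is the union of contributing methods."""
    if not tables:
        raise ParameterError("merge_tables requires at least one table")
    merged = OrthologTable()
    for table in tables:
        for (src, tgt), methods in table.mappings.items():
            merged.add(src, tgt, methods)
    merged._check_species_integrity()
    return merged


def map_genes(
    genes: Sequence[GeneRef],
    table: OrthologTable,
    target_species: str,
    min_sources: int = 1,
) -> tuple[list[GeneRef], pd.DataFrame]:
    """Project *genes* into *target_species* via *table*.

    Returns the lexicographically sorted, de-duplicated union of targets plus a
    per-query report (query_id, n_targets, target_ids semicolon-joined).  A
    mapping counts only if predicted by at least *min_sources* methods.
    """
    genes = [GeneRef(*g) for g in genes]
    if len({g.species for g in genes}) > 1:
        raise ParameterError("all query genes must share one species")
    if min_sources < 1:
        raise ParameterError("min_sources must be >= 1")
    if genes and target_species not in table.species():
        logger.warning("target species %r absent from ortholog table; empty result", target_species)

    forward = table.forward_index()
    mappings = table.mappings
    result: set[GeneRef] = set()
    report_rows = []
    for gene in genes:
        targets = sorted(
            t
            for t in forward.get(gene, [])
            if t.species == target_species and len(mappings[(gene, t)]) >= min_sources
        )
        result.update(targets)
        report_rows.append(
            {
                "query_id": gene.id,
                "n_targets": len(targets),
                "target_ids": ";".join(t.id for t in targets),
            }
        )
    report = pd.DataFrame(report_rows, columns=["query_id", "n_targets", "target_ids"])
    return sorted(result), report
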