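"""Synthetic inputs with controlled statistical structure for the pipeline.

Generates three linked gene universes (fly / mouse / human) with mixed
orthology topologies, a screen hit list and a developmental-lethal list, a
sparse binary interaction network, gene-set collections with planted
over-represented sets, and annotation lists with planted over-representation
among a chosen gene set.  Every generator is seed-reproducible: identical
seeds give byte-identical output files.

Generative model
----------------
* Universe: fly genes are partitioned into one-to-one, many-to-many,
  one-to-many and unmapped classes per the requested fractions.  Each mapped
  fly gene maps with the same topology into mouse and into human.  Every
  mapping edge is attributed to >=1 of four simulated prediction sources,
  so the union of the per-source tables realizes the full topology.
* Interactions: Erdős–Rényi over the fly universe with edge probability
  ``mean_degree / (n - 1)`` — the simplest null adequate for first-degree
  expansion logic.
* Planted gene sets: a set of size K planted at enrichment factor f over a
  universe of N genes containing H hits draws its number of hit members as
  ``Binomial(K, min(1, f·H/N))`` and then samples uniformly without
  replacement within the hit and non-hit strata, so the expected hit overlap
  is exactly ``K·f·H/N`` (below saturation).  Non-planted sets sample
  uniformly without replacement from the whole universe.
* Annotations: each gene carries an annotation independently per source —
  with probability ``annotation_hit_rate`` for designated map genes and
  ``annotation_base_rate`` otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .orthology import GeneRef, OrthologTable, merge_tables

__all__ = [
    "UniverseSpec",
    "PlantedEffects",
    "Universe",
    "METHOD_LABELS",
    "generate_universe",
    "generate_screen",
    "generate_interactions",
    "generate_genesets",
    "generate_annotations",
    "assign_classes",
]

SPECIES = ("fly", "mouse", "human")
METHOD_LABELS = ("compara", "homologene", "inparanoid", "orthomcl")
_ID_PREFIX = {"fly": "CG", "mouse": "Mm", "human": "Hs"}


@dataclass(frozen=True)
class UniverseSpec:
    """Sizes and orthology-topology fractions for the three gene universes.

    The three fractions must sum to <= 1; the remainder of fly genes is
    one-to-many (one fly gene, two mammalian targets).
    """

    n_fly: int = 14000
    n_mouse: int = 15000
    n_human: int = 15000
    frac_one_to_one: float = 0.6
    frac_many_to_many: float = 0.1
    frac_unmapped: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("n_fly", "n_mouse", "n_human"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        fracs = (self.frac_one_to_one, self.frac_many_to_many, self.frac_unmapped)
        if any(f < 0 or f > 1 for f in fracs):
            raise ParameterError("topology fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-9:
            raise ParameterError("topology fractions must sum to <= 1")

    @property
    def n_genes(self) -> dict[str, int]:
        return {"fly": self.n_fly, "mouse": self.n_mouse, "human": self.n_human}


@dataclass(frozen=True)
class PlantedEffects:
    """Planted-signal parameters for gene-set and annotation generators."""

    n_sets: int = 200
    set_size_range: tuple[int, int] = (30, 80)
    n_planted: int = 10
    enrichment_factor: float = 5.0
    annotation_base_rate: float = 0.015
    annotation_hit_rate: float = 0.22

    def __post_init__(self):
        if self.n_sets < 0 or self.n_planted < 0 or self.n_planted > self.n_sets:
            raise ParameterError("need 0 <= n_planted <= n_sets")
        lo, hi = self.set_size_range
        if lo < 1 or hi < lo:
            raise ParameterError("set_size_range must be a positive interval")
        if self.enrichment_factor < 1:
            raise ParameterError("enrichment_factor must be >= 1")
        for name in ("annotation_base_rate", "annotation_hit_rate"):
            rate = getattr(self, name)
            if rate < 0 or rate > 1:
                raise ParameterError(f"{name} must lie in [0, 1]")


@dataclass
class Universe:
    """Generated gene lists plus one ortholog table per prediction source."""

    spec: UniverseSpec
    genes: dict[str, list[str]]
    tables: dict[str, OrthologTable] = field(default_factory=dict)

    def merged_table(self) -> OrthologTable:
        return merge_tables(list(self.tables.values())) if self.tables else OrthologTable()


def _gene_ids(species: str, n: int) -> list[str]:
    return [f"{_ID_PREFIX[species]}{10000 + i}" for i in range(n)]


def generate_universe(spec: UniverseSpec) -> Universe:
    """Generate the three gene universes and per-source ortholog tables."""
    rng = np.random.default_rng(spec.seed)
    genes = {sp: _gene_ids(sp, spec.n_genes[sp]) for sp in SPECIES}

    n = spec.n_fly
    n_mm = 2 * int(round(n * spec.frac_many_to_many / 2))
    n_11 = int(round(n * spec.frac_one_to_one))
    n_un = int(round(n * spec.frac_unmapped))
    n_1m = n - n_11 - n_mm - n_un
    if n_1m < 0:  # rounding overshoot; shrink the largest class
        n_11 += n_1m
        n_1m = 0
    if min(n_11, n_un) < 0:
        raise ParameterError("topology fractions leave a negative class size")

    order = rng.permutation(n)
    fly_11 = order[:n_11]
    fly_mm = order[n_11 : n_11 + n_mm]
    fly_1m = order[n_11 + n_mm : n_11 + n_mm + n_1m]

    # per target species: 1 target per one-to-one gene, 2 per one-to-many gene,
    # and 1 target per many-to-many gene (pairs of fly genes share 2 targets)
    required = n_11 + 2 * n_1m + n_mm
    edges: list[tuple[str, str, str]] = []  # (fly_id, target_species, target_id)
    for sp in ("mouse", "human"):
        if required > spec.n_genes[sp]:
            raise ParameterError(
                f"{sp} universe too small: need {required} ortholog targets, have {spec.n_genes[sp]}"
            )
        pool = rng.permutation(spec.n_genes[sp])[:required]
        pos = 0
        for i in fly_11:
            edges.append((genes["fly"][i], sp, genes[sp][pool[pos]]))
            pos += 1
        for i in fly_1m:
            for t in pool[pos : pos + 2]:
                edges.append((genes["fly"][i], sp, genes[sp][t]))
            pos += 2
        for pair_start in range(0, n_mm, 2):
            block = pool[pos : pos + 2]
            pos += 2
            for i in fly_mm[pair_start : pair_start + 2]:
                for t in block:
                    edges.append((genes["fly"][i], sp, genes[sp][t]))

    # attribute each edge to >=1 of the prediction sources
    per_method: dict[str, dict[tuple[GeneRef, GeneRef], set[str]]] = {m: {} for m in METHOD_LABELS}
    if edges:
        primaries = rng.integers(0, len(METHOD_LABELS), size=len(edges))
        extra_draw = rng.random((len(edges), len(METHOD_LABELS)))
        for row, (fly_id, sp, tgt_id) in enumerate(edges):
            src = GeneRef("fly", fly_id)
            tgt = GeneRef(sp, tgt_id)
            for m_idx, method in enumerate(METHOD_LABELS):
                if m_idx == primaries[row] or extra_draw[row, m_idx] < 0.3:
                    per_method[method].setdefault((src, tgt), set()).add(method)
    tables = {m: OrthologTable(per_method[m]) for m in METHOD_LABELS}
    return Universe(spec=spec, genes=genes, tables=tables)


def generate_screen(
    universe: Universe, n_hits: int, n_lethal: int, seed: int
) -> tuple[list[str], list[str]]:
    """Sample disjoint hit and developmental-lethal lists from the fly universe."""
    fly = universe.genes["fly"]
    if n_hits < 0 or n_lethal < 0:
        raise ParameterError("counts must be >= 0")
    if n_hits + n_lethal > len(fly):
        raise ParameterError(f"n_hits + n_lethal = {n_hits + n_lethal} exceeds universe size {len(fly)}")
    perm = np.random.default_rng(seed).permutation(len(fly))
    hits = sorted(fly[i] for i in perm[:n_hits])
    lethal = sorted(fly[i] for i in perm[n_hits : n_hits + n_lethal])
    return hits, lethal


def _pair_from_index(t: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Invert the row-major upper-triangle linearization of pairs (i < j)."""
    t = t.astype(np.int64)
    i = (n - 2 - np.floor((np.sqrt(4 * n * (n - 1) - 8 * t - 7) - 1) / 2)).astype(np.int64)
    j = t + i + 1 - i * (2 * n - i - 1) // 2
    return i, j


def generate_interactions(universe: Universe, mean_degree: float, seed: int) -> pd.DataFrame:
    """Erdős–Rényi binary interactions over the fly universe.

    Edge count is Binomial(C(n,2), mean_degree/(n-1)); edges are sampled
    uniformly without replacement among all unordered pairs.
    """
    if mean_degree < 0:
        raise ParameterError("mean_degree must be >= 0")
    nodes = universe.genes["fly"]
    n = len(nodes)
    if n < 2 or mean_degree == 0:
        return pd.DataFrame(columns=["source_id", "target_id"])
    rng = np.random.default_rng(seed)
    n_pairs = n * (n - 1) // 2
    p = min(1.0, mean_degree / (n - 1))
    m = int(rng.binomial(n_pairs, p))
    chosen: set[int] = set()
    while len(chosen) < m:
        draw = rng.integers(0, n_pairs, size=(m - len(chosen)) + 16)
        for t in draw.tolist():
            if len(chosen) < m:
                chosen.add(t)
    idx = np.array(sorted(chosen), dtype=np.int64)
    i, j = _pair_from_index(idx, n)
    frame = pd.DataFrame(
        {"source_id": [nodes[a] for a in i], "target_id": [nodes[b] for b in j]}
    )
    return frame.sort_values(["source_id", "target_id"], ignore_index=True)


def generate_genesets(
    universe_genes: Sequence[str],
    effects: PlantedEffects,
    hit_list: Sequence[str],
    seed: int,
    name_prefix: str = "set",
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Generate a GMT-style collection with ``effects.n_planted`` enriched sets.

    Returns (collection, truth table).  The truth table has one row per
    planted set: set_name, planted_flag, enrichment_factor.
    """
    rng = np.random.default_rng(seed)
    genes = list(universe_genes)
    lo, hi = effects.set_size_range
    if hi > len(genes):
        raise ParameterError(f"set size {hi} exceeds universe size {len(genes)}")
    hit_set = set(hit_list)
    hits = [g for g in genes if g in hit_set]
    non_hits = [g for g in genes if g not in hit_set]
    p_hit = min(1.0, effects.enrichment_factor * len(hits) / len(genes)) if genes else 0.0

    collection: dict[str, list[str]] = {}
    truth_rows = []
    for i in range(effects.n_sets):
        name = f"{name_prefix}_{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        planted = i < effects.n_planted
        if planted:
            h = min(int(rng.binomial(size, p_hit)), len(hits), size)
            members = [hits[t] for t in rng.choice(len(hits), size=h, replace=False)] if h else []
            members += [
                non_hits[t] for t in rng.choice(len(non_hits), size=size - h, replace=False)
            ]
            truth_rows.append(
                {"set_name": name, "planted_flag": 1, "enrichment_factor": effects.enrichment_factor}
            )
        else:
            members = [genes[t] for t in rng.choice(len(genes), size=size, replace=False)]
        collection[name] = sorted(members)
    truth = pd.DataFrame(truth_rows, columns=["set_name", "planted_flag", "enrichment_factor"])
    return collection, truth


def generate_annotations(
    universe_genes: Sequence[str],
    map_genes: Sequence[str],
    effects: PlantedEffects,
    seed: int,
    labels: tuple[str, str] = ("OMIM", "microarray"),
) -> dict[str, list[str]]:
    """Two annotation gene lists with planted over-representation among *map_genes*.

    Each gene is annotated independently per source: map genes at
    ``annotation_hit_rate``, all other universe genes at ``annotation_base_rate``.
    """
    rng = np.random.default_rng(seed)
    map_set = set(map_genes)
    rates = np.array(
        [effects.annotation_hit_rate if g in map_set else effects.annotation_base_rate
         for g in universe_genes]
    )
    out: dict[str, list[str]] = {}
    for label in labels:
        draw = rng.random(len(rates))
        out[label] = sorted(g for g, u, r in zip(universe_genes, draw, rates) if u < r)
    return out


def assign_classes(set_names: Sequence[str], n_classes: int) -> dict[str, str]:
    """Deterministic round-robin assignment of gene sets to functional classes."""
    if n_classes < 1:
        raise ParameterError("n_classes must be >= 1")
    ordered = sorted(set_names)
    width = max(2, len(str(n_classes)))
    return {name: f"class_{(i % n_classes) + 1:0{width}d}" for i, name in enumerate(ordered)}
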