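"""Hypergeometric over-representation testing with per-collection significance
policies and GO-style parent–child pruning.

The statistic throughout is the one-sided upper tail P(X >= k) for X
hypergeometric with population N (background universe), K successes (gene-set
members in the background) and n draws (query size).  Collections carry their
own significance thresholds: GO and KEGG-style pathways at p < 0.1, C2-style
curated sets at p < 0.01.  Raw probabilities are reported; an optional
Benjamini–Hochberg adjustment exists but is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .errors import FormatError, ParameterError
from .io import read_tsv, write_tsv

logger = logging.getLogger(__name__)

__all__ = [
    "SignificancePolicy",
    "EnrichmentResult",
    "hypergeometric_upper_tail",
    "enrich_collection",
    "prune_go_results",
    "write_enrichment_table",
    "read_enrichment_table",
]


@dataclass(frozen=True)
class SignificancePolicy:
    """Per-collection alpha thresholds and the GO term-size ceiling."""

    go_alpha: float = 0.1
    kegg_alpha: float = 0.1
    c2_alpha: float = 0.01
    go_max_term_size: int = 500

    def __post_init__(self):
        for name in ("go_alpha", "kegg_alpha", "c2_alpha"):
            alpha = getattr(self, name)
            if not 0 < alpha < 1:
                raise ParameterError(f"{name} must lie in (0, 1)")
        if self.go_max_term_size < 1:
            raise ParameterError("go_max_term_size must be positive")

    def alpha_for(self, collection: str) -> float:
        key = collection.lower()
        if key == "go":
            return self.go_alpha
        if key == "kegg":
            return self.kegg_alpha
        if key == "c2":
            return self.c2_alpha
        raise ParameterError(f"unknown collection label {collection!r} (expected go/kegg/c2)")


@dataclass
class EnrichmentResult:
    """One gene set's hypergeometric outcome against one query."""

    set_name: str
    collection: str
    k: int  # overlap with the query
    K: int  # set size within the background
    n: int  # query size
    N: int  # background size
    p_value: float
    significant: bool
    member_hits: list[str] = field(default_factory=list)

    @property
    def percent_mapped(self) -> float:
        """100·k/K — the share of the set covered by the query."""
        return 100.0 * self.k / self.K if self.K else 0.0


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Numerically stable up to N ~ 1e6 (delegates to scipy's survival function,
    which works on log-gammas rather than factorial ratios).
    """
    for name, value in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(value) != value or value < 0:
            raise ParameterError(f"{name} must be a non-negative integer, got {value!r}")
    if K > N or n > N:
        raise ParameterError(f"need K <= N and n <= N (got K={K}, n={n}, N={N})")
    if k > min(K, n):
        raise ParameterError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_collection(
    query: Sequence[str],
    collection: Mapping[str, Sequence[str]],
    background: Sequence[str],
    policy: SignificancePolicy,
    collection_label: str,
    apply_bh: bool = False,
) -> list[EnrichmentResult]:
    """Test every set in *collection* for over-representation of *query*.

    Sets are intersected with the background before testing; query genes
    outside the background are dropped with a warning.  Results are sorted by
    (p, set name).  ``apply_bh=True`` replaces the significance call with a
    Benjamini–Hochberg decision at the same alpha (raw p-values unchanged).
    """
    background_set = set(background)
    if not background_set:
        raise ParameterError("background universe is empty")
    query_set = set(query)
    outside = query_set - background_set
    if outside:
        logger.warning("%d query gene(s) outside background dropped", len(outside))
        query_set &= background_set

    alpha = policy.alpha_for(collection_label)
    N, n = len(background_set), len(query_set)
    results = []
    for name, members in collection.items():
        members_in_bg = set(members) & background_set
        K = len(members_in_bg)
        hits = sorted(members_in_bg & query_set)
        k = len(hits)
        p = hypergeometric_upper_tail(k, n, K, N)
        results.append(
            EnrichmentResult(
                set_name=name,
                collection=collection_label,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=p,
                significant=bool(p < alpha),
                member_hits=hits,
            )
        )
    if apply_bh and results:
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests([r.p_value for r in results], alpha=alpha, method="fdr_bh")
        for res, rej in zip(results, reject):
            res.significant = bool(rej)
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def prune_go_results(
    results: Sequence[EnrichmentResult],
    parent_child: Sequence[tuple[str, str]],
    policy: SignificancePolicy,
) -> tuple[list[EnrichmentResult], list[dict[str, str]]]:
    """Size-filter and de-redundify GO-style results along the term hierarchy.

    1. Terms with K > ``go_max_term_size`` are dropped (regardless of p).
    2. Within each significant ancestor–descendant chain (transitive closure
       of the child→parent relation) only the term with maximal overlap k is
       retained; ties break by smaller p, then lexicographic name.

    Returns (pruned results, log) where the log records every removal as
    ``{"set_name": ..., "reason": ...}``.  A cyclic relation table raises
    FormatError.
    """
    hierarchy = nx.DiGraph()
    hierarchy.add_edges_from(parent_child)  # edges child -> parent
    if not nx.is_directed_acyclic_graph(hierarchy):
        raise FormatError("parent-child relation table contains a cycle")

    log: list[dict[str, str]] = []
    sized: list[EnrichmentResult] = []
    for res in results:
        if res.K > policy.go_max_term_size:
            log.append(
                {"set_name": res.set_name,
                 "reason": f"term size {res.K} > {policy.go_max_term_size}"}
            )
        else:
            sized.append(res)

    # ancestors of each significant term under the transitive closure
    lineage = {
        res.set_name: (nx.descendants(hierarchy, res.set_name) if res.set_name in hierarchy else set())
        for res in sized
        if res.significant
    }

    def comparable(a: str, b: str) -> bool:
        return b in lineage[a] or a in lineage[b]

    retained: list[str] = []
    removed: set[str] = set()
    for res in sorted(
        (r for r in sized if r.significant), key=lambda r: (-r.k, r.p_value, r.set_name)
    ):
        winner = next((kept for kept in retained if comparable(res.set_name, kept)), None)
        if winner is None:
            retained.append(res.set_name)
        else:
            removed.add(res.set_name)
            log.append(
                {"set_name": res.set_name,
                 "reason": f"ancestor/descendant of retained term {winner} with larger overlap"}
            )
    return [r for r in sized if r.set_name not in removed], log


_ENRICHMENT_COLUMNS = [
    "collection", "species", "set_name", "K", "k", "n", "N",
    "percent_mapped", "p_value", "significant", "member_hits",
]


def write_enrichment_table(
    results: Sequence[EnrichmentResult],
    path: str | Path,
    species: str = "",
    header: Sequence[str] | None = None,
) -> None:
    """Serialize results in supplementary-table style (one row per gene set)."""
    rows = [
        {
            "collection": r.collection,
            "species": species,
            "set_name": r.set_name,
            "K": r.K,
            "k": r.k,
            "n": r.n,
            "N": r.N,
            "percent_mapped": f"{r.percent_mapped:.4f}",
            "p_value": f"{r.p_value:.6g}",
            "significant": int(r.significant),
            "member_hits": ";".join(r.member_hits),
        }
        for r in results
    ]
    write_tsv(pd.DataFrame(rows, columns=_ENRICHMENT_COLUMNS), path, header=header)


def read_enrichment_table(path: str | Path) -> tuple[list[EnrichmentResult], list[str]]:
    """Load a serialized enrichment table; returns (results, per-row species)."""
    frame = read_tsv(path, _ENRICHMENT_COLUMNS)
    results, species = [], []
    for row in frame.itertuples(index=False):
        results.append(
            EnrichmentResult(
                set_name=row.set_name,
                collection=row.collection,
                k=int(row.k),
                K=int(row.K),
                n=int(row.n),
                N=int(row.N),
                p_value=float(row.p_value),
                significant=bool(int(row.significant)),
                member_hits=[g for g in row.member_hits.split(";") if g],
            )
        )
        species.append(row.species)
    return results, species
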