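"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the hypergeometric tail
is exhaustive enumeration over exact integer binomials, and the orthology
count walks the emitted TSV text directly.
"""

from math import comb
from pathlib import Path


def hypergeom_tail_enum(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by exact enumeration of the hypergeometric pmf."""
    denom = comb(N, n)
    total = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1))
    return total / denom


def hypergeom_tail_suffix(n: int, K: int, N: int) -> list[float]:
    """All tails [P(X>=0), ..., P(X>=m)] for one margin triple, exactly."""
    m = min(K, n)
    pmf = [comb(K, x) * comb(N - K, n - x) for x in range(m + 1)]
    denom = comb(N, n)
    tails, acc = [], 0
    for value in reversed(pmf):
        acc += value
        tails.append(acc / denom)
    return tails[::-1]


def walk_ortholog_tables(paths, source_species: str, target_species: str) -> set[str]:
    """Source IDs with >=1 target in *target_species*, by raw line walking."""
    mapped: set[str] = set()
    for path in paths:
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#") or line.startswith("source_species"):
                continue
            fields = line.split("\t")
            if fields[0] == source_species and fields[2] == target_species:
                mapped.add(fields[1])
    return mapped


def count_tsv_data_lines(path) -> int:
    """Non-comment, non-header data lines in a TSV file."""
    lines = [l for l in Path(path).read_text().splitlines() if l and not l.startswith("#")]
    return max(0, len(lines) - 1)
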