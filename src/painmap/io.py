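"""Readers and writers for the plain-text formats used throughout the pipeline.

All files are UTF-8 with LF line endings.  Lines starting with ``#`` are
provenance/comment lines and are skipped by every reader; every writer
accepts an optional list of header lines to embed (the pipeline uses this to
stamp tool version, config hash and seed into each output).

Formats
-------
gene list        one gene ID per line
ortholog table   TSV: source_species, source_id, target_species, target_id, method
interactions     TSV: source_id, target_id
GMT              tab-separated: set name, description, member genes
annotations      TSV: gene_id, source_label
parent-child     TSV: child_id, parent_id
class map        TSV: set_name, class_label
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError

ORTHOLOG_COLUMNS = ["source_species", "source_id", "target_species", "target_id", "method"]
INTERACTION_COLUMNS = ["source_id", "target_id"]
ANNOTATION_COLUMNS = ["gene_id", "source_label"]
PARENT_CHILD_COLUMNS = ["child_id", "parent_id"]
CLASS_MAP_COLUMNS = ["set_name", "class_label"]


def _header_block(header: Sequence[str] | None) -> str:
    if not header:
        return ""
    return "".join(f"# {line}\n" for line in header)


def write_lines(path: str | Path, lines: Iterable[str], header: Sequence[str] | None = None) -> None:
    text = _header_block(header) + "".join(f"{line}\n" for line in lines)
    Path(path).write_text(text, encoding="utf-8", newline="\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-ID-per-line gene list, skipping blanks and comments."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path, header: Sequence[str] | None = None) -> None:
    write_lines(path, genes, header=header)


def read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a TSV with a header row, validating the required columns."""
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file has no header row")
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return frame


def write_tsv(frame: pd.DataFrame, path: str | Path, header: Sequence[str] | None = None) -> None:
    buf = _io.StringIO()
    frame.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    Path(path).write_text(_header_block(header) + buf.getvalue(), encoding="utf-8", newline="\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection into an ordered ``{name: members}`` dict."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >=1 member")
        name = fields[0]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(
    sets: Mapping[str, Sequence[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
    header: Sequence[str] | None = None,
) -> None:
    lines = []
    for name, members in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *members]))
    write_lines(path, lines, header=header)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read annotation memberships grouped by source label."""
    frame = read_tsv(path, ANNOTATION_COLUMNS)
    out: dict[str, set[str]] = {}
    for gene, label in zip(frame["gene_id"], frame["source_label"]):
        out.setdefault(label, set()).add(gene)
    return out


def write_annotations(
    annotations: Mapping[str, Iterable[str]], path: str | Path, header: Sequence[str] | None = None
) -> None:
    rows = [
        {"gene_id": gene, "source_label": label}
        for label in sorted(annotations)
        for gene in sorted(annotations[label])
    ]
    write_tsv(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS), path, header=header)


def read_class_map(path: str | Path) -> dict[str, str]:
    frame = read_tsv(path, CLASS_MAP_COLUMNS)
    return dict(zip(frame["set_name"], frame["class_label"]))


def write_class_map(class_map: Mapping[str, str], path: str | Path, header: Sequence[str] | None = None) -> None:
    rows = [{"set_name": name, "class_label": label} for name, label in sorted(class_map.items())]
    write_tsv(pd.DataFrame(rows, columns=CLASS_MAP_COLUMNS), path, header=header)


def read_parent_child(path: str | Path) -> list[tuple[str, str]]:
    frame = read_tsv(path, PARENT_CHILD_COLUMNS)
    return list(zip(frame["child_id"], frame["parent_id"]))
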