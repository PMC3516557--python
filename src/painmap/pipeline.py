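"""End-to-end orchestration: simulate → map-orthologs → expand → enrich →
build-map → validate, with one config, one seed, and full provenance.

Every output file carries a header comment with the tool version, a hash of
the config, and the master seed; the run manifest (JSON) records per-stage
status, counts and output checksums.  Re-running with an identical config
and inputs is byte-identical.  Stage randomness is derived from the master
seed via :func:`painmap.seeds.child_seed`, so any stage can be regenerated
independently.

When simulation is enabled, the planted annotation lists depend on the
assembled map's gene membership, so they are generated at the validate stage
(after build-map); all other inputs are written up front by the simulate
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .enrichment import SignificancePolicy, enrich_collection, write_enrichment_table
from .errors import ParameterError, StageError
from .expansion import (
    BINDING_PARTNER,
    LETHAL,
    PAIN,
    categorize_nodes,
    first_degree_partners,
    load_interactions,
    write_node_table,
)
from .io import (
    read_annotations,
    read_class_map,
    read_gene_list,
    read_gmt,
    write_annotations,
    write_class_map,
    write_gene_list,
    write_gmt,
    write_tsv,
)
from .orthology import GeneRef, OrthologTable, load_ortholog_table, map_genes, merge_tables
from .seeds import child_seed
from .synthetic import (
    PlantedEffects,
    UniverseSpec,
    assign_classes,
    generate_annotations,
    generate_genesets,
    generate_interactions,
    generate_screen,
    generate_universe,
)
from .systems_map import (
    build_map,
    class_hit_representation,
    connectivity_without_partners,
    fly_anchor_unifier,
    pool_into_classes,
    write_graphml,
    write_membership_table,
    write_sif,
)
from .validation import overlap_report, random_list_null, union_overlap, percent

logger = logging.getLogger(__name__)

__all__ = ["SimulateParams", "InputPaths", "RunConfig", "run_all", "DEFAULT_CONFIG"]

STAGES = ("simulate", "map_orthologs", "expand", "enrich", "build_map", "validate")


@dataclass(frozen=True)
class SimulateParams:
    """Synthetic-input parameters; defaults are the study conditions."""

    n_fly: int = 14000
    n_mouse: int = 15000
    n_human: int = 15000
    frac_one_to_one: float = 0.6
    frac_many_to_many: float = 0.1
    frac_unmapped: float = 0.3
    n_hits: int = 580
    n_lethal: int = 300
    mean_degree: float = 0.15
    n_sets: int = 200
    set_size_min: int = 30
    set_size_max: int = 80
    n_planted: int = 10
    enrichment_factor: float = 5.0
    annotation_base_rate: float = 0.015
    annotation_hit_rate: float = 0.22
    n_classes: int = 20

    def effects(self) -> PlantedEffects:
        return PlantedEffects(
            n_sets=self.n_sets,
            set_size_range=(self.set_size_min, self.set_size_max),
            n_planted=self.n_planted,
            enrichment_factor=self.enrichment_factor,
            annotation_base_rate=self.annotation_base_rate,
            annotation_hit_rate=self.annotation_hit_rate,
        )

    def universe_spec(self, seed: int) -> UniverseSpec:
        return UniverseSpec(
            n_fly=self.n_fly,
            n_mouse=self.n_mouse,
            n_human=self.n_human,
            frac_one_to_one=self.frac_one_to_one,
            frac_many_to_many=self.frac_many_to_many,
            frac_unmapped=self.frac_unmapped,
            seed=seed,
        )


@dataclass
class InputPaths:
    """Paths to all pipeline inputs (filled automatically when simulating)."""

    hits: str = ""
    lethals: str = ""
    ortholog_tables: list[str] = field(default_factory=list)
    interactions: str = ""
    genesets: dict[str, dict[str, str]] = field(default_factory=dict)  # species -> {collection: path}
    backgrounds: dict[str, str] = field(default_factory=dict)  # species -> gene-list path
    class_map: str = ""
    annotations: str = ""  # optional; simulated at validate time when empty


@dataclass
class RunConfig:
    """Everything one run needs: inputs, thresholds, seeds, toggles."""

    outdir: str
    seed: int = 0
    simulate: SimulateParams | None = field(default_factory=SimulateParams)
    inputs: InputPaths = field(default_factory=InputPaths)
    policy: SignificancePolicy = field(default_factory=SignificancePolicy)
    stages: dict[str, bool] = field(
        default_factory=lambda: {"expand": True, "enrich": True, "build_map": True, "validate": True}
    )
    r_lists: int = 100
    target_species: tuple[str, ...] = ("mouse", "human")
    min_sources: int = 1

    # -- (de)serialization ---------------------------------------------------
    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        sim = raw.get("simulate")
        config = cls(
            outdir=str(raw.get("outdir", "painmap_out")),
            seed=int(raw.get("seed", 0)),
            simulate=SimulateParams(**sim) if isinstance(sim, Mapping) else (SimulateParams() if sim else None),
            inputs=InputPaths(**raw.get("inputs", {})),
            policy=SignificancePolicy(**raw.get("policy", {})),
            r_lists=int(raw.get("r_lists", 100)),
            target_species=tuple(raw.get("target_species", ("mouse", "human"))),
            min_sources=int(raw.get("min_sources", 1)),
        )
        config.stages.update(raw.get("stages", {}))
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {})

    def to_dict(self) -> dict[str, Any]:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "simulate": asdict(self.simulate) if self.simulate else None,
            "inputs": asdict(self.inputs),
            "policy": asdict(self.policy),
            "stages": dict(self.stages),
            "r_lists": self.r_lists,
            "target_species": list(self.target_species),
            "min_sources": self.min_sources,
        }

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        payload = self.to_dict()
        payload.pop("outdir")
        canonical = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:12]

    def header(self) -> list[str]:
        return [f"painmap {__version__}", f"config {self.config_hash()}", f"seed {self.seed}"]


DEFAULT_CONFIG = RunConfig(outdir="painmap_out")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig):
        self.data: dict[str, Any] = {
            "tool": f"painmap {__version__}",
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stages": [],
        }

    def record(self, name: str, status: str, outputs: Sequence[Path] = (), counts: Mapping[str, Any] = ()):
        self.data["stages"].append(
            {
                "name": name,
                "status": status,
                "outputs": {str(p): _sha256(Path(p)) for p in outputs},
                "counts": dict(counts),
            }
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline per *config*; returns the run manifest dict.

    Any stage failure raises :class:`StageError` tagged with the stage name;
    the manifest written so far is flushed with the failing stage marked
    incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.header()
    manifest = _Manifest(config)
    manifest_path = outdir / "manifest.json"
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8"
    )

    state: dict[str, Any] = {}
    try:
        for stage in STAGES:
            runner = globals()[f"_stage_{stage}"]
            if stage == "simulate" and config.simulate is None:
                manifest.record(stage, "skipped")
                continue
            if not config.stages.get(stage, True):
                manifest.record(stage, "skipped")
                if stage == "expand":
                    # Fig-S3 variant: no binding partners, lethals still shown
                    state["partners"] = []
                    state["lethals"] = (
                        read_gene_list(config.inputs.lethals) if config.inputs.lethals else []
                    )
                continue
            try:
                outputs, counts = runner(config, outdir, header, state)
            except StageError:
                raise
            except Exception as exc:  # tag unexpected failures with the stage
                raise StageError(stage, str(exc)) from exc
            manifest.record(stage, "complete", outputs, counts)
    except StageError as exc:
        manifest.record(exc.stage, "incomplete")
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    logger.info("pipeline complete: %s", manifest_path)
    return manifest.data


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, outdir: Path, header: list[str], state: dict):
    params = config.simulate
    assert params is not None
    seed = config.seed
    sim_dir = outdir / "inputs"
    sim_dir.mkdir(exist_ok=True)
    inputs = config.inputs

    universe = generate_universe(params.universe_spec(child_seed(seed, "universe")))
    state["universe"] = universe
    outputs: list[Path] = []
    for sp, genes in universe.genes.items():
        path = sim_dir / f"universe_{sp}.txt"
        write_gene_list(genes, path, header=header)
        inputs.backgrounds[sp] = str(path)
        outputs.append(path)
    inputs.ortholog_tables = []
    for method, table in universe.tables.items():
        path = sim_dir / f"orthologs_{method}.tsv"
        table.write(path, header=header)
        inputs.ortholog_tables.append(str(path))
        outputs.append(path)

    hits, lethals = generate_screen(
        universe, params.n_hits, params.n_lethal, child_seed(seed, "screen")
    )
    hits_path, lethal_path = sim_dir / "hits.txt", sim_dir / "lethals.txt"
    write_gene_list(hits, hits_path, header=header)
    write_gene_list(lethals, lethal_path, header=header)
    inputs.hits, inputs.lethals = str(hits_path), str(lethal_path)
    outputs += [hits_path, lethal_path]

    edges = generate_interactions(universe, params.mean_degree, child_seed(seed, "interactions"))
    interactions_path = sim_dir / "interactions.tsv"
    write_tsv(edges, interactions_path, header=header)
    inputs.interactions = str(interactions_path)
    outputs.append(interactions_path)

    # gene sets are planted around each species' projected (hits + partners)
    # query, mirroring the enrichment queries run downstream
    graph = nx.Graph()
    graph.add_edges_from(zip(edges["source_id"], edges["target_id"]))
    partners = first_degree_partners(hits, graph)
    fly_query = sorted(set(hits) | set(partners))
    merged = universe.merged_table()
    queries = {"fly": fly_query}
    for sp in config.target_species:
        mapped, _ = map_genes([GeneRef("fly", g) for g in fly_query], merged, sp)
        queries[sp] = [ref.id for ref in mapped]

    effects = params.effects()
    collections = {"fly": ["kegg"]} | {sp: ["kegg", "c2"] for sp in config.target_species}
    all_set_names: list[str] = []
    inputs.genesets = {}
    n_sets_written = 0
    for sp, labels in collections.items():
        inputs.genesets[sp] = {}
        for label in labels:
            sets, truth = generate_genesets(
                universe.genes[sp],
                effects,
                queries[sp],
                child_seed(seed, "genesets", sp, label),
                name_prefix=f"{sp}_{label}",
            )
            gmt_path = sim_dir / f"genesets_{sp}_{label}.gmt"
            write_gmt(sets, gmt_path, header=header)
            truth_path = sim_dir / f"truth_{sp}_{label}.tsv"
            write_tsv(truth, truth_path, header=header)
            inputs.genesets[sp][label] = str(gmt_path)
            all_set_names += list(sets)
            n_sets_written += len(sets)
            outputs += [gmt_path, truth_path]

    class_map = assign_classes(all_set_names, params.n_classes)
    class_map_path = sim_dir / "class_map.tsv"
    write_class_map(class_map, class_map_path, header=header)
    inputs.class_map = str(class_map_path)
    outputs.append(class_map_path)

    counts = {
        "n_fly": len(universe.genes["fly"]),
        "n_hits": len(hits),
        "n_lethal": len(lethals),
        "n_interactions": len(edges),
        "n_gene_sets": n_sets_written,
    }
    return outputs, counts


def _stage_map_orthologs(config: RunConfig, outdir: Path, header: list[str], state: dict):
    inputs = config.inputs
    if not inputs.hits or not inputs.ortholog_tables:
        raise ParameterError("map_orthologs requires hits and ortholog_tables inputs")
    hits = read_gene_list(inputs.hits)
    tables = [load_ortholog_table(path) for path in inputs.ortholog_tables]
    merged = merge_tables(tables)
    state["hits"] = hits
    state["merged_table"] = merged

    outputs, counts = [], {"n_hits": len(hits)}
    state["mapped_hits"] = {}
    for sp in config.target_species:
        mapped, report = map_genes(
            [GeneRef("fly", g) for g in hits], merged, sp, min_sources=config.min_sources
        )
        path = outdir / f"ortholog_report_{sp}.tsv"
        write_tsv(report, path, header=header)
        outputs.append(path)
        state["mapped_hits"][sp] = [ref.id for ref in mapped]
        counts[f"n_hits_mapped_{sp}"] = int((report["n_targets"] > 0).sum())
        counts[f"n_targets_{sp}"] = len(mapped)
    return outputs, counts


def _stage_expand(config: RunConfig, outdir: Path, header: list[str], state: dict):
    inputs = config.inputs
    hits = state["hits"]
    lethals = read_gene_list(inputs.lethals) if inputs.lethals else []
    graph = load_interactions(inputs.interactions) if inputs.interactions else nx.Graph()
    partners = first_degree_partners(hits, graph)
    state["partners"] = partners
    state["lethals"] = lethals

    categories = categorize_nodes(hits, partners, lethals)
    nodes_path = outdir / "expanded_nodes.tsv"
    write_node_table(categories, nodes_path, header=header)
    counts = {
        "n_input_hits": len(hits),
        "n_partners": len(partners),
        "n_nodes": len(categories),
    }
    return [nodes_path], counts


def _stage_enrich(config: RunConfig, outdir: Path, header: list[str], state: dict):
    inputs = config.inputs
    hits = state["hits"]
    partners = state.get("partners", [])
    merged: OrthologTable = state["merged_table"]
    fly_query = sorted(set(hits) | set(partners))

    queries = {"fly": fly_query}
    for sp in config.target_species:
        mapped, _ = map_genes(
            [GeneRef("fly", g) for g in fly_query], merged, sp, min_sources=config.min_sources
        )
        queries[sp] = [ref.id for ref in mapped]
    state["queries"] = queries

    outputs, counts = [], {}
    state["enrichment_runs"] = []  # list of (species, collection_label, results)
    for sp in sorted(inputs.genesets):
        for label in sorted(inputs.genesets[sp]):
            collection = read_gmt(inputs.genesets[sp][label])
            background = read_gene_list(inputs.backgrounds[sp])
            results = enrich_collection(queries[sp], collection, background, config.policy, label)
            path = outdir / f"enrichment_{sp}_{label}.tsv"
            write_enrichment_table(results, path, species=sp, header=header)
            outputs.append(path)
            state["enrichment_runs"].append((sp, label, results))
            counts[f"n_query_{sp}"] = len(set(queries[sp]))
            counts[f"n_significant_{sp}_{label}"] = sum(r.significant for r in results)
    return outputs, counts


def _stage_build_map(config: RunConfig, outdir: Path, header: list[str], state: dict):
    inputs = config.inputs
    if "enrichment_runs" not in state:
        raise ParameterError("build_map requires the enrich stage")
    class_map = read_class_map(inputs.class_map)
    merged: OrthologTable = state["merged_table"]
    categorized = set(state["hits"]) | set(state.get("partners", [])) | set(state.get("lethals", []))
    unify = fly_anchor_unifier(merged, prefer=categorized)

    runs = [(sp, results) for sp, _, results in state["enrichment_runs"]]
    membership, provenance, unassigned = pool_into_classes(runs, class_map, unify=unify)

    # developmental lethals join a class when they are members of one of its
    # contributing significant sets (they are never enrichment query seeds)
    lethals = set(state.get("lethals", []))
    if lethals:
        lethal_by_species = {"fly": lethals}
        for sp in config.target_species:
            mapped, _ = map_genes([GeneRef("fly", g) for g in sorted(lethals)], merged, sp)
            lethal_by_species[sp] = {ref.id for ref in mapped}
        gmt_cache = {
            (sp, label): read_gmt(inputs.genesets[sp][label])
            for sp in inputs.genesets
            for label in inputs.genesets[sp]
        }
        set_members: dict[str, tuple[str, set[str]]] = {}
        for (sp, _), sets in gmt_cache.items():
            for name, members in sets.items():
                set_members[name] = (sp, set(members))
        for label, contributing in provenance.items():
            for sp, set_name in contributing:
                sp_members = set_members.get(set_name, (sp, set()))[1]
                for gene in sp_members & lethal_by_species.get(sp, set()):
                    membership[label].add(unify(sp, gene))

    hits, partners = state["hits"], state.get("partners", [])
    categories = categorize_nodes(
        hits, partners, state.get("lethals", []),
        nodes=set(hits) | set(partners) | set(state.get("lethals", [])),
    )
    graph = build_map(membership, categories, provenance)
    state["systems_map"] = graph
    state["membership"] = membership

    fractions, n_at_or_below = class_hit_representation(graph)
    comp_full, comp_pruned, intact = connectivity_without_partners(graph)

    graphml_path = outdir / "systems_map.graphml"
    sif_path = outdir / "systems_map.sif"
    membership_path = outdir / "class_membership.tsv"
    write_graphml(graph, graphml_path)
    write_sif(graph, sif_path, header=header)
    node_categories = {g: d["category"] for g, d in graph.nodes(data=True) if d["category"] != "functional_class"}
    write_membership_table(membership, node_categories, membership_path, header=header)

    by_category = {
        cat: sum(1 for _, d in graph.nodes(data=True) if d["category"] == cat)
        for cat in (PAIN, BINDING_PARTNER, LETHAL)
    }
    counts = {
        "n_classes": len(membership),
        "n_unassigned_sets": len(unassigned),
        "n_pain": by_category[PAIN],
        "n_binding_partner": by_category[BINDING_PARTNER],
        "n_lethal": by_category[LETHAL],
        "n_classes_at_or_below_half_pain": n_at_or_below,
        "components_full": comp_full,
        "components_without_partners": comp_pruned,
        "connectivity_intact": intact,
    }
    return [graphml_path, sif_path, membership_path], counts


def _stage_validate(config: RunConfig, outdir: Path, header: list[str], state: dict):
    inputs = config.inputs
    if "systems_map" not in state:
        raise ParameterError("validate requires the build_map stage")
    graph = state["systems_map"]
    genes_by_category = {
        cat: {g for g, d in graph.nodes(data=True) if d["category"] == cat}
        for cat in (PAIN, BINDING_PARTNER)
    }
    background = read_gene_list(inputs.backgrounds["fly"])

    outputs = []
    if inputs.annotations:
        annotations = read_annotations(inputs.annotations)
    elif config.simulate is not None:
        map_genes_all = sorted(genes_by_category[PAIN] | genes_by_category[BINDING_PARTNER])
        annotations = generate_annotations(
            background, map_genes_all, config.simulate.effects(), child_seed(config.seed, "annotations")
        )
        annotations_path = Path(config.outdir) / "inputs" / "annotations.tsv"
        write_annotations(annotations, annotations_path, header=header)
        inputs.annotations = str(annotations_path)
        outputs.append(annotations_path)
    else:
        raise ParameterError("validate requires an annotations input when not simulating")

    labels = sorted(annotations)
    if len(labels) < 2:
        raise ParameterError(f"need two annotation sources, found {labels}")
    annot_a, annot_b = annotations[labels[0]], annotations[labels[1]]

    report = overlap_report(genes_by_category, annot_a, annot_b)
    report_path = outdir / "overlap_report.tsv"
    write_tsv(report, report_path, header=header)
    outputs.append(report_path)

    null_rows, null_json = [], {}
    counts = {}
    for cat, genes in genes_by_category.items():
        if not genes:
            continue
        observed = percent(union_overlap(genes, annot_a, annot_b), len(genes))
        null = random_list_null(
            background, len(genes), annot_a, annot_b,
            r_lists=config.r_lists, seed=child_seed(config.seed, "null", cat),
            observed_percent=observed,
        )
        null_rows += [{"category": cat, "replicate": i + 1, "percent": p}
                      for i, p in enumerate(null.percents)]
        null_json[cat] = {
            "observed_percent": observed,
            "null_max": null.max,
            "null_min": null.min,
            "empirical_p": null.empirical_p,
            "r_lists": null.r_lists,
            "list_size": null.list_size,
            "seed": null.seed,
        }
        counts[f"observed_percent_{cat}"] = observed
        counts[f"null_max_{cat}"] = null.max
        counts[f"empirical_p_{cat}"] = null.empirical_p

    null_path = outdir / "null_distribution.tsv"
    write_tsv(pd.DataFrame(null_rows, columns=["category", "replicate", "percent"]), null_path, header=header)
    json_path = outdir / "overlap_report.json"
    json_path.write_text(
        json.dumps({"report": report.to_dict(orient="records"), "null": null_json},
                   indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    outputs += [null_path, json_path]
    return outputs, counts
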