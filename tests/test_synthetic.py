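import numpy as np
import pytest
from scipy.stats import ks_2samp

from painmap.errors import ParameterError
from painmap.expansion import load_interactions
from painmap.io import (
    read_annotations,
    read_gene_list,
    read_gmt,
    write_annotations,
    write_gene_list,
    write_gmt,
    write_tsv,
)
from painmap.orthology import GeneRef, map_genes
from painmap.synthetic import (
    PlantedEffects,
    UniverseSpec,
    _pair_from_index,
    assign_classes,
    generate_annotations,
    generate_genesets,
    generate_interactions,
    generate_screen,
    generate_universe,
)

from oracles import walk_ortholog_tables


class TestUniverse:
    def test_zero_genes_gives_empty_everything(self):
        universe = generate_universe(UniverseSpec(n_fly=0, n_mouse=0, n_human=0, seed=1))
        assert all(not genes for genes in universe.genes.values())
        assert all(len(t) == 0 for t in universe.tables.values())

    def test_all_unmapped_gives_empty_tables(self):
        spec = UniverseSpec(
            n_fly=50, n_mouse=50, n_human=50,
            frac_one_to_one=0, frac_many_to_many=0, frac_unmapped=1, seed=1,
        )
        universe = generate_universe(spec)
        assert all(len(t) == 0 for t in universe.tables.values())

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ParameterError):
            UniverseSpec(frac_one_to_one=0.8, frac_many_to_many=0.3, frac_unmapped=0.3)
        with pytest.raises(ParameterError):
            UniverseSpec(frac_one_to_one=-0.1)

    def test_gene_ids_unique_within_species(self, small_universe):
        for genes in small_universe.genes.values():
            assert len(genes) == len(set(genes))

    def test_mapped_count_matches_table_walk_oracle(self, tmp_path):
        spec = UniverseSpec(
            n_fly=1000, n_mouse=1200, n_human=1200,
            frac_one_to_one=0.6, frac_many_to_many=0.1, frac_unmapped=0.3, seed=7,
        )
        universe = generate_universe(spec)
        paths = []
        for method, table in universe.tables.items():
            path = tmp_path / f"{method}.tsv"
            table.write(path)
            paths.append(path)
        oracle_mapped = walk_ortholog_tables(paths, "fly", "human")
        refs = [GeneRef("fly", g) for g in universe.genes["fly"]]
        _, report = map_genes(refs, universe.merged_table(), "human")
        assert int((report["n_targets"] > 0).sum()) == len(oracle_mapped)
        # the realized topology fractions follow the spec (0.7 of fly genes mapped)
        assert len(oracle_mapped) == pytest.approx(700, abs=2)

    def test_at_least_two_sources_cover_all_mappings(self, small_universe):
        union = small_universe.merged_table()
        nonempty = [t for t in small_universe.tables.values() if len(t) > 0]
        assert len(nonempty) >= 2
        assert sum(len(t) for t in nonempty) >= len(union)


class TestScreen:
    def test_zero_hits_empty_list(self, small_universe):
        hits, lethal = generate_screen(small_universe, 0, 10, seed=3)
        assert hits == [] and len(lethal) == 10

    def test_hits_unique_and_disjoint_from_lethals(self, small_universe):
        hits, lethal = generate_screen(small_universe, 120, 40, seed=3)
        assert len(hits) == 120 and len(set(hits)) == 120
        assert not set(hits) & set(lethal)

    def test_same_seed_identical_lists(self, small_universe):
        assert generate_screen(small_universe, 50, 20, seed=9) == generate_screen(
            small_universe, 50, 20, seed=9
        )

    def test_oversized_request_rejected(self, small_universe):
        with pytest.raises(ParameterError):
            generate_screen(small_universe, 290, 20, seed=1)


class TestInteractions:
    def test_zero_degree_zero_edges(self, small_universe):
        assert generate_interactions(small_universe, 0.0, seed=1).empty

    def test_edge_count_within_three_sd_of_binomial(self):
        spec = UniverseSpec(n_fly=1000, n_mouse=1200, n_human=1200, seed=5)
        universe = generate_universe(spec)
        edges = generate_interactions(universe, 4.0, seed=5)
        n_pairs = 1000 * 999 // 2
        p = 4.0 / 999
        sd = np.sqrt(n_pairs * p * (1 - p))
        assert abs(len(edges) - 2000) <= 3 * sd

    def test_simple_graph_no_loops_no_duplicates(self, small_universe):
        edges = generate_interactions(small_universe, 2.0, seed=2)
        assert (edges["source_id"] != edges["target_id"]).all()
        keys = set(map(tuple, edges[["source_id", "target_id"]].values))
        assert len(keys) == len(edges)
        assert not {(b, a) for a, b in keys} & keys

    def test_roundtrip_through_reader(self, small_universe, tmp_path):
        edges = generate_interactions(small_universe, 2.0, seed=2)
        path = tmp_path / "edges.tsv"
        write_tsv(edges, path)
        graph = load_interactions(path)
        assert graph.number_of_edges() == len(edges)
        written = {tuple(sorted(e)) for e in map(tuple, edges[["source_id", "target_id"]].values)}
        loaded = {tuple(sorted(e)) for e in graph.edges()}
        assert loaded == written

    def test_pair_index_inversion_is_a_bijection(self):
        n = 12
        idx = np.arange(n * (n - 1) // 2)
        i, j = _pair_from_index(idx, n)
        assert (i < j).all() and (j < n).all() and (i >= 0).all()
        assert len({(a, b) for a, b in zip(i, j)}) == len(idx)


class TestGenesets:
    def test_no_planted_sets_empty_truth(self, small_universe):
        effects = PlantedEffects(n_sets=5, n_planted=0, set_size_range=(5, 10))
        _, truth = generate_genesets(small_universe.genes["fly"], effects, [], seed=1)
        assert truth.empty

    def test_oversized_sets_rejected(self, small_universe):
        effects = PlantedEffects(n_sets=2, n_planted=0, set_size_range=(400, 400))
        with pytest.raises(ParameterError):
            generate_genesets(small_universe.genes["fly"], effects, [], seed=1)

    def test_planted_overlap_matches_analytic_expectation(self):
        """E[hits in planted set] = K * factor * H/N; 200 replicates, 3 SE."""
        genes = [f"CG{i}" for i in range(14000)]
        hits = genes[:580]
        effects = PlantedEffects(
            n_sets=1, n_planted=1, set_size_range=(50, 50), enrichment_factor=5.0
        )
        p = 5.0 * 580 / 14000
        expected = 50 * p
        overlaps = []
        for rep in range(200):
            sets, _ = generate_genesets(genes, effects, hits, seed=1000 + rep)
            (members,) = sets.values()
            overlaps.append(len(set(members) & set(hits)))
        se = np.sqrt(50 * p * (1 - p) / 200)
        assert abs(np.mean(overlaps) - expected) <= 3 * se

    def test_factor_one_indistinguishable_from_background(self):
        """At factor 1 the planted/non-planted hit-fraction distributions agree
        (KS test fails to reject at alpha=0.01 over 50 replicates)."""
        genes = [f"CG{i}" for i in range(2000)]
        hits = genes[:200]
        effects = PlantedEffects(
            n_sets=4, n_planted=2, set_size_range=(30, 60), enrichment_factor=1.0
        )
        planted_fracs, other_fracs = [], []
        for rep in range(50):
            sets, truth = generate_genesets(genes, effects, hits, seed=500 + rep)
            planted = set(truth["set_name"])
            for name, members in sets.items():
                frac = len(set(members) & set(hits)) / len(members)
                (planted_fracs if name in planted else other_fracs).append(frac)
        assert ks_2samp(planted_fracs, other_fracs).pvalue > 0.01


class TestAnnotations:
    def test_zero_rates_empty_lists(self, small_universe):
        effects = PlantedEffects(annotation_base_rate=0, annotation_hit_rate=0)
        annotations = generate_annotations(
            small_universe.genes["fly"], small_universe.genes["fly"][:20], effects, seed=1
        )
        assert all(not genes for genes in annotations.values())

    def test_hit_rate_one_annotates_every_map_gene(self, small_universe):
        effects = PlantedEffects(annotation_base_rate=0, annotation_hit_rate=1)
        map_genes_list = small_universe.genes["fly"][:20]
        annotations = generate_annotations(
            small_universe.genes["fly"], map_genes_list, effects, seed=1
        )
        for genes in annotations.values():
            assert set(genes) == set(map_genes_list)

    def test_union_overlap_matches_independence_closed_form(self):
        """Mean union-annotated fraction of map genes ~ 1-(1-rate)^2 over 100 reps."""
        genes = [f"CG{i}" for i in range(3000)]
        map_genes_list = genes[:166]
        effects = PlantedEffects(annotation_base_rate=0.03, annotation_hit_rate=0.38)
        expected = 1 - (1 - 0.38) ** 2
        fractions = []
        for rep in range(100):
            ann = generate_annotations(genes, map_genes_list, effects, seed=900 + rep)
            union = set(ann["OMIM"]) | set(ann["microarray"])
            fractions.append(len(union & set(map_genes_list)) / 166)
        se = np.sqrt(expected * (1 - expected) / (166 * 100))
        assert abs(np.mean(fractions) - expected) <= 3 * se


class TestDeterminismAndRoundtrip:
    def test_identical_seeds_byte_identical_files(self, tmp_path):
        spec = UniverseSpec(n_fly=120, n_mouse=160, n_human=160, seed=42)
        blobs = []
        for run in ("a", "b"):
            universe = generate_universe(spec)
            hits, lethal = generate_screen(universe, 30, 10, seed=42)
            edges = generate_interactions(universe, 1.5, seed=42)
            sets, _ = generate_genesets(
                universe.genes["fly"],
                PlantedEffects(n_sets=6, n_planted=2, set_size_range=(5, 15)),
                hits,
                seed=42,
            )
            ann = generate_annotations(universe.genes["fly"], hits, PlantedEffects(), seed=42)
            base = tmp_path / run
            base.mkdir()
            universe.tables["compara"].write(base / "orth.tsv")
            write_gene_list(hits, base / "hits.txt")
            write_tsv(edges, base / "edges.tsv")
            write_gmt(sets, base / "sets.gmt")
            write_annotations(ann, base / "ann.tsv")
            blobs.append(
                [p.read_bytes() for p in sorted(base.iterdir())]
            )
        assert blobs[0] == blobs[1]

    def test_generated_files_roundtrip_readers_losslessly(self, tmp_path):
        universe = generate_universe(UniverseSpec(n_fly=100, n_mouse=140, n_human=140, seed=8))
        hits, _ = generate_screen(universe, 25, 5, seed=8)
        sets, _ = generate_genesets(
            universe.genes["fly"],
            PlantedEffects(n_sets=4, n_planted=1, set_size_range=(5, 10)),
            hits,
            seed=8,
        )
        ann = generate_annotations(universe.genes["fly"], hits, PlantedEffects(), seed=8)

        write_gene_list(hits, tmp_path / "hits.txt", header=["prov line"])
        assert read_gene_list(tmp_path / "hits.txt") == hits
        write_gmt(sets, tmp_path / "sets.gmt", header=["prov line"])
        assert read_gmt(tmp_path / "sets.gmt") == sets
        write_annotations(ann, tmp_path / "ann.tsv", header=["prov line"])
        assert read_annotations(tmp_path / "ann.tsv") == {k: set(v) for k, v in ann.items()}


def test_assign_classes_round_robin_covers_all_sets():
    names = [f"s{i}" for i in range(10)]
    mapping = assign_classes(names, 3)
    assert set(mapping) == set(names)
    assert len(set(mapping.values())) == 3
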