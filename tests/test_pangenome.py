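import itertools

import numpy as np
import pytest

from panfba import (
    FunctionRules,
    GeneRecord,
    GenomeGeneSet,
    OrthologClusterSet,
    PanFixtureSpec,
    best_pangenome,
    build_pangenome,
    classify_functions,
    generate_pangenome_fixture,
    merge_augment,
    partition_categories,
    rbh_clusters,
)
from panfba.pangenome import (
    PangenomeInputError,
    read_clusters_tsv,
    read_gene_tables,
    write_pangenome_tsv,
)


def genome(gid, *genes, annotations=None):
    annotations = annotations or {}
    return GenomeGeneSet.from_records(
        gid, [GeneRecord(g, annotation=annotations.get(g, "")) for g in genes]
    )


class TestMergeAugment:
    def test_identical_genomes_fully_clustered_add_nothing(self):
        a = genome("A", "x", "y")
        b = genome("B", "x", "y")
        clusters = OrthologClusterSet(
            [frozenset({("A", "x"), ("B", "x")}), frozenset({("A", "y"), ("B", "y")})]
        )
        merged = merge_augment(a, b, clusters)
        assert set(merged.members) == set(a.members)

    def test_hand_enumerated_example(self):
        # base {a1,a2}, subject {b1,b2,b3}, cluster {a1,b1} -> {a1,a2,b2,b3}
        a = genome("A", "a1", "a2")
        b = genome("B", "b1", "b2", "b3")
        clusters = OrthologClusterSet([frozenset({("A", "a1"), ("B", "b1")})])
        merged = merge_augment(a, b, clusters)
        assert set(merged.members) == {
            ("A", "a1"), ("A", "a2"), ("B", "b2"), ("B", "b3"),
        }
        assert merged.constituents == ("A", "B")

    def test_idempotent_on_already_merged_genome(self):
        a = genome("A", "a1")
        b = genome("B", "b1", "b2")
        clusters = OrthologClusterSet([frozenset({("A", "a1"), ("B", "b1")})])
        once = merge_augment(a, b, clusters)
        twice = merge_augment(once, b, clusters)
        assert set(twice.members) == set(once.members)

    def test_gene_in_two_clusters_is_a_hard_error(self):
        with pytest.raises(PangenomeInputError, match="more than one cluster"):
            OrthologClusterSet(
                [frozenset({("A", "a1"), ("B", "b1")}),
                 frozenset({("A", "a1"), ("C", "c1")})]
            )

    def test_cluster_referencing_unknown_gene_is_an_error(self):
        a, b = genome("A", "a1"), genome("B", "b1")
        clusters = OrthologClusterSet([frozenset({("A", "ghost"), ("B", "b1")})])
        with pytest.raises(PangenomeInputError, match="unknown gene"):
            build_pangenome([a, b], clusters)


class TestBuildPangenome:
    def test_two_disjoint_single_gene_genomes(self):
        pan = build_pangenome(
            [genome("A", "a1"), genome("B", "b1")], OrthologClusterSet([])
        )
        assert partition_categories(pan) == (0, 0, 2)
        assert pan.n_genes == 2

    def test_planted_fixture_counts_are_recovered(self):
        genomes, clusters, expected = generate_pangenome_fixture(
            PanFixtureSpec(core=7, dispensable=4, unique=6, seed=11)
        )
        pan = build_pangenome(genomes, clusters)
        core, disp, uniq = partition_categories(pan)
        assert (core, disp, uniq) == (
            expected["core"], expected["dispensable"], expected["unique"]
        )

    def test_core_family_set_is_order_invariant(self):
        genomes, clusters, _ = generate_pangenome_fixture(
            PanFixtureSpec(core=5, dispensable=3, unique=4, seed=3)
        )
        by_id = {g.genome_id: g for g in genomes}
        cores = set()
        for order in itertools.permutations(sorted(by_id)):
            pan = build_pangenome([by_id[g] for g in order], clusters)
            cores.add(frozenset(pan.core_families()))
        assert len(cores) == 1

    def test_duplicate_genome_id_raises(self):
        with pytest.raises(PangenomeInputError, match="duplicate"):
            build_pangenome(
                [genome("A", "a1"), genome("A", "a2")], OrthologClusterSet([])
            )

    def test_adding_a_genome_never_increases_the_core(self):
        rng = np.random.default_rng(7)
        for seed in range(10):
            genomes, clusters, _ = generate_pangenome_fixture(
                PanFixtureSpec(
                    core=int(rng.integers(1, 8)),
                    dispensable=int(rng.integers(0, 6)),
                    unique=int(rng.integers(0, 6)),
                    seed=seed,
                )
            )
            pan_all = build_pangenome(genomes, clusters)
            subset = genomes[:3]
            kept = {g.genome_id for g in subset}
            sub_clusters = OrthologClusterSet([
                trimmed
                for cl in clusters.clusters
                if len(trimmed := frozenset(p for p in cl if p[0] in kept)) >= 2
            ])
            pan_fewer = build_pangenome(subset, sub_clusters)
            assert len(pan_all.core_families()) <= len(pan_fewer.core_families())


class TestBestPangenome:
    def test_tie_break_returns_lexicographically_first_order(self):
        a, b = genome("A", "x"), genome("B", "x")
        clusters = OrthologClusterSet([frozenset({("A", "x"), ("B", "x")})])
        pan = best_pangenome([b, a], clusters)
        assert pan.construction_order == ("A", "B")

    def test_order_dependent_counts_pick_the_maximum(self):
        # a co-ortholog cluster holding two paralogs of one genome makes the
        # gene count order-dependent: starting from A keeps both paralogs,
        # any other start collapses the cluster to one representative.
        a, b, c = genome("A", "a1", "a2"), genome("B", "b1"), genome("C", "c1")
        clusters = OrthologClusterSet(
            [frozenset({("A", "a1"), ("A", "a2"), ("B", "b1"), ("C", "c1")})]
        )
        lookup = {"A": a, "B": b, "C": c}
        sizes = {
            order: build_pangenome([lookup[g] for g in order], clusters).n_genes
            for order in itertools.permutations("ABC")
        }
        assert min(sizes.values()) < max(sizes.values())  # genuinely order-dependent
        pan = best_pangenome([a, b, c], clusters)
        assert pan.n_genes == max(sizes.values())

    def test_explicit_order_list_is_respected(self):
        a, b = genome("A", "a1"), genome("B", "b1")
        pan = best_pangenome([a, b], OrthologClusterSet([]), orders=[("B", "A")])
        assert pan.construction_order == ("B", "A")
        with pytest.raises(PangenomeInputError):
            best_pangenome([a, b], OrthologClusterSet([]), orders=[])


class TestPartitionAndClassification:
    def test_identical_genomes_are_all_core(self):
        names = [f"g{i}" for i in range(6)]
        genomes = [genome(gid, *names) for gid in "ABCD"]
        clusters = OrthologClusterSet(
            [frozenset({(gid, n) for gid in "ABCD"}) for n in names]
        )
        pan = build_pangenome(genomes, clusters)
        assert partition_categories(pan) == (6, 0, 0)

    def test_three_family_toy_partitions_one_each(self):
        genomes = [
            genome("A", "core", "pair", "only"),
            genome("B", "core", "pair"),
            genome("C", "core"),
            genome("D", "core"),
        ]
        clusters = OrthologClusterSet(
            [frozenset({(g, "core") for g in "ABCD"}),
             frozenset({("A", "pair"), ("B", "pair")})]
        )
        pan = build_pangenome(genomes, clusters)
        assert partition_categories(pan) == (1, 1, 1)
        counts = pan.counts()
        assert sum(counts.values()) == len(pan.families)

    def test_partition_sums_to_total_on_random_fixtures(self):
        for seed in range(20):
            spec = PanFixtureSpec(
                core=seed % 7, dispensable=(seed * 3) % 5, unique=(seed * 5) % 9,
                seed=seed,
            )
            genomes, clusters, expected = generate_pangenome_fixture(spec)
            if expected["total"] == 0:
                continue
            pan = build_pangenome(genomes, clusters)
            assert sum(partition_categories(pan)) == len(pan.families)

    def test_classification_rules(self):
        genomes = [
            genome("A", "rdh1", "tran1", "myst1",
                   annotations={"rdh1": "reductive dehalogenase subunit A",
                                "tran1": "IS4 family transposase"}),
            genome("B", "rdh1b", annotations={"rdh1b": "reductive dehalogenase"}),
        ]
        clusters = OrthologClusterSet([frozenset({("A", "rdh1"), ("B", "rdh1b")})])
        pan = build_pangenome(genomes, clusters)
        annotations = {
            pair: rec.annotation for g in genomes for pair, rec in g.members.items()
        }
        rules = FunctionRules(
            keywords=[("dehalogenase", "metabolic"), ("transposase", "non-metabolic")]
        )
        labelled = classify_functions(pan, rules, annotations=annotations)
        by_gene = {
            next(iter(sorted(f.members)))[1]: f.function_class
            for f in labelled.families
        }
        assert by_gene["rdh1"] == "metabolic"
        assert by_gene["tran1"] == "non-metabolic"
        assert by_gene["myst1"] == "hypothetical"  # no annotation -> hypothetical

    def test_explicit_lookup_overrides_keywords(self):
        genomes = [genome("A", "g1", annotations={"g1": "transposase"}),
                   genome("B", "h1")]
        pan = build_pangenome(genomes, OrthologClusterSet([]))
        rules = FunctionRules(keywords=[("transposase", "non-metabolic")],
                              explicit={"g1": "metabolic"})
        labelled = classify_functions(pan, rules)
        classes = {next(iter(f.members))[1]: f.function_class for f in labelled.families}
        assert classes["g1"] == "metabolic"

    def test_malformed_rule_table_raises(self):
        with pytest.raises(PangenomeInputError, match="invalid function class"):
            FunctionRules(keywords=[("x", "enzymatic")])


class TestRBHFallback:
    def test_reciprocal_best_hits_cluster_by_single_linkage(self):
        rows = [
            ("A", "a1", "B", "b1", 85.0), ("B", "b1", "A", "a1", 85.0),
            ("B", "b1", "C", "c1", 60.0), ("C", "c1", "B", "b1", 60.0),
            # below-threshold reciprocal pair
            ("A", "a2", "B", "b2", 22.0), ("B", "b2", "A", "a2", 22.0),
            # non-reciprocal: a3's best in B is b3, but b3 prefers a1
            ("A", "a3", "B", "b3", 70.0), ("B", "b3", "A", "a1", 70.0),
        ]
        clusters = rbh_clusters(rows, threshold=30.0)
        assert clusters.clusters == [
            frozenset({("A", "a1"), ("B", "b1"), ("C", "c1")})
        ]


class TestTableIO:
    def test_gene_and_cluster_tsv_round_trip(self, tmp_path):
        genomes, clusters, expected = generate_pangenome_fixture(
            PanFixtureSpec(core=3, dispensable=2, unique=2, seed=9)
        )
        import pandas as pd

        gene_rows = [
            {"genome_id": src, "gene_id": rec.gene_id,
             "locus_tag": rec.locus_tag, "annotation": rec.annotation}
            for g in genomes for (src, _), rec in g.members.items()
        ]
        genes_tsv = tmp_path / "genes.tsv"
        pd.DataFrame(gene_rows).to_csv(genes_tsv, sep="\t", index=False)
        cluster_rows = [
            {"cluster_id": f"c{i}", "genome_id": g, "gene_id": x}
            for i, cl in enumerate(clusters.clusters) for g, x in sorted(cl)
        ]
        clusters_tsv = tmp_path / "clusters.tsv"
        pd.DataFrame(cluster_rows).to_csv(clusters_tsv, sep="\t", index=False)

        pan = best_pangenome(read_gene_tables(genes_tsv), read_clusters_tsv(clusters_tsv))
        assert partition_categories(pan) == (
            expected["core"], expected["dispensable"], expected["unique"]
        )
        out = tmp_path / "pan.tsv"
        write_pangenome_tsv(pan, out)
        table = pd.read_csv(out, sep="\t")
        assert len(table) == len(pan.families)
        assert set(table["category"]) <= {"core", "dispensable", "unique"}
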