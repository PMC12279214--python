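"""Atlas construction: filtering, clustering, contig integration, pooling,
rarefaction, and the metagenome comparison statistic."""

import numpy as np
import pandas as pd
import pytest

import taxatlas as tx
from taxatlas.classify import AbundanceVector
from taxatlas.atlas import (
    annotate_clusters,
    build_matrix,
    clustering_error_rate,
    compare_to_metagenome,
    embed_and_cluster,
    filter_vectors,
    genome_coverage,
    integrate_contigs,
    pool_cluster_reads,
    rarefaction_coverage,
    subcluster,
)


def vec(a, mapped=1.0, rank="genus", barcode=""):
    return AbundanceVector(rank=rank, a=a, mapped_fraction=mapped, n_reads=1000,
                           barcode=barcode)


class TestFilterVectors:
    def test_purity_boundary_is_strict(self):
        vs = [vec({"A": p, "B": round(1 - p, 10)}) for p in (0.79, 0.80, 0.81)]
        kept = filter_vectors(vs, min_mapped_fraction=0.0, min_purity=0.80)
        assert [max(v.a.values()) for v in kept] == [0.81]

    def test_mapped_fraction_boundary_is_inclusive(self):
        vs = [vec({"A": 1.0}, mapped=m) for m in (0.49, 0.50, 0.51)]
        kept = filter_vectors(vs, min_mapped_fraction=0.50, min_purity=0.0)
        assert [v.mapped_fraction for v in kept] == [0.50, 0.51]

    def test_zero_thresholds_keep_all_nonempty(self):
        vs = [vec({"A": 1.0}), AbundanceVector(rank="genus"), vec({"B": 1.0})]
        kept = filter_vectors(vs, 0.0, 0.0)
        assert len(kept) == 2  # empty vector always removed

    def test_retention_monotone_in_purity_sweep(self, tda_replica):
        vectors = tda_replica["vectors"]
        sizes = [len(filter_vectors(vectors, 0.5, p))
                 for p in np.arange(0.5, 1.0, 0.05)]
        assert sizes == sorted(sizes, reverse=True)


class TestBuildMatrix:
    def test_union_and_zero_fill(self):
        m = build_matrix([vec({"A": 1.0}, barcode="b1"), vec({"B": 1.0}, barcode="b2")])
        assert list(m.columns) == ["A", "B"]
        np.testing.assert_array_equal(m.to_numpy(), [[1, 0], [0, 1]])

    def test_single_vector(self):
        m = build_matrix([vec({"A": 0.7, "B": 0.3}, barcode="b")])
        assert m.shape == (1, 2)
        assert m.loc["b", "A"] == 0.7

    def test_column_sums_conserve_components(self, tda_replica):
        retained = tda_replica["retained"]
        m = tda_replica["matrix"]
        for taxon in m.columns:
            expect = sum(v.a.get(taxon, 0.0) for v in retained)
            assert m[taxon].sum() == pytest.approx(expect)

    def test_mixed_ranks_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            build_matrix([vec({"A": 1.0}), vec({"B": 1.0}, rank="species")])


class TestEmbedAndCluster:
    def test_two_identical_blocks_give_two_clusters(self):
        vs = ([vec({"A": 1.0}, barcode=f"a{i}") for i in range(12)]
              + [vec({"B": 1.0}, barcode=f"b{i}") for i in range(12)])
        m = build_matrix(vs)
        result = embed_and_cluster(m, n_neighbors=5, seed=0)
        labels = result.table["cluster"]
        assert labels.nunique() == 2
        assert labels[[f"a{i}" for i in range(12)]].nunique() == 1
        assert labels[[f"b{i}" for i in range(12)]].nunique() == 1

    def test_deterministic_given_seed(self, tda_replica):
        m = tda_replica["matrix"]
        a = embed_and_cluster(m, seed=0)
        b = embed_and_cluster(m, seed=0)
        assert (a.table["cluster"] == b.table["cluster"]).all()
        np.testing.assert_array_equal(a.table[["x", "y"]], b.table[["x", "y"]])

    def test_small_input_reduces_neighbors_with_warning(self):
        vs = [vec({"A": 1.0}, barcode=f"r{i}") for i in range(4)]
        m = build_matrix(vs)
        with pytest.warns(UserWarning, match="reducing"):
            embed_and_cluster(m, n_neighbors=15, seed=0)

    def test_single_row_rejected(self):
        m = build_matrix([vec({"A": 1.0})])
        with pytest.raises(ValueError, match="at least 2"):
            embed_and_cluster(m, seed=0)

    def test_separable_simulation_recovers_truth(self, tda_replica):
        from taxatlas.pipeline import evaluate_against_truth

        report = evaluate_against_truth(
            tda_replica["atlas"], tda_replica["truth"], tda_replica["taxonomy"],
            tda_replica["taxids"])
        assert report["adjusted_rand"] >= 0.9
        assert report["annotation_accuracy"] >= 0.95


class TestAnnotation:
    def test_cluster_annotated_by_summed_argmax(self):
        vs = [vec({"A": 0.9, "B": 0.1}, barcode=f"r{i}") for i in range(6)]
        m = build_matrix(vs)
        result = embed_and_cluster(m, n_neighbors=3, seed=0)
        assert set(result.annotation.values()) == {"A"}

    def test_singleton_cluster_keeps_own_dominant(self):
        table = pd.DataFrame({"x": [0.0], "y": [0.0], "cluster": [0],
                              "batch": ["single_cell"]}, index=["b"])
        atlas = tx.AtlasResult(table=table)
        m = build_matrix([vec({"Z": 0.6, "A": 0.4}, barcode="b")])
        assert annotate_clusters(atlas, m) == {0: "Z"}

    def test_tie_breaks_lexicographically(self):
        table = pd.DataFrame({"x": [0, 0], "y": [0, 0], "cluster": [0, 0],
                              "batch": ["single_cell"] * 2}, index=["b1", "b2"])
        atlas = tx.AtlasResult(table=table)
        m = build_matrix([vec({"B": 1.0}, barcode="b1"), vec({"A": 1.0}, barcode="b2")])
        assert annotate_clusters(atlas, m) == {0: "A"}


class TestIntegrateContigs:
    def test_identical_contig_gets_matching_row_label(self, tda_replica):
        ref, matrix = tda_replica["atlas"], tda_replica["matrix"]
        row = matrix.index[0]
        contig = AbundanceVector(rank="genus", a=dict(matrix.loc[row][matrix.loc[row] > 0]),
                                 mapped_fraction=1.0, n_reads=1, barcode="contig_x")
        joint, _ = integrate_contigs(ref, matrix, [contig])
        assert joint.table.loc["contig_x", "cluster"] == ref.table.loc[row, "cluster"]
        assert joint.table.loc["contig_x", "batch"] == "contig"

    def test_low_purity_contig_excluded(self, tda_replica):
        contig = vec({"A": 0.85, "B": 0.15}, barcode="impure")
        joint, _ = integrate_contigs(tda_replica["atlas"], tda_replica["matrix"],
                                     [contig], min_contig_purity=0.90)
        assert "impure" not in joint.table.index

    def test_reference_labels_unchanged(self, tda_replica):
        ref, matrix = tda_replica["atlas"], tda_replica["matrix"]
        contigs = [vec({"genus_00": 1.0}, barcode=f"c{i}") for i in range(5)]
        joint, _ = integrate_contigs(ref, matrix, contigs)
        before = ref.table["cluster"]
        after = joint.table.loc[before.index, "cluster"]
        assert (before == after).all()

    def test_simulated_contigs_follow_source_cluster(self, tda_replica):
        community = tda_replica["community"]
        taxonomy = tda_replica["taxonomy"]
        index = tda_replica["index"]
        records, contig_truth = tx.simulate_contigs(community, 60, (5000, 5000), seed=55)
        from taxatlas.demux import BarcodeGroup

        vectors = []
        for cid, seq in records:
            group = BarcodeGroup(cid, [((cid, seq, "I" * len(seq)), (cid, "", ""))])
            vectors.append(tx.abundance_vector(group, index, taxonomy))
        joint, _ = integrate_contigs(tda_replica["atlas"], tda_replica["matrix"], vectors)
        truth_by_contig = contig_truth.set_index("contig_id")["source_id"]
        genus_of_source = {g.seq_id: taxonomy.name(taxonomy.ancestor_at_rank(g.taxid, "genus"))
                           for g in community.genomes}
        correct = 0
        placed = [c for c in truth_by_contig.index if c in joint.table.index]
        for cid in placed:
            cluster = int(joint.table.loc[cid, "cluster"])
            if joint.annotation.get(cluster) == genus_of_source[truth_by_contig[cid]]:
                correct += 1
        assert len(placed) >= 50
        assert correct / len(placed) >= 0.9

    def test_empty_reference_rejected(self, tda_replica):
        empty = pd.DataFrame()
        with pytest.raises(ValueError, match="empty reference"):
            integrate_contigs(tda_replica["atlas"], empty, [vec({"A": 1.0})])


class TestPooling:
    def test_pools_partition_retained_reads(self, tda_replica):
        atlas = tda_replica["atlas"]
        groups = {b: g for b, g in tda_replica["groups"].items()
                  if b in atlas.table.index}
        pools = pool_cluster_reads(groups, atlas)
        total = sum(len(p) for p in pools.values())
        assert total == 2 * sum(g.n_reads for g in groups.values())

    def test_error_free_separable_pool_has_zero_error_rate(self, toy_db):
        from taxatlas.demux import BarcodeGroup
        from taxatlas.dna import revcomp

        g = toy_db["community"].genomes[0]
        reads = []
        for i in range(50):
            frag = g.sequence[i * 40 : i * 40 + 300]
            reads.append((f"r{i}/1", frag[:150], "I" * 150))
            reads.append((f"r{i}/2", revcomp(frag)[:150], "I" * 150))
        assert clustering_error_rate(reads, (g.seq_id, g.sequence)) == 0.0

    def test_injected_foreign_reads_raise_error_rate(self, toy_db):
        from taxatlas.dna import revcomp

        g0 = toy_db["community"].genomes[0]
        g1 = toy_db["community"].genomes[1]
        reads = []
        for i in range(190):
            start = (i * 37) % (len(g0.sequence) - 150)
            reads.append((f"ok{i}", g0.sequence[start : start + 150], "I" * 150))
        for i in range(10):  # 5% foreign
            start = (i * 53) % (len(g1.sequence) - 150)
            reads.append((f"bad{i}", g1.sequence[start : start + 150], "I" * 150))
        rate = clustering_error_rate(reads, (g0.seq_id, g0.sequence))
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_empty_pool_returns_none(self, toy_db):
        g = toy_db["community"].genomes[0]
        assert clustering_error_rate([], (g.seq_id, g.sequence)) is None


class TestSubcluster:
    def test_two_species_one_genus_split_at_species_rank(self):
        # one genus-level cluster hiding two species
        sp = ([vec({"s1": 1.0}, rank="species", barcode=f"x{i}") for i in range(10)]
              + [vec({"s2": 1.0}, rank="species", barcode=f"y{i}") for i in range(10)])
        species_matrix = build_matrix(sp)
        table = pd.DataFrame({"x": 0.0, "y": 0.0, "cluster": 0,
                              "batch": "single_cell"}, index=species_matrix.index)
        atlas = tx.AtlasResult(table=table)
        result = subcluster(atlas, species_matrix, 0, n_neighbors=5, seed=0)
        labels = result.table["cluster"]
        assert labels.nunique() == 2
        assert set(result.table.index) == set(species_matrix.index)  # partition
        assert labels[[f"x{i}" for i in range(10)]].nunique() == 1

    def test_too_small_cluster_rejected(self):
        m = build_matrix([vec({"s1": 1.0}, rank="species", barcode="only")])
        table = pd.DataFrame({"x": [0.0], "y": [0.0], "cluster": [0],
                              "batch": ["single_cell"]}, index=["only"])
        with pytest.raises(ValueError, match="fewer than 2"):
            subcluster(tx.AtlasResult(table=table), m, 0)


class TestCoverage:
    def test_single_read_arithmetic(self):
        assert genome_coverage(np.array([[0, 150]]), 10000) == pytest.approx(0.015)

    def test_tiled_reads_reach_full_coverage(self):
        intervals = np.array([[i, i + 150] for i in range(0, 10000 - 149, 50)])
        assert genome_coverage(intervals, 10000) == 1.0

    def test_rarefaction_matches_brute_force_union(self):
        rng = np.random.default_rng(91)
        starts = rng.integers(0, 9850, size=200)
        intervals = np.stack([starts, starts + 150], axis=1)
        curve = rarefaction_coverage(intervals, 10000, step_reads=25, seed=7)
        # brute force: replay the same permutation and recompute each prefix
        order = np.random.default_rng(7).permutation(200)
        for _, row in curve.iterrows():
            chosen = intervals[order[: int(row.n_reads)]]
            covered = np.zeros(10000, dtype=bool)
            for s, e in chosen:
                covered[s:e] = True
            assert row.coverage == pytest.approx(covered.mean())

    def test_rarefaction_monotone(self):
        rng = np.random.default_rng(92)
        starts = rng.integers(0, 5000, size=300)
        intervals = np.stack([starts, starts + 100], axis=1)
        curve = rarefaction_coverage(intervals, 5100, step_reads=30, seed=8)
        assert (np.diff(curve.coverage) >= 0).all()

    def test_out_of_range_intervals_rejected(self):
        with pytest.raises(ValueError):
            genome_coverage(np.array([[9990, 10050]]), 10000)


class TestMetagenomeComparison:
    def test_identical_profiles_correlate_perfectly(self):
        a = {"x": 10.0, "y": 20.0, "z": 5.0}
        r, _ = compare_to_metagenome(a, dict(a))
        assert r == pytest.approx(1.0)

    def test_anti_ranked_three_taxa(self):
        r, _ = compare_to_metagenome({"a": 1, "b": 2, "c": 3}, {"a": 3, "b": 2, "c": 1})
        assert r == pytest.approx(-1.0)

    def test_too_few_shared_taxa_warns_and_returns_none(self):
        with pytest.warns(UserWarning, match="shared taxa"):
            r, table = compare_to_metagenome({"a": 1, "b": 2}, {"a": 1, "c": 4})
        assert r is None
        assert set(table.index) == {"a", "b", "c"}

    def test_exclusion_list_applied(self):
        a = {"x": 1.0, "y": 2.0, "z": 3.0, "w": 4.0}
        b = {"x": 1.0, "y": 2.0, "z": 3.0, "w": 0.1}
        r_all, _ = compare_to_metagenome(a, b)
        r_excl, table = compare_to_metagenome(a, b, exclude={"w"})
        assert "w" not in table.index
        assert r_excl == pytest.approx(1.0)
        assert r_all < r_excl

    def test_matched_community_sampled_two_ways(self):
        """Two independent samplings of one uneven community (cell counts vs
        assembled-contig counts) must correlate strongly."""
        base, _ = tx.make_community(6, 5000, seed=94)
        abundances = [0.3, 0.25, 0.2, 0.15, 0.07, 0.03]
        community = tx.CommunitySpec(list(zip(base.genomes, abundances)))
        rng = np.random.default_rng(95)
        cells = rng.multinomial(600, abundances)
        single_cell = {g.seq_id: float(n) for g, n in zip(base.genomes, cells)}
        _, truth = tx.simulate_contigs(community, 600, (2000, 4000), seed=96)
        meta = truth.source_id.value_counts().to_dict()
        r, _ = compare_to_metagenome(single_cell,
                                     {k: float(v) for k, v in meta.items()})
        assert r >= 0.9
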