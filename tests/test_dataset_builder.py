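"""Encoders, neighbourhood-graph assembly, splits, and the leakage filter."""

import numpy as np
import pytest

from csnn.chem_encoding import tanimoto_cross
from csnn.csn_graph import query_neighbours
from csnn.dataset_builder import (BioactivityClassScheme,
                                  RandomProjectionCompoundEncoder,
                                  SeededReceptorEncoder, TableReceptorEncoder,
                                  audit_split, build_graph_multi,
                                  build_graph_single,
                                  compute_dense_representation,
                                  compute_target_embedding, iid_split,
                                  leakage_filter, murcko_scaffold,
                                  read_dataset, restrict_neighbours,
                                  scaffold_split, write_dataset)
from tests.conftest import make_graphs
from tests.test_csn_graph import make_record, random_library


class TestEncoders:
    def test_compound_encoder_deterministic_and_full_width(self, small_space):
        enc = RandomProjectionCompoundEncoder(seed=4)
        v1 = compute_dense_representation(small_space.compounds[0], enc)
        v2 = compute_dense_representation(small_space.compounds[0], enc)
        assert v1.shape == (300,)
        assert (v1 == v2).all()
        assert np.isfinite(v1).all()

    def test_distinct_fingerprints_distinct_vectors(self, small_space):
        enc = RandomProjectionCompoundEncoder(dim=32, seed=4)
        vecs = [enc.encode(r) for r in small_space.compounds[:10]]
        for i in range(10):
            for j in range(i + 1, 10):
                assert not np.allclose(vecs[i], vecs[j])

    def test_receptor_encoder_deterministic_and_full_width(self):
        enc = SeededReceptorEncoder(seed=1)
        v1 = compute_target_embedding("R001", enc)
        assert v1.shape == (320,)
        assert (v1 == compute_target_embedding("R001", enc)).all()
        assert not np.allclose(v1, compute_target_embedding("R002", enc))

    def test_unknown_receptor_raises(self):
        enc = SeededReceptorEncoder(known=["R001"])
        with pytest.raises(KeyError):
            enc.encode("R999")

    def test_table_receptor_encoder(self, tmp_path):
        path = tmp_path / "emb.csv"
        path.write_text("receptor_id,p0,p1\nR1,0.5,-1.0\n")
        enc = TableReceptorEncoder(path)
        assert enc.encode("R1") == pytest.approx([0.5, -1.0])
        with pytest.raises(KeyError):
            enc.encode("R2")


class TestBuildGraphSingle:
    def test_edge_width_and_one_hot(self, single_graphs, small_csn):
        withedges = [g for g in single_graphs if g.n_edges > 0]
        assert withedges
        for g in withedges[:20]:
            assert g.edge_features.shape[1] == 7
            onehot = g.edge_features[:, :6]
            assert (onehot.sum(axis=1) == 1).all()
            # similarity column equals the stored network weight
            qi = small_csn.index_of(g.query_id)
            for e in range(g.n_edges):
                ni = small_csn.index_of(g.node_ids[1 + e])
                assert g.edge_features[e, 6] == pytest.approx(
                    small_csn.adjacency[qi, ni])

    def test_zero_labelled_neighbours_is_valid_ood(self, small_space,
                                                   compound_lookup, scheme,
                                                   encoders, small_csn):
        enc, renc = encoders
        q = small_space.compounds[0]
        nq = query_neighbours(small_csn, q.compound_id)
        g = build_graph_single(q, "R000", nq, {}, compound_lookup, scheme,
                               enc, renc)
        assert g.is_ood
        assert g.node_features.shape[0] == 1
        assert (g.laf_vector == 0).all()

    def test_label_one_hot_and_laf_distribution(self, single_graphs):
        for g in single_graphs[:20]:
            assert g.label is not None and g.label.sum() == 1
            if g.n_edges:
                assert g.laf_vector.sum() == pytest.approx(1.0)

    def test_edges_point_at_query(self, single_graphs):
        for g in single_graphs[:20]:
            assert (g.edge_src == np.arange(1, g.n_edges + 1)).all()


class TestBuildGraphMulti:
    def test_edge_width_blocks(self, multi_graphs, small_space):
        width = 7 * small_space.spec.n_receptors
        for g in multi_graphs[:20]:
            if g.n_edges:
                assert g.edge_features.shape[1] == width
                blocks = g.edge_features.reshape(g.n_edges, -1, 7)
                assert (blocks.sum(axis=2) == 1).all()

    def test_no_data_blocks_count(self, multi_graphs, small_space):
        nd = small_space.spec.n_classes  # no-data index
        labels_by_r = small_space.labels_by_receptor()
        g = next(g for g in multi_graphs if g.n_edges)
        blocks = g.edge_features.reshape(g.n_edges, -1, 7)
        for e in range(g.n_edges):
            cid = g.node_ids[1 + e]
            n_labelled = sum(cid in labels_by_r[r]
                             for r in small_space.receptor_ids)
            assert (blocks[e].argmax(axis=1) == nd).sum() == \
                small_space.spec.n_receptors - n_labelled

    def test_label_vector_with_no_data_markers(self, multi_graphs, small_space):
        labels_by_r = small_space.labels_by_receptor()
        for g in multi_graphs[:20]:
            for ri, rid in enumerate(small_space.receptor_ids):
                expected = labels_by_r[rid].get(g.query_id,
                                                small_space.spec.n_classes)
                assert g.label[ri] == expected

    def test_consistent_with_single_mode(self, single_graphs, multi_graphs):
        """Same query: node features and similarity columns agree."""
        multi_by_id = {g.query_id: g for g in multi_graphs}
        for g in single_graphs[:10]:
            m = multi_by_id[g.query_id]
            assert np.allclose(g.node_features[0], m.node_features[0])
            # single-mode neighbours are a subset of multi-mode neighbours
            msims = dict(zip(m.node_ids[1:], m.similarities))
            for cid, s in zip(g.node_ids[1:], g.similarities):
                assert msims[cid] == pytest.approx(s)


class TestSplits:
    def test_single_scaffold_all_train(self):
        df = scaffold_split(["a", "b", "c"], groups={"a": 0, "b": 0, "c": 0})
        assert (df["partition"] == "train").all()

    def test_ten_equal_scaffolds_8_1_1(self):
        ids = [f"c{g}{i}" for g in range(10) for i in range(5)]
        groups = {cid: cid[1] for cid in ids}
        df = scaffold_split(ids, seed=3, groups=groups)
        by_part = df.groupby("partition")["scaffold_id"].nunique()
        assert by_part["train"] == 8
        assert by_part["test"] == 1
        assert by_part["val"] == 1

    def test_scaffold_never_in_two_partitions(self, small_space):
        ids = list(small_space.cluster_of)
        df = scaffold_split(ids, seed=0, groups=small_space.scaffold_of)
        counts = df.groupby("scaffold_id")["partition"].nunique()
        assert (counts == 1).all()

    def test_deterministic_under_seed(self, small_space):
        ids = list(small_space.cluster_of)
        a = scaffold_split(ids, seed=5, groups=small_space.scaffold_of)
        b = scaffold_split(ids, seed=5, groups=small_space.scaffold_of)
        assert a.equals(b)

    def test_murcko_groups_from_smiles(self):
        smiles = {"benzo": "c1ccccc1CCN", "benzo2": "c1ccccc1CCC(=O)O",
                  "chain": "CCCCO"}
        df = scaffold_split(list(smiles), smiles=smiles)
        groups = dict(zip(df["compound_id"], df["scaffold_id"]))
        assert groups["benzo"] == groups["benzo2"]  # same ring system
        assert groups["chain"] != groups["benzo"]

    def test_murcko_scaffold_values(self):
        assert murcko_scaffold("c1ccccc1CCN") == "c1ccccc1"
        assert murcko_scaffold("CCCC") == ""  # acyclic

    def test_iid_fractions(self):
        ids = [f"c{i}" for i in range(100)]
        df = iid_split(ids, seed=1)
        counts = df["partition"].value_counts()
        assert counts["train"] == 80
        assert counts["test"] == 10
        assert counts["val"] == 10


class TestLeakageFilter:
    def test_boundary_and_removal(self):
        held = [make_record("h", [1] * 13 + [0] * 7)]
        near = make_record("near", [1] * 14 + [0] * 6)   # T = 13/14 > 0.65
        at = make_record("at", [1] * 20)                 # T = 13/20 = 0.65
        far = make_record("far", [0] * 13 + [1] * 7)
        kept, removed = leakage_filter([near, at, far], held, 0.65)
        assert removed == ["near"]
        assert [r.compound_id for r in kept] == ["at", "far"]

    def test_post_filter_cross_similarity_bounded(self):
        dataset = random_library(60, seed=21)
        held = random_library(10, n_bits=128, density=0.3, seed=22)
        kept, _ = leakage_filter(dataset, held, 0.65)
        if kept:
            sims = tanimoto_cross(
                np.stack([r.fingerprint for r in kept]),
                np.stack([r.fingerprint for r in held]))
            assert sims.max() <= 0.65


class TestSplitPolicy:
    def test_restrict_drops_query_and_outsiders(self):
        from csnn.csn_graph import NeighbourQuery
        nq = NeighbourQuery("q", [("q", 1.0), ("a", 0.9), ("b", 0.8)])
        out = restrict_neighbours(nq, allowed_ids={"a"})
        assert out.ids == ["a"]

    def test_full_split_audit_clean(self, small_space, small_csn,
                                    compound_lookup, scheme, encoders):
        """Eval-mode graphs for test queries draw only train neighbours."""
        enc, renc = encoders
        ids = list(small_space.cluster_of)
        assignment = scaffold_split(ids, seed=0,
                                    groups=small_space.scaffold_of)
        part = dict(zip(assignment["compound_id"], assignment["partition"]))
        train_ids = {c for c, p in part.items() if p == "train"}
        labels = small_space.labels_for("R000")
        graphs = []
        for cid in sorted(labels):
            if part[cid] == "val":
                continue
            allowed = train_ids  # train refer to train; test refer to train
            nq = restrict_neighbours(
                query_neighbours(small_csn, cid, max_neighbours=None),
                allowed_ids=allowed - {cid}, cap=40)
            graphs.append(build_graph_single(
                compound_lookup[cid], "R000", nq, labels, compound_lookup,
                scheme, enc, renc))
        assert audit_split(graphs, assignment, mode="eval") == []

    def test_audit_flags_violation(self, small_space, small_csn,
                                   compound_lookup, scheme, encoders):
        enc, renc = encoders
        ids = list(small_space.cluster_of)
        assignment = scaffold_split(ids, seed=0,
                                    groups=small_space.scaffold_of)
        part = dict(zip(assignment["compound_id"], assignment["partition"]))
        test_ids = [c for c, p in part.items() if p == "test"]
        labels = small_space.labels_for("R000")
        # deliberately unrestricted neighbours for a test query
        victims = [c for c in test_ids if c in labels]
        if not victims:
            pytest.skip("no labelled test queries in this fixture")
        cid = victims[0]
        nq = restrict_neighbours(
            query_neighbours(small_csn, cid, max_neighbours=None), cap=40)
        g = build_graph_single(compound_lookup[cid], "R000", nq, labels,
                               compound_lookup, scheme, enc, renc)
        if g.n_edges == 0:
            pytest.skip("query has no labelled neighbours at all")
        assert audit_split([g], assignment, mode="eval") != []


class TestSerialization:
    def test_round_trip_bit_identical(self, tmp_path, single_graphs,
                                      multi_graphs):
        graphs = single_graphs[:5] + multi_graphs[:5]
        path = tmp_path / "ds.npz"
        write_dataset(graphs, path)
        back = read_dataset(path)
        assert len(back) == len(graphs)
        for orig, rec in zip(graphs, back):
            assert rec.query_id == orig.query_id
            assert rec.node_ids == orig.node_ids
            assert rec.mode == orig.mode
            assert (rec.node_features == orig.node_features).all()
            assert (rec.edge_features == orig.edge_features).all()
            assert (rec.similarities == orig.similarities).all()
            assert (rec.laf_vector == orig.laf_vector).all()
            if orig.target_embedding is not None:
                assert (rec.target_embedding == orig.target_embedding).all()
            if orig.label is not None:
                assert (rec.label == orig.label).all()
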