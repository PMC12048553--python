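"""Shared fixtures: small synthetic spaces, networks, and model graphs."""

import numpy as np
import pytest

from csnn.csn_graph import build_csn, query_neighbours
from csnn.dataset_builder import (BioactivityClassScheme,
                                  RandomProjectionCompoundEncoder,
                                  SeededReceptorEncoder, build_graph_multi,
                                  build_graph_single, restrict_neighbours)
from csnn.synthetic_data import SyntheticSpec, generate_space


@pytest.fixture(scope="session")
def small_space():
    """Homophilous space: 6 clusters x 8 compounds, 4 receptors."""
    return generate_space(SyntheticSpec(
        n_clusters=6, compounds_per_cluster=8, n_receptors=4,
        homophily=0.9, label_sparsity=0.3, seed=11))


@pytest.fixture(scope="session")
def small_csn(small_space):
    return build_csn(small_space.compounds)


@pytest.fixture(scope="session")
def compound_lookup(small_space):
    return {r.compound_id: r for r in small_space.compounds}


@pytest.fixture(scope="session")
def scheme():
    return BioactivityClassScheme()


@pytest.fixture(scope="session")
def encoders():
    """(compound encoder, receptor encoder) at reduced toy dimensions."""
    return (RandomProjectionCompoundEncoder(dim=24, seed=7),
            SeededReceptorEncoder(dim=12, seed=7))


def make_graphs(space, csn, lookup, scheme, enc, renc, mode="single",
                receptor_ids=None, labelled_only=True):
    """Build neighbourhood graphs for every labelled query."""
    receptor_ids = receptor_ids or space.receptor_ids
    labels_by_r = space.labels_by_receptor()
    graphs = []
    if mode == "single":
        for rid in receptor_ids:
            labels = labels_by_r[rid]
            for cid in sorted(labels):
                nq = restrict_neighbours(
                    query_neighbours(csn, cid, max_neighbours=None), cap=40)
                graphs.append(build_graph_single(
                    lookup[cid], rid, nq, labels, lookup, scheme, enc, renc))
    else:
        queried = sorted({c for d in labels_by_r.values() for c in d}
                         if labelled_only else lookup)
        for cid in queried:
            nq = restrict_neighbours(
                query_neighbours(csn, cid, max_neighbours=None), cap=40)
            graphs.append(build_graph_multi(
                lookup[cid], nq, labels_by_r, receptor_ids, lookup,
                scheme, enc))
    return graphs


@pytest.fixture(scope="session")
def single_graphs(small_space, small_csn, compound_lookup, scheme, encoders):
    enc, renc = encoders
    return make_graphs(small_space, small_csn, compound_lookup, scheme,
                       enc, renc, mode="single")


@pytest.fixture(scope="session")
def multi_graphs(small_space, small_csn, compound_lookup, scheme, encoders):
    enc, renc = encoders
    return make_graphs(small_space, small_csn, compound_lookup, scheme,
                       enc, renc, mode="multi")
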