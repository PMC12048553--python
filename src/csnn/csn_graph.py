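"""Sparse thresholded chemical space networks and neighbourhood queries.

The chemical space network (CSN) connects every pair of compounds whose
Tanimoto similarity strictly exceeds a threshold ``epsilon_sim`` (default
0.4); weights below or equal to the threshold are dropped to keep the
adjacency sparse. The graph is undirected (both directions of each edge are
stored), has no self-loops, and answers one-hop ranked neighbour lookups
(capped, default 40), n-hop reachability queries, and external one-vs-all
scans for compounds outside the network.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from csnn.chem_encoding import CompoundRecord, tanimoto_matrix, tanimoto_cross

__all__ = [
    "ChemicalSpaceNetwork",
    "NeighbourQuery",
    "build_csn",
    "query_neighbours",
    "query_external",
    "write_csn",
    "read_csn",
]

DEFAULT_EPSILON = 0.4
DEFAULT_MAX_NEIGHBOURS = 40


@dataclass
class NeighbourQuery:
    """Ranked neighbourhood of one query compound.

    ``neighbours`` is a list of (compound_id, similarity) sorted by
    descending similarity, ties broken by ascending compound id, truncated
    to ``max_neighbours``. For multi-hop queries the similarity entry is the
    direct-edge weight where one exists and NaN for nodes reached only
    through intermediates.
    """

    query_id: str
    neighbours: list[tuple[str, float]]
    hops: int = 1
    max_neighbours: int = DEFAULT_MAX_NEIGHBOURS

    @property
    def ids(self) -> list[str]:
        return [cid for cid, _ in self.neighbours]

    def __len__(self) -> int:
        return len(self.neighbours)


@dataclass
class ChemicalSpaceNetwork:
    """epsilon-thresholded Tanimoto similarity graph over a compound library."""

    node_ids: list[str]
    adjacency: sp.csr_matrix  # symmetric, zero diagonal, weights > epsilon_sim
    epsilon_sim: float = DEFAULT_EPSILON

    def __post_init__(self):
        self._index = {cid: i for i, cid in enumerate(self.node_ids)}

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._index

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return self.adjacency.nnz // 2

    def index_of(self, compound_id: str) -> int:
        try:
            return self._index[compound_id]
        except KeyError:
            raise KeyError(f"compound {compound_id!r} not in network") from None

    def edge_table(self) -> pd.DataFrame:
        """Undirected edge list (id_i, id_j, similarity), i < j by node order."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return pd.DataFrame({
            "id_i": [self.node_ids[i] for i in coo.row],
            "id_j": [self.node_ids[j] for j in coo.col],
            "similarity": coo.data,
        })


def build_csn(library: Sequence[CompoundRecord],
              epsilon_sim: float = DEFAULT_EPSILON) -> ChemicalSpaceNetwork:
    """Build the all-vs-all Tanimoto network over a compound library.

    Keeps exactly the pairs with similarity strictly greater than
    ``epsilon_sim``. Deterministic; duplicate compound ids are rejected.
    """
    if not library:
        raise ValueError("library is empty")
    ids = [r.compound_id for r in library]
    seen, dups = set(), []
    for cid in ids:
        if cid in seen:
            dups.append(cid)
        seen.add(cid)
    if dups:
        raise ValueError(f"duplicate compound ids: {sorted(set(dups))}")
    packed = np.stack([r.fingerprint for r in library])
    sim = tanimoto_matrix(packed)
    np.fill_diagonal(sim, 0.0)
    sim[sim <= epsilon_sim] = 0.0
    adj = sp.csr_matrix(sim)
    adj.eliminate_zeros()
    return ChemicalSpaceNetwork(node_ids=ids, adjacency=adj,
                                epsilon_sim=epsilon_sim)


def _rank_neighbours(ids: Sequence[str], sims: Sequence[float],
                     cap: Optional[int]) -> list[tuple[str, float]]:
    # descending similarity, ties by ascending compound id
    order = sorted(range(len(ids)), key=lambda k: (-sims[k], ids[k]))
    if cap is not None:
        order = order[:cap]
    return [(ids[k], float(sims[k])) for k in order]


def query_neighbours(csn: ChemicalSpaceNetwork, query_id: str,
                     hops: int = 1,
                     max_neighbours: Optional[int] = DEFAULT_MAX_NEIGHBOURS
                     ) -> NeighbourQuery:
    """Neighbours of a member compound within ``hops`` graph steps.

    One-hop queries return direct neighbours ranked by similarity and capped.
    Multi-hop queries (used for visualisation and leakage scans, not as
    model input) return every node within graph distance ``hops``; nodes
    without a direct edge to the query carry similarity NaN and rank after
    direct neighbours.
    """
    if hops < 1:
        raise ValueError("hops must be >= 1")
    qi = csn.index_of(query_id)
    indptr, indices, data = (csn.adjacency.indptr, csn.adjacency.indices,
                             csn.adjacency.data)

    direct = {int(j): float(w) for j, w in
              zip(indices[indptr[qi]:indptr[qi + 1]],
                  data[indptr[qi]:indptr[qi + 1]])}
    if hops == 1:
        reach = set(direct)
    else:
        # plain BFS out to the hop limit
        reach = set()
        frontier = deque([(qi, 0)])
        seen = {qi}
        while frontier:
            node, d = frontier.popleft()
            if d == hops:
                continue
            for j in indices[indptr[node]:indptr[node + 1]]:
                j = int(j)
                if j not in seen:
                    seen.add(j)
                    reach.add(j)
                    frontier.append((j, d + 1))
    ids = [csn.node_ids[j] for j in sorted(reach)]
    sims = [direct.get(j, float("nan")) for j in sorted(reach)]
    # NaN similarity sorts after any real similarity
    order = sorted(range(len(ids)),
                   key=lambda k: (not np.isfinite(sims[k]) and 1 or 0,
                                  -(sims[k] if np.isfinite(sims[k]) else 0.0),
                                  ids[k]))
    if max_neighbours is not None:
        order = order[:max_neighbours]
    return NeighbourQuery(
        query_id=query_id,
        neighbours=[(ids[k], sims[k]) for k in order],
        hops=hops,
        max_neighbours=max_neighbours if max_neighbours is not None else -1)


def query_external(csn: ChemicalSpaceNetwork, query: CompoundRecord,
                   library: Sequence[CompoundRecord],
                   max_neighbours: Optional[int] = DEFAULT_MAX_NEIGHBOURS
                   ) -> NeighbourQuery:
    """One-vs-all inference-time lookup for a compound not (necessarily) in
    the network.

    Scans the query fingerprint against every member, applies the network's
    similarity threshold and the neighbour cap. An empty result is the
    out-of-distribution guard: no neighbourhood, no prediction.
    """
    packed = np.stack([r.fingerprint for r in library])
    sims = tanimoto_cross(query.fingerprint[None, :], packed)[0]
    keep = [(library[k].compound_id, float(sims[k]))
            for k in range(len(library))
            if sims[k] > csn.epsilon_sim
            and library[k].compound_id != query.compound_id]
    ranked = _rank_neighbours([c for c, _ in keep], [s for _, s in keep],
                              max_neighbours)
    return NeighbourQuery(query_id=query.compound_id, neighbours=ranked,
                          hops=1,
                          max_neighbours=max_neighbours if max_neighbours is not None else -1)


_CSN_FORMAT_VERSION = 1


def write_csn(csn: ChemicalSpaceNetwork, out_dir,
              extra_meta: Optional[dict] = None) -> None:
    """Serialize as an undirected triplet table plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # %.17g keeps the float64 weights exact through the text round trip
    csn.edge_table().to_csv(out / "edges.csv", index=False,
                            float_format="%.17g")
    pd.DataFrame({"compound_id": csn.node_ids}).to_csv(
        out / "nodes.csv", index=False)
    meta = {"format_version": _CSN_FORMAT_VERSION,
            "epsilon_sim": csn.epsilon_sim,
            "n_nodes": csn.n_nodes, "n_edges": csn.n_edges}
    if extra_meta:
        meta.update(extra_meta)
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def read_csn(in_dir) -> ChemicalSpaceNetwork:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    node_ids = pd.read_csv(src / "nodes.csv")["compound_id"].astype(str).tolist()
    index = {cid: i for i, cid in enumerate(node_ids)}
    edges = pd.read_csv(src / "edges.csv", float_precision="round_trip")
    n = len(node_ids)
    if len(edges):
        rows = edges["id_i"].astype(str).map(index).to_numpy()
        cols = edges["id_j"].astype(str).map(index).to_numpy()
        w = edges["similarity"].to_numpy()
        adj = sp.coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
            shape=(n, n)).tocsr()
    else:
        adj = sp.csr_matrix((n, n))
    return ChemicalSpaceNetwork(node_ids=node_ids, adjacency=adj,
                                epsilon_sim=float(meta["epsilon_sim"]))
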