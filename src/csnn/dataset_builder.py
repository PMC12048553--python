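"""Per-query neighbourhood graphs, pluggable encoders, and data splits.

Each labelled (compound, receptor) pair becomes a one-hop star graph: the
query node plus its labelled chemical neighbours, every edge directed at the
query, with the neighbour's bioactivity label one-hot encoded in the edge
features next to the Tanimoto similarity (labels as features). Node features
are dense compound representations (length 300), receptors are embedded as
fixed vectors (length 320). Both encoders are pluggable interfaces with
deterministic seeded stand-ins plus file-backed tables, so externally
computed representations can be dropped in without touching the graph code.

Splitting supports scaffold-grouped and i.i.d. record-level partitions, a
cross-set Tanimoto leakage filter, and the transductive neighbour policy:
during evaluation, test/validation queries may only see training compounds
as neighbours, and a query's own label never appears among its edges.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from csnn.chem_encoding import (CompoundRecord, tanimoto_cross, unpack_bits)
from csnn.csn_graph import (ChemicalSpaceNetwork, NeighbourQuery,
                            query_neighbours, DEFAULT_MAX_NEIGHBOURS)
from csnn.laf_inference import LabelFrequencyVector

__all__ = [
    "BioactivityClassScheme",
    "NeighbourhoodGraph",
    "RandomProjectionCompoundEncoder",
    "TableCompoundEncoder",
    "SeededReceptorEncoder",
    "TableReceptorEncoder",
    "compute_dense_representation",
    "compute_target_embedding",
    "restrict_neighbours",
    "build_graph_single",
    "build_graph_multi",
    "murcko_scaffold",
    "scaffold_split",
    "iid_split",
    "leakage_filter",
    "audit_split",
    "write_dataset",
    "read_dataset",
]

DENSE_DIM = 300
TARGET_DIM = 320
DEFAULT_CLASS_NAMES = ("Agonist", "Partial Agonist", "Antagonist",
                       "Inverse Agonist", "Allosteric Modulator", "No Effect")


@dataclass(frozen=True)
class BioactivityClassScheme:
    """Ordered bioactivity classes plus the reserved no-data index used by
    the multi-receptor encoding (index == number of classes)."""

    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self):
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def no_data_index(self) -> int:
        return self.n_classes

    def index_of(self, name: str) -> int:
        try:
            return self.class_names.index(name)
        except ValueError:
            raise ValueError(f"unknown bioactivity class {name!r}; "
                             f"known: {list(self.class_names)}") from None


@dataclass
class NeighbourhoodGraph:
    """One-hop directed star graph feeding the neighbourhood models.

    Node 0 is the query; every edge points from a neighbour node to the
    query. ``edge_features`` has width n_classes+1 in single-receptor mode
    (one-hot class + similarity) or n_receptors*(n_classes+1) in
    multi-receptor mode. ``laf_vector`` is the normalised neighbourhood
    label-frequency skip connection. A graph with zero edges is a valid
    single-node graph flagged out-of-distribution.
    """

    query_id: str
    node_ids: list[str]
    node_features: np.ndarray            # |V| x 300
    edge_src: np.ndarray                 # neighbour node index per edge
    edge_features: np.ndarray            # |E| x width
    similarities: np.ndarray             # |E|
    laf_vector: np.ndarray               # skip connection (e_tot)
    mode: str                            # "single" | "multi"
    receptor_id: Optional[str] = None
    target_embedding: Optional[np.ndarray] = None  # 320 (single mode)
    label: Optional[np.ndarray] = None   # one-hot (single) / int vector (multi)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    @property
    def is_ood(self) -> bool:
        return self.n_edges == 0


# ---------------------------------------------------------------------------
# Encoders


class RandomProjectionCompoundEncoder:
    """Deterministic stand-in compound encoder.

    Projects the unpacked fingerprint bits through a seeded Gaussian matrix
    to ``dim`` dimensions (scaled by 1/sqrt(n_bits)). A fixed seed gives the
    same vector for the same compound, always.
    """

    def __init__(self, dim: int = DENSE_DIM, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._mats: dict[int, np.ndarray] = {}

    def _matrix(self, n_bits: int) -> np.ndarray:
        if n_bits not in self._mats:
            rng = np.random.default_rng([self.seed, n_bits])
            self._mats[n_bits] = rng.standard_normal(
                (n_bits, self.dim)) / np.sqrt(n_bits)
        return self._mats[n_bits]

    def encode(self, compound: CompoundRecord) -> np.ndarray:
        try:
            bits = unpack_bits(compound.fingerprint, compound.n_bits)
        except Exception as exc:  # surface the offending compound
            raise RuntimeError(
                f"encoder failed for compound {compound.compound_id!r}") from exc
        return bits.astype(float) @ self._matrix(compound.n_bits)


class TableCompoundEncoder:
    """File-backed compound representations (CSV: compound_id, x0..x{d-1})."""

    def __init__(self, path):
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c != "compound_id"]
        self._table = {str(r["compound_id"]): r[cols].to_numpy(dtype=float)
                       for _, r in df.iterrows()}
        self.dim = len(cols)

    def encode(self, compound: CompoundRecord) -> np.ndarray:
        try:
            return self._table[compound.compound_id]
        except KeyError:
            raise KeyError(
                f"no representation for compound {compound.compound_id!r}") from None


class SeededReceptorEncoder:
    """Deterministic stand-in target encoder: one fixed seeded Gaussian
    vector of length ``dim`` per receptor id."""

    def __init__(self, dim: int = TARGET_DIM, seed: int = 0,
                 known: Optional[Sequence[str]] = None):
        self.dim = dim
        self.seed = seed
        self.known = set(known) if known is not None else None

    def encode(self, receptor_id: str) -> np.ndarray:
        if self.known is not None and receptor_id not in self.known:
            raise KeyError(f"unknown receptor {receptor_id!r}")
        rng = np.random.default_rng(
            [self.seed, zlib.crc32(receptor_id.encode())])
        return rng.standard_normal(self.dim)


class TableReceptorEncoder:
    """File-backed receptor embeddings (CSV: receptor_id, p0..p{d-1})."""

    def __init__(self, path):
        df = pd.read_csv(path)
        cols = [c for c in df.columns if c != "receptor_id"]
        self._table = {str(r["receptor_id"]): r[cols].to_numpy(dtype=float)
                       for _, r in df.iterrows()}
        self.dim = len(cols)

    def encode(self, receptor_id: str) -> np.ndarray:
        if receptor_id not in self._table:
            raise KeyError(f"unknown receptor {receptor_id!r}")
        return self._table[receptor_id]


def compute_dense_representation(compound: CompoundRecord,
                                 encoder=None) -> np.ndarray:
    """Dense compound representation (default: seeded random projection)."""
    if encoder is None:
        encoder = RandomProjectionCompoundEncoder()
    return np.asarray(encoder.encode(compound), dtype=float)


def compute_target_embedding(receptor_id: str, provider=None) -> np.ndarray:
    """Fixed-length receptor embedding (default: seeded stand-in)."""
    if provider is None:
        provider = SeededReceptorEncoder()
    return np.asarray(provider.encode(receptor_id), dtype=float)


# ---------------------------------------------------------------------------
# Graph construction


def restrict_neighbours(nq: NeighbourQuery,
                        allowed_ids: Optional[set] = None,
                        exclude: Optional[str] = None,
                        cap: Optional[int] = DEFAULT_MAX_NEIGHBOURS
                        ) -> NeighbourQuery:
    """Apply the transductive neighbour policy to a ranked neighbour list.

    Drops the query itself and (when ``allowed_ids`` is given) any compound
    outside the allowed partition — e.g. test compounds may only refer to
    training compounds during evaluation. The rank cap applies after
    restriction.
    """
    kept = [(cid, s) for cid, s in nq.neighbours
            if cid != nq.query_id and cid != exclude
            and (allowed_ids is None or cid in allowed_ids)]
    if cap is not None:
        kept = kept[:cap]
    return NeighbourQuery(query_id=nq.query_id, neighbours=kept,
                          hops=nq.hops, max_neighbours=cap if cap is not None else -1)


def _canonical_edge_order(ids: Sequence[str]) -> np.ndarray:
    return np.asarray(sorted(range(len(ids)), key=lambda k: ids[k]), dtype=int)


def build_graph_single(query: CompoundRecord,
                       receptor_id: str,
                       neighbours: NeighbourQuery,
                       labels: Mapping[str, int],
                       compound_lookup: Mapping[str, CompoundRecord],
                       scheme: BioactivityClassScheme = BioactivityClassScheme(),
                       compound_encoder=None,
                       receptor_encoder=None) -> NeighbourhoodGraph:
    """Single-receptor neighbourhood graph with (n_classes+1)-wide edges.

    One edge per neighbour that carries a label on this receptor; neighbours
    unlabelled here are dropped (matching the frequency semantics of the
    training-free predictor). Edge feature = [one-hot class, similarity].
    """
    if compound_encoder is None:
        compound_encoder = RandomProjectionCompoundEncoder()
    if receptor_encoder is None:
        receptor_encoder = SeededReceptorEncoder()
    C = scheme.n_classes
    lab_ids, lab_sims, lab_cls = [], [], []
    for cid, sim in neighbours.neighbours:
        if cid == query.compound_id:
            continue
        cls = labels.get(cid)
        if cls is None:
            continue
        lab_ids.append(cid)
        lab_sims.append(float(sim))
        lab_cls.append(int(cls))
    order = _canonical_edge_order(lab_ids)
    lab_ids = [lab_ids[k] for k in order]
    lab_sims = np.asarray([lab_sims[k] for k in order])
    lab_cls = np.asarray([lab_cls[k] for k in order], dtype=int)

    node_ids = [query.compound_id] + lab_ids
    feats = [compute_dense_representation(query, compound_encoder)]
    for cid in lab_ids:
        feats.append(compute_dense_representation(compound_lookup[cid],
                                                  compound_encoder))
    E = len(lab_ids)
    edge_features = np.zeros((E, C + 1))
    if E:
        edge_features[np.arange(E), lab_cls] = 1.0
        edge_features[:, C] = lab_sims
    laf = np.zeros(C)
    if E:
        laf = np.bincount(lab_cls, minlength=C).astype(float) / E
    label = None
    if query.compound_id in labels:
        label = np.zeros(C)
        label[int(labels[query.compound_id])] = 1.0
    return NeighbourhoodGraph(
        query_id=query.compound_id,
        node_ids=node_ids,
        node_features=np.stack(feats),
        edge_src=np.arange(1, E + 1, dtype=int),
        edge_features=edge_features,
        similarities=lab_sims,
        laf_vector=laf,
        mode="single",
        receptor_id=receptor_id,
        target_embedding=compute_target_embedding(receptor_id, receptor_encoder),
        label=label,
    )


def build_graph_multi(query: CompoundRecord,
                      neighbours: NeighbourQuery,
                      labels_by_receptor: Mapping[str, Mapping[str, int]],
                      receptor_ids: Sequence[str],
                      compound_lookup: Mapping[str, CompoundRecord],
                      scheme: BioactivityClassScheme = BioactivityClassScheme(),
                      compound_encoder=None) -> NeighbourhoodGraph:
    """Multi-receptor neighbourhood graph.

    Each edge carries a flattened (n_receptors x (n_classes+1)) one-hot
    block: the neighbour's class where data exists on that receptor, the
    reserved no-data index otherwise, so every 7-wide block sums to 1. A
    neighbour enters the graph if it is labelled on ANY receptor. The label
    is an integer class vector over receptors with the no-data index marking
    unlabelled query positions (those are masked in the loss).
    """
    if compound_encoder is None:
        compound_encoder = RandomProjectionCompoundEncoder()
    C = scheme.n_classes
    R = len(receptor_ids)
    width = C + 1
    lab_ids, lab_sims = [], []
    for cid, sim in neighbours.neighbours:
        if cid == query.compound_id:
            continue
        if any(cid in labels_by_receptor.get(r, {}) for r in receptor_ids):
            lab_ids.append(cid)
            lab_sims.append(float(sim))
    order = _canonical_edge_order(lab_ids)
    lab_ids = [lab_ids[k] for k in order]
    lab_sims = np.asarray([lab_sims[k] for k in order])

    E = len(lab_ids)
    edge_features = np.zeros((E, R * width))
    for e, cid in enumerate(lab_ids):
        for ri, r in enumerate(receptor_ids):
            cls = labels_by_receptor.get(r, {}).get(cid)
            idx = scheme.no_data_index if cls is None else int(cls)
            edge_features[e, ri * width + idx] = 1.0
    node_ids = [query.compound_id] + lab_ids
    feats = [compute_dense_representation(query, compound_encoder)]
    for cid in lab_ids:
        feats.append(compute_dense_representation(compound_lookup[cid],
                                                  compound_encoder))
    laf = np.zeros(R * width)
    if E:
        laf = edge_features.mean(axis=0)
    label = np.full(R, scheme.no_data_index, dtype=int)
    for ri, r in enumerate(receptor_ids):
        cls = labels_by_receptor.get(r, {}).get(query.compound_id)
        if cls is not None:
            label[ri] = int(cls)
    return NeighbourhoodGraph(
        query_id=query.compound_id,
        node_ids=node_ids,
        node_features=np.stack(feats),
        edge_src=np.arange(1, E + 1, dtype=int),
        edge_features=edge_features,
        similarities=lab_sims,
        laf_vector=laf,
        mode="multi",
        label=label,
    )


# ---------------------------------------------------------------------------
# Splitting


def murcko_scaffold(smiles: str) -> str:
    """Murcko scaffold SMILES of a molecule ("" for acyclic molecules)."""
    from rdkit import Chem
    from rdkit.Chem.Scaffolds import MurckoScaffold

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def scaffold_split(compound_ids: Sequence[str],
                   fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                   seed: int = 0,
                   groups: Optional[Mapping[str, object]] = None,
                   smiles: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Group-disjoint train/test/val split at compound granularity.

    Groups come from ``groups`` (any hashable group key per compound, e.g.
    the synthetic generator's cluster ids) or are computed as Murcko
    scaffolds from ``smiles``. Groups are assigned greedily, largest first
    (equal sizes shuffled by ``seed``), to the partition with the largest
    remaining deficit relative to its target fraction — so every group lands
    wholly in one partition and the compound-level fractions approximate the
    targets. Returns a DataFrame (compound_id, scaffold_id, partition).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if groups is None:
        if smiles is None:
            raise ValueError("need either groups or smiles")
        groups = {cid: murcko_scaffold(smiles[cid]) for cid in compound_ids}
    members: dict[object, list[str]] = {}
    for cid in compound_ids:
        members.setdefault(groups[cid], []).append(cid)
    group_keys = list(members)
    rng = np.random.default_rng(seed)
    rng.shuffle(group_keys)
    group_keys.sort(key=lambda g: -len(members[g]))  # stable: ties keep shuffle

    parts = ("train", "test", "val")
    total = len(compound_ids)
    target = {p: f * total for p, f in zip(parts, fractions)}
    assigned = {p: 0 for p in parts}
    scaffold_index = {g: i for i, g in enumerate(group_keys)}
    rows = []
    for g in group_keys:
        part = max(parts, key=lambda p: target[p] - assigned[p])
        assigned[part] += len(members[g])
        for cid in members[g]:
            rows.append({"compound_id": cid, "scaffold_id": scaffold_index[g],
                         "partition": part})
    return pd.DataFrame(rows)


def iid_split(compound_ids: Sequence[str],
              fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
              seed: int = 0) -> pd.DataFrame:
    """Record-level i.i.d. split (each compound its own group)."""
    return scaffold_split(compound_ids, fractions, seed,
                          groups={cid: cid for cid in compound_ids})


def leakage_filter(dataset: Sequence[CompoundRecord],
                   held_out: Sequence[CompoundRecord],
                   similarity_threshold: float = 0.65
                   ) -> tuple[list[CompoundRecord], list[str]]:
    """Remove dataset compounds too similar to a held-out library.

    A compound is removed when its Tanimoto similarity to ANY held-out
    compound strictly exceeds the threshold (default 0.65); similarity
    exactly at the threshold is retained. Returns (kept, removed_ids).
    """
    if not dataset or not held_out:
        return list(dataset), []
    sims = tanimoto_cross(np.stack([r.fingerprint for r in dataset]),
                          np.stack([r.fingerprint for r in held_out]))
    max_sim = sims.max(axis=1)
    kept = [r for r, s in zip(dataset, max_sim) if s <= similarity_threshold]
    removed = [r.compound_id for r, s in zip(dataset, max_sim)
               if s > similarity_threshold]
    return kept, removed


def audit_split(graphs: Sequence[NeighbourhoodGraph],
                assignment: pd.DataFrame,
                mode: str = "eval") -> list[str]:
    """Audit the transductive neighbour policy over built graphs.

    Returns a list of human-readable violations (empty means the policy
    holds): a query appearing among its own neighbours, or — for eval-mode
    graphs of test/val queries — any neighbour outside the train partition.
    """
    part = dict(zip(assignment["compound_id"], assignment["partition"]))
    violations = []
    for g in graphs:
        neigh = g.node_ids[1:]
        if g.query_id in neigh:
            violations.append(f"{g.query_id}: appears in own neighbourhood")
        if mode == "eval" and part.get(g.query_id) in ("test", "val"):
            for cid in neigh:
                if part.get(cid) != "train":
                    violations.append(
                        f"{g.query_id}: non-train neighbour {cid}")
    return violations


# ---------------------------------------------------------------------------
# Serialization


def write_dataset(graphs: Sequence[NeighbourhoodGraph], path) -> None:
    """Write graphs to one .npz archive (bit-exact round trip)."""
    import json

    arrays = {}
    meta = []
    for i, g in enumerate(graphs):
        arrays[f"g{i}_x"] = g.node_features
        arrays[f"g{i}_src"] = g.edge_src
        arrays[f"g{i}_e"] = g.edge_features
        arrays[f"g{i}_sim"] = g.similarities
        arrays[f"g{i}_laf"] = g.laf_vector
        if g.target_embedding is not None:
            arrays[f"g{i}_p"] = g.target_embedding
        if g.label is not None:
            arrays[f"g{i}_y"] = g.label
        meta.append({"query_id": g.query_id, "node_ids": g.node_ids,
                     "mode": g.mode, "receptor_id": g.receptor_id})
    arrays["_meta"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8).copy()
    np.savez(path, **arrays)


def read_dataset(path) -> list[NeighbourhoodGraph]:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        graphs = []
        for i, m in enumerate(meta):
            graphs.append(NeighbourhoodGraph(
                query_id=m["query_id"],
                node_ids=list(m["node_ids"]),
                node_features=z[f"g{i}_x"],
                edge_src=z[f"g{i}_src"],
                edge_features=z[f"g{i}_e"],
                similarities=z[f"g{i}_sim"],
                laf_vector=z[f"g{i}_laf"],
                mode=m["mode"],
                receptor_id=m["receptor_id"],
                target_embedding=z[f"g{i}_p"] if f"g{i}_p" in z else None,
                label=z[f"g{i}_y"] if f"g{i}_y" in z else None,
            ))
    return graphs
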