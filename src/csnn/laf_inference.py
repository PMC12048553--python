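"""Training-free labels-as-features (LaF) inference.

Given a query compound's ranked chemical neighbourhood and the known
bioactivity labels of those neighbours on a receptor, the most frequent
neighbour label is itself a prediction: under network homophily ("similarity
breeds connection") nearby compounds tend to share bioactivity. This module
implements that argmax prediction, its regression analogue (neighbourhood
aggregates of affinity values), and the novelty filter that flags
experimental hits with no labelled chemical neighbourhood.

A query with zero labelled neighbours yields ABSTAIN — the out-of-
distribution guard: no neighbourhood, no prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from csnn.csn_graph import ChemicalSpaceNetwork, NeighbourQuery, query_neighbours

__all__ = [
    "ABSTAIN",
    "LabelFrequencyVector",
    "ClassPrediction",
    "label_frequency",
    "argmax_predict",
    "aggregate_regression",
    "novelty_filter",
]


class _Abstain:
    """Sentinel for 'no labelled neighbourhood, no prediction'."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "ABSTAIN"

    def __bool__(self):
        return False


ABSTAIN = _Abstain()

DEFAULT_N_CLASSES = 6


@dataclass
class LabelFrequencyVector:
    """Per-class frequency of labels in a query's labelled neighbourhood.

    ``freqs`` sums to 1 when ``support`` (the number of labelled neighbours)
    is positive and is all-zero when support is 0.
    """

    freqs: np.ndarray
    support: int

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)


@dataclass
class ClassPrediction:
    predicted_class: object  # int class index or ABSTAIN
    frequency_vector: LabelFrequencyVector
    tie: bool = False

    @property
    def is_abstain(self) -> bool:
        return self.predicted_class is ABSTAIN


def label_frequency(neighbours: NeighbourQuery,
                    labels: Mapping[str, int],
                    n_classes: int = DEFAULT_N_CLASSES,
                    exclude: Optional[str] = None) -> LabelFrequencyVector:
    """Normalised class-frequency vector over the labelled neighbours.

    Neighbours absent from ``labels`` (no data on this receptor) are
    skipped; the result is a proper distribution over classes whenever any
    labelled neighbour exists. Permutation-invariant in neighbour order.
    ``exclude`` drops one compound id (the query itself — its own label must
    never leak into its features).
    """
    counts = np.zeros(n_classes, dtype=float)
    support = 0
    for cid, _sim in neighbours.neighbours:
        if cid == neighbours.query_id or (exclude is not None and cid == exclude):
            continue
        cls = labels.get(cid)
        if cls is None:
            continue
        if not 0 <= cls < n_classes:
            raise ValueError(f"class index {cls} out of range for {cid!r}")
        counts[cls] += 1
        support += 1
    if support:
        counts /= support
    return LabelFrequencyVector(freqs=counts, support=support)


def argmax_predict(freqs: LabelFrequencyVector) -> ClassPrediction:
    """Most frequent neighbourhood label; ABSTAIN when support is 0.

    Exact frequency ties are resolved to the lowest class index and flagged,
    so downstream consumers can treat ambiguous calls separately.
    """
    if freqs.support == 0:
        return ClassPrediction(predicted_class=ABSTAIN, frequency_vector=freqs)
    best = int(np.argmax(freqs.freqs))
    tie = int((freqs.freqs == freqs.freqs[best]).sum()) > 1
    return ClassPrediction(predicted_class=best, frequency_vector=freqs, tie=tie)


def aggregate_regression(neighbours: NeighbourQuery,
                         values: Mapping[str, float],
                         method: str = "mean",
                         exclude: Optional[str] = None):
    """Neighbourhood-aggregate affinity prediction on the -log10(Ki) scale.

    ``method`` is one of mean / max / min / weighted; "weighted" is the
    similarity-weighted mean sum(w_j y_j)/sum(w_j) with w_j the Tanimoto
    edge weight. Returns ABSTAIN when no neighbour carries a value.
    """
    ys, ws = [], []
    for cid, sim in neighbours.neighbours:
        if cid == neighbours.query_id or (exclude is not None and cid == exclude):
            continue
        y = values.get(cid)
        if y is None:
            continue
        ys.append(float(y))
        ws.append(float(sim))
    if not ys:
        return ABSTAIN
    ys_arr = np.asarray(ys)
    if method == "mean":
        return float(ys_arr.mean())
    if method == "max":
        return float(ys_arr.max())
    if method == "min":
        return float(ys_arr.min())
    if method == "weighted":
        w = np.asarray(ws)
        if not np.isfinite(w).all() or w.sum() <= 0:
            return float(ys_arr.mean())
        return float((w * ys_arr).sum() / w.sum())
    raise ValueError(f"unknown aggregation method {method!r}")


def novelty_filter(hits: pd.DataFrame,
                   csn: ChemicalSpaceNetwork,
                   labels: Mapping[str, Mapping[str, int]],
                   z_threshold: float = 3.0,
                   max_neighbours: Optional[int] = None) -> pd.DataFrame:
    """Keep significant experimental hits with no labelled neighbourhood.

    ``hits`` needs columns (compound_id, receptor_id, z). A row survives
    when |z| > ``z_threshold`` and the compound has zero neighbours carrying
    a label for that receptor in the network — i.e. the interaction is not
    anticipated by any database knowledge in the chemical neighbourhood.
    ``labels`` maps receptor_id -> {compound_id: class}.
    """
    required = {"compound_id", "receptor_id", "z"}
    if not required.issubset(hits.columns):
        raise ValueError(f"hits table needs columns {sorted(required)}")
    keep = []
    for _, row in hits.iterrows():
        if abs(float(row["z"])) <= z_threshold:
            continue
        cid = str(row["compound_id"])
        if cid not in csn:
            keep.append(row)
            continue
        nq = query_neighbours(csn, cid, hops=1, max_neighbours=max_neighbours)
        rec_labels = labels.get(str(row["receptor_id"]), {})
        fv = label_frequency(nq, rec_labels)
        if fv.support == 0:
            keep.append(row)
    if not keep:
        return hits.iloc[0:0].copy()
    return pd.DataFrame(keep).reset_index(drop=True)
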