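"""Reusable benchmark harnesses over synthetic chemical spaces.

These compose the generator, the network, the training-free predictors and
the baseline models into the recurring experiments: transductive argmax
evaluation, homophily sweeps, and the labels-as-features (+N) advantage
study for both regression and classification. Each harness is deterministic
under its seed arguments and returns plain dictionaries / DataFrames.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from csnn.baselines import featurize, fit_baseline
from csnn.csn_graph import ChemicalSpaceNetwork, build_csn, query_neighbours
from csnn.dataset_builder import (RandomProjectionCompoundEncoder,
                                  SeededReceptorEncoder, scaffold_split,
                                  restrict_neighbours)
from csnn.evaluation import (ClassMetrics, classification_metrics,
                             regression_metrics)
from csnn.laf_inference import (ABSTAIN, aggregate_regression, argmax_predict,
                                label_frequency)
from csnn.synthetic_data import SyntheticSpec, SyntheticSpace, generate_space

__all__ = [
    "argmax_transductive_eval",
    "homophily_f1_sweep",
    "laf_regression_benchmark",
    "laf_classification_benchmark",
]


def argmax_transductive_eval(space: SyntheticSpace,
                             csn: Optional[ChemicalSpaceNetwork] = None,
                             max_neighbours: int = 40) -> ClassMetrics:
    """Leave-own-label-out argmax evaluation over every labelled DTI.

    For each labelled (compound, receptor) pair the query's chemical
    neighbours vote with their labels on that receptor — the query's own
    label is excluded from its features — and the most frequent label is
    compared against the observed one. Queries with no labelled neighbour
    abstain and are excluded from the metrics (their count is reported on
    the result).
    """
    if csn is None:
        csn = build_csn(space.compounds)
    n_classes = space.spec.n_classes
    cache: dict[str, object] = {}
    t_list, p_list = [], []
    for rid in space.receptor_ids:
        labels = space.labels_for(rid)
        for cid, true_cls in labels.items():
            nq = cache.get(cid)
            if nq is None:
                nq = query_neighbours(csn, cid, hops=1, max_neighbours=None)
                cache[cid] = nq
            restricted = restrict_neighbours(nq, cap=max_neighbours)
            fv = label_frequency(restricted, labels, n_classes=n_classes,
                                 exclude=cid)
            pred = argmax_predict(fv)
            t_list.append(true_cls)
            p_list.append(ABSTAIN if pred.is_abstain else pred.predicted_class)
    return classification_metrics(t_list, p_list, n_classes)


def homophily_f1_sweep(h_values: Sequence[float],
                       seeds: Sequence[int],
                       base_spec: Optional[SyntheticSpec] = None
                       ) -> pd.DataFrame:
    """Mean argmax weighted F1 as a function of the homophily level.

    Returns a tidy frame (homophily, seed, weighted_f1) — under the
    generative model the mean over seeds should be non-decreasing in h.
    """
    if base_spec is None:
        base_spec = SyntheticSpec()
    rows = []
    for h in h_values:
        for seed in seeds:
            spec = dataclasses.replace(base_spec, homophily=h, seed=seed)
            space = generate_space(spec)
            metrics = argmax_transductive_eval(space)
            rows.append({"homophily": h, "seed": seed,
                         "weighted_f1": metrics.weighted_f1,
                         "n_abstain": metrics.n_abstain})
    return pd.DataFrame(rows)


def _dti_features(space: SyntheticSpace, csn: ChemicalSpaceNetwork,
                  records: pd.DataFrame, allowed_ids: set,
                  task: str, with_neighbourhood: bool,
                  compound_encoder, receptor_encoder,
                  max_neighbours: int = 40
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lookup = {r.compound_id: r for r in space.compounds}
    labels_by_r = {rid: space.labels_for(rid) for rid in space.receptor_ids}
    values_by_r = {rid: space.values_for(rid) for rid in space.receptor_ids}
    X, y, ood = [], [], []
    nq_cache: dict[str, object] = {}
    for _, row in records.iterrows():
        cid, rid = row["compound_id"], row["receptor_id"]
        nq = nq_cache.get(cid)
        if nq is None:
            nq = query_neighbours(csn, cid, hops=1, max_neighbours=None)
            nq_cache[cid] = nq
        restricted = restrict_neighbours(nq, allowed_ids=allowed_ids,
                                         exclude=cid, cap=max_neighbours)
        rec_labels = {c: k for c, k in labels_by_r[rid].items()
                      if c in allowed_ids and c != cid}
        rec_values = {c: v for c, v in values_by_r[rid].items()
                      if c in allowed_ids and c != cid}
        vec, is_ood = featurize(
            compound_encoder.encode(lookup[cid]),
            receptor_encoder.encode(rid),
            neighbours=restricted,
            labels=rec_labels, values=rec_values,
            with_neighbourhood=True, task=task,
            n_classes=space.spec.n_classes, exclude=cid)
        if not with_neighbourhood:
            # matched capacity: same record set, neighbourhood columns cut
            n_extra = space.spec.n_classes if task == "classification" else 1
            vec = vec[:-n_extra]
        X.append(vec)
        y.append(int(row["class_idx"]) if task == "classification"
                 else float(row["value"]))
        ood.append(is_ood)
    return np.asarray(X), np.asarray(y), np.asarray(ood, dtype=bool)


_FAST_GRIDS = {
    "ridge": {"alpha": [1.0]},
    "rf": {"max_depth": [20], "min_samples_leaf": [2], "n_estimators": [100]},
    "mlp": {"hidden_layer_sizes": [(64,)], "activation": ["relu"],
            "alpha": [1e-3]},
}


def laf_regression_benchmark(spec: Optional[SyntheticSpec] = None,
                             seed: int = 0,
                             model_family: str = "ridge",
                             grid: Optional[dict] = None) -> dict:
    """Pooled regression with and without the neighbourhood-mean column.

    One model is trained across all receptors with the receptor embedding
    concatenated into the features. The transductive policy holds: training
    records refer to other training records; test records refer to training
    records only. Returns test MSEs for the plain and the +N variant and
    the neighbourhood-mean predictor's own MSE.
    """
    if spec is None:
        spec = SyntheticSpec(seed=seed)
    space = generate_space(spec)
    csn = build_csn(space.compounds)
    assignment = scaffold_split([r.compound_id for r in space.compounds],
                                seed=seed, groups=space.scaffold_of)
    part = dict(zip(assignment["compound_id"], assignment["partition"]))
    train_ids = {c for c, p in part.items() if p == "train"}
    dti = space.dti
    train_recs = dti[dti["compound_id"].map(part) == "train"]
    test_recs = dti[dti["compound_id"].map(part) == "test"]
    enc = RandomProjectionCompoundEncoder(seed=seed)
    renc = SeededReceptorEncoder(seed=seed)
    grid = grid if grid is not None else _FAST_GRIDS[model_family]

    out = {"n_train": len(train_recs), "n_test": len(test_recs)}
    for tag, with_n in (("plain", False), ("laf", True)):
        Xtr, ytr, _ = _dti_features(space, csn, train_recs, train_ids,
                                    "regression", with_n, enc, renc)
        Xte, yte, ood = _dti_features(space, csn, test_recs, train_ids,
                                      "regression", with_n, enc, renc)
        # no neighbourhood, no prediction: OOD test records are excluded
        # from the comparison identically for both variants
        Xte, yte = Xte[~ood], yte[~ood]
        fit = fit_baseline(Xtr, ytr, model_family=model_family,
                           task="regression", grid=grid, seed=seed)
        pred = fit.model.predict(Xte)
        m = regression_metrics(yte, pred)
        out[f"mse_{tag}"] = m.mse
        out[f"pearson_{tag}"] = m.pearson
        out["n_test_ood"] = int(ood.sum())
    # the neighbourhood mean alone (the +N column) as its own predictor
    values_by_r = {rid: space.values_for(rid) for rid in space.receptor_ids}
    preds, truths = [], []
    for _, row in test_recs.iterrows():
        nq = restrict_neighbours(
            query_neighbours(csn, row["compound_id"], max_neighbours=None),
            allowed_ids=train_ids, exclude=row["compound_id"], cap=40)
        vals = {c: v for c, v in values_by_r[row["receptor_id"]].items()
                if c in train_ids}
        p = aggregate_regression(nq, vals, method="mean")
        preds.append(p)
        truths.append(float(row["value"]))
    m = regression_metrics(truths, preds)
    out["mse_neighbourhood_mean"] = m.mse
    out["n_abstain_mean_predictor"] = m.n_abstain
    return out


def laf_classification_benchmark(spec: Optional[SyntheticSpec] = None,
                                 seed: int = 0,
                                 model_family: str = "rf",
                                 grid: Optional[dict] = None) -> dict:
    """Classification F1 with and without the label-frequency columns.

    Same capacity (identical family and grid) for both variants; the only
    difference is the six appended neighbourhood frequencies.
    """
    if spec is None:
        spec = SyntheticSpec(seed=seed)
    space = generate_space(spec)
    csn = build_csn(space.compounds)
    assignment = scaffold_split([r.compound_id for r in space.compounds],
                                seed=seed, groups=space.scaffold_of)
    part = dict(zip(assignment["compound_id"], assignment["partition"]))
    train_ids = {c for c, p in part.items() if p == "train"}
    dti = space.dti
    train_recs = dti[dti["compound_id"].map(part) == "train"]
    test_recs = dti[dti["compound_id"].map(part) == "test"]
    enc = RandomProjectionCompoundEncoder(seed=seed)
    renc = SeededReceptorEncoder(seed=seed)
    grid = grid if grid is not None else _FAST_GRIDS[model_family]

    out = {"n_train": len(train_recs), "n_test": len(test_recs)}
    for tag, with_n in (("plain", False), ("laf", True)):
        Xtr, ytr, _ = _dti_features(space, csn, train_recs, train_ids,
                                    "classification", with_n, enc, renc)
        Xte, yte, ood = _dti_features(space, csn, test_recs, train_ids,
                                      "classification", with_n, enc, renc)
        Xte, yte = Xte[~ood], yte[~ood]
        fit = fit_baseline(Xtr, ytr, model_family=model_family,
                           task="classification", grid=grid, seed=seed)
        pred = fit.model.predict(Xte)
        m = classification_metrics(yte, pred, space.spec.n_classes)
        out[f"weighted_f1_{tag}"] = m.weighted_f1
        out["n_test_ood"] = int(ood.sum())
    return out
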