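"""Edge-attributed neighbourhood models (single- and multi-receptor CSNN).

The model maps a one-hop labelled neighbourhood graph to bioactivity logits
in three stages:

1. **Aggregation.** Each neighbour message is ReLU(x_j + W_e e_ji + b_e),
   where the learned linear map (W_e, b_e) lifts the edge feature (one-hot
   neighbour label + similarity) to the node-feature width. Messages are
   summed — not averaged — and mixed with the query's own features:

       s = (1 + eps) * x_i  +  sum_j ReLU(x_j + W_e e_ji + b_e)

   followed by a two-layer ReLU MLP ``h_theta`` producing the local
   representation r_i. One aggregation layer suffices: every edge already
   points at the query, so the output is a pooled graph representation.
2. **Skip connection.** r_i is concatenated with the normalised
   neighbourhood label-frequency vector, and (in single-receptor mode) the
   receptor embedding: widths 256+320+6 = 582 (single) and 64+896 = 960
   (multi).
3. **Head.** A 2-hidden-layer MLP (width 512) emits raw class scores —
   6 in single-receptor mode, 128*7 = 896 in multi-receptor mode, the
   latter reshaped to (128, 7) with a per-receptor softmax over the six
   classes plus the no-data index.

The loss is batch-mean cross-entropy; in multi-receptor mode receptor
positions where the query has no label (the no-data index) are masked out,
and fully-masked records do not contribute to the batch mean at all.

Everything is plain NumPy with hand-derived gradients and a hand-rolled
Adam, which keeps the model dependency-free and makes the analytic
gradients directly checkable against finite differences. Edge order is
canonicalised before every summation, so all outputs are bit-exactly
invariant to edge permutations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from csnn.dataset_builder import NeighbourhoodGraph, DENSE_DIM, TARGET_DIM
from csnn.laf_inference import ABSTAIN

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "PredictionWithConfidence",
    "CSNNModel",
    "batch_loss",
    "train",
    "TrainResult",
    "confidence_filter",
]


@dataclass(frozen=True)
class ModelConfig:
    """Shapes of one CSNN instance.

    ``mode`` is "single" (per-receptor logits over the classes) or "multi"
    (one forward pass emitting logits for every receptor at once).
    """

    mode: str = "single"
    n_classes: int = 6
    n_receptors: int = 128          # multi mode only
    node_dim: int = DENSE_DIM
    target_dim: int = TARGET_DIM    # single mode only
    gnn_hidden: int = 256
    gnn_out: int = 256              # 64 in multi mode
    head_hidden: int = 512
    eps_gin: float = 0.0            # fixed mixing weight for the query node

    @property
    def edge_dim(self) -> int:
        if self.mode == "single":
            return self.n_classes + 1
        return self.n_receptors * (self.n_classes + 1)

    @property
    def skip_dim(self) -> int:
        """Width of the concatenated representation entering the head."""
        if self.mode == "single":
            return self.gnn_out + self.target_dim + self.n_classes
        return self.gnn_out + self.n_receptors * (self.n_classes + 1)

    @property
    def out_dim(self) -> int:
        if self.mode == "single":
            return self.n_classes
        return self.n_receptors * (self.n_classes + 1)

    @staticmethod
    def nn_single(**overrides) -> "ModelConfig":
        return ModelConfig(mode="single", **overrides)

    @staticmethod
    def nn_multi(**overrides) -> "ModelConfig":
        overrides.setdefault("gnn_out", 64)
        return ModelConfig(mode="multi", **overrides)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (adaptive-moment gradient descent)."""

    learning_rate: float = 1e-5     # 5e-5 for the multi-receptor model
    weight_decay: float = 1e-4
    batch_size: int = 16
    epochs: int = 100
    seed: int = 0
    n_repeats: int = 5

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


@dataclass
class PredictionWithConfidence:
    """Class probabilities plus the max-probability confidence.

    Single mode: ``probabilities`` has shape (n_classes,). Multi mode:
    (n_receptors, n_classes+1) with per-receptor rows summing to 1;
    ``predicted_class`` / ``confidence`` are then per-receptor arrays.
    """

    probabilities: np.ndarray
    predicted_class: np.ndarray | int
    confidence: np.ndarray | float
    query_id: str = ""
    receptor_id: Optional[str] = None


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _glorot(rng, fan_out, fan_in):
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=(fan_out, fan_in))


def _canonical_order(graph: NeighbourhoodGraph) -> np.ndarray:
    """Deterministic edge order independent of storage order."""
    keys = [(graph.node_ids[graph.edge_src[e]],
             graph.edge_features[e].tobytes())
            for e in range(graph.n_edges)]
    return np.asarray(sorted(range(graph.n_edges), key=keys.__getitem__),
                      dtype=int)


class CSNNModel:
    """One CSNN instance: parameters, forward pass, analytic gradients."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.params: dict[str, np.ndarray] = {
            "We": _glorot(rng, c.node_dim, c.edge_dim),
            "be": np.zeros(c.node_dim),
            "W1": _glorot(rng, c.gnn_hidden, c.node_dim),
            "b1": np.zeros(c.gnn_hidden),
            "W2": _glorot(rng, c.gnn_out, c.gnn_hidden),
            "b2": np.zeros(c.gnn_out),
            "V1": _glorot(rng, c.head_hidden, c.skip_dim),
            "c1": np.zeros(c.head_hidden),
            "V2": _glorot(rng, c.head_hidden, c.head_hidden),
            "c2": np.zeros(c.head_hidden),
            "V3": _glorot(rng, c.out_dim, c.head_hidden),
            "c3": np.zeros(c.out_dim),
        }

    # -- forward -----------------------------------------------------------

    def _skip_vector(self, graph: NeighbourhoodGraph, r: np.ndarray) -> np.ndarray:
        if self.config.mode == "single":
            if graph.target_embedding is None:
                raise ValueError(
                    f"graph {graph.query_id!r} lacks a target embedding")
            return np.concatenate([r, graph.target_embedding, graph.laf_vector])
        return np.concatenate([r, graph.laf_vector])

    def aggregate_local(self, graph: NeighbourhoodGraph) -> np.ndarray:
        """Local representation r_i of one graph (no head)."""
        return self._forward(graph)["r"]

    def _forward(self, graph: NeighbourhoodGraph) -> dict:
        p, c = self.params, self.config
        x0 = graph.node_features[0]
        if graph.n_edges:
            order = _canonical_order(graph)
            Xn = graph.node_features[graph.edge_src[order]]
            Ef = graph.edge_features[order]
            A = Xn + Ef @ p["We"].T + p["be"]
            M = _relu(A)
            s = (1.0 + c.eps_gin) * x0 + M.sum(axis=0)
        else:
            Ef = np.zeros((0, c.edge_dim))
            A = np.zeros((0, c.node_dim))
            s = (1.0 + c.eps_gin) * x0
        a1 = p["W1"] @ s + p["b1"]
        h1 = _relu(a1)
        a2 = p["W2"] @ h1 + p["b2"]
        r = _relu(a2)
        rp = self._skip_vector(graph, r)
        u1a = p["V1"] @ rp + p["c1"]
        u1 = _relu(u1a)
        u2a = p["V2"] @ u1 + p["c2"]
        u2 = _relu(u2a)
        z = p["V3"] @ u2 + p["c3"]
        return {"Ef": Ef, "A": A, "s": s, "a1": a1, "h1": h1, "a2": a2,
                "r": r, "rp": rp, "u1a": u1a, "u1": u1, "u2a": u2a,
                "u2": u2, "z": z}

    def logits(self, graph: NeighbourhoodGraph) -> np.ndarray:
        return self._forward(graph)["z"]

    def _backward(self, cache: dict, dz: np.ndarray,
                  grads: dict[str, np.ndarray]) -> None:
        """Accumulate parameter gradients for one graph into ``grads``."""
        p = self.params
        grads["V3"] += np.outer(dz, cache["u2"])
        grads["c3"] += dz
        du2 = (p["V3"].T @ dz) * (cache["u2a"] > 0)
        grads["V2"] += np.outer(du2, cache["u1"])
        grads["c2"] += du2
        du1 = (p["V2"].T @ du2) * (cache["u1a"] > 0)
        grads["V1"] += np.outer(du1, cache["rp"])
        grads["c1"] += du1
        drp = p["V1"].T @ du1
        dr = drp[: self.config.gnn_out]
        da2 = dr * (cache["a2"] > 0)
        grads["W2"] += np.outer(da2, cache["h1"])
        grads["b2"] += da2
        dh1 = p["W2"].T @ da2
        da1 = dh1 * (cache["a1"] > 0)
        grads["W1"] += np.outer(da1, cache["s"])
        grads["b1"] += da1
        ds = p["W1"].T @ da1
        if len(cache["A"]):
            dA = (cache["A"] > 0) * ds[None, :]
            grads["We"] += dA.T @ cache["Ef"]
            grads["be"] += dA.sum(axis=0)

    # -- prediction --------------------------------------------------------

    def predict(self, graph: NeighbourhoodGraph):
        """Probabilistic prediction; ABSTAIN for a neighbourhood-free graph
        (the out-of-distribution guard — never a fabricated distribution)."""
        if graph.is_ood:
            return ABSTAIN
        z = self.logits(graph)
        if self.config.mode == "single":
            probs = _softmax(z)
            return PredictionWithConfidence(
                probabilities=probs,
                predicted_class=int(np.argmax(probs)),
                confidence=float(probs.max()),
                query_id=graph.query_id,
                receptor_id=graph.receptor_id)
        width = self.config.n_classes + 1
        probs = _softmax(z.reshape(self.config.n_receptors, width), axis=1)
        return PredictionWithConfidence(
            probabilities=probs,
            predicted_class=probs.argmax(axis=1),
            confidence=probs.max(axis=1),
            query_id=graph.query_id)

    # -- loss --------------------------------------------------------------

    def loss_and_grads(self, graphs: Sequence[NeighbourhoodGraph]
                       ) -> tuple[float, dict[str, np.ndarray]]:
        """Batch loss and analytic parameter gradients.

        Single mode: per-graph cross-entropy against the one-hot label.
        Multi mode: cross-entropy summed over the receptors where the query
        is labelled; fully-unlabelled records are excluded from the batch
        mean entirely, so adding them never changes the loss.
        """
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        total = 0.0
        contributing = 0
        width = self.config.n_classes + 1
        pending: list[tuple[dict, np.ndarray]] = []
        for g in graphs:
            if g.label is None:
                continue
            cache = self._forward(g)
            z = cache["z"]
            if self.config.mode == "single":
                y = np.asarray(g.label, dtype=float)
                probs = _softmax(z)
                total += float(-(y * np.log(probs + 1e-300)).sum())
                pending.append((cache, probs - y))
                contributing += 1
            else:
                y = np.asarray(g.label, dtype=int)
                # the no-data index equals n_classes; those positions are masked
                mask = y != self.config.n_classes
                if not mask.any():
                    continue
                Z = z.reshape(self.config.n_receptors, width)
                probs = _softmax(Z, axis=1)
                dz = np.zeros_like(Z)
                for ri in np.flatnonzero(mask):
                    total += float(-np.log(probs[ri, y[ri]] + 1e-300))
                    dz[ri] = probs[ri]
                    dz[ri, y[ri]] -= 1.0
                pending.append((cache, dz.ravel()))
                contributing += 1
        if contributing == 0:
            raise ValueError("batch contains no labelled positions; "
                             "loss is undefined")
        for cache, dz in pending:
            self._backward(cache, dz / contributing, grads)
        return total / contributing, grads

    # -- persistence -------------------------------------------------------

    _FORMAT_VERSION = 1

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        cfg = {k: getattr(self.config, k) for k in
               ("mode", "n_classes", "n_receptors", "node_dim", "target_dim",
                "gnn_hidden", "gnn_out", "head_hidden", "eps_gin")}
        cfg["format_version"] = self._FORMAT_VERSION
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=1))

    @classmethod
    def load(cls, path) -> "CSNNModel":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        cfg.pop("format_version", None)
        model = cls(ModelConfig(**cfg))
        with np.load(path.with_suffix(".npz")) as z:
            model.params = {k: z[k] for k in z.files}
        return model


def batch_loss(model: CSNNModel, graphs: Sequence[NeighbourhoodGraph]) -> float:
    """Batch cross-entropy only (no gradients)."""
    return model.loss_and_grads(graphs)[0]


class _Adam:
    """Adaptive-moment gradient descent with L2 weight decay."""

    def __init__(self, params, lr, weight_decay, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k] + self.wd * params[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainResult:
    model: CSNNModel
    loss_history: list[float]            # mean train loss per epoch
    repeat_metrics: Optional["object"] = None  # per-repeat metric table
    summary: Optional[dict] = None       # mean +/- std across repeats


def _train_once(dataset, model_config, train_config, seed,
                eval_fn=None) -> TrainResult:
    rng = np.random.default_rng(seed)
    model = CSNNModel(model_config, seed=seed)
    trainable = [g for g in dataset if g.label is not None]
    if not trainable:
        raise ValueError("no labelled graphs to train on")
    opt = _Adam(model.params, train_config.learning_rate,
                train_config.weight_decay)
    history = []
    n = len(trainable)
    for _epoch in range(train_config.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, train_config.batch_size):
            batch = [trainable[i] for i in order[start:start + train_config.batch_size]]
            try:
                loss, grads = model.loss_and_grads(batch)
            except ValueError:
                continue  # batch happened to be fully masked
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss {loss} at epoch "
                    f"{_epoch}, seed {seed}")
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))
    return TrainResult(model=model, loss_history=history)


def train(dataset: Sequence[NeighbourhoodGraph],
          model_config: ModelConfig = ModelConfig(),
          train_config: TrainConfig = TrainConfig(),
          eval_fn=None) -> TrainResult:
    """Train with ``n_repeats`` independent seeded runs.

    ``eval_fn(model) -> dict`` (optional) is evaluated after each repeat;
    the result carries the per-repeat metric rows and their mean +/- std.
    The returned model is from the first repeat (seed = train_config.seed).
    """
    import pandas as pd

    rows = []
    first: Optional[TrainResult] = None
    for k in range(train_config.n_repeats):
        res = _train_once(dataset, model_config, train_config,
                          seed=train_config.seed + k)
        if first is None:
            first = res
        row = {"repeat": k, "seed": train_config.seed + k,
               "final_train_loss": res.loss_history[-1]}
        if eval_fn is not None:
            row.update(eval_fn(res.model))
        rows.append(row)
    table = pd.DataFrame(rows)
    metric_cols = [c for c in table.columns if c not in ("repeat", "seed")]
    summary = {c: {"mean": float(table[c].mean()), "std": float(table[c].std(ddof=1))
                   if len(table) > 1 else 0.0}
               for c in metric_cols}
    assert first is not None
    first.repeat_metrics = table
    first.summary = summary
    return first


def gradient_check(model: CSNNModel, graphs: Sequence[NeighbourhoodGraph],
                   n_samples: int = 5, h: float = 1e-6,
                   seed: int = 0) -> float:
    """Max relative error between analytic and central-difference gradients.

    Samples ``n_samples`` entries of every parameter tensor and perturbs
    each by ±h; entries where both gradients are below 1e-8 in magnitude
    are skipped (zero-gradient plateaus of the ReLUs).
    """
    rng = np.random.default_rng(seed)
    _, grads = model.loss_and_grads(graphs)
    worst = 0.0
    for k in model.params:
        flat = model.params[k].ravel()
        idxs = rng.choice(flat.size, size=min(n_samples, flat.size),
                          replace=False)
        for idx in idxs:
            orig = flat[idx]
            flat[idx] = orig + h
            lp = model.loss_and_grads(graphs)[0]
            flat[idx] = orig - h
            lm = model.loss_and_grads(graphs)[0]
            flat[idx] = orig
            numeric = (lp - lm) / (2 * h)
            analytic = grads[k].ravel()[idx]
            if abs(numeric) > 1e-8 or abs(analytic) > 1e-8:
                worst = max(worst, abs(numeric - analytic)
                            / max(abs(numeric), abs(analytic)))
    return worst


def confidence_filter(predictions: Sequence, threshold: float = 0.8
                      ) -> tuple[list, float]:
    """Retain predictions with confidence strictly above ``threshold``.

    ABSTAIN entries never pass. Returns (retained, retained_fraction).
    """
    kept = [p for p in predictions
            if p is not ABSTAIN and float(np.max(p.confidence)) > threshold]
    frac = len(kept) / len(predictions) if predictions else 0.0
    return kept, frac
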