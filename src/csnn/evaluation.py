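"""Performance metrics, enrichment tables, and receptor distances.

Classification metrics are computed from first principles off the confusion
matrix: per-class precision TP/(TP+FP), recall TP/(TP+FN), their harmonic
mean F1, and a weighted F1 where each class is weighted by its share of the
true instances. Regression metrics are MSE, MAE and the Pearson, Spearman
and Kendall correlations. Enrichment compares predicted hits (label not
'No Effect' AND predicted Ki below a threshold) against experimental hits
(screen Z-score above threshold) in a 2x2 table. Receptor distances come
either from a bias-corrected Cramer's V over co-occurring compound labels
or from cosine distance between receptor embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from csnn.laf_inference import ABSTAIN

__all__ = [
    "ClassMetrics",
    "RegressionMetrics",
    "EnrichmentTable",
    "classification_metrics",
    "regression_metrics",
    "homophily_performance",
    "enrichment",
    "receptor_distance",
    "coverage_stats",
]


@dataclass
class ClassMetrics:
    precision: np.ndarray   # per class
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray     # true instances per class
    weighted_f1: float
    n_abstain: int = 0

    def as_frame(self, class_names: Optional[Sequence[str]] = None) -> pd.DataFrame:
        idx = class_names if class_names is not None else range(len(self.f1))
        return pd.DataFrame({"precision": self.precision, "recall": self.recall,
                             "f1": self.f1, "support": self.support}, index=idx)


@dataclass
class RegressionMetrics:
    mse: float
    mae: float
    pearson: float
    spearman: float
    kendall: float
    n: int
    n_abstain: int = 0


def classification_metrics(true_classes: Sequence, predicted: Sequence,
                           n_classes: int,
                           abstain_policy: str = "exclude") -> ClassMetrics:
    """Per-class precision/recall/F1 and class-weighted F1.

    ``abstain_policy`` controls ABSTAIN predictions: "exclude" drops those
    pairs, "error" counts them as a wrong prediction (a reserved class that
    can never be correct). A class with zero predicted and zero true
    instances gets precision = recall = 0 and weight 0.
    """
    t_list, p_list, n_abstain = [], [], 0
    for t, p in zip(true_classes, predicted, strict=True):
        if p is ABSTAIN:
            n_abstain += 1
            if abstain_policy == "exclude":
                continue
            elif abstain_policy == "error":
                p = n_classes  # reserved never-correct bucket
            else:
                raise ValueError(f"unknown abstain_policy {abstain_policy!r}")
        t_list.append(int(t))
        p_list.append(int(p))
    t_arr = np.asarray(t_list, dtype=int)
    p_arr = np.asarray(p_list, dtype=int)
    precision = np.zeros(n_classes)
    recall = np.zeros(n_classes)
    f1 = np.zeros(n_classes)
    support = np.zeros(n_classes)
    for c in range(n_classes):
        tp = int(((p_arr == c) & (t_arr == c)).sum())
        fp = int(((p_arr == c) & (t_arr != c)).sum())
        fn = int(((p_arr != c) & (t_arr == c)).sum())
        support[c] = tp + fn
        precision[c] = tp / (tp + fp) if tp + fp else 0.0
        recall[c] = tp / (tp + fn) if tp + fn else 0.0
        if precision[c] + recall[c] > 0:
            f1[c] = 2 * precision[c] * recall[c] / (precision[c] + recall[c])
    weights = support / support.sum() if support.sum() else np.zeros(n_classes)
    return ClassMetrics(precision=precision, recall=recall, f1=f1,
                        support=support,
                        weighted_f1=float((weights * f1).sum()),
                        n_abstain=n_abstain)


def regression_metrics(true_values: Sequence, predicted: Sequence
                       ) -> RegressionMetrics:
    """MSE, MAE and rank/linear correlations; ABSTAIN pairs are excluded
    (their count is reported). Zero-variance inputs give NaN correlations."""
    t_list, p_list, n_abstain = [], [], 0
    for t, p in zip(true_values, predicted, strict=True):
        if p is ABSTAIN:
            n_abstain += 1
            continue
        t_list.append(float(t))
        p_list.append(float(p))
    t = np.asarray(t_list)
    p = np.asarray(p_list)
    if len(t) == 0:
        return RegressionMetrics(float("nan"), float("nan"), float("nan"),
                                 float("nan"), float("nan"), 0, n_abstain)
    mse = float(np.mean((t - p) ** 2))
    mae = float(np.mean(np.abs(t - p)))
    if len(t) < 2 or np.std(t) == 0 or np.std(p) == 0:
        pear = spear = kend = float("nan")
    else:
        pear = float(stats.pearsonr(t, p).statistic)
        spear = float(stats.spearmanr(t, p).statistic)
        kend = float(stats.kendalltau(t, p).statistic)
    return RegressionMetrics(mse=mse, mae=mae, pearson=pear, spearman=spear,
                             kendall=kend, n=len(t), n_abstain=n_abstain)


def homophily_performance(mean_predictor_pearson: Sequence[float],
                          model_pearson: Sequence[float]) -> dict:
    """Correlation between per-receptor homophily and model skill.

    x is the per-receptor Pearson of the neighbourhood-mean predictor (a
    direct proxy for how homophilous that receptor's label landscape is);
    y is the per-receptor Pearson of a model. Returns their Pearson
    correlation with the two-sided t-statistic p-value, plus the scatter
    data. Requires at least 3 receptors.
    """
    x = np.asarray(mean_predictor_pearson, dtype=float)
    y = np.asarray(model_pearson, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 receptors with finite metrics")
    res = stats.pearsonr(x, y)
    return {"correlation": float(res.statistic),
            "p_value": float(res.pvalue),
            "n_receptors": int(len(x)),
            "x": x, "y": y}


@dataclass
class EnrichmentTable:
    """2x2 confusion of predicted vs experimental hits with derived rates.

    ``baseline_hit_rate`` is the experimental hit fraction over all matched
    pairs; ``enriched_hit_rate`` the hit fraction within the predicted-hit
    subset (equal to precision); enrichment = their ratio.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    n_unmatched: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def baseline_hit_rate(self) -> float:
        return (self.tp + self.fn) / self.n if self.n else float("nan")

    @property
    def enriched_hit_rate(self) -> float:
        return self.precision

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "specificity": self.specificity, "precision": self.precision,
                "sensitivity": self.sensitivity,
                "baseline_hit_rate": self.baseline_hit_rate,
                "enriched_hit_rate": self.enriched_hit_rate,
                "n_unmatched": self.n_unmatched}


def enrichment(predicted: pd.DataFrame, experimental: pd.DataFrame,
               ki_threshold_nm: float = 100.0,
               z_threshold: float = 3.0) -> EnrichmentTable:
    """Predicted-hit vs experimental-hit confusion table.

    ``predicted`` needs (compound_id, receptor_id, predicted_class_name,
    predicted_ki_nm); ``experimental`` needs (compound_id, receptor_id, z).
    Predicted hit: class is not 'No Effect' AND predicted Ki < threshold.
    Experimental hit: Z > threshold (positive activation). Keys present in
    only one table are counted as unmatched, never silently dropped.
    """
    key = ["compound_id", "receptor_id"]
    merged = predicted.merge(experimental, on=key, how="outer",
                             indicator=True)
    unmatched = int((merged["_merge"] != "both").sum())
    both = merged[merged["_merge"] == "both"]
    pred_hit = ((both["predicted_class_name"] != "No Effect")
                & (both["predicted_ki_nm"] < ki_threshold_nm))
    exp_hit = both["z"] > z_threshold
    return EnrichmentTable(
        tp=int((pred_hit & exp_hit).sum()),
        fp=int((pred_hit & ~exp_hit).sum()),
        fn=int((~pred_hit & exp_hit).sum()),
        tn=int((~pred_hit & ~exp_hit).sum()),
        n_unmatched=unmatched)


def receptor_distance(labels_i: dict[str, int], labels_j: dict[str, int],
                      metric: str = "cramers_v",
                      embeddings: Optional[tuple[np.ndarray, np.ndarray]] = None,
                      min_cooccurring: int = 5) -> float:
    """Distance between two receptors.

    ``cramers_v``: 1 - bias-corrected Cramer's V over the bioactivity labels
    of compounds with data on both receptors; fewer than ``min_cooccurring``
    shared compounds gives the maximum distance 1. ``cosine``: 1 - cosine
    similarity of the two receptor embeddings (range [0, 2]).
    """
    if metric == "cosine":
        if embeddings is None:
            raise ValueError("cosine metric needs embeddings")
        a, b = embeddings
        return float(1.0 - (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    if metric != "cramers_v":
        raise ValueError(f"unknown metric {metric!r}")
    shared = sorted(set(labels_i) & set(labels_j))
    if len(shared) < min_cooccurring:
        return 1.0
    x = np.array([labels_i[c] for c in shared])
    y = np.array([labels_j[c] for c in shared])
    return 1.0 - _cramers_v_corrected(x, y)


def _cramers_v_corrected(x: np.ndarray, y: np.ndarray) -> float:
    """Bias-corrected (Bergsma) Cramer's V between two categorical vectors."""
    xi = pd.factorize(x)[0]
    yi = pd.factorize(y)[0]
    table = pd.crosstab(xi, yi).to_numpy()
    n = table.sum()
    r, c = table.shape
    if r < 2 or c < 2:
        # one of the vectors is constant; association is maximal when both
        # are constant together, but there is no variation to measure
        return 1.0 if r == 1 and c == 1 else 0.0
    chi2 = stats.chi2_contingency(table, correction=False).statistic
    phi2 = chi2 / n
    phi2_corr = max(0.0, phi2 - (r - 1) * (c - 1) / (n - 1))
    r_corr = r - (r - 1) ** 2 / (n - 1)
    c_corr = c - (c - 1) ** 2 / (n - 1)
    denom = min(r_corr - 1, c_corr - 1)
    if denom <= 0:
        return 0.0
    return float(np.sqrt(phi2_corr / denom))


def coverage_stats(n_compounds: int, n_receptors: int, n_labelled: int) -> dict:
    """Size of the full compound x receptor interaction matrix and the
    fraction of it that carries a label."""
    possible = n_compounds * n_receptors
    return {"possible_dtis": possible,
            "possible_dtis_millions": possible / 1e6,
            "coverage_percent": 100.0 * n_labelled / possible if possible else 0.0}
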