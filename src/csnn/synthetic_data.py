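"""Synthetic homophilous chemical spaces with sparse compound-receptor labels.

The generator emulates the structural features that make labels-as-features
inference work on real bioactivity data, at desk scale:

* compounds fall into clusters around random bit-vector prototypes — the
  analogue of chemical series, so within-cluster Tanimoto similarity is high
  and across-cluster similarity low;
* each (cluster, receptor) pair draws one latent bioactivity class and one
  latent affinity; a member compound inherits the cluster class with
  probability ``homophily`` (else a uniformly random other class), so the
  within-cluster label-agreement rate is a direct dial for network homophily;
* labels are dropped i.i.d. to emulate the sparse annotation of public
  databases;
* a simulated single-point luminescence screen places inactive pairs on a
  per-receptor Gaussian baseline (in log10 RLU) and shifts active pairs by a
  stated effect size in baseline-sigma units.

Synthetic compounds are abstract bit vectors with generated ids — no SMILES
are synthesised. Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from csnn.chem_encoding import CompoundRecord, pack_bits

__all__ = ["SyntheticSpec", "SyntheticSpace", "generate_space", "generate_screen"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic chemical space.

    ``homophily`` is the probability that a compound inherits its cluster's
    latent class on a receptor; ``label_sparsity`` the fraction of
    (compound, receptor) labels dropped; ``flip_rate`` the per-bit mutation
    probability of cluster members relative to their prototype.
    """

    n_clusters: int = 12
    compounds_per_cluster: int = 15
    scaffolds_per_cluster: int = 3
    fingerprint_length: int = 512
    prototype_density: float = 0.3
    flip_rate: float = 0.02
    n_receptors: int = 8
    homophily: float = 0.9
    label_sparsity: float = 0.3
    regression_noise_sd: float = 0.3
    n_classes: int = 6
    affinity_range: tuple[float, float] = (4.0, 9.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("prototype_density", "flip_rate", "homophily",
                     "label_sparsity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_clusters", "compounds_per_cluster", "n_receptors",
                     "n_classes", "fingerprint_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SyntheticSpace:
    """Output of :func:`generate_space`."""

    spec: SyntheticSpec
    compounds: list[CompoundRecord]
    cluster_of: dict[str, int]  # compound_id -> ground-truth cluster
    scaffold_of: dict[str, str]  # compound_id -> scaffold-like subgroup key
    dti: pd.DataFrame  # observed labels: compound_id, receptor_id, class_idx, value
    truth: pd.DataFrame  # all pairs: compound_id, receptor_id, class_idx, value, labelled
    latent: pd.DataFrame  # cluster, receptor_id, latent_class, latent_value

    @property
    def receptor_ids(self) -> list[str]:
        return [f"R{r:03d}" for r in range(self.spec.n_receptors)]

    def labels_for(self, receptor_id: str) -> dict[str, int]:
        sub = self.dti[self.dti["receptor_id"] == receptor_id]
        return dict(zip(sub["compound_id"], sub["class_idx"].astype(int)))

    def values_for(self, receptor_id: str) -> dict[str, float]:
        sub = self.dti[self.dti["receptor_id"] == receptor_id]
        return dict(zip(sub["compound_id"], sub["value"].astype(float)))

    def labels_by_receptor(self) -> dict[str, dict[str, int]]:
        return {r: self.labels_for(r) for r in self.receptor_ids}


def generate_space(spec: SyntheticSpec) -> SyntheticSpace:
    """Draw one synthetic chemical space from the given conditions."""
    rng = np.random.default_rng(spec.seed)
    n_bits = spec.fingerprint_length

    compounds: list[CompoundRecord] = []
    cluster_of: dict[str, int] = {}
    scaffold_of: dict[str, str] = {}
    for c in range(spec.n_clusters):
        proto = (rng.random(n_bits) < spec.prototype_density).astype(np.uint8)
        for m in range(spec.compounds_per_cluster):
            flips = rng.random(n_bits) < spec.flip_rate
            bits = np.where(flips, 1 - proto, proto).astype(np.uint8)
            cid = f"C{c:03d}_{m:03d}"
            compounds.append(CompoundRecord(
                compound_id=cid, smiles=None,
                fingerprint=pack_bits(bits), n_bits=n_bits))
            cluster_of[cid] = c
            # chemical series hold several ring-system scaffolds; splitting
            # on these subgroups keeps scaffold-disjointness without
            # severing every within-cluster neighbour relation
            scaffold_of[cid] = f"S{c:03d}_{m % spec.scaffolds_per_cluster}"

    lo, hi = spec.affinity_range
    latent_rows = []
    latent_class = np.empty((spec.n_clusters, spec.n_receptors), dtype=int)
    latent_value = np.empty((spec.n_clusters, spec.n_receptors))
    for c in range(spec.n_clusters):
        for r in range(spec.n_receptors):
            latent_class[c, r] = rng.integers(spec.n_classes)
            latent_value[c, r] = rng.uniform(lo, hi)
            latent_rows.append({"cluster": c, "receptor_id": f"R{r:03d}",
                                "latent_class": int(latent_class[c, r]),
                                "latent_value": float(latent_value[c, r])})

    rows = []
    for rec in compounds:
        c = cluster_of[rec.compound_id]
        for r in range(spec.n_receptors):
            if rng.random() < spec.homophily:
                cls = int(latent_class[c, r])
            else:
                # uniformly random *other* class
                offset = int(rng.integers(1, spec.n_classes)) if spec.n_classes > 1 else 0
                cls = (int(latent_class[c, r]) + offset) % spec.n_classes
            value = float(latent_value[c, r]
                          + rng.normal(0.0, spec.regression_noise_sd))
            labelled = bool(rng.random() >= spec.label_sparsity)
            rows.append({"compound_id": rec.compound_id,
                         "receptor_id": f"R{r:03d}",
                         "class_idx": cls, "value": value,
                         "labelled": labelled})
    truth = pd.DataFrame(rows)
    dti = truth[truth["labelled"]].drop(columns="labelled").reset_index(drop=True)
    return SyntheticSpace(spec=spec, compounds=compounds, cluster_of=cluster_of,
                          scaffold_of=scaffold_of, dti=dti, truth=truth,
                          latent=pd.DataFrame(latent_rows))


def generate_screen(dti_truth: pd.DataFrame,
                    active: pd.Series | np.ndarray,
                    effect_size_sd: float = 6.0,
                    baseline_mean: float = 4.0,
                    baseline_sd: float = 0.2,
                    seed: int = 0) -> pd.DataFrame:
    """Simulate a single-point luminescence screen over given DTI pairs.

    ``dti_truth`` needs columns (compound_id, receptor_id); ``active`` marks
    which pairs produce a real signal. Inactive pairs draw log10 RLU from
    the per-receptor baseline Normal(baseline_mean, baseline_sd); active
    pairs are shifted upward by ``effect_size_sd`` baseline standard
    deviations. Returns (compound_id, receptor_id, rlu, active) with RLU on
    the raw (linear) scale, strictly positive by construction.
    """
    rng = np.random.default_rng(seed)
    active = np.asarray(active, dtype=bool)
    if len(active) != len(dti_truth):
        raise ValueError("active flag length must match dti_truth")
    log_rlu = rng.normal(baseline_mean, baseline_sd, size=len(dti_truth))
    log_rlu = log_rlu + active * effect_size_sd * baseline_sd
    out = dti_truth[["compound_id", "receptor_id"]].copy()
    out["rlu"] = np.power(10.0, log_rlu)
    out["active"] = active
    return out
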