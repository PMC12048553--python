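"""Z-score analysis of single-point luminescence screens and hit calling.

Raw relative luminescence (RLU) readings are log10-transformed (the log
makes the per-receptor distribution approximately Gaussian), then
standardised per receptor:

    Z      = (x - mu_r) / sigma_r
    Z_mod  = 0.6745 * (x - median_r) / MAD_r,  MAD_r = median(|x - median_r|)

The modified Z-score is the robust variant (median and MAD resist the very
outliers a screen is hunting for); the 0.6745 factor makes it consistent
with the plain Z under normality. Hits are readings whose score strictly
exceeds the threshold (default 3), either two-sided on |Z| or positive-only.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["validate_screen", "zscore", "modified_zscore", "call_hits"]

MAD_CONSISTENCY = 0.6745


def validate_screen(table: pd.DataFrame,
                    exclusion_list: Optional[Sequence[str]] = None
                    ) -> pd.DataFrame:
    """Validate a long-format screen table and drop excluded compounds.

    Needs columns (compound_id, receptor_id, rlu) with strictly positive
    RLU; (compound, receptor, replicate) must be unique. ``exclusion_list``
    removes compounds known to perturb the readout receptor-independently
    (e.g. luminescence-dampening compounds).
    """
    required = {"compound_id", "receptor_id", "rlu"}
    if not required.issubset(table.columns):
        raise ValueError(f"screen table needs columns {sorted(required)}")
    if (table["rlu"] <= 0).any():
        bad = table.loc[table["rlu"] <= 0, "compound_id"].unique()
        raise ValueError(f"RLU must be strictly positive; offending "
                         f"compounds: {list(bad)[:5]}")
    key = ["compound_id", "receptor_id"]
    if "replicate" in table.columns:
        key.append("replicate")
    if table.duplicated(subset=key).any():
        raise ValueError("duplicate (compound, receptor, replicate) rows")
    if exclusion_list:
        table = table[~table["compound_id"].isin(set(exclusion_list))]
    return table.reset_index(drop=True)


def zscore(table: pd.DataFrame, ddof: int = 1,
           exclusion_list: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-receptor Z-score of log10 RLU.

    ``ddof=1`` (sample standard deviation) by default; set 0 for the
    population convention. Each receptor needs at least 2 readings and a
    non-zero spread. Adds columns ``log_rlu`` and ``z``.
    """
    table = validate_screen(table, exclusion_list)
    out = table.copy()
    out["log_rlu"] = np.log10(out["rlu"].astype(float))
    grouped = out.groupby("receptor_id")["log_rlu"]
    counts = grouped.transform("size")
    if (counts < 2).any():
        bad = out.loc[counts < 2, "receptor_id"].unique()
        raise ValueError(f"receptors with <2 readings: {list(bad)}")
    mu = grouped.transform("mean")
    sigma = grouped.transform("std", ddof=ddof)
    if (sigma == 0).any() or sigma.isna().any():
        bad = out.loc[(sigma == 0) | sigma.isna(), "receptor_id"].unique()
        raise ValueError(f"zero RLU spread for receptors: {list(bad)}")
    out["z"] = (out["log_rlu"] - mu) / sigma
    return out


def modified_zscore(table: pd.DataFrame,
                    exclusion_list: Optional[Sequence[str]] = None
                    ) -> pd.DataFrame:
    """Per-receptor robust (median/MAD) Z-score of log10 RLU.

    Adds columns ``log_rlu`` and ``z_mod``. Raises when a receptor's MAD is
    zero (more than half the readings identical).
    """
    table = validate_screen(table, exclusion_list)
    out = table.copy()
    out["log_rlu"] = np.log10(out["rlu"].astype(float))
    med = out.groupby("receptor_id")["log_rlu"].transform("median")
    abs_dev = (out["log_rlu"] - med).abs()
    mad = abs_dev.groupby(out["receptor_id"]).transform("median")
    if (mad == 0).any():
        bad = out.loc[mad == 0, "receptor_id"].unique()
        raise ValueError(f"zero MAD for receptors: {list(bad)}")
    out["z_mod"] = MAD_CONSISTENCY * (out["log_rlu"] - med) / mad
    return out


def call_hits(scored: pd.DataFrame, threshold: float = 3.0,
              sign: str = "two_sided", column: str = "z") -> pd.DataFrame:
    """Flag hits by strict threshold on a score column.

    ``sign='two_sided'`` calls |Z| > threshold; ``'positive'`` calls
    Z > threshold only (activation hits). A score exactly at the threshold
    is never a hit. Adds a boolean ``hit`` column.
    """
    out = scored.copy()
    z = out[column].astype(float)
    if sign == "two_sided":
        out["hit"] = z.abs() > threshold
    elif sign == "positive":
        out["hit"] = z > threshold
    else:
        raise ValueError(f"unknown sign {sign!r}")
    return out
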