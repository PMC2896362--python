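"""Spot-volume quantification and fold-change filtering.

Normalizes each spot's optical density to the total spot volume of its
gel, computes symmetric fold changes with a direction flag, and applies
the inclusive "at least X-fold" filters used to pick spots (1.1-fold) and
to select the analysis set (1.5-fold).  Also provides the gene-expression
centering and log fold-difference used when comparing against microarray
data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PICK_FOLD = 1.1
ANALYSIS_FOLD = 1.5


def normalize_volumes(spots: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw spot volumes to each condition's total.

    Input columns: ``spot_id, raw_A, raw_B`` (extra columns such as
    ``accession`` pass through).  Spots missing in one condition (NaN)
    are excluded with a warning; an all-zero condition is a degenerate
    input.  Adds ``norm_A, norm_B, fold_change, direction`` where
    fold_change = max(norm)/min(norm) >= 1 and direction is one of
    ``up_in_A / up_in_B / unchanged``.
    """
    df = spots.copy()
    present = df["raw_A"].notna() & df["raw_B"].notna()
    if (~present).any():
        log.warning("excluding %d spot(s) present in only one gel",
                    int((~present).sum()))
        df = df[present].copy()
    if df.empty:
        raise ValueError("no spots present in both conditions")
    if (df["raw_A"] < 0).any() or (df["raw_B"] < 0).any():
        raise ValueError("raw volumes must be non-negative")
    for col in ("raw_A", "raw_B"):
        total = df[col].sum()
        if total <= 0:
            raise ValueError(f"condition {col[-1]} has zero total volume")
        df[f"norm_{col[-1]}"] = df[col] / total
    hi = df[["norm_A", "norm_B"]].max(axis=1)
    lo = df[["norm_A", "norm_B"]].min(axis=1)
    with np.errstate(divide="ignore"):
        df["fold_change"] = np.where(lo > 0, hi / lo, np.inf)
    df["direction"] = np.select(
        [df["norm_A"] > df["norm_B"], df["norm_B"] > df["norm_A"]],
        ["up_in_A", "up_in_B"], default="unchanged")
    return df


def fold_filter(records: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Retain spots changed by at least ``threshold``-fold (inclusive).

    Input order is preserved; requires a ``fold_change`` column as
    produced by :func:`normalize_volumes`.
    """
    if threshold < 1:
        raise ValueError("fold threshold must be >= 1")
    return records[records["fold_change"] >= threshold].copy()


def center_and_fold(expr: pd.DataFrame, line_a: str, line_b: str
                    ) -> pd.DataFrame:
    """Center log-abundance expression rows and compute fold-differences.

    ``expr`` is a probe x cell-line matrix of log10 abundances.  Each
    probe is centered by subtracting its row mean; the fold-difference
    between the two named lines is log10(A) - log10(B) (so 0.3 is about a
    2-fold linear difference).  Probes with missing values are excluded
    and logged.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two cell lines")
    for line in (line_a, line_b):
        if line not in expr.columns:
            raise KeyError(f"cell line {line!r} not in matrix")
    complete = expr.notna().all(axis=1)
    if (~complete).any():
        log.warning("excluding %d probe(s) with missing values",
                    int((~complete).sum()))
    expr = expr[complete]
    centered = expr.sub(expr.mean(axis=1), axis=0)
    out = centered.copy()
    out["fold_difference"] = expr[line_a] - expr[line_b]
    out["direction"] = np.select(
        [out["fold_difference"] > 0, out["fold_difference"] < 0],
        [f"up_in_{line_a}", f"up_in_{line_b}"], default="unchanged")
    return out
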