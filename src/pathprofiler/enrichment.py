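"""Canonical-pathway over-representation analysis.

For each pathway a 2x2 contingency table is built from the focus
(differentially expressed) proteins: k focus proteins among the pathway's
n members, out of K focus proteins in a universe of N annotated proteins.
Significance is a right-tailed Fisher's exact test (the hypergeometric
tail P(X >= k)) with Benjamini-Hochberg correction across pathways; each
pathway also carries the coverage ratio k/n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """The (k, n, K, N) quadruple for one pathway.

    k: focus proteins in the pathway; n: pathway size; K: total focus
    proteins; N: universe size.  All four cells of the implied 2x2 table
    must be non-negative.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        cells = (self.k, self.n - self.k, self.K - self.k,
                 (self.N - self.n) - (self.K - self.k))
        if min(cells) < 0 or self.n > self.N or self.K > self.N:
            raise ValueError(f"inconsistent contingency table {self}")


def build_tables(focus: set[str], knowledgebase: dict[str, set[str]],
                 universe: set[str] | None = None
                 ) -> dict[str, ContingencyTable]:
    """One contingency table per pathway.

    The universe defaults to the union of all pathway members (every
    protein with at least one annotation); focus proteins outside the
    universe are dropped with a warning, which reduces K.
    """
    if universe is None:
        universe = set().union(*knowledgebase.values()) if knowledgebase \
            else set()
    in_universe = focus & universe
    dropped = focus - universe
    if dropped:
        log.warning("dropping %d focus protein(s) absent from the "
                    "annotation universe: %s", len(dropped),
                    ", ".join(sorted(dropped)[:5]))
    K, N = len(in_universe), len(universe)
    return {pid: ContingencyTable(k=len(in_universe & members & universe),
                                  n=len(members & universe), K=K, N=N)
            for pid, members in knowledgebase.items()}


def fisher_right_tail(table: ContingencyTable) -> float:
    """Right-tailed Fisher's exact test.

    p = P(X >= k) for X hypergeometric(N, K, n); evaluated with the
    stable log-space survival function.  Always in (0, 1].
    """
    p = float(hypergeom.sf(table.k - 1, table.N, table.K, table.n))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j>=i} p_(j) * m / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def rank_pathways(focus: set[str], knowledgebase: dict[str, set[str]],
                  alpha: float = 0.05,
                  universe: set[str] | None = None) -> pd.DataFrame:
    """Full over-representation report, one row per pathway.

    Columns: k, n, K, N, ratio (= k/n), p_raw, p_bh, significant
    (p_bh < alpha, strict), rank_by_p (ascending p_bh) and rank_by_ratio
    (descending ratio); ties in either ranking break by pathway_id.
    """
    tables = build_tables(focus, knowledgebase, universe)
    pids = sorted(tables)
    rows = []
    for pid in pids:
        t = tables[pid]
        rows.append({"pathway_id": pid, "k": t.k, "n": t.n, "K": t.K,
                     "N": t.N, "ratio": t.k / t.n if t.n else 0.0,
                     "p_raw": fisher_right_tail(t)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.reindex(columns=["pathway_id", "k", "n", "K", "N",
                                   "ratio", "p_raw", "p_bh", "significant",
                                   "rank_by_p", "rank_by_ratio"])
    df["p_bh"] = bh_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_bh"] < alpha
    by_p = df.sort_values(["p_bh", "pathway_id"]).index
    df.loc[by_p, "rank_by_p"] = np.arange(1, len(df) + 1)
    by_ratio = df.sort_values(["ratio", "pathway_id"],
                              ascending=[False, True]).index
    df.loc[by_ratio, "rank_by_ratio"] = np.arange(1, len(df) + 1)
    df[["rank_by_p", "rank_by_ratio"]] = \
        df[["rank_by_p", "rank_by_ratio"]].astype(int)
    return df.sort_values("rank_by_p").reset_index(drop=True)
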