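"""Multiple-test correction, candidate merging and enrichment testing.

P-values are corrected *within each phylogenetic condition* (each condition
is its own family of tests).  A group becomes a candidate when at least one
condition gives q below the FDR threshold (default 0.2) *and* the fitted
foreground omega exceeds the background omega there — the elevated-dN/dS
direction requirement.  The final check is a one-sided hypergeometric
(Fisher) exact test for enrichment of known genes among the candidates.

The q-values are Benjamini-Hochberg step-up values (with an optional
Storey pi0-adjusted variant); BH is distribution-free and well defined at
small batch sizes, so its numbers will differ from empirical-null local-fdr
estimators fitted to genome-scale batches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    ``q_(i) = min_(j>=i) min(1, p_(j) * n / j)`` over the sorted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def storey_qvalues(pvalues, lambda_: float = 0.5) -> np.ndarray:
    """Storey pi0-adjusted q-values (optional, less conservative variant)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    pi0 = min(1.0, float((p > lambda_).mean()) / (1.0 - lambda_))
    pi0 = max(pi0, 1.0 / p.size)
    return np.minimum(bh_fdr(p) * pi0, 1.0)


def add_qvalues(scan: pd.DataFrame, method: str = "bh") -> pd.DataFrame:
    """Append a ``q`` column, correcting within each condition separately."""
    fn = {"bh": bh_fdr, "storey": storey_qvalues}[method]
    out = scan.copy()
    out["q"] = np.nan
    for cond, idx in out.groupby("condition").groups.items():
        rows = out.loc[idx]
        tested = rows.index[rows["status"] == "tested"]
        if len(tested):
            out.loc[tested, "q"] = fn(out.loc[tested, "p"].to_numpy())
    return out


@dataclass
class CandidateList:
    """Groups flagged by the scan, with their supporting conditions."""

    table: pd.DataFrame  # group_id, best_condition, min_q, omega_fg, omega_bg
    conditions: Dict[str, List[int]]  # group -> conditions with q < threshold

    @property
    def group_ids(self) -> List[str]:
        return list(self.table["group_id"])


def merge_candidates(scan_q: pd.DataFrame,
                     threshold: float = 0.2) -> CandidateList:
    """Merge per-condition discoveries into the final candidate list.

    A group qualifies iff some condition has ``q < threshold`` (strict) and
    ``omega_fg > omega_bg`` (strict) in that same test.  Output is sorted
    by minimum q, ties by group id.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    hits = scan_q[(scan_q["status"] == "tested")
                  & (scan_q["q"] < threshold)
                  & (scan_q["omega_fg"] > scan_q["omega_bg"])]
    rows = []
    conditions: Dict[str, List[int]] = {}
    for gid, sub in hits.groupby("group_id"):
        best = sub.loc[sub["q"].idxmin()]
        conditions[gid] = sorted(sub["condition"].tolist())
        rows.append({
            "group_id": gid,
            "best_condition": int(best["condition"]),
            "min_q": float(best["q"]),
            "omega_fg": float(best["omega_fg"]),
            "omega_bg": float(best["omega_bg"]),
            "n_conditions": len(conditions[gid]),
        })
    table = pd.DataFrame(
        rows, columns=["group_id", "best_condition", "min_q",
                       "omega_fg", "omega_bg", "n_conditions"])
    if len(table):
        table = table.sort_values(["min_q", "group_id"],
                                  kind="mergesort").reset_index(drop=True)
    return CandidateList(table=table, conditions=conditions)


def enrichment_fisher(n_total: int, n_candidates: int,
                      n_known: int, n_known_detected: int) -> float:
    """One-sided enrichment P: hypergeometric upper tail P(X >= observed).

    ``X`` counts known genes among the candidates when ``n_candidates``
    genes are drawn from ``n_total`` containing ``n_known`` known genes.
    Computed by exact summation in log space.
    """
    N, n, K, x = n_total, n_candidates, n_known, n_known_detected
    if not (0 <= x <= K <= N and 0 <= n <= N and x <= n):
        raise ValueError("inconsistent contingency counts")
    if x == 0:
        return 1.0

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    terms = []
    for k in range(x, min(K, n) + 1):
        terms.append(log_choose(K, k) + log_choose(N - K, n - k)
                     - log_choose(N, n))
    terms = np.asarray(terms)
    m = terms.max()
    return float(min(1.0, np.exp(m) * np.exp(terms - m).sum()))
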