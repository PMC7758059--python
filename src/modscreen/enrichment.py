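"""Hypergeometric gene-list overlap tests and multiple-testing correction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class OverlapTest:
    size_a: int
    size_b: int
    overlap: int
    universe: int
    p_upper: float
    expected: float
    fold: float


def hypergeom_overlap(size_a: int, size_b: int, overlap: int, universe: int) -> OverlapTest:
    """Upper-tail hypergeometric test of the overlap between two gene lists.

    p = P(X >= overlap) with X ~ Hypergeometric(universe, size_a, size_b):
    the chance that two random lists of these sizes drawn from the universe
    share at least this many genes.  The observed value is included in the
    tail (standard convention).
    """
    if not (0 <= size_a <= universe and 0 <= size_b <= universe):
        raise ValueError("list sizes must lie within the universe")
    if overlap > min(size_a, size_b):
        raise ValueError("overlap exceeds the smaller list")
    if overlap < max(0, size_a + size_b - universe):
        raise ValueError("overlap impossible given the margins")
    p_upper = float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))
    expected = size_a * size_b / universe if universe else 0.0
    fold = overlap / expected if expected > 0 else np.inf
    return OverlapTest(size_a, size_b, overlap, universe, min(p_upper, 1.0), expected, fold)


def bh_qvalues(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q >= p elementwise)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def set_enrichment(
    query: list[str] | set[str],
    collection: dict[str, list[str]],
    universe: list[str] | set[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query gene list against each set.

    The universe must be supplied explicitly; it defines both the sampling
    frame and the margins (sets are intersected with it).  One upper-tail
    test per set, with Benjamini-Hochberg q-values over the collection.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValueError("query gene list is empty")
    extra = query - universe
    if extra:
        raise ValueError(f"query genes outside the universe: {sorted(extra)[:5]}")
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & universe
        if not members:
            continue
        k = len(query & members)
        t = hypergeom_overlap(len(query), len(members), k, len(universe))
        rows.append(
            {
                "set_name": name,
                "set_size": len(members),
                "overlap": k,
                "expected": t.expected,
                "fold": t.fold,
                "p_value": t.p_upper,
            }
        )
    out = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "expected", "fold", "p_value"])
    if len(out):
        out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    return out
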