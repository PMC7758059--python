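"""Evolutionary rate covariation against a focal gene.

For each taxonomic clade, a gene's branch-specific relative rates are the
residuals of regressing its log branch lengths on the log clade-average
branch lengths; genes that evolve in a correlated fashion (e.g. members of
one pathway or complex) show positively correlated relative-rate vectors.
Per-clade one-sided correlation p-values are integrated across the clades
where both genes are present by summing -log10 p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from modscreen.containers import RateTreeSet

PSEUDOCOUNT = 1e-6
MIN_BRANCHES_RELATIVE = 4


class InsufficientBranchesError(ValueError):
    pass


def relative_rates(
    gene_branches: np.ndarray, clade_mean_branches: np.ndarray, pseudocount: float = PSEUDOCOUNT
) -> np.ndarray:
    """Branch-specific relative rates as log-scale OLS residuals.

    Both vectors are log-transformed after flooring at a small pseudocount
    (admitting zero-length branches; flooring rather than adding keeps the
    transform exactly scale-equivariant for branches above the floor); the
    gene vector is regressed on the clade mean with an intercept, so a
    constant rate multiplier (gene-wide fast or slow evolution) is absorbed
    and only branch-specific deviations remain.  Residuals have mean zero by
    construction.
    """
    g = np.asarray(gene_branches, dtype=float)
    m = np.asarray(clade_mean_branches, dtype=float)
    if g.shape != m.shape:
        raise ValueError("gene and clade-mean vectors must align on the same branches")
    if len(g) < MIN_BRANCHES_RELATIVE:
        raise InsufficientBranchesError(f"need >= {MIN_BRANCHES_RELATIVE} branches, got {len(g)}")
    if np.any(g < 0) or np.any(m < 0):
        raise ValueError("branch lengths must be non-negative")
    lg = np.log(np.maximum(g, pseudocount))
    lm = np.log(np.maximum(m, pseudocount))
    X = np.column_stack([np.ones_like(lm), lm])
    coef, *_ = np.linalg.lstsq(X, lg, rcond=None)
    return lg - X @ coef


def erc_pair(
    rr_a: np.ndarray, rr_b: np.ndarray, min_branches: int = 8
) -> tuple[float, float, int]:
    """Pearson correlation of two relative-rate vectors with a one-sided p.

    The p-value tests r > 0 through the t-transform
    t = r sqrt((n-2)/(1-r^2)); identical vectors give p at the numerical
    floor rather than zero.
    """
    a = np.asarray(rr_a, dtype=float)
    b = np.asarray(rr_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("relative-rate vectors must share the same branches")
    n = len(a)
    if n < min_branches:
        raise InsufficientBranchesError(f"only {n} shared branches (< {min_branches})")
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0, 1.0, n
    r = float(np.corrcoef(a, b)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0 if r > 0 else 1.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(stats.t.sf(t, n - 2))
    p = max(p, np.finfo(float).tiny)
    return r, min(p, 1.0), n


def integrate_clades(per_clade: list[tuple[float, float]], log_base: float = 10.0) -> float:
    """Integrated covariation score: sum of -log p over the present clades."""
    if not per_clade:
        raise ValueError("need at least one clade")
    return float(sum(-np.log(p) / np.log(log_base) for _, p in per_clade))


@dataclass
class ERCResult:
    gene_id: str
    per_clade: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    sum_nlogpv: float = 0.0

    def nlogpv(self, clade: str, log_base: float = 10.0) -> float:
        _, p, _ = self.per_clade[clade]
        return float(-np.log(p) / np.log(log_base))


def compute_relative_rates(trees: RateTreeSet) -> dict[str, dict[str, np.ndarray]]:
    """Relative-rate vectors for every gene in every clade where it occurs."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for clade in trees.clade_ids:
        mean = trees.clade_mean(clade)
        out[clade] = {}
        for gene, vec in trees.branch_lengths[clade].items():
            out[clade][gene] = relative_rates(vec, mean)
    return out


def erc_against_focal(
    focal: str,
    trees: RateTreeSet,
    hit_threshold: float = 2.0,
    min_branches: int = 8,
    log_base: float = 10.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Score every other gene's rate covariation with the focal gene.

    For each gene, per-clade correlations are computed over the clades where
    both the gene and the focal gene are present (and have enough branches);
    the integrated score sums -log10 p over those clades.  Hits are genes
    with integrated score strictly above ``hit_threshold``.  Returns the
    table sorted descending by score (ties by gene id) and the hit list.
    """
    focal_clades = trees.clades_with(focal)
    if not focal_clades:
        raise ValueError(f"focal gene {focal!r} absent from every clade")
    rr = compute_relative_rates(trees)

    rows = []
    for gene in trees.genes():
        if gene == focal:
            continue
        per_clade: list[tuple[float, float]] = []
        rec: dict[str, float] = {"gene_id": gene}
        for clade in trees.clade_ids:
            r = p = n = np.nan
            if clade in focal_clades and gene in rr[clade]:
                try:
                    r, p, n = erc_pair(rr[clade][focal], rr[clade][gene], min_branches)
                    per_clade.append((r, p))
                except InsufficientBranchesError:
                    pass
            rec[f"r_{clade}"] = r
            rec[f"p_{clade}"] = p
            rec[f"n_{clade}"] = n
            rec[f"nlogpv_{clade}"] = (
                -np.log(p) / np.log(log_base) if isinstance(p, float) and not np.isnan(p) else np.nan
            )
        rec["n_clades"] = len(per_clade)
        rec["sum_nlogpv"] = integrate_clades(per_clade, log_base) if per_clade else 0.0
        rows.append(rec)

    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["sum_nlogpv", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    hits = table.loc[table["sum_nlogpv"] > hit_threshold, "gene_id"].tolist()
    return table, hits
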