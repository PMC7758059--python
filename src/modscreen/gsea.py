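"""Variant-derived gene scores and weighted enrichment-score analysis.

Each gene is scored by the strength of its best associated variant
(-log10 of the minimum p-value over its assigned variants); gene sets are
then tested with the weighted Kolmogorov-Smirnov running-sum statistic
against a gene-label permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from modscreen.annotate import VariantAssignment


class EmptySetError(ValueError):
    """Gene set has no member in the ranked list."""


def gene_scores(
    assoc: pd.DataFrame, unique_assignments: dict[str, VariantAssignment]
) -> pd.DataFrame:
    """Per-gene metric: -log10 of the gene's best variant p-value.

    Only genes with at least one (uniquely) assigned, tested variant appear.
    The list is sorted descending by score; ties break by gene id so the
    ranking is deterministic.
    """
    p_best: dict[str, float] = {}
    pvals = dict(zip(assoc["id"], assoc["p_value"]))
    for vid, a in unique_assignments.items():
        if a.category == "intergenic" or not a.gene_id:
            continue
        p = pvals.get(vid)
        if p is None or np.isnan(p):
            continue
        cur = p_best.get(a.gene_id)
        if cur is None or p < cur:
            p_best[a.gene_id] = p
    rows = [
        {"gene_id": g, "score": -np.log10(max(p, 1e-300))} for g, p in p_best.items()
    ]
    out = pd.DataFrame(rows, columns=["gene_id", "score"])
    out = out.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def enrichment_score(
    ranked: pd.DataFrame,
    gene_set: list[str] | set[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score over a ranked gene list.

    Walking down the list, hitting a set member increments the sum by
    ``score**w / sum(set scores**w)``, a miss decrements by ``1/(N - k)``.
    ES is the signed maximum deviation from zero; the walk ends at 0.
    """
    genes = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    member = np.isin(genes, list(gene_set))
    k = int(member.sum())
    N = len(genes)
    if k == 0:
        raise EmptySetError("gene set has no member in the ranked list")
    w = np.abs(scores) ** weight_exponent
    denom = w[member].sum()
    steps = np.where(
        member,
        (w / denom) if denom > 0 else (1.0 / k),
        0.0,
    )
    if denom == 0:
        steps = np.where(member, 1.0 / k, 0.0)
    if N > k:
        steps = steps - np.where(member, 0.0, 1.0 / (N - k))
    walk = np.cumsum(steps)
    es = float(walk[np.argmax(np.abs(walk))])
    return es, walk


def permutation_p(
    ranked: pd.DataFrame,
    gene_set: list[str] | set[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Gene-label permutation p-value for the positive enrichment score.

    Set-membership labels are shuffled over the ranked list ``n_perm`` times;
    p = (1 + #{perm ES >= observed}) / (n_perm + 1).  Returns (ES, p).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    es_obs, _ = enrichment_score(ranked, gene_set, weight_exponent)
    genes = ranked["gene_id"].to_numpy()
    k = int(np.isin(genes, list(gene_set)).sum())
    N = len(genes)
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(N, size=k, replace=False)
        perm_set = genes[idx]
        es_perm, _ = enrichment_score(ranked, perm_set, weight_exponent)
        if es_perm >= es_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return es_obs, float(p)


@dataclass
class GeneSetResult:
    name: str
    size: int
    es: float
    p_perm: float
    leading_edge: list[str]


def analyse_sets(
    ranked: pd.DataFrame,
    collection: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> list[GeneSetResult]:
    """ES and permutation p for every set with at least one ranked member.

    The leading edge is the set members at or before the walk's maximum
    (for positive ES).
    """
    rng = np.random.default_rng(seed)
    genes = ranked["gene_id"].to_numpy()
    results = []
    for name in sorted(collection):
        members = collection[name]
        present = [g for g in members if g in set(genes)]
        if not present:
            continue
        es, walk = enrichment_score(ranked, members, weight_exponent)
        _, p = permutation_p(
            ranked, members, n_perm=n_perm, weight_exponent=weight_exponent, rng=rng
        )
        peak = int(np.argmax(np.abs(walk)))
        in_set = np.isin(genes, members)
        leading = (
            [g for g, m in zip(genes[: peak + 1], in_set[: peak + 1]) if m]
            if es >= 0
            else [g for g, m in zip(genes[peak:], in_set[peak:]) if m]
        )
        results.append(GeneSetResult(name, len(present), es, p, leading))
    return results


def filter_sets(
    results: list[GeneSetResult],
    min_size: int = 5,
    min_es: float = 0.25,
    max_p: float = 0.05,
) -> list[GeneSetResult]:
    """Reporting filter: size >= min_size, ES strictly > min_es, p strictly < max_p."""
    return [r for r in results if r.size >= min_size and r.es > min_es and r.p_perm < max_p]


def results_table(results: list[GeneSetResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.name,
                "size": r.size,
                "es": r.es,
                "p_perm": r.p_perm,
                "leading_edge": ",".join(r.leading_edge),
            }
            for r in results
        ],
        columns=["set_name", "size", "es", "p_perm", "leading_edge"],
    )
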