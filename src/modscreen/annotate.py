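"""Variant-to-gene assignment and the candidate-gene table.

A variant is assigned to a gene when it lies inside the gene body (the
transcript span including UTRs) or within a window (default 1 kb) of either
end.  Multi-gene assignments are resolved by the category priority
exon > UTR > intron > upstream/downstream, then by distance, then by gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from modscreen.containers import GeneModelSet

logger = logging.getLogger(__name__)

CATEGORY_PRIORITY = {"exon": 0, "UTR": 1, "intron": 2, "upstream": 3, "downstream": 3}


@dataclass
class VariantAssignment:
    variant_id: str
    gene_id: str
    category: str  # exon | UTR | intron | upstream | downstream | intergenic
    distance: int  # bp from the gene body; 0 if inside


def _in_interval(pos: int, iv: tuple[int, int]) -> bool:
    return iv[0] <= pos <= iv[1]


def _categorise(pos: int, gene) -> tuple[str, int]:
    """Category and distance of a position relative to one gene model."""
    if gene.start <= pos <= gene.end:
        if any(_in_interval(pos, iv) for iv in gene.exons):
            return "exon", 0
        if any(_in_interval(pos, iv) for iv in gene.utrs):
            return "UTR", 0
        return "intron", 0
    if pos < gene.start:
        dist = gene.start - pos
        side = "upstream" if gene.strand == "+" else "downstream"
    else:
        dist = pos - gene.end
        side = "downstream" if gene.strand == "+" else "upstream"
    return side, dist


def assign_all(
    variants: pd.DataFrame, models: GeneModelSet, window: int = 1000
) -> list[VariantAssignment]:
    """Emit every (variant, gene) pair within the window; multi-maps allowed.

    ``variants`` needs columns ``chrom``, ``pos``, ``id``.  The window is
    inclusive: a variant exactly ``window`` bp from a gene body is assigned.
    Variants near no gene get a single ``intergenic`` assignment.
    """
    by_chrom: dict[str, list] = {}
    for g in models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.start)

    out: list[VariantAssignment] = []
    for row in variants.itertuples(index=False):
        genes = by_chrom.get(row.chrom, [])
        pos = int(row.pos)
        matched = False
        # genes are sorted by start; gene bodies in a screen annotation are
        # short relative to chromosome length, so a windowed linear scan over
        # a position-bracketed slice is adequate
        starts = [g.start for g in genes]
        i = np.searchsorted(starts, pos + window + 1)
        for g in genes[:i]:
            if pos > g.end + window:
                continue
            cat, dist = _categorise(pos, g)
            out.append(VariantAssignment(row.id, g.gene_id, cat, dist))
            matched = True
        if not matched:
            out.append(VariantAssignment(row.id, "", "intergenic", -1))
    return out


def unique_assign(assignments: list[VariantAssignment]) -> dict[str, VariantAssignment]:
    """Resolve multi-gene variants to one gene by category priority.

    exon beats UTR beats intron beats upstream/downstream (the latter two are
    equal priority); ties break by smaller distance, then lexicographic gene
    id (logged).
    """
    best: dict[str, VariantAssignment] = {}
    for a in assignments:
        if a.category == "intergenic":
            best.setdefault(a.variant_id, a)
            continue
        cur = best.get(a.variant_id)
        if cur is None or cur.category == "intergenic":
            best[a.variant_id] = a
            continue
        key_new = (CATEGORY_PRIORITY[a.category], a.distance, a.gene_id)
        key_cur = (CATEGORY_PRIORITY[cur.category], cur.distance, cur.gene_id)
        if key_new < key_cur:
            if key_new[:2] == key_cur[:2]:
                logger.info(
                    "%s: tie between %s and %s broken lexicographically",
                    a.variant_id,
                    cur.gene_id,
                    a.gene_id,
                )
            best[a.variant_id] = a
    return best


def candidate_genes(
    assoc: pd.DataFrame,
    models: GeneModelSet,
    p_threshold: float = 1e-5,
    window: int = 1000,
    assignments: list[VariantAssignment] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Rank candidate genes by their most significant associated variant.

    Takes the association table, keeps variants with p below threshold,
    assigns them to genes (multi-mapping allowed, as for the headline
    variant/gene counts), and ranks genes by best variant p-value.  Returns
    the candidate table and a count summary (significant, in-gene,
    intergenic variants, genes).
    """
    sig = assoc[assoc["p_value"] < p_threshold]
    counts = {"n_significant": len(sig), "n_in_gene": 0, "n_intergenic": 0, "n_genes": 0}
    if sig.empty:
        return (
            pd.DataFrame(columns=["rank", "gene_id", "best_p", "n_variants", "categories"]),
            counts,
        )
    if assignments is None:
        assignments = assign_all(sig, models, window=window)
    sig_ids = set(sig["id"])
    p_by_variant = dict(zip(sig["id"], sig["p_value"]))

    per_gene: dict[str, list[VariantAssignment]] = {}
    genic_variants: set[str] = set()
    for a in assignments:
        if a.variant_id not in sig_ids:
            continue
        if a.category == "intergenic":
            continue
        per_gene.setdefault(a.gene_id, []).append(a)
        genic_variants.add(a.variant_id)

    counts["n_in_gene"] = len(genic_variants)
    counts["n_intergenic"] = len(sig_ids) - len(genic_variants)
    counts["n_genes"] = len(per_gene)

    rows = []
    for gene_id, alist in per_gene.items():
        best_p = min(p_by_variant[a.variant_id] for a in alist)
        cats = sorted({a.category for a in alist}, key=lambda c: CATEGORY_PRIORITY[c])
        rows.append(
            {
                "gene_id": gene_id,
                "best_p": best_p,
                "n_variants": len(alist),
                "categories": ",".join(cats),
                "variant_ids": ",".join(sorted(a.variant_id for a in alist)),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["best_p", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    logger.info(
        "candidates: %d significant variants, %d in-gene, %d intergenic, %d genes",
        counts["n_significant"],
        counts["n_in_gene"],
        counts["n_intergenic"],
        counts["n_genes"],
    )
    return table, counts
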