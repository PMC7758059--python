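"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan


@dataclass
class GenotypePanel:
    """Inbred-strain genotypes at biallelic variants.

    Genotypes are coded 0 (homozygous reference) / 1 (homozygous alternate);
    inbred lines carry no heterozygotes, so a single bit per strain suffices.
    Missing calls are ``nan``.

    Attributes
    ----------
    strain_ids : list of str
        Strain identifiers, one per matrix row.
    variants : pandas.DataFrame
        Per-variant table with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``, ``id``; positions strictly increasing within a
        chromosome.
    genotypes : numpy.ndarray, shape (n_strains, n_variants)
        Float matrix with entries in {0.0, 1.0, nan}.
    """

    strain_ids: list[str]
    variants: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.strain_ids), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.strain_ids)} strains x {len(self.variants)} variants"
            )
        for _, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("variant positions must be strictly increasing per chromosome")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, computed on non-missing calls."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.genotypes, axis=0)
        return np.minimum(freq, 1.0 - freq)

    def missingness(self) -> np.ndarray:
        """Fraction of missing calls per variant."""
        return np.mean(np.isnan(self.genotypes), axis=0)

    def subset_variants(self, mask: np.ndarray) -> "GenotypePanel":
        """Return a panel restricted to the variants selected by ``mask``."""
        return GenotypePanel(
            strain_ids=list(self.strain_ids),
            variants=self.variants.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[:, np.asarray(mask)],
        )

    def imputed(self) -> np.ndarray:
        """Genotype matrix with missing entries replaced by the variant mean."""
        G = self.genotypes.astype(float).copy()
        if np.any(np.isnan(G)):
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(G, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(G))
            G[idx] = col_mean[idx[1]]
        return G

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.strain_ids == other.strain_ids
            and self.variants.reset_index(drop=True).equals(other.variants.reset_index(drop=True))
            and np.array_equal(self.genotypes, other.genotypes, equal_nan=True)
        )


@dataclass
class KinshipMatrix:
    """Centered genetic relatedness matrix K = W Wᵀ / p.

    W is the genotype matrix with each variant column mean-centered and p the
    number of variants used.  Row sums of K are zero by construction and K is
    positive semi-definite up to numerical tolerance.
    """

    K: np.ndarray
    strain_ids: list[str]
    p_variants_used: int

    def __post_init__(self) -> None:
        n = len(self.strain_ids)
        if self.K.shape != (n, n):
            raise ValueError(f"K has shape {self.K.shape}, expected ({n}, {n})")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")

    @property
    def n(self) -> int:
        return len(self.strain_ids)


@dataclass
class GeneModel:
    """One gene body with exon / UTR substructure, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utrs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        for lo, hi in self.exons:
            if lo < self.start or hi > self.end:
                raise ValueError(f"{self.gene_id}: exon ({lo},{hi}) outside gene body")


@dataclass
class GeneModelSet:
    """Collection of gene models on a shared coordinate system."""

    genes: list[GeneModel]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class RateTreeSet:
    """Per-clade, per-gene branch-length vectors on a common species-tree topology.

    For every clade there is one fixed set of branches (identified by index)
    and, for each gene present in that clade, a vector of branch lengths in
    substitutions per site aligned to that branch set.  Genes may be absent
    from individual clades.

    Attributes
    ----------
    clade_ids : list of str
    n_branches : dict clade -> branch count
    branch_lengths : dict clade -> dict gene -> array of branch lengths
    topologies : dict clade -> newick string of the species tree (optional,
        used by the Newick writer; the analyses only need the vectors).
    """

    clade_ids: list[str]
    n_branches: dict[str, int]
    branch_lengths: dict[str, dict[str, np.ndarray]]
    topologies: dict[str, str] = field(default_factory=dict)

    def genes(self) -> list[str]:
        """All gene ids present in at least one clade, sorted."""
        out: set[str] = set()
        for clade in self.clade_ids:
            out.update(self.branch_lengths[clade].keys())
        return sorted(out)

    def clades_with(self, gene_id: str) -> list[str]:
        return [c for c in self.clade_ids if gene_id in self.branch_lengths[c]]

    def clade_mean(self, clade: str) -> np.ndarray:
        """Average branch-length vector over all genes present in a clade."""
        vecs = list(self.branch_lengths[clade].values())
        if not vecs:
            raise ValueError(f"clade {clade} has no genes")
        return np.mean(np.stack(vecs), axis=0)
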