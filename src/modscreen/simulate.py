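"""Synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure a knockdown-by-panel screen
produces: a panel of fully inbred strains with subpopulation relatedness, a
bounded survival-proportion phenotype composed of causal, polygenic and noise
parts, balancer-class cross counts around a 1:1:1:1 Mendelian expectation,
gene models and gene sets on one chromosome, and per-gene branch-length trees
in which a designated group of genes shares branch-specific rate fluctuations
(the evolutionary-rate-covariation signal).

All randomness flows from ``SimConfig.seed`` (or an explicit ``rng``); the
same configuration and seed reproduce byte-identical output.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from modscreen.containers import GeneModel, GeneModelSet, GenotypePanel, RateTreeSet

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic screen world.

    Variance parameters partition the phenotype: ``polygenic_var`` and
    ``noise_var`` are fractions of ``total_var``, the overall phenotypic
    variance on the proportion scale.  ``causal_effects`` are in phenotype
    units (survival proportion) per alternate allele.
    """

    n_strains: int = 160
    n_variants: int = 5000
    n_subpops: int = 1
    fst_like_drift: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_causal: int = 0
    causal_effects: list[float] = field(default_factory=list)
    polygenic_var: float = 0.0
    noise_var: float = 1.0
    total_var: float = 0.04
    mean_survival: float = 0.5
    n_genes: int = 200
    chrom_length: int = 2_000_000
    chrom_name: str = "2L"
    n_gene_sets: int = 10
    genes_per_set: int = 10
    n_clades: int = 3
    n_species_per_clade: int = 12
    covarying_group: list[str] = field(default_factory=list)
    rate_sd: float = 0.1
    latent_rate_sd: float = 0.5
    presence_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.polygenic_var and 0.0 <= self.noise_var):
            raise ConfigurationError("variance fractions must be non-negative")
        if self.polygenic_var + self.noise_var > 1.0 + 1e-12:
            raise ConfigurationError(
                f"variance fractions sum to {self.polygenic_var + self.noise_var:.3f} > 1"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range {self.maf_range} must lie within (0, 0.5]")
        if self.n_causal > self.n_variants:
            raise ConfigurationError("n_causal exceeds n_variants")
        if not (0.0 <= self.fst_like_drift <= 1.0):
            raise ConfigurationError("fst_like_drift must be in [0, 1]")
        if self.causal_effects and len(self.causal_effects) != self.n_causal:
            raise ConfigurationError("causal_effects length must equal n_causal")


def _rng(cfg_seed: int, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg_seed)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotype_panel(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypePanel:
    """Simulate inbred 0/1 genotypes with optional subpopulation structure.

    Each variant has an ancestral allele frequency drawn uniformly from
    ``cfg.maf_range``.  With ``n_subpops > 1`` and positive ``fst_like_drift``,
    per-subpopulation frequencies are drawn from the Balding-Nichols beta
    distribution around the ancestral frequency, so that the realized centered
    relatedness matrix shows within- versus between-subpopulation block
    structure.  Strains are fully homozygous: each line fixes the 0 or the 1
    allele with probability given by its subpopulation frequency.
    """
    rng = _rng(cfg.seed, rng)
    lo, hi = cfg.maf_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_variants)

    subpop = np.arange(cfg.n_strains) % cfg.n_subpops
    F = cfg.fst_like_drift
    if cfg.n_subpops > 1 and F > 0:
        if F >= 1.0:
            # complete drift: each subpop fixes one allele
            p_sub = (rng.random((cfg.n_subpops, cfg.n_variants)) < p_anc).astype(float)
        else:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            p_sub = rng.beta(a, b, size=(cfg.n_subpops, cfg.n_variants))
    else:
        p_sub = np.tile(p_anc, (cfg.n_subpops, 1))

    G = (rng.random((cfg.n_strains, cfg.n_variants)) < p_sub[subpop]).astype(float)

    spacing = max(1, cfg.chrom_length // (cfg.n_variants + 1))
    pos = np.arange(1, cfg.n_variants + 1) * spacing
    variants = pd.DataFrame(
        {
            "chrom": cfg.chrom_name,
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "id": [f"{cfg.chrom_name}_{p}" for p in pos],
        }
    )
    return GenotypePanel(
        strain_ids=[f"line_{i:03d}" for i in range(cfg.n_strains)],
        variants=variants,
        genotypes=G,
    )


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PhenotypeResult:
    """Simulated survival-proportion phenotype with provenance."""

    y: np.ndarray
    causal_indices: np.ndarray
    causal_effects: np.ndarray
    polygenic: np.ndarray
    noise: np.ndarray
    n_clamped: int


def simulate_phenotypes(
    panel: GenotypePanel,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    causal_indices: np.ndarray | None = None,
) -> PhenotypeResult:
    """Compose y = clamp[0,1](mu + sum_j beta_j x_j + g + e).

    The polygenic part ``g`` is multivariate normal with covariance
    proportional to the realized centered relatedness matrix of ``panel``,
    scaled so that its marginal variance is ``polygenic_var * total_var``;
    ``e`` is independent noise with variance ``noise_var * total_var``.
    Clamping to the unit interval is applied last and logged.
    """
    from modscreen.relatedness import centered_grm

    rng = _rng(cfg.seed + 1, rng)
    n = panel.n_strains

    if causal_indices is None:
        causal_indices = (
            rng.choice(panel.n_variants, size=cfg.n_causal, replace=False)
            if cfg.n_causal
            else np.empty(0, dtype=int)
        )
    causal_indices = np.asarray(causal_indices, dtype=int)
    if causal_indices.size and causal_indices.max() >= panel.n_variants:
        raise ConfigurationError("causal variant index outside panel")

    effects = np.asarray(cfg.causal_effects, dtype=float)
    if effects.size == 0 and causal_indices.size:
        effects = np.full(causal_indices.size, 0.3)

    y = np.full(n, cfg.mean_survival)
    if causal_indices.size:
        X = panel.imputed()[:, causal_indices]
        y = y + X @ effects

    g = np.zeros(n)
    if cfg.polygenic_var > 0:
        K = centered_grm(panel).K
        scale = np.mean(np.diag(K))
        if scale > 0:
            cov = K * (cfg.polygenic_var * cfg.total_var / scale)
            # eigenvalue clipping keeps the Cholesky-free sampler stable on a
            # PSD-up-to-roundoff matrix
            w, V = np.linalg.eigh(cov)
            w = np.clip(w, 0.0, None)
            g = V @ (np.sqrt(w) * rng.standard_normal(n))

    e = rng.standard_normal(n) * np.sqrt(cfg.noise_var * cfg.total_var)
    raw = y + g + e
    clamped = np.clip(raw, 0.0, 1.0)
    n_clamped = int(np.sum(clamped != raw))
    if n_clamped:
        logger.info("clamped %d of %d phenotype values into [0, 1]", n_clamped, n)
    return PhenotypeResult(
        y=clamped,
        causal_indices=causal_indices,
        causal_effects=effects,
        polygenic=g,
        noise=e,
        n_clamped=n_clamped,
    )


# ---------------------------------------------------------------------------
# cross counts


def simulate_cross_counts(
    true_survival: np.ndarray | list[float],
    n_expected: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    strain_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Draw balancer-class counts for each strain.

    The three balancer classes (CyO, Sb, double-balanced) are independent
    Poisson(n_expected); the knockdown class is Binomial(n_expected, survival),
    i.e. Mendelian 1:1:1:1 distorted by knockdown lethality.
    """
    true_survival = np.asarray(true_survival, dtype=float)
    if np.any((true_survival < 0) | (true_survival > 1)):
        raise ValueError("survival fractions must lie in [0, 1]")
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    rng = _rng(seed if seed is not None else 0, rng)
    n = len(true_survival)
    cyo = rng.poisson(n_expected, size=n)
    sb = rng.poisson(n_expected, size=n)
    dbl = rng.poisson(n_expected, size=n)
    kd = rng.binomial(n_expected, true_survival)
    if strain_ids is None:
        strain_ids = [f"line_{i:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "strain": strain_ids,
            "count_cyo": cyo,
            "count_sb": sb,
            "count_double": dbl,
            "count_none": kd,
        }
    )


# ---------------------------------------------------------------------------
# gene models and gene sets


def simulate_gene_models(cfg: SimConfig, rng: np.random.Generator | None = None) -> GeneModelSet:
    """Lay out non-overlapping genes with UTR/exon/intron substructure.

    Genes are placed on one chromosome on alternating strands, each with a
    5' UTR, two exons separated by an intron, and a 3' UTR.  Intergenic gaps
    always exceed 2 kb so the +/- 1 kb assignment window is exercised without
    every variant multi-mapping.
    """
    rng = _rng(cfg.seed + 2, rng)
    slot = cfg.chrom_length // cfg.n_genes
    min_gene_span = 600
    if slot < min_gene_span + 2100:
        raise ConfigurationError(
            f"chrom_length {cfg.chrom_length} too small for {cfg.n_genes} genes"
        )
    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        slot_start = i * slot + 1
        max_len = slot - 2100
        length = int(rng.integers(min_gene_span, min(max_len, 20_000) + 1))
        start = slot_start + int(rng.integers(0, max_len - length + 1))
        end = start + length - 1
        strand = "+" if i % 2 == 0 else "-"
        utr5_len = max(30, length // 10)
        utr3_len = max(30, length // 10)
        coding_start = start + utr5_len
        coding_end = end - utr3_len
        mid = (coding_start + coding_end) // 2
        intron_half = max(20, (coding_end - coding_start) // 6)
        exon1 = (coding_start, mid - intron_half)
        exon2 = (mid + intron_half, coding_end)
        gene = GeneModel(
            gene_id=f"gene_{i:04d}",
            chrom=cfg.chrom_name,
            start=start,
            end=end,
            strand=strand,
            exons=[exon1, exon2],
            utrs=[(start, coding_start - 1), (coding_end + 1, end)],
        )
        genes.append(gene)
    return GeneModelSet(genes=genes)


def simulate_gene_sets(
    cfg: SimConfig,
    models: GeneModelSet,
    enriched_genes: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, list[str]]:
    """Sample gene sets from the gene universe.

    If ``enriched_genes`` is given, the first set (``set_causal``) is exactly
    that list, emulating a pathway enriched for planted modifier genes.
    """
    rng = _rng(cfg.seed + 3, rng)
    universe = models.gene_ids()
    sets: dict[str, list[str]] = {}
    if enriched_genes is not None:
        missing = set(enriched_genes) - set(universe)
        if missing:
            raise ConfigurationError(f"enriched genes not in universe: {sorted(missing)}")
        sets["set_causal"] = list(enriched_genes)
    n_random = cfg.n_gene_sets - len(sets)
    for i in range(n_random):
        k = min(cfg.genes_per_set, len(universe))
        members = sorted(rng.choice(universe, size=k, replace=False).tolist())
        sets[f"set_{i:03d}"] = members
    return sets


# ---------------------------------------------------------------------------
# rate trees


def _random_topology(n_species: int, rng: np.random.Generator) -> tuple[str, int]:
    """Random rooted binary species tree; returns a newick skeleton with
    ``{b<i>}`` placeholders for branch lengths and the branch count."""
    nodes = [f"sp{j}" for j in range(n_species)]
    counter = [0]

    def fmt(label: str) -> str:
        s = f"{label}:{{b{counter[0]}}}"
        counter[0] += 1
        return s

    parts = [fmt(n) for n in nodes]
    while len(parts) > 2:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        merged = fmt(f"({parts[i]},{parts[j]})")
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    skeleton = f"({parts[0]},{parts[1]});"
    # renumber placeholders in string order so branch index i is the i-th
    # branch of the serialized newick (the reader's convention)
    idx = [0]

    def renumber(_m: re.Match) -> str:
        s = f"{{b{idx[0]}}}"
        idx[0] += 1
        return s

    skeleton = re.sub(r"\{b\d+\}", renumber, skeleton)
    return skeleton, counter[0]


def simulate_rate_trees(cfg: SimConfig, rng: np.random.Generator | None = None) -> RateTreeSet:
    """Simulate per-gene branch-length vectors with a planted covarying group.

    For each clade a fixed species-tree branch set is drawn, with clade-level
    expected lengths t_b ~ Exponential(mean 0.1).  Gene g's length on branch b
    is ``t_b * m_g * exp(d_gb)`` where ``m_g`` is a lognormal gene rate
    multiplier and ``d_gb`` a branch-specific deviation.  Genes in
    ``cfg.covarying_group`` share one latent deviation vector per clade (sd
    ``latent_rate_sd``) plus independent noise of sd ``rate_sd``; all other
    genes have independent deviations of the same total sd.  Each gene is
    present in a clade with probability ``presence_prob`` (always at least one
    clade).
    """
    rng = _rng(cfg.seed + 4, rng)
    gene_ids = [f"gene_{i:04d}" for i in range(cfg.n_genes)]
    group = set(cfg.covarying_group)
    unknown = group - set(gene_ids)
    if unknown:
        raise ConfigurationError(f"covarying_group gene(s) not simulated: {sorted(unknown)}")

    total_sd = float(np.hypot(cfg.latent_rate_sd, cfg.rate_sd))
    multipliers = {g: float(rng.lognormal(0.0, 0.3)) for g in gene_ids}

    presence = {
        g: (rng.random(cfg.n_clades) < cfg.presence_prob) for g in gene_ids
    }
    for g, pres in presence.items():
        if not pres.any():
            pres[rng.integers(cfg.n_clades)] = True

    clade_ids = [f"clade_{c}" for c in range(cfg.n_clades)]
    n_branches: dict[str, int] = {}
    branch_lengths: dict[str, dict[str, np.ndarray]] = {}
    topologies: dict[str, str] = {}

    for ci, clade in enumerate(clade_ids):
        skeleton, nb = _random_topology(cfg.n_species_per_clade, rng)
        n_branches[clade] = nb
        topologies[clade] = skeleton
        t = rng.exponential(0.1, size=nb)
        latent = rng.standard_normal(nb) * cfg.latent_rate_sd
        vecs: dict[str, np.ndarray] = {}
        for g in gene_ids:
            if not presence[g][ci]:
                continue
            if g in group:
                d = latent + rng.standard_normal(nb) * cfg.rate_sd
            else:
                d = rng.standard_normal(nb) * total_sd
            vecs[g] = t * multipliers[g] * np.exp(d)
        branch_lengths[clade] = vecs

    return RateTreeSet(
        clade_ids=clade_ids,
        n_branches=n_branches,
        branch_lengths=branch_lengths,
        topologies=topologies,
    )
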