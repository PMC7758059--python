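"""Variant filtering and the centered genetic relatedness matrix."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from modscreen.containers import GenotypePanel, KinshipMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_retained: int


def filter_variants(
    panel: GenotypePanel,
    min_maf: float = 0.05,
    max_missing: float = 0.2,
) -> tuple[GenotypePanel, FilterReport]:
    """Keep variants with MAF >= ``min_maf`` (inclusive) and missingness
    <= ``max_missing``.

    The MAF threshold is inclusive: a variant at exactly the threshold is
    retained.  Counts removed per rule are reported; an empty result is a
    warning, not an error.
    """
    if not (0.0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    maf = panel.maf()
    miss = panel.missingness()
    maf_ok = maf >= min_maf
    miss_ok = miss <= max_missing
    keep = maf_ok & miss_ok
    report = FilterReport(
        n_input=panel.n_variants,
        n_removed_maf=int(np.sum(~maf_ok)),
        n_removed_missing=int(np.sum(maf_ok & ~miss_ok)),
        n_retained=int(np.sum(keep)),
    )
    logger.info(
        "variant filter: %d in, %d below MAF %.3g, %d above missingness %.3g, %d retained",
        report.n_input,
        report.n_removed_maf,
        report.n_removed_missing,
        max_missing,
        report.n_retained,
    )
    if report.n_retained == 0:
        logger.warning("variant filter removed every variant")
    return panel.subset_variants(keep), report


def centered_grm(panel: GenotypePanel) -> KinshipMatrix:
    """K = W Wᵀ / p with W the per-variant mean-centered genotype matrix.

    Missing genotypes are mean-imputed per variant before centering, which
    keeps the strain set constant across variants; imputed entries center to
    exactly zero so they contribute nothing to relatedness.
    """
    if panel.n_strains < 2 or panel.n_variants < 1:
        raise ValueError("need at least 2 strains and 1 variant")
    G = panel.imputed()
    W = G - G.mean(axis=0, keepdims=True)
    K = (W @ W.T) / panel.n_variants
    K = (K + K.T) / 2.0  # enforce exact symmetry against roundoff
    return KinshipMatrix(K=K, strain_ids=list(panel.strain_ids), p_variants_used=panel.n_variants)
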