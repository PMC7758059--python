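"""Survival-proportion scoring from balancer-class cross counts.

A modifier-screen cross segregates four offspring classes distinguishable by
dominant balancer markers: CyO only, Sb only, double-balanced, and
no-balancer (the knockdown class).  Under Mendelian segregation the four
classes arrive 1:1:1:1; balancers carry a small viability cost, so the
largest balancer class is the best estimate of the expected class size and
the screen phenotype is knockdown count divided by that largest class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BALANCER_CLASSES = ("count_cyo", "count_sb", "count_double")
KNOCKDOWN_CLASS = "count_none"


class ScoringError(ValueError):
    """Raised when a strain's counts cannot be scored."""


@dataclass
class SurvivalRecord:
    strain_id: str
    proportion_surviving: float
    largest_class: str
    largest_class_count: int
    total_scored: int
    low_count_flag: bool
    chisq_stat: float
    chisq_df: int
    chisq_p: float


def survival_proportion(
    strain_id: str,
    count_cyo: int,
    count_sb: int,
    count_double: int,
    count_none: int,
    min_total: int = 200,
) -> SurvivalRecord:
    """Score one strain: knockdown count over the largest balancer class.

    Proportions above 1 are retained (the denominator is an estimate of the
    expected class size, not a hard ceiling) with a logged warning.  Strains
    with fewer than ``min_total`` scored flies are flagged, not dropped.
    A chi-square goodness of fit of knockdown versus largest-balancer counts
    against the 1:1 Mendelian expectation is attached.
    """
    counts = {
        "count_cyo": int(count_cyo),
        "count_sb": int(count_sb),
        "count_double": int(count_double),
    }
    if any(v < 0 for v in counts.values()) or count_none < 0:
        raise ScoringError(f"{strain_id}: negative counts")
    largest_class = max(counts, key=lambda k: (counts[k], k))
    largest = counts[largest_class]
    if largest == 0:
        raise ScoringError(f"{strain_id}: all balancer classes are zero")
    proportion = count_none / largest
    if proportion > 1:
        logger.warning(
            "%s: knockdown class (%d) exceeds largest balancer class (%d)",
            strain_id,
            count_none,
            largest,
        )
    total = sum(counts.values()) + int(count_none)
    stat, df, p = mendelian_chisq([int(count_none), largest], [0.5, 0.5])
    return SurvivalRecord(
        strain_id=strain_id,
        proportion_surviving=proportion,
        largest_class=largest_class,
        largest_class_count=largest,
        total_scored=total,
        low_count_flag=total < min_total,
        chisq_stat=stat,
        chisq_df=df,
        chisq_p=p,
    )


def chisq_tail(stat: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    return float(stats.chi2.sf(stat, df))


def mendelian_chisq(
    observed: list[int] | np.ndarray, expected_ratio: list[float] | np.ndarray
) -> tuple[float, int, float]:
    """Pearson chi-square of observed class counts against a Mendelian ratio.

    Returns (statistic, degrees of freedom = #classes - 1, upper-tail p).
    """
    observed = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if observed.shape != ratio.shape:
        raise ValueError("observed and expected_ratio must have equal length")
    total = observed.sum()
    if total <= 0:
        raise ValueError("total observed count must be positive")
    if not np.isclose(ratio.sum(), 1.0):
        raise ValueError("expected_ratio must sum to 1")
    expected = total * ratio
    if np.any(expected <= 0):
        raise ValueError("zero expected count")
    stat = float(np.sum((observed - expected) ** 2 / expected))
    df = len(observed) - 1
    return stat, df, chisq_tail(stat, df)


def score_screen(counts: pd.DataFrame, min_total: int = 200) -> pd.DataFrame:
    """Score every strain in a cross-count table.

    Expects columns ``strain``, ``count_cyo``, ``count_sb``, ``count_double``,
    ``count_none``; returns one row per scorable strain (unscorable strains
    are logged and skipped).
    """
    records = []
    for row in counts.itertuples(index=False):
        try:
            rec = survival_proportion(
                row.strain,
                row.count_cyo,
                row.count_sb,
                row.count_double,
                row.count_none,
                min_total=min_total,
            )
        except ScoringError as exc:
            logger.warning("skipping strain: %s", exc)
            continue
        records.append(rec.__dict__)
    return pd.DataFrame(records)


@dataclass
class ScreenSummary:
    n_strains: int
    min_proportion: float
    max_proportion: float
    mean_proportion: float
    r_squared: float
    slope_p: float


def screen_summary(records: pd.DataFrame) -> ScreenSummary:
    """Summarise the screen and test for denominator leakage.

    Regresses survival proportion on the largest balancer-class count; a large
    R-squared would indicate that the phenotype is driven by the size of the
    balancer control class rather than knockdown lethality.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 scored strains")
    y = records["proportion_surviving"].to_numpy(dtype=float)
    x = records["largest_class_count"].to_numpy(dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        r2, p = 0.0, 1.0
    else:
        res = stats.linregress(x, y)
        r2, p = float(res.rvalue**2), float(res.pvalue)
    return ScreenSummary(
        n_strains=len(records),
        min_proportion=float(y.min()),
        max_proportion=float(y.max()),
        mean_proportion=float(y.mean()),
        r_squared=r2,
        slope_p=p,
    )
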