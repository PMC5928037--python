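"""Length-matched background sampling and distributional comparisons.

The focal protein set is contrasted against a same-size random proteome
sample constructed to match its length distribution (intrinsic disorder
depends on protein length, so the control must remove length bias).  Each
feature is then compared with the two-sample Kolmogorov-Smirnov test
(optionally Mann-Whitney), and summarized with quartiles plus 10th/90th
centiles, the whisker convention of the study's box plots.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InputError
from .mapping import ProteinRecord

SIGNIFICANCE_ALPHA = 0.05
#: exact p-values when n*m is at most this (K-S)
KS_EXACT_LIMIT = 10_000
#: exact p-values when n*m is at most this and there are no ties (Mann-Whitney)
MW_EXACT_LIMIT = 200
#: smallest group size for which a comparison is attempted
MIN_GROUP_SIZE = 5

LOW_SAMPLE_NOTE = "not performed due to the low sample size"


@dataclass
class DistributionSummary:
    """Box-plot summary: quartiles plus the 10th and 90th centiles."""

    p10: float
    q1: float
    median: float
    q3: float
    p90: float
    n: int


@dataclass
class ComparisonResult:
    feature: str
    performed: bool
    focal_summary: Optional[DistributionSummary]
    background_summary: Optional[DistributionSummary]
    ks_D: Optional[float]
    ks_p: Optional[float]
    mw_U: Optional[float]
    mw_p: Optional[float]
    n_focal: int
    n_background: int
    n_excluded: int
    note: str = ""

    @property
    def significant(self) -> Optional[bool]:
        if not self.performed:
            return None
        return self.ks_p < SIGNIFICANCE_ALPHA


def length_matched_sample(
    proteome: Sequence[ProteinRecord],
    focal: Sequence[ProteinRecord],
    seed: int,
) -> list[ProteinRecord]:
    """Draw one background protein per focal protein, matched on length.

    Sampling is without replacement; each focal protein (visited in seeded
    random order) takes a proteome protein of identical length when one is
    available, otherwise the nearest available length (ties broken toward
    the shorter length, the pick within a length by seeded RNG).  The result
    is aligned with the focal input order.
    """
    focal_accs = {r.accession for r in focal}
    if focal_accs & {r.accession for r in proteome}:
        raise InputError("proteome pool must be disjoint from the focal set")
    if len(proteome) < len(focal):
        raise InputError(
            f"proteome ({len(proteome)}) smaller than focal set ({len(focal)})"
        )
    rng = np.random.default_rng(seed)
    pools: dict[int, list[ProteinRecord]] = {}
    for rec in proteome:
        pools.setdefault(rec.length, []).append(rec)
    available = sorted(pools)

    chosen: dict[int, ProteinRecord] = {}
    for i in rng.permutation(len(focal)):
        target = focal[int(i)].length
        if target in pools:
            length = target
        else:
            pos = bisect.bisect_left(available, target)
            below = available[pos - 1] if pos > 0 else None
            above = available[pos] if pos < len(available) else None
            if below is None:
                length = above
            elif above is None:
                length = below
            else:  # tie toward the shorter length
                length = below if target - below <= above - target else above
        pool = pools[length]
        rec = pool.pop(int(rng.integers(len(pool))))
        if not pool:
            del pools[length]
            available.remove(length)
        chosen[int(i)] = rec
    return [chosen[i] for i in range(len(focal))]


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample K-S statistic and p-value.

    Exact p when n*m <= 10,000, else the asymptotic Kolmogorov distribution
    with effective size nm/(n+m).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("K-S test requires non-empty samples")
    method = "exact" if x.size * y.size <= KS_EXACT_LIMIT else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (of x) and p-value.

    Exact by enumeration when n*m <= 200 and there are no ties, else the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("Mann-Whitney test requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= MW_EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def summarize_distribution(values: Sequence[float]) -> DistributionSummary:
    """Quantiles by linear interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("cannot summarize an empty sample")
    p10, q1, median, q3, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    return DistributionSummary(
        p10=float(p10), q1=float(q1), median=float(median),
        q3=float(q3), p90=float(p90), n=int(v.size),
    )


def compare_feature(
    focal_values: Sequence[float],
    background_values: Sequence[float],
    feature: str,
    with_mann_whitney: bool = False,
    min_group_size: int = MIN_GROUP_SIZE,
) -> ComparisonResult:
    """Distribution summaries plus K-S (and optional Mann-Whitney) tests.

    NaN values (e.g. proteins without PPI information) are excluded and
    counted; a group falling below ``min_group_size`` after exclusion makes
    the comparison report itself as not performed instead of raising.
    """
    fv = np.asarray(focal_values, dtype=float)
    bv = np.asarray(background_values, dtype=float)
    n_excluded = int(np.isnan(fv).sum() + np.isnan(bv).sum())
    fv = fv[~np.isnan(fv)]
    bv = bv[~np.isnan(bv)]
    if fv.size < min_group_size or bv.size < min_group_size:
        return ComparisonResult(
            feature=feature, performed=False,
            focal_summary=summarize_distribution(fv) if fv.size else None,
            background_summary=summarize_distribution(bv) if bv.size else None,
            ks_D=None, ks_p=None, mw_U=None, mw_p=None,
            n_focal=int(fv.size), n_background=int(bv.size),
            n_excluded=n_excluded, note=LOW_SAMPLE_NOTE,
        )
    ks_d, ks_p = ks_two_sample(fv, bv)
    mw_u = mw_p = None
    if with_mann_whitney:
        mw_u, mw_p = mann_whitney(fv, bv)
    return ComparisonResult(
        feature=feature, performed=True,
        focal_summary=summarize_distribution(fv),
        background_summary=summarize_distribution(bv),
        ks_D=ks_d, ks_p=ks_p, mw_U=mw_u, mw_p=mw_p,
        n_focal=int(fv.size), n_background=int(bv.size),
        n_excluded=n_excluded,
    )
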