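"""Regime inference: counterfactual nulls and chi-square comparisons.

Two nulls discriminate mixed-severity from low/moderate-severity fire
regimes in a stand-origin distribution:

* *no fire exclusion*: the 1810-1889 origin-class proportions, shifted
  forward 120 years onto 1930-2009 and rescaled to the observed total,
  are what today's distribution would look like had the pre-suppression
  regime continued;
* *low/moderate severity*: a regime without stand-replacing fire leaves
  stands evenly spread over old age classes -- 12.5% of stands in each
  40-year class spanning ages 0-319 at the onset of exclusion.

Both are tested as chi-square goodness-of-fit comparisons; 2x2
comparisons of proportions (e.g. pine vs non-pine establishment) use the
two-proportion chi-square with Yates continuity correction by default.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .severity import DomainError
from .standage import BIN_WIDTH, AgeDistribution, ProcessedPlot

__all__ = [
    "HISTORICAL_WINDOW",
    "RECENT_WINDOW",
    "CounterfactualDistribution",
    "ChiSquareResult",
    "RegimeVerdict",
    "counterfactual_no_exclusion",
    "uniform_lowmod_expected",
    "chisq_gof",
    "chisq_two_proportions",
    "counts_from_percent",
    "establishment_change_factor",
    "compare_forest_types",
    "analyze_distribution",
]

#: Pre-exclusion source window (origin years, two 40-yr bins).
HISTORICAL_WINDOW = (1810, 1890)
#: Suppression-era target window (origin years, two 40-yr bins).
RECENT_WINDOW = (1930, 2010)
#: Calendar shift taking the source window onto the target window.
WINDOW_SHIFT = RECENT_WINDOW[0] - HISTORICAL_WINDOW[0]


@dataclass
class CounterfactualDistribution:
    """Expected suppression-era counts had fire exclusion never occurred."""

    source_window: tuple[int, int]
    target_window: tuple[int, int]
    source_counts: np.ndarray
    expected_counts: np.ndarray
    rescale_total: float

    def __post_init__(self) -> None:
        self.source_counts = np.asarray(self.source_counts, dtype=float)
        self.expected_counts = np.asarray(self.expected_counts, dtype=float)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    continuity_corrected: bool = False
    pooled_bins: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "continuity_corrected": self.continuity_corrected,
            "pooled_bins": self.pooled_bins,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


@dataclass
class RegimeVerdict:
    """Alpha-level decisions for one region's distribution."""

    region: str
    reject_no_exclusion_null: bool
    reject_lowmod_null: bool
    establishment_change_factor: float
    alpha: float = 0.05


def _historical_counts(historical) -> np.ndarray:
    if isinstance(historical, AgeDistribution):
        counts = historical.window_counts(*HISTORICAL_WINDOW)
    else:
        counts = np.asarray(historical, dtype=float)
    if counts.size != 2:
        raise ValueError(
            "need the two 40-yr bins [1810,1850) and [1850,1890); "
            f"got {counts.size} bins"
        )
    return counts.astype(float)


def counterfactual_no_exclusion(
    historical, observed_total: float
) -> CounterfactualDistribution:
    """Project pre-exclusion origin classes onto the suppression era.

    The counts of the [1810,1850) and [1850,1890) bins are shifted forward
    120 years onto [1930,1970) and [1970,2010) and rescaled so the expected
    total equals ``observed_total``, preserving within-window proportions.
    """
    src = _historical_counts(historical)
    total = src.sum()
    if total <= 0:
        raise DomainError("both historical bins are zero; the null is degenerate")
    if observed_total <= 0:
        raise DomainError(f"observed total must be positive; got {observed_total!r}")
    expected = src / total * observed_total
    return CounterfactualDistribution(
        source_window=HISTORICAL_WINDOW,
        target_window=RECENT_WINDOW,
        source_counts=src,
        expected_counts=expected,
        rescale_total=float(observed_total),
    )


def uniform_lowmod_expected(n_total: float, n_classes: int = 8) -> np.ndarray:
    """Expected counts under the low/moderate-severity null.

    That regime leaves 12.5% of stands in each of the eight 40-yr classes
    covering ages 0-319 at the onset of fire exclusion; a different
    ``n_classes`` is allowed but warned about.
    """
    if not n_total > 0:
        raise DomainError(f"total must be positive; got {n_total!r}")
    if n_classes != 8:
        warnings.warn(
            f"low/moderate-severity null normally uses 8 classes; got {n_classes}",
            stacklevel=2,
        )
    return np.full(n_classes, n_total / n_classes, dtype=float)


def counts_from_percent(percent: float, n: int) -> int:
    """Reconstruct an integer count from a printed rounded percentage.

    Returns the nearest integer to ``percent/100 * n``.  When several
    integer counts are consistent with the printed (rounded) percentage, a
    warning lists all of them, since published summaries sometimes cannot
    be inverted uniquely.
    """
    if n < 1:
        raise DomainError(f"group size must be >= 1; got {n}")
    if not 0 <= percent <= 100:
        raise DomainError(f"percentage outside [0, 100]: {percent!r}")
    best = int(round(percent / 100 * n))
    # decimals printed, inferred from the text representation
    decimals = max(0, len(f"{percent}".rstrip("0").split(".")[1]) if "." in f"{percent}" else 0)
    consistent = [
        x for x in range(n + 1) if round(100 * x / n, decimals) == round(percent, decimals)
    ]
    if len(consistent) > 1:
        warnings.warn(
            f"{percent}% of {n} is ambiguous: consistent counts {consistent}",
            stacklevel=2,
        )
    return best


def _pool_small_bins(
    observed: np.ndarray, expected: np.ndarray, min_expected: float
) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """Merge adjacent bins left-to-right until every expected >= min_expected."""
    groups: list[list[int]] = []
    cur: list[int] = []
    acc = 0.0
    for i, e in enumerate(expected):
        cur.append(i)
        acc += e
        if acc >= min_expected:
            groups.append(cur)
            cur = []
            acc = 0.0
    if cur:
        if groups:
            groups[-1].extend(cur)
        else:
            groups.append(cur)
    obs = np.array([observed[g].sum() for g in groups])
    exp = np.array([expected[g].sum() for g in groups])
    pooled = [g for g in groups if len(g) > 1]
    return obs, exp, pooled


def chisq_gof(
    observed: Sequence[float],
    expected: Sequence[float],
    min_expected: float = 5.0,
    pool: bool = True,
) -> ChiSquareResult:
    """Chi-square goodness of fit, sum (O-E)^2/E, df = bins - 1.

    Adjacent bins with small expected counts are pooled (Zar's < 5
    guidance) unless ``pool`` is false; any pooling is recorded in the
    result.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError(f"shape mismatch: observed {obs.shape} vs expected {exp.shape}")
    if exp.sum() <= 0:
        raise DomainError("expected counts sum to zero")
    pooled: list[list[int]] = []
    if pool:
        obs, exp, pooled = _pool_small_bins(obs, exp, min_expected)
    if np.any(exp <= 0):
        raise DomainError("an expected count is <= 0 after pooling")
    if obs.size < 2:
        raise DomainError("fewer than two bins after pooling; test is degenerate")
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = int(obs.size - 1)
    return ChiSquareResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        continuity_corrected=False,
        pooled_bins=pooled,
    )


def chisq_two_proportions(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = True
) -> ChiSquareResult:
    """Chi-square test that two binomial proportions are equal (df = 1).

    With ``continuity`` (Yates), |p1 - p2| is shrunk by 0.5*(1/n1 + 1/n2),
    clamped at zero.  The uncorrected statistic is algebraically the
    Pearson chi-square of the 2x2 contingency table.
    """
    for x, n, lbl in ((x1, n1, "1"), (x2, n2, "2")):
        if n < 1:
            raise DomainError(f"group {lbl}: sample size must be >= 1; got {n}")
        if not 0 <= x <= n:
            raise DomainError(f"group {lbl}: count {x} outside [0, {n}]")
    p1, p2 = x1 / n1, x2 / n2
    pbar = (x1 + x2) / (n1 + n2)
    if pbar in (0.0, 1.0):
        # all successes or all failures: proportions are equal by construction
        return ChiSquareResult(0.0, 1, 1.0, continuity_corrected=continuity)
    diff = abs(p1 - p2)
    if continuity:
        diff = max(diff - 0.5 * (1 / n1 + 1 / n2), 0.0)
    stat = diff**2 / (pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    return ChiSquareResult(
        statistic=float(stat),
        df=1,
        p_value=float(stats.chi2.sf(stat, 1)),
        continuity_corrected=continuity,
    )


def establishment_change_factor(
    dist: AgeDistribution,
    historical_window: tuple[int, int] = HISTORICAL_WINDOW,
    recent_window: tuple[int, int] = RECENT_WINDOW,
) -> float:
    """Pre- vs suppression-era mean establishment per 40-yr class.

    (mean count per bin, 1810-1889) / (mean count per bin, 1930-2009),
    computed on a distribution with corrections already applied.  A zero
    denominator yields ``math.inf``.
    """
    hist = dist.window_counts(*historical_window)
    recent = dist.window_counts(*recent_window)
    if hist.size == 0 or recent.size == 0:
        raise ValueError("distribution does not cover both comparison windows")
    denom = recent.mean()
    if denom == 0:
        return math.inf
    return float(hist.mean() / denom)


def compare_forest_types(
    plots: Iterable[ProcessedPlot],
    cutoff_year: int = 1900,
    window: tuple[int, int] = (1800, 1900),
    continuity: bool = True,
) -> ChiSquareResult:
    """Pine vs non-pine shares of old stands originating inside a window.

    Among stands with origin <= ``cutoff_year``, compares the proportion of
    ponderosa/Jeffrey-pine plots whose origin falls in ``window`` (closed)
    with the same proportion for other forest types.  Less mixed-severity
    fire in pine forests would show as a lower pine proportion.
    """
    lo, hi = window
    n = {True: 0, False: 0}
    x = {True: 0, False: 0}
    for p in plots:
        if p.origin_year > cutoff_year:
            continue
        n[p.pine] += 1
        if lo <= p.origin_year <= hi:
            x[p.pine] += 1
    if n[True] == 0 or n[False] == 0:
        raise DomainError(
            "one forest-type group has no stands at or before "
            f"{cutoff_year} (pine n={n[True]}, other n={n[False]})"
        )
    return chisq_two_proportions(x[True], n[True], x[False], n[False], continuity)


def analyze_distribution(
    dist: AgeDistribution,
    alpha: float = 0.05,
    pool: bool = True,
    min_expected: float = 5.0,
    lowmod_window: tuple[int, int] | None = None,
) -> dict:
    """Run both regime tests and the establishment factor on one region.

    The no-exclusion null is tested as a goodness of fit of the observed
    1930-2009 counts against the rescaled 1810-1889 counterfactual; the
    low/moderate-severity null against uniform expected counts over the
    eight 40-yr classes covering ages 0-319 at the exclusion onset
    (origins 1610-1930 by default).

    Returns a dict with both :class:`ChiSquareResult` objects, the
    counterfactual, the change factor, and a :class:`RegimeVerdict`.
    """
    observed_recent = dist.window_counts(*RECENT_WINDOW)
    if observed_recent.size != 2:
        raise ValueError("distribution must cover both suppression-era bins")
    cf = counterfactual_no_exclusion(dist, observed_total=float(observed_recent.sum()))
    gof = chisq_gof(
        observed_recent, cf.expected_counts, min_expected=min_expected, pool=pool
    )

    if lowmod_window is None:
        onset = RECENT_WINDOW[0]
        lowmod_window = (onset - 8 * BIN_WIDTH, onset)
    observed_old = dist.window_counts(*lowmod_window)
    expected_old = uniform_lowmod_expected(
        float(observed_old.sum()), n_classes=observed_old.size
    )
    lowmod = chisq_gof(
        observed_old, expected_old, min_expected=min_expected, pool=pool
    )

    factor = establishment_change_factor(dist)
    verdict = RegimeVerdict(
        region=dist.region,
        reject_no_exclusion_null=gof.p_value < alpha,
        reject_lowmod_null=lowmod.p_value < alpha,
        establishment_change_factor=factor,
        alpha=alpha,
    )
    return {
        "counterfactual": cf,
        "no_exclusion_test": gof,
        "lowmod_test": lowmod,
        "establishment_change_factor": factor,
        "verdict": verdict,
    }
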