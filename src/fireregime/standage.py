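"""Forest-inventory plot processing: stand ages, filters, and 40-yr binning.

The pipeline mirrors how FIA-style plot tables are turned into stand-origin
distributions for fire-regime inference:

* stand age of a stocked plot = cover-weighted mean ring count of dominant
  and codominant cores, plus 8 years for growth to breast height;
* split-age plots (subplot ages differing by more than the FIA split
  threshold for their age class) are excluded, as are plots outside
  protected lands or the qualifying land class;
* stand-origin years (measurement year minus stand age) are binned on a
  fixed 40-year calendar grid with left edges ..., 1810, 1850, ..., 1930,
  1970, ...;
* non-stocked plots are dated by their recorded fire-disturbance year, or
  placed in the most recent bin when no disturbance was coded;
* the newest bin is inflated by 40/(40 - m), m being the mean time plots
  could have burned after sampling, to offset right-censoring of recent
  fire.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .severity import DomainError

__all__ = [
    "BIN_WIDTH",
    "BIN_ANCHOR",
    "BREAST_HEIGHT_OFFSET",
    "DataError",
    "TreeCore",
    "PlotRecord",
    "ProcessedPlot",
    "AgeDistribution",
    "compute_stand_age",
    "split_threshold",
    "detect_split",
    "filter_plots",
    "bin_start",
    "assign_origin_and_bin",
    "assign_nonstocked",
    "process_plot",
    "process_plots",
    "PipelineResult",
    "build_age_distribution",
    "correct_recent_bin",
    "proportional_age_sd",
    "read_plot_table",
    "read_tree_table",
    "plot_records_from_tables",
    "write_age_distribution",
    "read_age_distribution",
]

#: Width of stand-origin classes, years.
BIN_WIDTH = 40
#: A left edge of the calendar bin grid; fixes ..., 1810, 1850, 1930, 1970 ...
BIN_ANCHOR = 1930
#: Years added to breast-height ring counts for time to grow to 1.4 m.
BREAST_HEIGHT_OFFSET = 8

DOMINANT = "dominant"
CODOMINANT = "codominant"
_AGING_CROWN_CLASSES = frozenset({DOMINANT, CODOMINANT})


class DataError(ValueError):
    """A plot or core record violates a pipeline precondition."""


@dataclass(frozen=True)
class TreeCore:
    """A breast-height increment core from one tree."""

    ring_count: float
    cover_weight: float = 1.0
    crown_class: str = DOMINANT

    def __post_init__(self) -> None:
        if self.ring_count < 0:
            raise DataError(f"ring count must be >= 0; got {self.ring_count!r}")
        if self.cover_weight < 0:
            raise DataError(f"cover weight must be >= 0; got {self.cover_weight!r}")


@dataclass
class PlotRecord:
    """Raw fields of one inventory plot, as read from a plot table."""

    plot_id: str
    measurement_year: int
    region: str = ""
    forest_type: str = ""
    pine: bool = False
    protected: bool = True
    land_class_ok: bool = True
    stocked: bool = True
    subplot_ages: list[float] = field(default_factory=list)
    disturbance_code: str | None = None
    disturbance_year: float | None = None
    tree_cores: list[TreeCore] | None = None


@dataclass
class ProcessedPlot:
    """One retained plot with its derived stand age, origin year and bin."""

    plot_id: str
    region: str
    pine: bool
    measurement_year: int
    stand_age_years: float
    origin_year: float
    bin_start: int
    excluded_split: bool = False
    nonstocked_assigned: bool = False
    stocked: bool = True


def compute_stand_age(
    cores: Sequence[TreeCore], breast_height_offset: float = BREAST_HEIGHT_OFFSET
) -> float:
    """Cover-weighted mean ring count of dominant/codominant cores + offset.

    Only dominant and codominant trees describe the overstory canopy cohort;
    other crown classes are ignored.
    """
    qual = [c for c in cores if c.crown_class in _AGING_CROWN_CLASSES]
    if not qual:
        raise DataError("no dominant or codominant cores to age the stand from")
    weights = np.array([c.cover_weight for c in qual], dtype=float)
    rings = np.array([c.ring_count for c in qual], dtype=float)
    wsum = weights.sum()
    if wsum <= 0:
        raise DataError("total cover weight of aging cores is zero")
    return float(np.average(rings, weights=weights)) + breast_height_offset


def split_threshold(age_years: float) -> float:
    """FIA split-age threshold for a subplot age class.

    <=100 years: stands split when ages differ by as little as 1 year;
    100-199 years: 2 years; >=200 years: 15 years.  Age exactly 100 uses
    the smaller (more conservative) threshold.
    """
    if age_years <= 100:
        return 1.0
    if age_years < 200:
        return 2.0
    return 15.0


def detect_split(subplot_ages: Sequence[float]) -> bool:
    """True when any pair of subplot ages would be split by FIA.

    Pairs straddling the age categories use the younger member's threshold,
    the conservative choice (more exclusions).
    """
    ages = list(subplot_ages)
    if not ages:
        raise DataError("subplot age list is empty")
    ages.sort()
    for i in range(len(ages) - 1):
        for j in range(i + 1, len(ages)):
            if ages[j] - ages[i] >= split_threshold(ages[i]):
                return True
    return False


def filter_plots(
    plots: Iterable[PlotRecord],
) -> tuple[list[PlotRecord], dict[str, int]]:
    """Retain protected, land-class-qualifying, single-stand-age plots.

    Returns the retained plots and a per-reason exclusion tally.  A plot is
    counted under the first failing reason, in the order unprotected,
    land_class, split.  Non-stocked plots carry no subplot ages and cannot
    be split.
    """
    kept: list[PlotRecord] = []
    tally = {"unprotected": 0, "land_class": 0, "split": 0}
    for p in plots:
        if not p.protected:
            tally["unprotected"] += 1
            continue
        if not p.land_class_ok:
            tally["land_class"] += 1
            continue
        if p.stocked and len(p.subplot_ages) >= 2 and detect_split(p.subplot_ages):
            tally["split"] += 1
            continue
        kept.append(p)
    return kept, tally


def bin_start(origin_year: float, anchor: int = BIN_ANCHOR) -> int:
    """Left edge of the half-open 40-yr calendar bin containing origin_year."""
    return int(anchor + BIN_WIDTH * math.floor((origin_year - anchor) / BIN_WIDTH))


def assign_origin_and_bin(
    plot_id: str,
    measurement_year: int,
    stand_age_years: float,
    *,
    region: str = "",
    pine: bool = False,
    anchor: int = BIN_ANCHOR,
    nonstocked_assigned: bool = False,
    stocked: bool = True,
) -> ProcessedPlot:
    """Derive the stand-origin year and its 40-yr bin for one plot."""
    origin = measurement_year - stand_age_years
    if origin > measurement_year:
        raise DataError(
            f"plot {plot_id}: origin year {origin} is after measurement year "
            f"{measurement_year} (negative stand age)"
        )
    return ProcessedPlot(
        plot_id=plot_id,
        region=region,
        pine=pine,
        measurement_year=measurement_year,
        stand_age_years=stand_age_years,
        origin_year=origin,
        bin_start=bin_start(origin, anchor),
        nonstocked_assigned=nonstocked_assigned,
        stocked=stocked,
    )


def assign_nonstocked(plot: PlotRecord, anchor: int = BIN_ANCHOR) -> ProcessedPlot:
    """Date a non-stocked plot from its recorded fire year, or place it in
    the most recent bin (flagged) when no disturbance was coded."""
    if plot.stocked:
        raise ValueError(f"plot {plot.plot_id} is stocked; use process_plot")
    if plot.disturbance_year is not None:
        origin = float(plot.disturbance_year)
        flagged = False
    else:
        origin = float(plot.measurement_year)
        flagged = True
    return assign_origin_and_bin(
        plot.plot_id,
        plot.measurement_year,
        stand_age_years=plot.measurement_year - origin,
        region=plot.region,
        pine=plot.pine,
        anchor=anchor,
        nonstocked_assigned=flagged,
        stocked=False,
    )


def process_plot(
    plot: PlotRecord,
    anchor: int = BIN_ANCHOR,
    breast_height_offset: float = BREAST_HEIGHT_OFFSET,
) -> ProcessedPlot:
    """Derive stand age, origin year and bin for one retained plot.

    Stocked plots are aged from their tree cores when a tree table is
    available, otherwise from the mean of the recorded subplot stand ages
    (already breast-height corrected by FIA).
    """
    if not plot.stocked:
        return assign_nonstocked(plot, anchor=anchor)
    if plot.tree_cores:
        age = compute_stand_age(plot.tree_cores, breast_height_offset)
    elif plot.subplot_ages:
        age = float(np.mean(plot.subplot_ages))
    else:
        raise DataError(f"stocked plot {plot.plot_id} has no cores or subplot ages")
    return assign_origin_and_bin(
        plot.plot_id,
        plot.measurement_year,
        age,
        region=plot.region,
        pine=plot.pine,
        anchor=anchor,
    )


@dataclass
class PipelineResult:
    processed: list[ProcessedPlot]
    exclusions: dict[str, int]

    @property
    def n_input(self) -> int:
        return len(self.processed) + sum(self.exclusions.values())


def process_plots(
    plots: Iterable[PlotRecord],
    anchor: int = BIN_ANCHOR,
    breast_height_offset: float = BREAST_HEIGHT_OFFSET,
) -> PipelineResult:
    """Filter raw plots and derive origins and bins for the retained set."""
    kept, tally = filter_plots(plots)
    processed = [
        process_plot(p, anchor=anchor, breast_height_offset=breast_height_offset)
        for p in kept
    ]
    return PipelineResult(processed=processed, exclusions=tally)


@dataclass
class AgeDistribution:
    """Plot counts per 40-yr stand-origin class for a region and window.

    Counts are reals because the recent-bin correction rescales them.
    ``older_count`` holds plots whose origin predates the first configured
    bin (kept, reported separately).
    """

    region: str
    window_label: str
    bin_starts: np.ndarray
    counts: np.ndarray
    n_plots: int
    older_count: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_starts = np.asarray(self.bin_starts, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_starts.size != self.counts.size:
            raise ValueError("bin_starts and counts must have the same length")
        if self.bin_starts.size and np.any(np.diff(self.bin_starts) != BIN_WIDTH):
            raise ValueError("bins must be contiguous 40-yr intervals")

    def bin_labels(self) -> list[str]:
        return [f"[{a},{a + BIN_WIDTH})" for a in self.bin_starts]

    def window_counts(self, start: int, stop: int) -> np.ndarray:
        """Counts for bins with left edges in [start, stop)."""
        mask = (self.bin_starts >= start) & (self.bin_starts < stop)
        return self.counts[mask]

    def copy(self) -> "AgeDistribution":
        return dataclasses.replace(
            self,
            bin_starts=self.bin_starts.copy(),
            counts=self.counts.copy(),
            metadata=dict(self.metadata),
        )


def build_age_distribution(
    processed: Iterable[ProcessedPlot],
    region: str = "",
    window_label: str = "",
    start: int | None = None,
    stop: int | None = None,
    anchor: int = BIN_ANCHOR,
) -> AgeDistribution:
    """Count retained plots per 40-yr origin class.

    ``start``/``stop`` bound the binned calendar range (both on the bin
    grid); plots originating before ``start`` go to ``older_count``.
    """
    plots = list(processed)
    if not plots:
        raise DataError("no processed plots to bin")
    bins = np.array([p.bin_start for p in plots])
    lo = int(bins.min()) if start is None else int(start)
    hi = int(bins.max()) + BIN_WIDTH if stop is None else int(stop)
    for edge in (lo, hi):
        if (edge - anchor) % BIN_WIDTH != 0:
            raise ValueError(f"window edge {edge} is not on the {anchor}-anchored grid")
    if bins.max() >= hi:
        raise ValueError("distribution window ends before the newest plot origin")
    starts = np.arange(lo, hi, BIN_WIDTH)
    older = int((bins < lo).sum())
    counts = np.array([(bins == a).sum() for a in starts], dtype=float)
    return AgeDistribution(
        region=region,
        window_label=window_label or f"{lo}-{hi}",
        bin_starts=starts,
        counts=counts,
        n_plots=len(plots),
        older_count=float(older),
    )


def correct_recent_bin(
    dist: AgeDistribution,
    sampling_window: tuple[float, float],
    horizon: float,
    factor: float | None = None,
) -> AgeDistribution:
    """Inflate the newest bin for fire that plots could not yet have seen.

    The mean post-sample exposure is m = horizon - midpoint(sampling
    window) under uniform sampling through the window; the newest bin is
    multiplied by 40/(40 - m).  A verbatim ``factor`` override is accepted
    for region-specific published weightings.
    """
    first, last = sampling_window
    if last < first:
        raise ValueError(f"empty sampling window {sampling_window!r}")
    if horizon < last:
        raise ValueError("horizon must not precede the end of the sampling window")
    m = horizon - (first + last) / 2.0
    if factor is None:
        if m >= BIN_WIDTH:
            raise DomainError(
                f"mean post-sample exposure {m} >= bin width {BIN_WIDTH}"
            )
        factor = BIN_WIDTH / (BIN_WIDTH - m)
    out = dist.copy()
    out.counts[-1] *= factor
    out.metadata.update(
        {
            "recent_bin_factor": factor,
            "mean_post_sample_exposure_years": m,
            "sampling_window": list(sampling_window),
            "horizon": horizon,
        }
    )
    return out


def proportional_age_sd(
    plots: Iterable[PlotRecord],
    breast_height_offset: float = BREAST_HEIGHT_OFFSET,
) -> float:
    """Pooled within-plot SD of (tree age - stand age) / stand age.

    Tree ages are core ring counts plus the breast-height offset; the stand
    age is the plot's cover-weighted mean.  Because each plot's stand age is
    estimated from its own trees, the pooled variance divides by
    (n_trees - n_plots), which is unbiased for the proportional noise
    variance under equal cover weights.  Plots with stand age 0 are skipped
    with a warning.
    """
    sq = 0.0
    n_trees = 0
    n_plots = 0
    for p in plots:
        if not p.stocked or not p.tree_cores:
            continue
        qual = [c for c in p.tree_cores if c.crown_class in _AGING_CROWN_CLASSES]
        if not qual:
            continue
        stand_age = compute_stand_age(qual, breast_height_offset)
        if stand_age <= 0:
            warnings.warn(
                f"plot {p.plot_id}: stand age {stand_age} <= 0 excluded from "
                "proportional-SD pooling",
                stacklevel=2,
            )
            continue
        for c in qual:
            d = (c.ring_count + breast_height_offset - stand_age) / stand_age
            sq += d * d
            n_trees += 1
        n_plots += 1
    if n_trees < 2:
        raise DataError("need at least two trees across plots")
    dof = n_trees - n_plots
    if dof < 1:
        raise DataError(
            "every plot has a single core; within-plot variation is undefined"
        )
    return math.sqrt(sq / dof)


# ---------------------------------------------------------------------------
# delimited-text I/O
#
# Plot table columns (one row per plot): plot_id, region, forest_type, pine,
# measurement_year, protected, land_class_ok, stocked, subplot_ages (values
# joined with "|"), disturbance_code, disturbance_year.  Companion tree table
# (one row per core): plot_id, ring_count, cover_weight, crown_class.


def read_plot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {
        "plot_id",
        "measurement_year",
        "stocked",
        "subplot_ages",
    }
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"plot table missing columns: {sorted(missing)}")
    return df


def read_tree_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"plot_id", "ring_count"} - set(df.columns)
    if missing:
        raise DataError(f"tree table missing columns: {sorted(missing)}")
    return df


def _parse_subplot_ages(val) -> list[float]:
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return []
    s = str(val).strip()
    if not s:
        return []
    return [float(x) for x in s.split("|")]


def plot_records_from_tables(
    plots: pd.DataFrame, trees: pd.DataFrame | None = None
) -> list[PlotRecord]:
    """Assemble :class:`PlotRecord` objects from plot (+ optional tree) tables."""
    cores_by_plot: dict[str, list[TreeCore]] = {}
    if trees is not None:
        for row in trees.itertuples(index=False):
            cores_by_plot.setdefault(str(row.plot_id), []).append(
                TreeCore(
                    ring_count=float(row.ring_count),
                    cover_weight=float(getattr(row, "cover_weight", 1.0)),
                    crown_class=str(getattr(row, "crown_class", DOMINANT)),
                )
            )
    records = []
    for row in plots.itertuples(index=False):
        pid = str(row.plot_id)
        dist_year = getattr(row, "disturbance_year", None)
        if dist_year is not None and (
            isinstance(dist_year, float) and math.isnan(dist_year)
        ):
            dist_year = None
        dist_code = getattr(row, "disturbance_code", None)
        if isinstance(dist_code, float) and math.isnan(dist_code):
            dist_code = None
        records.append(
            PlotRecord(
                plot_id=pid,
                measurement_year=int(row.measurement_year),
                region=str(getattr(row, "region", "")),
                forest_type=str(getattr(row, "forest_type", "")),
                pine=bool(getattr(row, "pine", False)),
                protected=bool(getattr(row, "protected", True)),
                land_class_ok=bool(getattr(row, "land_class_ok", True)),
                stocked=bool(row.stocked),
                subplot_ages=_parse_subplot_ages(row.subplot_ages),
                disturbance_code=dist_code,
                disturbance_year=None if dist_year is None else float(dist_year),
                tree_cores=cores_by_plot.get(pid),
            )
        )
    return records


def write_age_distribution(
    dist: AgeDistribution, counts_path: str | Path, meta_path: str | Path
) -> None:
    pd.DataFrame(
        {
            "bin_start": dist.bin_starts,
            "bin_end": dist.bin_starts + BIN_WIDTH,
            "count": dist.counts,
        }
    ).to_csv(counts_path, index=False)
    meta = {
        "region": dist.region,
        "window_label": dist.window_label,
        "n_plots": dist.n_plots,
        "older_count": dist.older_count,
        "metadata": dist.metadata,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_age_distribution(
    counts_path: str | Path, meta_path: str | Path
) -> AgeDistribution:
    df = pd.read_csv(counts_path)
    meta = json.loads(Path(meta_path).read_text())
    return AgeDistribution(
        region=meta["region"],
        window_label=meta["window_label"],
        bin_starts=df["bin_start"].to_numpy(),
        counts=df["count"].to_numpy(),
        n_plots=meta["n_plots"],
        older_count=meta.get("older_count", 0.0),
        metadata=meta.get("metadata", {}),
    )
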