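"""Fire-severity classification and fire-rotation arithmetic.

Severity is classified from basal-area mortality of woody species: low
(0-20%), moderate (20-70%), high (>70%).  The fire rotation is the time
required for an area equal to the area of interest to burn at the chosen
severities: the observation period divided by the fraction of the region
burned in that period.  Burned areas are summed, not unioned, so a region
in which the same ground reburns can have a burned fraction above one --
this is the Heinselman-style rotation, which concerns "an area equal to
the area of interest" rather than a distinct footprint.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LOW",
    "MODERATE",
    "HIGH",
    "SEVERITY_LABELS",
    "LOW_MODERATE_EDGE",
    "MODERATE_HIGH_EDGE",
    "DomainError",
    "classify_severity",
    "FireEvent",
    "BurnRecord",
    "RotationEstimate",
    "fraction_burned",
    "rotation",
    "rotation_from_record",
    "rotation_from_age_cdf",
    "read_burn_record",
    "write_burn_record",
]

LOW = "low"
MODERATE = "moderate"
HIGH = "high"
SEVERITY_LABELS = (LOW, MODERATE, HIGH)

#: Basal-area mortality band edges.  The bands partition [0, 1]:
#: low = [0, 0.20), moderate = [0.20, 0.70], high = (0.70, 1].
#: Boundaries are assigned to the lower-intensity contiguous class, except
#: that "high" is strictly above 0.70 (">70%").
LOW_MODERATE_EDGE = 0.20
MODERATE_HIGH_EDGE = 0.70


class DomainError(ValueError):
    """An input value is outside the domain the operation is defined on."""


def classify_severity(mortality_fraction: float) -> str:
    """Classify fire severity from the basal-area mortality fraction.

    Parameters
    ----------
    mortality_fraction
        Fraction of woody basal area killed, in [0, 1].

    Returns
    -------
    str
        ``"low"`` for [0, 0.20), ``"moderate"`` for [0.20, 0.70],
        ``"high"`` for (0.70, 1].
    """
    m = float(mortality_fraction)
    if math.isnan(m) or not (0.0 <= m <= 1.0):
        raise DomainError(
            f"basal-area mortality fraction must lie in [0, 1]; got {mortality_fraction!r}"
        )
    if m < LOW_MODERATE_EDGE:
        return LOW
    if m <= MODERATE_HIGH_EDGE:
        return MODERATE
    return HIGH


@dataclass(frozen=True)
class FireEvent:
    """One dated burned patch with its basal-area mortality fraction."""

    year: float
    area_ha: float
    mortality_fraction: float

    def __post_init__(self) -> None:
        if not self.area_ha > 0:
            raise DomainError(f"event area must be positive; got {self.area_ha!r}")
        # validates the mortality fraction as a side effect
        classify_severity(self.mortality_fraction)

    @property
    def severity(self) -> str:
        return classify_severity(self.mortality_fraction)


@dataclass
class BurnRecord:
    """Burned patches observed over a region and a time window.

    ``window`` is ``(start_year, end_year)``; the observation period is
    ``end_year - start_year`` (years are treated as reals, no +1).
    """

    region_area_ha: float
    window: tuple[float, float]
    events: list[FireEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.region_area_ha > 0:
            raise DomainError(
                f"region area must be positive; got {self.region_area_ha!r}"
            )
        start, end = self.window
        if not end - start >= 1:
            raise DomainError(f"window must span at least 1 year; got {self.window!r}")
        for ev in self.events:
            if not (start <= ev.year <= end):
                raise DomainError(
                    f"event year {ev.year} outside record window {self.window}"
                )

    @property
    def period_years(self) -> float:
        return self.window[1] - self.window[0]


def _validate_classes(classes: Iterable[str]) -> frozenset[str]:
    cls = frozenset(classes)
    if not cls:
        raise ValueError("severity class set must be non-empty")
    unknown = cls - set(SEVERITY_LABELS)
    if unknown:
        raise ValueError(f"unknown severity labels: {sorted(unknown)}")
    return cls


def fraction_burned(record: BurnRecord, classes: Iterable[str]) -> float:
    """Fraction of the region burned at the given severities.

    Event areas are summed (reburns count again), so the result may
    exceed 1.
    """
    cls = _validate_classes(classes)
    total = sum(ev.area_ha for ev in record.events if ev.severity in cls)
    return total / record.region_area_ha


def rotation(period_years: float, fraction: float) -> float:
    """Fire rotation: observation period / fraction of the region burned.

    A zero fraction yields ``math.inf`` (no qualifying fire observed)
    rather than an error, so multi-region pipelines do not abort.
    """
    if not period_years > 0:
        raise DomainError(f"period must be positive; got {period_years!r}")
    if fraction < 0:
        raise DomainError(f"burned fraction must be non-negative; got {fraction!r}")
    if fraction == 0:
        return math.inf
    return period_years / fraction


@dataclass(frozen=True)
class RotationEstimate:
    """A fire-rotation estimate with the inputs it was computed from."""

    classes: tuple[str, ...]
    period_years: float
    fraction_burned: float
    rotation_years: float
    region_area_ha: float | None = None
    window: tuple[float, float] | None = None
    n_events: int | None = None

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.rotation_years)

    def to_dict(self) -> dict:
        d = {
            "classes": list(self.classes),
            "period_years": self.period_years,
            "fraction_burned": self.fraction_burned,
            "rotation_years": None if self.is_infinite else self.rotation_years,
            "infinite": self.is_infinite,
            "region_area_ha": self.region_area_ha,
            "window": list(self.window) if self.window else None,
            "n_events": self.n_events,
        }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def rotation_from_record(
    record: BurnRecord, classes: Iterable[str]
) -> RotationEstimate:
    """Compose :func:`fraction_burned` and :func:`rotation` over a record."""
    cls = _validate_classes(classes)
    frac = fraction_burned(record, cls)
    n = sum(1 for ev in record.events if ev.severity in cls)
    return RotationEstimate(
        classes=tuple(sorted(cls)),
        period_years=record.period_years,
        fraction_burned=frac,
        rotation_years=rotation(record.period_years, frac),
        region_area_ha=record.region_area_ha,
        window=record.window,
        n_events=n,
    )


def rotation_from_age_cdf(age_threshold_years: float, fraction_younger: float) -> float:
    """Rotation implied by the stand-age CDF of a stationary regime.

    Under stationary stand replacement at rotation R, stand ages are
    exponentially distributed and P(age < t) = 1 - exp(-t/R); inverting
    gives R = -t / ln(1 - fraction_younger).
    """
    if not age_threshold_years > 0:
        raise DomainError(f"age threshold must be positive; got {age_threshold_years!r}")
    if not 0.0 < fraction_younger < 1.0:
        raise DomainError(
            "fraction younger must lie strictly inside (0, 1); "
            f"got {fraction_younger!r}"
        )
    return -age_threshold_years / math.log1p(-fraction_younger)


# ---------------------------------------------------------------------------
# delimited-text I/O: one event per row plus a JSON header for the region


def write_burn_record(
    record: BurnRecord, events_path: str | Path, header_path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "year": [ev.year for ev in record.events],
            "area_ha": [ev.area_ha for ev in record.events],
            "mortality_fraction": [ev.mortality_fraction for ev in record.events],
        }
    )
    df.to_csv(events_path, index=False)
    header = {
        "region_area_ha": record.region_area_ha,
        "window": list(record.window),
        "n_events": len(record.events),
    }
    Path(header_path).write_text(json.dumps(header, indent=2, sort_keys=True))


def read_burn_record(events_path: str | Path, header_path: str | Path) -> BurnRecord:
    header = json.loads(Path(header_path).read_text())
    df = pd.read_csv(events_path)
    events = [
        FireEvent(year=row.year, area_ha=row.area_ha, mortality_fraction=row.mortality_fraction)
        for row in df.itertuples(index=False)
    ]
    return BurnRecord(
        region_area_ha=header["region_area_ha"],
        window=tuple(header["window"]),
        events=events,
    )
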