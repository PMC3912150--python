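"""Synthetic landscape-fire simulator emitting FIA-like plot tables.

The landscape is a set of 1-ha cells, each carrying the origin year of the
stand occupying it.  Each simulated year, every severity channel burns an
expected area of region_area / rotation (scaled by the exclusion
multiplier after the exclusion onset), realised as a Poisson number of
patches whose sizes follow a truncated power law placed on uniformly
random cells.  High-severity patches reset the origin year of every cell
they cover; moderate-severity patches reset each covered cell
independently with probability equal to the patch's drawn basal-area
mortality fraction; low-severity patches reset nothing.  There is no
spatial contagion: the downstream analysis consumes only marginal age
distributions and burned fractions, which random placement reproduces.

Plot sampling emulates the FIA design: one plot per ~2,400 ha at uniform
random cells, a measurement year uniform over the inventory window, tree
ring counts drawn as stand_age * (1 + Normal(0, sd)) minus the 8-yr
breast-height offset (so the pipeline's +8 is unbiased), optional
split-age plots straddling patch edges, and non-stocked plots where the
stand is too young to core.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .severity import LOW, MODERATE, HIGH, BurnRecord, DomainError, FireEvent
from .standage import BREAST_HEIGHT_OFFSET

__all__ = [
    "RegimeParameters",
    "SampleDesign",
    "Landscape",
    "patch_size_moments",
    "sample_patch_sizes",
    "simulate_fire_history",
    "sample_plots",
    "generate_fixture",
]


@dataclass
class RegimeParameters:
    """Configuration of the generative fire regime.

    Rotations are in years (expected annual burned fraction is
    1/rotation); ``exclusion_multiplier`` scales every channel's annual
    burned-fraction target from ``exclusion_start_year`` on.
    """

    region_area_ha: float
    high_rotation_years: float
    cell_size_ha: float = 1.0
    moderate_rotation_years: float | None = None
    lowsev_rotation_years: float | None = None
    patch_tail_exponent: float = 2.0
    patch_min_ha: float = 1.0
    patch_max_ha: float = 5000.0
    exclusion_start_year: int | None = None
    exclusion_multiplier: float = 1.0
    span: tuple[int, int] = (1810, 2009)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.region_area_ha > 0:
            raise DomainError("region area must be positive")
        for r in (
            self.high_rotation_years,
            self.moderate_rotation_years,
            self.lowsev_rotation_years,
        ):
            if r is not None and not r > 0:
                raise DomainError(f"rotations must be positive; got {r!r}")
        if not self.patch_tail_exponent > 1:
            raise DomainError("patch tail exponent must exceed 1")
        if not 0 < self.patch_min_ha <= self.patch_max_ha:
            raise DomainError("need 0 < patch_min_ha <= patch_max_ha")
        if self.patch_max_ha > self.region_area_ha:
            raise DomainError("patch_max_ha exceeds the region area")
        if not 0 < self.exclusion_multiplier <= 1:
            raise DomainError("exclusion multiplier must lie in (0, 1]")
        start, end = self.span
        if not end > start:
            raise DomainError(f"simulation span {self.span!r} is empty")

    @property
    def n_cells(self) -> int:
        return int(round(self.region_area_ha / self.cell_size_ha))


@dataclass
class SampleDesign:
    """FIA-like plot sampling configuration."""

    plot_density_ha: float = 2400.0
    measurement_window: tuple[int, int] = (2001, 2009)
    tree_age_noise_sd: float = 0.14
    trees_per_plot: int = 5
    split_prob: float = 0.0
    nonstocked_lag_years: float = 5.0
    missing_code_prob: float = 0.0
    pacific_coding: bool = False
    pine_fraction: float = 0.3
    unprotected_prob: float = 0.0
    land_class_fail_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.plot_density_ha > 0:
            raise DomainError("plot density must be positive")
        for p, lbl in (
            (self.split_prob, "split_prob"),
            (self.missing_code_prob, "missing_code_prob"),
            (self.pine_fraction, "pine_fraction"),
            (self.unprotected_prob, "unprotected_prob"),
            (self.land_class_fail_prob, "land_class_fail_prob"),
        ):
            if not 0 <= p <= 1:
                raise DomainError(f"{lbl} must lie in [0, 1]; got {p!r}")
        first, last = self.measurement_window
        if last < first:
            raise DomainError("measurement window is empty")


@dataclass
class Landscape:
    """Cell-based stand-origin state at a simulation year."""

    origin: np.ndarray
    prev_origin: np.ndarray
    year: int
    cell_size_ha: float = 1.0

    @property
    def n_cells(self) -> int:
        return int(self.origin.size)

    def ages(self) -> np.ndarray:
        return self.year - self.origin


def _moment(k: float, alpha: float, a: float, b: float) -> float:
    """Integral of x^(k - alpha) over [a, b]."""
    e = k - alpha + 1.0
    if abs(e) < 1e-12:
        return math.log(b / a)
    return (b**e - a**e) / e


def patch_size_moments(
    alpha: float, patch_min_ha: float, patch_max_ha: float
) -> tuple[float, float]:
    """Mean and second moment of the truncated power-law patch size.

    The density is proportional to x^(-alpha) on [patch_min, patch_max].
    """
    z = _moment(0.0, alpha, patch_min_ha, patch_max_ha)
    return (
        _moment(1.0, alpha, patch_min_ha, patch_max_ha) / z,
        _moment(2.0, alpha, patch_min_ha, patch_max_ha) / z,
    )


def sample_patch_sizes(
    rng: np.random.Generator, n: int, alpha: float, a: float, b: float
) -> np.ndarray:
    """Inverse-CDF draws from the truncated power law on [a, b]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return a * (b / a) ** u
    e = 1.0 - alpha
    return (a**e + u * (b**e - a**e)) ** (1.0 / e)


_CHANNELS = (
    # (label, rotation attribute, mortality sampler, resets origins)
    (HIGH, "high_rotation_years"),
    (MODERATE, "moderate_rotation_years"),
    (LOW, "lowsev_rotation_years"),
)


def _draw_mortality(rng: np.random.Generator, channel: str, n: int) -> np.ndarray:
    if channel == HIGH:
        return 1.0 - rng.uniform(0.0, 0.30, n)  # (0.70, 1.00]
    if channel == MODERATE:
        return rng.uniform(0.20, 0.70, n)  # [0.20, 0.70)
    return rng.uniform(0.0, 0.20, n)  # [0.00, 0.20)


def simulate_fire_history(
    params: RegimeParameters, rng: np.random.Generator | None = None
) -> tuple[Landscape, BurnRecord]:
    """Evolve a landscape over the configured span and log every patch.

    Initial stand ages are drawn from the stationary exponential
    distribution of the high-severity rotation, so the landscape starts in
    the regime's steady state.  Returns the landscape at the end year and
    the full burn record.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_cells
    if n < 1:
        raise DomainError("region smaller than one cell")
    start, end = params.span
    init_ages = rng.exponential(params.high_rotation_years, n)
    origin = (start - np.ceil(init_ages)).astype(np.int64)
    prev_origin = origin.copy()

    ev_years: list[np.ndarray] = []
    ev_areas: list[np.ndarray] = []
    ev_mort: list[np.ndarray] = []

    for year in range(start + 1, end + 1):
        excluded = (
            params.exclusion_start_year is not None
            and year >= params.exclusion_start_year
        )
        mult = params.exclusion_multiplier if excluded else 1.0
        for channel, rot_attr in _CHANNELS:
            rot = getattr(params, rot_attr)
            if rot is None:
                continue
            target_area = params.region_area_ha / rot * mult
            mean_size, _ = patch_size_moments(
                params.patch_tail_exponent, params.patch_min_ha, params.patch_max_ha
            )
            n_patches = int(rng.poisson(target_area / mean_size))
            if n_patches == 0:
                continue
            sizes = sample_patch_sizes(
                rng,
                n_patches,
                params.patch_tail_exponent,
                params.patch_min_ha,
                params.patch_max_ha,
            )
            mort = _draw_mortality(rng, channel, n_patches)
            cells_per_patch = np.maximum(
                1, np.rint(sizes / params.cell_size_ha).astype(np.int64)
            )
            idx = rng.integers(0, n, int(cells_per_patch.sum()))
            if channel == HIGH:
                reset = idx
            elif channel == MODERATE:
                probs = np.repeat(mort, cells_per_patch)
                reset = idx[rng.random(idx.size) < probs]
            else:
                reset = idx[:0]
            if reset.size:
                prev_origin[reset] = origin[reset]
                origin[reset] = year
            ev_years.append(np.full(n_patches, year))
            ev_areas.append(sizes)
            ev_mort.append(mort)

    if ev_years:
        years = np.concatenate(ev_years)
        areas = np.concatenate(ev_areas)
        morts = np.concatenate(ev_mort)
    else:
        years = areas = morts = np.empty(0)
    events = [
        FireEvent(year=float(y), area_ha=float(a), mortality_fraction=float(m))
        for y, a, m in zip(years, areas, morts)
    ]
    record = BurnRecord(
        region_area_ha=params.region_area_ha, window=(start, end), events=events
    )
    landscape = Landscape(
        origin=origin, prev_origin=prev_origin, year=end, cell_size_ha=params.cell_size_ha
    )
    return landscape, record


def _origin_at_measurement(
    landscape: Landscape, cells: np.ndarray, years: np.ndarray
) -> np.ndarray:
    """Origin year each sampled cell had at its measurement year.

    Cells that burned after measurement fall back to their previous origin
    (one level of history; a double post-measurement burn is clipped to the
    measurement year and is vanishingly rare at realistic rotations).
    """
    o = landscape.origin[cells]
    prev = landscape.prev_origin[cells]
    o = np.where(o > years, prev, o)
    return np.minimum(o, years)


def sample_plots(
    landscape: Landscape,
    design: SampleDesign,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an FIA-like plot table (and tree table) from a landscape.

    Returns ``(plots, trees)`` data frames in the dialect the stand-age
    pipeline reads.  Ring counts are emitted so that the pipeline's
    cover-weighted mean + 8 recovers the cell age in expectation.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    area = landscape.n_cells * landscape.cell_size_ha
    n_plots = int(area // design.plot_density_ha)
    if n_plots < 1:
        raise DomainError(
            f"plot density {design.plot_density_ha} ha/plot implies zero plots "
            f"for a {area} ha region"
        )
    first, last = design.measurement_window
    cells = rng.choice(landscape.n_cells, size=n_plots, replace=False)
    my = rng.integers(first, last + 1, n_plots)
    origin = _origin_at_measurement(landscape, cells, my)
    age = (my - origin).astype(float)

    stocked = age >= design.nonstocked_lag_years
    pine = rng.random(n_plots) < design.pine_fraction
    protected = rng.random(n_plots) >= design.unprotected_prob
    land_ok = rng.random(n_plots) >= design.land_class_fail_prob
    split = (rng.random(n_plots) < design.split_prob) & stocked

    # second subplot age for split plots: nearest following cell with a
    # different origin at the same measurement year
    age2 = np.full(n_plots, np.nan)
    for i in np.flatnonzero(split):
        for step in range(1, 50):
            j = (cells[i] + step) % landscape.n_cells
            oj = _origin_at_measurement(
                landscape, np.array([j]), np.array([my[i]])
            )[0]
            if oj != origin[i]:
                age2[i] = my[i] - oj
                break
        else:
            split[i] = False

    k = design.trees_per_plot
    noise = rng.normal(0.0, design.tree_age_noise_sd, (n_plots, k))
    rings = np.maximum(
        np.rint(age[:, None] * (1.0 + noise)) - BREAST_HEIGHT_OFFSET, 0.0
    )

    plot_rows = []
    tree_rows = []
    for i in range(n_plots):
        pid = f"P{i:05d}"
        if stocked[i]:
            ages_str = f"{age[i]:.0f}"
            if split[i]:
                ages_str += f"|{age2[i]:.0f}"
            dist_code = None
            dist_year = None
            for t in range(k):
                tree_rows.append(
                    {
                        "plot_id": pid,
                        "tree_id": t,
                        "ring_count": rings[i, t],
                        "cover_weight": 1.0,
                        "crown_class": "dominant" if t % 2 == 0 else "codominant",
                    }
                )
        else:
            ages_str = ""
            dist_code = "fire"
            dist_year = float(origin[i])
            coded = True
            if design.pacific_coding and age[i] >= 6:
                coded = False
            if rng.random() < design.missing_code_prob:
                coded = False
            if not coded:
                dist_code = None
                dist_year = None
        plot_rows.append(
            {
                "plot_id": pid,
                "region": "synthetic",
                "forest_type": "ponderosa_jeffrey_pine" if pine[i] else "mixed_conifer",
                "pine": bool(pine[i]),
                "measurement_year": int(my[i]),
                "protected": bool(protected[i]),
                "land_class_ok": bool(land_ok[i]),
                "stocked": bool(stocked[i]),
                "subplot_ages": ages_str,
                "disturbance_code": dist_code,
                "disturbance_year": dist_year,
            }
        )
    plots = pd.DataFrame(plot_rows)
    trees = pd.DataFrame(
        tree_rows,
        columns=["plot_id", "tree_id", "ring_count", "cover_weight", "crown_class"],
    )
    return plots, trees


def _params_from_config(config: dict) -> tuple[RegimeParameters, SampleDesign]:
    regime = dict(config.get("regime", {}))
    design = dict(config.get("design", {}))
    if "span" in regime:
        regime["span"] = tuple(regime["span"])
    if "measurement_window" in design:
        design["measurement_window"] = tuple(design["measurement_window"])
    return RegimeParameters(**regime), SampleDesign(**design)


def generate_fixture(
    config: dict | str | Path, out_dir: str | Path
) -> dict[str, Path]:
    """Simulate one region and write its tables and ground truth to disk.

    ``config`` is a dict or a YAML file with ``seed``, ``regime`` and
    ``design`` sections.  Writes plots.csv, trees.csv, burn_events.csv,
    burn_region.json and ground_truth.json; two runs with the same seed
    are byte-identical.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    params, design = _params_from_config(config)
    seed = config.get("seed", params.seed)
    rng = np.random.default_rng(seed)
    landscape, record = simulate_fire_history(params, rng)
    plots, trees = sample_plots(landscape, design, rng)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "plots": out / "plots.csv",
        "trees": out / "trees.csv",
        "burn_events": out / "burn_events.csv",
        "burn_region": out / "burn_region.json",
        "ground_truth": out / "ground_truth.json",
    }
    plots.to_csv(paths["plots"], index=False)
    trees.to_csv(paths["trees"], index=False)
    from .severity import write_burn_record

    write_burn_record(record, paths["burn_events"], paths["burn_region"])
    truth = {
        "seed": seed,
        "high_rotation_years": params.high_rotation_years,
        "moderate_rotation_years": params.moderate_rotation_years,
        "lowsev_rotation_years": params.lowsev_rotation_years,
        "exclusion_start_year": params.exclusion_start_year,
        "exclusion_multiplier": params.exclusion_multiplier,
        "tree_age_noise_sd": design.tree_age_noise_sd,
        "span": list(params.span),
        "region_area_ha": params.region_area_ha,
        "n_plots": int(len(plots)),
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
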