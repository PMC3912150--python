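"""Region summary tables and observed-vs-expected histogram figures."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .inference import CounterfactualDistribution
from .standage import BIN_WIDTH, AgeDistribution, ProcessedPlot

__all__ = ["mean_stand_age", "mean_stand_age_at", "region_summary", "plot_observed_vs_expected"]


def mean_stand_age(plots: Sequence[ProcessedPlot]) -> float:
    if not plots:
        raise ValueError("no plots")
    return float(np.mean([p.stand_age_years for p in plots]))


def mean_stand_age_at(plots: Sequence[ProcessedPlot], year: float = 1930) -> float:
    """Mean stand age rewound to a reference year.

    Each retained plot is rewound to ``year`` (age = year - origin); plots
    originating after ``year`` did not exist then and are dropped.
    """
    ages = [year - p.origin_year for p in plots if p.origin_year <= year]
    if not ages:
        raise ValueError(f"no plots originate at or before {year}")
    return float(np.mean(ages))


def region_summary(
    plots: Sequence[ProcessedPlot],
    sampled_area_ha: float,
    chi_square: float,
    p_value: float,
    region: str = "",
    reference_year: float = 1930,
) -> pd.DataFrame:
    """One-row summary: n, sampled area, mean stand age now and at the
    fire-exclusion onset, and the no-exclusion test result."""
    return pd.DataFrame(
        [
            {
                "region": region,
                "n_plots": len(plots),
                "sampled_area_ha": sampled_area_ha,
                "mean_stand_age_now": round(mean_stand_age(plots), 1),
                f"mean_stand_age_{reference_year:.0f}": round(
                    mean_stand_age_at(plots, reference_year), 1
                ),
                "chi_square": round(chi_square, 2),
                "p_value": p_value,
            }
        ]
    )


def plot_observed_vs_expected(
    dist: AgeDistribution,
    counterfactual: CounterfactualDistribution,
    png_path: str | Path | None = None,
    data_path: str | Path | None = None,
) -> pd.DataFrame:
    """Paired-bar panel: observed origin classes vs the no-exclusion null.

    Observed counts are drawn for every bin; the counterfactual bars cover
    the suppression-era bins it projects onto.  The data behind the figure
    are always returned (and optionally written) as a table; the PNG is
    optional so headless runs never require a display.
    """
    expected = np.full(dist.counts.size, np.nan)
    lo, hi = counterfactual.target_window
    mask = (dist.bin_starts >= lo) & (dist.bin_starts < hi)
    expected[mask] = counterfactual.expected_counts
    table = pd.DataFrame(
        {
            "bin_start": dist.bin_starts,
            "bin_end": dist.bin_starts + BIN_WIDTH,
            "observed": dist.counts,
            "expected_no_exclusion": expected,
        }
    )
    if data_path is not None:
        table.to_csv(data_path, sep="\t", index=False)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        x = np.arange(len(table))
        width = 0.42
        ax.bar(x - width / 2, table["observed"], width, color="black", label="observed")
        ax.bar(
            x + width / 2,
            table["expected_no_exclusion"].fillna(0.0),
            width,
            color="0.6",
            label="expected, no fire exclusion",
        )
        ax.set_xticks(x)
        ax.set_xticklabels(
            [f"{a}–{a + BIN_WIDTH - 1}" for a in table["bin_start"]],
            rotation=45,
            ha="right",
            fontsize=8,
        )
        ax.set_xlabel("stand-origin class (calendar years)")
        ax.set_ylabel("plots")
        title = dist.region or "region"
        ax.set_title(f"{title}: stand-origin distribution")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return table
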