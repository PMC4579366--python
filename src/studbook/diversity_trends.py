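"""Rate of inbreeding, effective population size and 5-year-block trends.

The rate of inbreeding per annum is the (negated) regression coefficient of
ln(1 - F_t) on year of birth, where F_t is the mean inbreeding coefficient of
animals born in year t.  Multiplying by the generation interval L gives the
rate per generation, dF = -b * L, and the effective population size is
Ne = 1 / (2 dF) — the size of an idealised population with the same
per-generation inbreeding increment.  A negative or zero dF leaves Ne
undetermined (genetic diversity is not being lost), which is a first-class
result here, never an exception, so batch reports over many breeds or blocks
do not abort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

from .demography import SireUsageStats, block_usage, registrations_by_year
from .pedigree_core import Pedigree
from .relatedness import CohortSeries

__all__ = [
    "Undetermined",
    "TrendEstimate",
    "BlockSummary",
    "annual_inbreeding_rate",
    "delta_f_per_generation",
    "effective_population_size",
    "trend_estimate",
    "default_blocks",
    "block_statistics",
    "compare_blocks",
    "write_trend_table",
]

#: closed enumeration of reasons a quantity can be undetermined
UNDETERMINED_REASONS = frozenset(
    {
        "negative_rate",      # dF <= 0 with dF < 0: diversity apparently rising
        "zero_rate",          # dF == 0 exactly: division guard
        "insufficient_years", # fewer than 3 usable cohort years
        "insufficient_data",  # no usable records at all
    }
)


@dataclass(frozen=True)
class Undetermined:
    """Marker value for a statistic that cannot be computed, with a reason
    code from a closed enumeration (machine-readable in reports)."""

    reason: str

    def __post_init__(self):
        if self.reason not in UNDETERMINED_REASONS:
            raise ValueError(f"unknown reason code {self.reason!r}")


MaybeFloat = Union[float, Undetermined]


@dataclass
class TrendEstimate:
    """Whole-period (or within-block) inbreeding trend.

    ``slope_b`` is the regression coefficient of ln(1-F_t) on year;
    ``dF_annual = -slope_b`` so that rising inbreeding gives a positive rate;
    ``dF_gen = dF_annual * L``; ``Ne = 1/(2 dF_gen)`` when dF_gen > 0.
    """

    slope_b: float
    dF_annual: float
    L: float
    dF_gen: float
    Ne: MaybeFloat
    window: tuple[int, int]
    n_years: int


def annual_inbreeding_rate(
    series: CohortSeries,
    window: tuple[int, int] | None = None,
    *,
    transform: str = "slope",
) -> tuple[float, float]:
    """Regression coefficient of ln(1-F_t) on year, and the annual rate.

    Returns ``(slope_b, dF_annual)``.  Years inside the window with at least
    one birth qualify; the regression is unweighted across years.  With the
    default ``transform="slope"`` the annual rate is -slope_b (the literal
    regression-coefficient method); ``transform="exp"`` returns
    1 - exp(slope_b), the exact per-annum rate implied by a log-linear
    decline of 1-F (the two differ only at third order for realistic rates).

    Raises
    ------
    ValueError
        With fewer than 3 qualifying years, or if any mean F_t >= 1.
    """
    t = series.table
    if window is not None:
        t = t.loc[(t.index >= int(window[0])) & (t.index <= int(window[1]))]
    t = t[(t["n_born"] >= 1) & t["mean_F"].notna()]
    if len(t) < 3:
        raise ValueError("rate of inbreeding requires >= 3 years with births")
    if (t["mean_F"] >= 1).any():
        raise ValueError("degenerate cohort with mean F >= 1")
    res = stats.linregress(t.index.to_numpy(dtype=float),
                           np.log1p(-t["mean_F"].to_numpy()))
    slope_b = float(res.slope)
    if transform == "slope":
        rate = -slope_b
    elif transform == "exp":
        rate = 1.0 - math.exp(slope_b)
    else:
        raise ValueError("transform must be 'slope' or 'exp'")
    return slope_b, rate


def delta_f_per_generation(dF_annual: float, L: float) -> float:
    """Rate of inbreeding per generation: dF = dF_annual * L (L in years)."""
    if L <= 0:
        raise ValueError("generation interval must be positive")
    return dF_annual * L


def effective_population_size(dF_gen: float) -> MaybeFloat:
    """Ne = 1/(2 dF); undetermined when dF <= 0 (no loss of diversity)."""
    if dF_gen > 0:
        return 1.0 / (2.0 * dF_gen)
    if dF_gen == 0:
        return Undetermined("zero_rate")
    return Undetermined("negative_rate")


def trend_estimate(
    series: CohortSeries,
    L: float,
    window: tuple[int, int] | None = None,
    *,
    transform: str = "slope",
) -> TrendEstimate:
    """Convenience composition: regression -> annual rate -> dF -> Ne."""
    slope_b, dF_annual = annual_inbreeding_rate(series, window, transform=transform)
    dF_gen = delta_f_per_generation(dF_annual, L)
    t = series.table
    if window is not None:
        t = t.loc[(t.index >= int(window[0])) & (t.index <= int(window[1]))]
    used = int(((t["n_born"] >= 1) & t["mean_F"].notna()).sum())
    win = window if window is not None else series.window
    return TrendEstimate(
        slope_b=slope_b,
        dF_annual=dF_annual,
        L=L,
        dF_gen=dF_gen,
        Ne=effective_population_size(dF_gen),
        window=(int(win[0]), int(win[1])),
        n_years=used,
    )


def default_blocks(start: int = 1980, end: int = 2014) -> list[tuple[int, int]]:
    """Consecutive 5-year blocks partitioning [start, end] (default: the seven
    blocks 1980-1984 ... 2010-2014)."""
    if (end - start + 1) % 5:
        raise ValueError("window length must be a multiple of 5 years")
    return [(y, y + 4) for y in range(start, end + 1, 5)]


@dataclass
class BlockSummary:
    """Registrations, trend and usage concentration within one 5-year block."""

    label: str
    years: tuple[int, int]
    mean_registrations: float
    trend: TrendEstimate | Undetermined
    sire_usage: SireUsageStats | None
    dam_usage: SireUsageStats | None
    included: bool  # mean registrations > inclusion threshold


#: a breed enters cross-breed block statistics only above this mean
#: registrations per year in every block
INCLUSION_MIN_REGS = 50.0


def block_statistics(
    p: Pedigree,
    series: CohortSeries,
    L: float,
    blocks: list[tuple[int, int]] | None = None,
    *,
    transform: str = "slope",
) -> list[BlockSummary]:
    """Per-block registrations, within-block trend estimate and usage summary.

    The whole-period generation interval L is reused inside each block (the
    per-block regression only re-estimates the slope).  Blocks with fewer
    than 3 usable years yield an ``Undetermined`` trend, not an error.  The
    ``included`` flag records the >50 mean-registrations-per-year rule for
    cross-breed comparisons.
    """
    if blocks is None:
        blocks = default_blocks(*series.window)
    out = []
    for b0, b1 in blocks:
        regs = registrations_by_year(p, (b0, b1))
        mean_regs = float(regs.mean())
        try:
            tr: TrendEstimate | Undetermined = trend_estimate(
                series, L, (b0, b1), transform=transform)
        except ValueError:
            tr = Undetermined("insufficient_years")
        usage = {}
        for role in ("sire", "dam"):
            try:
                usage[role] = block_usage(p, range(b0, b1 + 1), role)
            except ValueError:
                usage[role] = None
        out.append(
            BlockSummary(
                label=f"{b0}-{b1}",
                years=(b0, b1),
                mean_registrations=mean_regs,
                trend=tr,
                sire_usage=usage["sire"],
                dam_usage=usage["dam"],
                included=mean_regs > INCLUSION_MIN_REGS,
            )
        )
    return out


def compare_blocks(block_values: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA of a per-breed x per-block statistic (e.g. dF per
    generation), treating breeds as replicates within blocks.

    ``block_values`` has one row per breed and one column per block; missing
    entries are ignored.  Returns (F statistic, p value).
    """
    groups = [c.dropna().to_numpy(dtype=float) for _, c in block_values.items()]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 blocks with >= 2 breeds each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("degenerate ANOVA: zero within-block variance everywhere")
    f, pval = stats.f_oneway(*groups)
    return float(f), float(pval)


def _ne_repr(ne: MaybeFloat) -> str:
    return f"{ne:.1f}" if isinstance(ne, float) else f"UNDETERMINED({ne.reason})"


def write_trend_table(
    whole: TrendEstimate,
    blocks: list[BlockSummary],
    path,
    *,
    sep: str = "\t",
) -> None:
    """Whole-period row plus one row per block, delimited text."""
    rows = [_trend_row("whole_period", whole)]
    for b in blocks:
        if isinstance(b.trend, Undetermined):
            rows.append(
                {"period": b.label, "slope_b": "", "dF_annual": "", "L": "",
                 "dF_gen": "", "Ne": f"UNDETERMINED({b.trend.reason})",
                 "n_years": 0, "mean_registrations": round(b.mean_registrations, 2),
                 "included": b.included})
        else:
            row = _trend_row(b.label, b.trend)
            row["mean_registrations"] = round(b.mean_registrations, 2)
            row["included"] = b.included
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def _trend_row(label: str, t: TrendEstimate) -> dict:
    return {
        "period": label,
        "slope_b": f"{t.slope_b:.6f}",
        "dF_annual": f"{t.dF_annual:.6f}",
        "L": f"{t.L:.3f}",
        "dF_gen": f"{t.dF_gen:.6f}",
        "Ne": _ne_repr(t.Ne),
        "n_years": t.n_years,
        "mean_registrations": "",
        "included": "",
    }
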