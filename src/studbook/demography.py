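"""Generation intervals, registration trends and parent-usage concentration.

The generation interval L is the mean age of parents at the birth of progeny
which themselves go on to reproduce; it converts per-annum inbreeding rates
to per-generation rates.  Sire-usage statistics quantify the "popular sire"
phenomenon: a small fraction of males siring a large share of each year's
registrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree_core import MISSING, Pedigree, parental_ages

__all__ = [
    "GenerationInterval",
    "SireUsageStats",
    "generation_interval",
    "sire_usage",
    "block_usage",
    "usage_counts",
    "registration_trend",
    "registrations_by_year",
    "write_usage_table",
]


@dataclass
class GenerationInterval:
    """Per-year mean parental age at the birth of breeding progeny, and the
    whole-period mean L (unweighted across years with a defined value)."""

    yearly: pd.Series  # index year, value mean parental age in years
    L: float
    n_pairs: int  # parent/offspring age observations used


def generation_interval(
    p: Pedigree,
    year_range: tuple[int, int],
    *,
    max_parent_age: float = 20.0,
    resolution: str | None = None,
) -> GenerationInterval:
    """Mean age of parents at the birth of progeny that themselves reproduce.

    For every animal born in year t (within the range) that has at least one
    offspring anywhere in the pedigree, the ages of its sire and dam at its
    birth are pooled; the yearly value is the mean of that pool and L is the
    unweighted mean of the yearly values.  Ages are day differences / 365.25
    at date resolution and integer year differences at year resolution.
    Chronologically impossible or implausible ages (<= 0 or > max_parent_age)
    are excluded.

    Raises
    ------
    ValueError
        If no breeding progeny with usable parental ages exist in the range.
    """
    y0, y1 = int(year_range[0]), int(year_range[1])
    breeders = set(p.df.loc[p.df["sire"] != MISSING, "sire"]) | set(
        p.df.loc[p.df["dam"] != MISSING, "dam"])
    ages = parental_ages(p, resolution=resolution)
    ages = ages[(ages["age_years"] > 0) & (ages["age_years"] <= max_parent_age)]
    ages = ages[ages["offspring"].isin(breeders)]
    ages = ages.dropna(subset=["offspring_year"])
    ages = ages[(ages["offspring_year"] >= y0) & (ages["offspring_year"] <= y1)]
    if ages.empty:
        raise ValueError("generation interval undeterminable: no breeding "
                         "progeny with usable parental ages in range")
    yearly = ages.groupby(ages["offspring_year"].astype(int))["age_years"].mean()
    return GenerationInterval(yearly=yearly, L=float(yearly.mean()),
                              n_pairs=len(ages))


@dataclass
class SireUsageStats:
    """Concentration of one year's registrations over parents of one role."""

    year: int
    role: str  # "sire" or "dam"
    n_unique: int
    n_progeny: int  # registrations that year with a known parent of the role
    max: int
    mean: float
    median: float
    mode: int
    sd: float
    pct_top: dict[int, float] = field(default_factory=dict)  # {50,25,10,5} -> %
    multimodal: bool = False
    single_parent: bool = False  # sd reported as 0 because n_unique == 1


def usage_counts(p: Pedigree, years, role: str) -> pd.Series:
    """Progeny born in the given year(s) per unique parent of ``role``,
    sorted by descending count then ascending parent identifier."""
    if role not in ("sire", "dam"):
        raise ValueError("role must be 'sire' or 'dam'")
    years = {int(years)} if np.isscalar(years) else {int(y) for y in years}
    df = p.df
    in_years = df["birth_year"].isin(years).fillna(False)
    known = df[role] != MISSING
    sub = df.loc[in_years.to_numpy(dtype=bool) & known.to_numpy(dtype=bool), role]
    counts = sub.value_counts()
    order = sorted(counts.index, key=lambda a: (-counts[a], a))
    return counts.reindex(order)


def _usage_from_counts(counts: pd.Series, year: int, role: str) -> SireUsageStats:
    k = counts.to_numpy()
    n_unique = len(k)
    total = int(k.sum())
    modes, mode_count = [], 0
    vals, freqs = np.unique(k, return_counts=True)
    mode_count = freqs.max()
    modes = vals[freqs == mode_count]
    single = n_unique == 1
    stats_ = SireUsageStats(
        year=year,
        role=role,
        n_unique=n_unique,
        n_progeny=total,
        max=int(k.max()),
        mean=float(k.mean()),
        median=float(np.median(k)),
        mode=int(modes.min()),  # smallest modal value when multimodal
        sd=0.0 if single else float(np.std(k, ddof=1)),
        multimodal=len(modes) > 1,
        single_parent=single,
    )
    # most prolific ceil(q% of parents), ties broken by the deterministic
    # counts order (descending count, ascending identifier)
    for q in (50, 25, 10, 5):
        top = math.ceil(q / 100 * n_unique)
        stats_.pct_top[q] = 100.0 * float(k[:top].sum()) / total
    return stats_


def sire_usage(p: Pedigree, year: int, role: str = "sire") -> SireUsageStats:
    """Usage-concentration statistics for one birth year and parental role.

    ``pct_top[q]`` is the percentage of the year's known-parent registrations
    born to the most prolific ceil(q% of n_unique) parents.  Registrations
    with an unknown parent of the role are excluded from the denominator.
    The standard deviation uses the n-1 denominator; with a single parent it
    is reported as 0 and flagged.
    """
    counts = usage_counts(p, year, role)
    if counts.empty:
        raise ValueError(f"no registrations with known {role} born in {year}")
    return _usage_from_counts(counts, int(year), role)


def block_usage(p: Pedigree, years, role: str = "sire") -> SireUsageStats:
    """Usage statistics pooled over a block of years (progeny per parent
    counted across the whole block)."""
    years = sorted(int(y) for y in years)
    counts = usage_counts(p, years, role)
    if counts.empty:
        raise ValueError(f"no registrations with known {role} born in {years}")
    return _usage_from_counts(counts, years[0], role)


def registrations_by_year(p: Pedigree, year_range: tuple[int, int]) -> pd.Series:
    """Number of registered animals born per year; years with none are 0."""
    y0, y1 = int(year_range[0]), int(year_range[1])
    yr = p.df["birth_year"].dropna().astype(int)
    counts = yr[(yr >= y0) & (yr <= y1)].value_counts()
    return counts.reindex(range(y0, y1 + 1), fill_value=0).sort_index()


def registration_trend(
    p: Pedigree, year_range: tuple[int, int]
) -> tuple[float, float]:
    """OLS slope (animals/year) and its standard error of births on year.

    Years with zero registrations count as data points.  Requires >= 3 years.
    """
    counts = registrations_by_year(p, year_range)
    if len(counts) < 3:
        raise ValueError("registration trend requires at least 3 years")
    res = stats.linregress(counts.index.to_numpy(dtype=float),
                           counts.to_numpy(dtype=float))
    return float(res.slope), float(res.stderr)


def write_usage_table(stats_list: list[SireUsageStats], path, *, sep: str = "\t") -> None:
    """Long-format writer: one row per year per role with all statistics."""
    rows = []
    for s in stats_list:
        rows.append(
            {
                "year": s.year, "role": s.role, "n_unique": s.n_unique,
                "n_progeny": s.n_progeny, "max": s.max, "mean": s.mean,
                "median": s.median, "mode": s.mode, "sd": s.sd,
                "pct_top50": s.pct_top[50], "pct_top25": s.pct_top[25],
                "pct_top10": s.pct_top[10], "pct_top5": s.pct_top[5],
                "multimodal": s.multimodal, "single_parent": s.single_parent,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.6f")
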