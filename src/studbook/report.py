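"""Per-breed and cross-breed report generation.

Composes the whole pipeline — registrations, parent usage, observed/expected
inbreeding, whole-period and 5-year-block trends — into delimited-text tables
plus a machine-readable JSON summary per breed.  Components that cannot be
computed from the available data are emitted as UNDETERMINED with a reason
code, never silently omitted, so sparse registries still yield partial
reports.  For fixed inputs and seed, regeneration is byte-identical on all
tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .demography import (
    GenerationInterval,
    generation_interval,
    registration_trend,
    registrations_by_year,
    sire_usage,
    write_usage_table,
)
from .diversity_trends import (
    BlockSummary,
    TrendEstimate,
    Undetermined,
    block_statistics,
    compare_blocks,
    trend_estimate,
    write_trend_table,
)
from .pedigree_core import Pedigree, read_pedigree, validate_pedigree
from .relatedness import cohort_series, inbreeding_all, stagger_expected, write_cohort_series

__all__ = ["BreedReport", "run_report", "run_cross_breed"]


@dataclass
class BreedReport:
    """Everything a per-breed report contains, before serialisation."""

    breed: str
    window: tuple[int, int]
    registrations: pd.Series
    registration_trend: tuple[float, float] | Undetermined
    usage: dict[str, list]  # role -> list[SireUsageStats]
    series: object  # staggered CohortSeries (or None)
    L: float | Undetermined
    whole_trend: TrendEstimate | Undetermined
    blocks: list[BlockSummary]
    provenance: dict


def _maybe(value):
    if isinstance(value, Undetermined):
        return {"status": "undetermined", "reason": value.reason}
    return value


def _trend_json(t):
    if isinstance(t, Undetermined):
        return _maybe(t)
    return {
        "slope_b": t.slope_b,
        "dF_annual": t.dF_annual,
        "L": t.L,
        "dF_gen": t.dF_gen,
        "Ne": _maybe(t.Ne),
        "window": list(t.window),
        "n_years": t.n_years,
    }


def run_report(
    pedigree,
    out_dir,
    *,
    window: tuple[int, int] | None = None,
    seed: int = 0,
    L_override: float | None = None,
    transform: str = "slope",
    compute_expected: bool = True,
    plots: bool = False,
    source_path=None,
) -> BreedReport:
    """Run the full per-breed analysis and write its tables to ``out_dir``.

    ``pedigree`` is a :class:`Pedigree` or a path to a pedigree file.  The
    analysis window defaults to the span of observed birth years.  Writes
    ``registrations.tsv``, ``usage_sire.tsv``, ``usage_dam.tsv``,
    ``cohort_series.tsv``, ``trend_blocks.tsv`` and ``summary.json`` (plus
    optional plots); returns the in-memory report.
    """
    if not isinstance(pedigree, Pedigree):
        source_path = Path(pedigree)
        pedigree = read_pedigree(source_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    breed_vals = [b for b in pedigree.df["breed"].unique() if b]
    breed = breed_vals[0] if breed_vals else "unknown"

    years = pedigree.df["birth_year"].dropna()
    if window is None:
        if years.empty:
            window = (0, 0)
        else:
            window = (int(years.min()), int(years.max()))

    issues = validate_pedigree(pedigree)

    # registrations
    regs = registrations_by_year(pedigree, window)
    try:
        reg_trend: tuple[float, float] | Undetermined = registration_trend(
            pedigree, window)
    except ValueError:
        reg_trend = Undetermined("insufficient_years")
    regs.rename("n_born").reset_index().rename(columns={"index": "year"}).to_csv(
        out / "registrations.tsv", sep="\t", index=False)

    # usage
    usage: dict[str, list] = {"sire": [], "dam": []}
    for role in ("sire", "dam"):
        for year in regs.index:
            try:
                usage[role].append(sire_usage(pedigree, int(year), role))
            except ValueError:
                continue
        write_usage_table(usage[role], out / f"usage_{role}.tsv")

    # generation interval
    try:
        gi: GenerationInterval | None = generation_interval(pedigree, window)
        L: float | Undetermined = gi.L
    except ValueError:
        gi, L = None, Undetermined("insufficient_data")
    if L_override is not None:
        L = float(L_override)

    # cohort series, trend, blocks
    series = None
    whole: TrendEstimate | Undetermined
    blocks: list[BlockSummary] = []
    if years.empty:
        whole = Undetermined("insufficient_data")
    else:
        F = inbreeding_all(pedigree)
        series = cohort_series(pedigree, window, rng_seed=seed,
                               compute_expected=compute_expected, F=F)
        if isinstance(L, Undetermined):
            whole = Undetermined("insufficient_data")
        else:
            try:
                whole = trend_estimate(series, L, transform=transform)
            except ValueError:
                whole = Undetermined("insufficient_years")
            try:
                blocks = block_statistics(pedigree, series, L, transform=transform)
            except ValueError:
                blocks = []
        staggered = (stagger_expected(series, L)
                     if compute_expected and isinstance(L, float) and L >= 0.5
                     else series)
        write_cohort_series(staggered, out / "cohort_series.tsv")
        series = staggered
    if isinstance(whole, TrendEstimate):
        write_trend_table(whole, blocks, out / "trend_blocks.tsv")

    provenance = {
        "package_version": __version__,
        "seed": seed,
        "input_sha256": (hashlib.sha256(Path(source_path).read_bytes()).hexdigest()
                         if source_path else None),
        "n_records": len(pedigree),
        "n_soft_issues": len(issues),
        "resolution": pedigree.resolution,
    }
    report = BreedReport(
        breed=breed,
        window=window,
        registrations=regs,
        registration_trend=reg_trend,
        usage=usage,
        series=series,
        L=L,
        whole_trend=whole,
        blocks=blocks,
        provenance=provenance,
    )

    summary = {
        "breed": breed,
        "window": list(window),
        "registrations": {
            "total": int(regs.sum()),
            "mean_per_year": float(regs.mean()) if len(regs) else 0.0,
            "trend": (_maybe(reg_trend) if isinstance(reg_trend, Undetermined)
                      else {"slope": reg_trend[0], "se": reg_trend[1]}),
        },
        "generation_interval": _maybe(L),
        "whole_period": _trend_json(whole),
        "blocks": [
            {
                "label": b.label,
                "mean_registrations": b.mean_registrations,
                "included": b.included,
                "trend": _trend_json(b.trend),
            }
            for b in blocks
        ],
        "issues": {"n": len(issues)},
        "provenance": provenance,
    }
    # timestamp lives in the run log, not summary.json, so reruns are
    # byte-identical
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "run.log").write_text(
        f"studbook {__version__} report for {breed} generated "
        f"{datetime.now(timezone.utc).isoformat()}\n"
        f"records={len(pedigree)} soft_issues={len(issues)} seed={seed}\n")

    if plots:
        _make_plots(report, out)
    return report


def _make_plots(report: BreedReport, out: Path) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.series is not None:
        t = report.series.table
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(t.index, t["mean_F"], label="observed inbreeding", color="tab:blue")
        if t["expected_F"].notna().any():
            ax.plot(t.index, t["expected_F"], label="expected inbreeding (staggered)",
                    color="tab:red")
            sd = t["expected_F_sd"]
            if sd.notna().any():
                ax.fill_between(t.index, t["expected_F"] - sd, t["expected_F"] + sd,
                                color="tab:red", alpha=0.2)
        ax.set_xlabel("year of birth")
        ax.set_ylabel("inbreeding coefficient")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "inbreeding.png", dpi=120)
        plt.close(fig)
    if report.blocks:
        labels = [b.label for b in report.blocks]
        vals = [b.trend.dF_gen if isinstance(b.trend, TrendEstimate) else np.nan
                for b in report.blocks]
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.bar(labels, vals, color="tab:blue")
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("dF per generation")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(out / "block_dF.png", dpi=120)
        plt.close(fig)


def run_cross_breed(reports: list[BreedReport], out_dir) -> dict:
    """Cross-breed tables: Ne vs census, per-block mean dF, block ANOVA.

    Only breeds passing the inclusion rule (mean registrations above the
    threshold in every block) enter the block comparison.  Requires at least
    two breed reports; with fewer than two included breeds the ANOVA is
    refused with a reason rather than computed.
    """
    if len(reports) < 2:
        raise ValueError("cross-breed analysis requires >= 2 breed reports")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for r in reports:
        ne = (r.whole_trend.Ne
              if isinstance(r.whole_trend, TrendEstimate) else r.whole_trend)
        rows.append(
            {
                "breed": r.breed,
                "mean_registrations": float(r.registrations.mean()),
                "Ne": ne if isinstance(ne, float) else np.nan,
                "included": bool(r.blocks) and all(b.included for b in r.blocks),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "ne_vs_registrations.tsv", sep="\t", index=False,
                 float_format="%.4f")

    det = table.dropna(subset=["Ne"])
    corr = {"status": "undetermined", "reason": "insufficient_data"}
    if len(det) >= 3:
        r_val, p_val = stats.pearsonr(np.log(det["mean_registrations"]),
                                      np.log(det["Ne"]))
        corr = {"r": float(r_val), "p": float(p_val), "n": int(len(det))}

    included = [r for r, row in zip(reports, rows) if row["included"]]
    if not included:
        raise ValueError("no breed passes the inclusion rule "
                         f"(>50 mean registrations/year in every block)")

    block_labels = [b.label for b in included[0].blocks]
    dF = pd.DataFrame(
        {
            lab: [
                (b.trend.dF_gen if isinstance(b.trend, TrendEstimate) else np.nan)
                for r in included
                for b in [dict((bb.label, bb) for bb in r.blocks)[lab]]
            ]
            for lab in block_labels
        },
        index=[r.breed for r in included],
    )
    summary_rows = pd.DataFrame(
        {
            "block": block_labels,
            "mean_dF_gen": [dF[lab].mean() for lab in block_labels],
            "se_dF_gen": [dF[lab].std(ddof=1) / np.sqrt(dF[lab].notna().sum())
                          for lab in block_labels],
            "n_breeds": [int(dF[lab].notna().sum()) for lab in block_labels],
        }
    )
    summary_rows.to_csv(out / "block_mean_dF.tsv", sep="\t", index=False,
                        float_format="%.6f")

    if len(included) < 2:
        anova = {"status": "undetermined", "reason": "insufficient_data"}
    else:
        try:
            f_stat, p_val = compare_blocks(dF)
            anova = {"F": f_stat, "p": p_val}
        except ValueError as e:
            anova = {"status": "undetermined", "reason": "insufficient_data",
                     "detail": str(e)}

    result = {"ne_census_correlation": corr, "block_anova": anova,
              "n_reports": len(reports), "n_included": len(included)}
    (out / "cross_summary.json").write_text(
        json.dumps(result, indent=2, sort_keys=True))
    return result
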