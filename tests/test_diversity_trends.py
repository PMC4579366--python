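import math

import numpy as np
import pandas as pd
import pytest

from conftest import build_pedigree
from studbook.diversity_trends import (
    TrendEstimate,
    Undetermined,
    annual_inbreeding_rate,
    block_statistics,
    compare_blocks,
    default_blocks,
    delta_f_per_generation,
    effective_population_size,
    trend_estimate,
)
from studbook.relatedness import CohortSeries


def series_from_rate(delta, years=(1980, 2014), n_born=100, f0=0.0):
    """CohortSeries whose mean F follows 1-F_t = (1-f0) (1-delta)^(t-t0).

    ``delta`` may be a mapping year -> per-annum rate for piecewise models.
    """
    y0, y1 = years
    rows, oneF = [], 1.0 - f0
    for t in range(y0, y1 + 1):
        d = delta[t] if isinstance(delta, dict) else delta
        if t > y0:
            oneF *= 1.0 - d
        rows.append((t, n_born, 1.0 - oneF, np.nan, np.nan, 0, "exhaustive",
                     False))
    table = pd.DataFrame(rows, columns=["year", "n_born", "mean_F",
                                        "expected_F", "expected_F_sd",
                                        "n_pairs", "regime", "beyond_window"]
                         ).set_index("year")
    return CohortSeries(table=table, window=years)


class TestAnnualRate:
    def test_geometric_decline_recovered_exactly(self):
        # ln(1-F_t) is exactly linear with slope ln(1-delta)
        series = series_from_rate(0.002)
        slope, rate = annual_inbreeding_rate(series)
        assert slope == pytest.approx(math.log(1 - 0.002), abs=1e-12)
        assert rate == pytest.approx(-math.log(1 - 0.002), abs=1e-12)
        # the exp transform returns delta itself
        _, rate_exp = annual_inbreeding_rate(series, transform="exp")
        assert rate_exp == pytest.approx(0.002, abs=1e-12)

    def test_constant_f_zero_rate(self):
        series = series_from_rate(0.0, f0=0.05)
        slope, rate = annual_inbreeding_rate(series)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert rate == pytest.approx(0.0, abs=1e-12)

    def test_declining_f_negative_rate(self):
        series = series_from_rate(-0.003, f0=0.2)
        _, rate = annual_inbreeding_rate(series)
        assert rate < 0

    def test_requires_three_years(self):
        series = series_from_rate(0.002, years=(1980, 1981))
        with pytest.raises(ValueError, match=">= 3 years"):
            annual_inbreeding_rate(series)

    def test_degenerate_f_of_one(self):
        series = series_from_rate(0.0, f0=1.0)
        with pytest.raises(ValueError, match="mean F >= 1"):
            annual_inbreeding_rate(series)

    def test_empty_years_omitted(self):
        series = series_from_rate(0.002)
        series.table.loc[1990:1995, "n_born"] = 0
        slope, _ = annual_inbreeding_rate(series)
        assert slope == pytest.approx(math.log(1 - 0.002), abs=1e-12)


class TestPerGenerationAndNe:
    def test_scaling_by_generation_interval(self):
        assert delta_f_per_generation(0.0025, 4.0) == pytest.approx(0.01)
        assert delta_f_per_generation(0.0, 3.3) == 0.0
        assert delta_f_per_generation(-0.001, 3.5) == pytest.approx(-0.0035)

    def test_sustainability_threshold(self):
        assert effective_population_size(0.01) == 50.0

    def test_worked_example_rate(self):
        assert effective_population_size(0.125) == 4.0

    def test_negative_and_zero_rates_undetermined(self):
        ne = effective_population_size(-0.003)
        assert isinstance(ne, Undetermined) and ne.reason == "negative_rate"
        ne = effective_population_size(0.0)
        assert isinstance(ne, Undetermined) and ne.reason == "zero_rate"

    def test_exact_inversion_across_grid(self):
        for df in np.linspace(1e-4, 0.5, 200):
            ne = effective_population_size(df)
            assert 2.0 * df * ne == pytest.approx(1.0, abs=1e-12)

    def test_sign_coherence(self):
        for delta in (0.004, -0.004):
            series = series_from_rate(delta, f0=0.1)
            t = trend_estimate(series, 4.0)
            assert np.sign(t.dF_annual) == np.sign(t.dF_gen) == np.sign(delta)


class TestBlocks:
    def _pedigree_with_counts(self, per_year, years=(1980, 2014)):
        rows, k = [], 0
        for y in range(years[0], years[1] + 1):
            n = per_year(y) if callable(per_year) else per_year
            for _ in range(n):
                rows.append((f"A{k:05d}", "", "", "unknown", y))
                k += 1
        return build_pedigree(rows)

    def test_default_blocks_partition(self):
        blocks = default_blocks()
        assert len(blocks) == 7
        assert blocks[0] == (1980, 1984) and blocks[-1] == (2010, 2014)

    def test_stationary_rate_equal_across_blocks(self):
        ped = self._pedigree_with_counts(60)
        series = series_from_rate(0.003)
        out = block_statistics(ped, series, L=4.0)
        vals = [b.trend.dF_gen for b in out]
        assert all(v == pytest.approx(vals[0], abs=1e-10) for v in vals)
        assert all(b.included for b in out)

    def test_rate_halved_after_2000(self):
        ped = self._pedigree_with_counts(60)
        delta = {y: (0.004 if y < 2000 else 0.002) for y in range(1980, 2015)}
        series = series_from_rate(delta)
        out = block_statistics(ped, series, L=4.0)
        early = out[0].trend.dF_gen
        late = out[-1].trend.dF_gen
        # ratio ln(0.998)/ln(0.996) differs from 1/2 only at second order
        assert late == pytest.approx(early / 2, rel=5e-3)

    def test_small_census_block_excluded(self):
        ped = self._pedigree_with_counts(lambda y: 40 if y < 1985 else 60)
        series = series_from_rate(0.003)
        out = block_statistics(ped, series, L=4.0)
        assert not out[0].included
        assert all(b.included for b in out[1:])

    def test_sparse_block_undetermined_not_error(self):
        ped = self._pedigree_with_counts(lambda y: 10 if y >= 1990 else 0)
        series = series_from_rate(0.003)
        series.table.loc[1980:1989, ["n_born", "mean_F"]] = (0, np.nan)
        out = block_statistics(ped, series, L=4.0)
        assert isinstance(out[0].trend, Undetermined)
        assert out[0].trend.reason == "insufficient_years"
        assert isinstance(out[-1].trend, TrendEstimate)


class TestCompareBlocks:
    def test_identical_means_high_p(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0.01, 0.002, size=20)
        table = pd.DataFrame({f"b{i}": base for i in range(7)})
        f, p = compare_blocks(table)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_separated_means_significant(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({
            "b0": rng.normal(0.02, 0.001, size=20),
            "b1": rng.normal(0.002, 0.001, size=20),
        })
        _, p = compare_blocks(table)
        assert p < 0.001

    def test_degenerate_zero_variance(self):
        table = pd.DataFrame({"b0": [0.01] * 5, "b1": [0.02] * 5})
        with pytest.raises(ValueError, match="degenerate"):
            compare_blocks(table)

    def test_requires_two_blocks(self):
        with pytest.raises(ValueError, match=">= 2 blocks"):
            compare_blocks(pd.DataFrame({"b0": [0.01, 0.02]}))
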