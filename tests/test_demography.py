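import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_pedigree
from studbook.demography import (
    generation_interval,
    registration_trend,
    registrations_by_year,
    sire_usage,
)
from studbook.pedigree_core import MISSING, Pedigree
import pandas as pd


def pedigree_from_sire_counts(counts, year=1990):
    """One-year pedigree where sire i has counts[i] progeny."""
    rows = []
    for i in range(len(counts)):
        rows.append((f"S{i:02d}", "", "", "male", 1980))
    rows.append(("D", "", "", "female", 1980))
    k = 0
    for i, c in enumerate(counts):
        for _ in range(c):
            rows.append((f"C{k:04d}", f"S{i:02d}", "D", "unknown", year))
            k += 1
    return build_pedigree(rows)


class TestSireUsage:
    def test_hand_computed_statistics(self):
        ped = pedigree_from_sire_counts([10, 5, 3, 2])
        s = sire_usage(ped, 1990, "sire")
        assert s.n_unique == 4
        assert s.max == 10
        assert s.mean == 5.0
        assert s.median == 4.0
        assert s.mode == 2  # all counts distinct: smallest of the modal set
        assert s.multimodal
        assert s.sd == pytest.approx(math.sqrt(38 / 3))
        assert s.pct_top[50] == pytest.approx(75.0)   # (10+5)/20
        assert s.pct_top[25] == pytest.approx(50.0)   # top 1 of 4
        assert s.pct_top[10] == pytest.approx(50.0)
        assert s.pct_top[5] == pytest.approx(50.0)

    def test_single_sire(self):
        ped = pedigree_from_sire_counts([7])
        s = sire_usage(ped, 1990, "sire")
        assert all(s.pct_top[q] == 100.0 for q in (50, 25, 10, 5))
        assert s.sd == 0.0 and s.single_parent

    def test_uniform_usage(self):
        ped = pedigree_from_sire_counts([1, 1, 1, 1])
        s = sire_usage(ped, 1990, "sire")
        assert s.pct_top[50] == pytest.approx(50.0)
        assert s.mode == 1 and s.sd == 0.0

    def test_no_known_parent_errors(self):
        ped = build_pedigree([("A", "", "", "male", 1990)])
        with pytest.raises(ValueError, match="known sire"):
            sire_usage(ped, 1990, "sire")

    def test_dam_role(self):
        ped = pedigree_from_sire_counts([3, 1])
        s = sire_usage(ped, 1990, "dam")
        assert s.n_unique == 1 and s.n_progeny == 4

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=25), min_size=1,
                    max_size=12))
    def test_concentration_invariants(self, counts):
        ped = pedigree_from_sire_counts(counts)
        s = sire_usage(ped, 1990, "sire")
        # monotone as the top fraction shrinks
        assert s.pct_top[50] >= s.pct_top[25] >= s.pct_top[10] >= s.pct_top[5]
        # the top half always covers at least half the registrations
        assert s.pct_top[50] >= 50.0 - 1e-9
        # mean x unique == known-parent registrations
        assert s.n_unique * s.mean == pytest.approx(sum(counts))


class TestGenerationInterval:
    def test_single_lineage(self):
        rows = [("A", "", "", "male", 1980), ("Am", "", "", "female", 1980),
                ("B", "A", "Am", "male", 1984), ("Bm", "", "", "female", 1984),
                ("C", "B", "Bm", "male", 1988)]
        gi = generation_interval(build_pedigree(rows), (1980, 1990))
        # only B (born 1984) is breeding progeny with dated parents;
        # only C's parents count for 1988 if C itself bred - it did not
        assert gi.yearly.to_dict() == {1984: 4.0}
        assert gi.L == 4.0

    def test_unweighted_mean_across_years(self):
        rows = [("S1", "", "", "male", 1980), ("D1", "", "", "female", 1982),
                ("S2", "", "", "male", 1980), ("D2", "", "", "female", 1980),
                # born 1983, parental ages {3.0, 1.0} -> mean 2.0
                ("B1", "S1", "D1", "male", 1983),
                # born 1986, parental ages {6.0, 6.0} -> mean 6.0
                ("B2", "S2", "D2", "female", 1986),
                ("Z", "B1", "B2", "male", 1990)]
        gi = generation_interval(build_pedigree(rows), (1980, 1990))
        assert gi.yearly.to_dict() == {1983: 2.0, 1986: 6.0}
        assert gi.L == 4.0

    def test_row_order_invariance(self):
        rows = [("S1", "", "", "male", 1980), ("D1", "", "", "female", 1982),
                ("B1", "S1", "D1", "male", 1983), ("D2", "", "", "female", 1984),
                ("C1", "B1", "D2", "male", 1988)]
        ped = build_pedigree(rows)
        shuffled = Pedigree(
            df=ped.df.sample(frac=1, random_state=5).reset_index(drop=True),
            resolution="year")
        a = generation_interval(ped, (1980, 1990))
        b = generation_interval(shuffled, (1980, 1990))
        assert a.L == b.L
        assert a.yearly.to_dict() == b.yearly.to_dict()

    def test_no_breeding_progeny_errors(self, trio_csv):
        from studbook.pedigree_core import read_pedigree

        with pytest.raises(ValueError, match="undeterminable"):
            generation_interval(read_pedigree(trio_csv), (1980, 1990))

    def test_chronology_violations_excluded(self):
        rows = [("S", "", "", "male", 1984), ("D", "", "", "female", 1980),
                ("B", "S", "D", "male", 1984),  # sire age 0: excluded
                ("D2", "", "", "female", 1984), ("C", "B", "D2", "male", 1988)]
        gi = generation_interval(build_pedigree(rows), (1980, 1990))
        # only the dam side of B (age 4) survives for 1984; C never bred
        assert gi.yearly.to_dict() == {1984: 4.0}

    def test_fixed_parental_age_simulator_recovers_age_exactly(self):
        from studbook.synthetic_pedigree import SimConfig, simulate

        ped, truth = simulate(SimConfig(years=(1980, 1999), n_sires=8,
                                        n_dams=10, litter_mean=4.0, seed=5))
        gi = generation_interval(ped, (1984, 1999), resolution="year")
        assert gi.L == truth.expected_L == 4.0


class TestRegistrationTrend:
    def test_exact_linear_counts(self):
        rows = []
        k = 0
        for j, year in enumerate(range(1990, 1995)):
            for _ in range(100 + 10 * j):
                rows.append((f"A{k:05d}", "", "", "unknown", year))
                k += 1
        slope, se = registration_trend(build_pedigree(rows), (1990, 1994))
        assert slope == pytest.approx(10.0, abs=1e-9)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_constant_counts_zero_slope(self):
        rows = [(f"A{k}", "", "", "unknown", 1990 + k % 4) for k in range(40)]
        slope, _ = registration_trend(build_pedigree(rows), (1990, 1993))
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_zero_years_counted_as_data(self):
        rows = [("A", "", "", "unknown", 1990), ("B", "", "", "unknown", 1994)]
        counts = registrations_by_year(build_pedigree(rows), (1990, 1994))
        assert list(counts) == [1, 0, 0, 0, 1]

    def test_too_few_years_errors(self):
        rows = [("A", "", "", "unknown", 1990)]
        with pytest.raises(ValueError, match="3 years"):
            registration_trend(build_pedigree(rows), (1990, 1991))
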