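import numpy as np
import pandas as pd
import pytest

from studbook.pedigree_core import MISSING, Pedigree


def build_pedigree(rows, resolution="year"):
    """Construct a validated Pedigree from (id, sire, dam, sex, year) tuples.

    ``year`` may be None; sire/dam may be "" for missing.
    """
    ids, sires, dams, sexes, years = [], [], [], [], []
    for r in rows:
        aid, sire, dam, sex, year = r
        ids.append(aid)
        sires.append(sire or MISSING)
        dams.append(dam or MISSING)
        sexes.append(sex)
        years.append(year if year is not None else pd.NA)
    df = pd.DataFrame(
        {
            "id": pd.array(ids, dtype=object),
            "sire": pd.array(sires, dtype=object),
            "dam": pd.array(dams, dtype=object),
            "sex": pd.array(sexes, dtype=object),
            "birth_date": pd.to_datetime([pd.NaT] * len(ids)),
            "birth_year": pd.array(years, dtype="Int64"),
            "breed": pd.array(["test"] * len(ids), dtype=object),
        }
    )
    ped = Pedigree(df=df, resolution=resolution)
    ped.topological_row_order()
    return ped


def half_sib_pedigree(n_dams=2, mate_pair=True):
    """The textbook popular-sire pedigree: one founder sire S over unrelated
    founder dams; optionally mates the first two half-sib progeny."""
    rows = [("S", "", "", "male", 1980)]
    for i in range(n_dams):
        rows.append((f"D{i}", "", "", "female", 1980))
    for i in range(n_dams):
        sex = "male" if i == 0 else "female"
        rows.append((f"P{i}", "S", f"D{i}", sex, 1984))
    if mate_pair:
        rows.append(("X", "P0", "P1", "male", 1988))
    return build_pedigree(rows)


@pytest.fixture
def trio_csv(tmp_path):
    path = tmp_path / "trio.csv"
    path.write_text(
        "id,sire,dam,sex,birth_date,breed\n"
        "A,,,m,1980,Demo\n"
        "B,,,f,1980,Demo\n"
        "C,A,B,m,1984,Demo\n"
    )
    return path


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated registry shared across read-only tests."""
    from studbook.synthetic_pedigree import SimConfig, simulate

    cfg = SimConfig(years=(1970, 2014), n_sires=15, n_dams=20,
                    litter_mean=4.0, sire_skew=0.3, seed=42)
    ped, truth = simulate(cfg)
    return ped, truth, cfg


def full_sib_cohort(n, year=1990):
    """Pedigree whose ``year`` cohort is n full siblings (pairwise kinship
    exactly 1/4)."""
    rows = [("SIRE", "", "", "male", 1980), ("DAM", "", "", "female", 1980)]
    for i in range(n):
        rows.append((f"C{i:05d}", "SIRE", "DAM",
                     "male" if i % 2 else "female", year))
    return build_pedigree(rows)
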