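"""Independent oracles for relatedness computations.

Both oracles deliberately avoid the package's tabular machinery: the naive
kinship follows the textbook recursion on identifiers, and the gene dropper
estimates identity-by-descent by Monte Carlo transmission of distinct
founder alleles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from studbook.pedigree_core import MISSING, Pedigree


class NaiveKinship:
    """Memoised textbook recursion f(x,y) = 1/2 [f(sire_x,y) + f(dam_x,y)].

    Recursion always expands the individual with the greater pedigree depth,
    which is never an ancestor of the other; f through an unknown parent is
    0 and f(x,x) = 1/2 (1 + f(sire_x, dam_x)).
    """

    def __init__(self, ped: Pedigree):
        df = ped.df
        self.sire = dict(zip(df["id"], df["sire"]))
        self.dam = dict(zip(df["id"], df["dam"]))
        self._depth: dict[str, int] = {}
        self._memo: dict[tuple[str, str], float] = {}

    def depth(self, x: str) -> int:
        if x not in self._depth:
            s, d = self.sire[x], self.dam[x]
            self._depth[x] = 1 + max(
                self.depth(s) if s != MISSING else 0,
                self.depth(d) if d != MISSING else 0,
            )
        return self._depth[x]

    def F(self, x: str) -> float:
        s, d = self.sire[x], self.dam[x]
        if s == MISSING or d == MISSING:
            return 0.0
        return self.f(s, d)

    def f(self, x: str, y: str) -> float:
        if x == MISSING or y == MISSING:
            return 0.0
        key = (x, y) if x <= y else (y, x)
        if key in self._memo:
            return self._memo[key]
        if x == y:
            val = 0.5 * (1.0 + self.F(x))
        else:
            if self.depth(x) < self.depth(y):
                x, y = y, x
            val = 0.5 * (self.f(self.sire[x], y) + self.f(self.dam[x], y))
        self._memo[key] = val
        return val


def gene_drop_inbreeding(
    ped: Pedigree, n_drops: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte Carlo IBD probability per animal (aligned with ped.df rows).

    Founders receive two unique allele labels; every transmission picks one
    of the parent's two alleles uniformly.  The estimate for each animal is
    the fraction of drops in which its two alleles are identical by descent.
    An unknown parent contributes a private allele, so animals with missing
    parents score exactly 0.
    """
    sire, dam = ped.parent_indices()
    order = ped.topological_row_order()
    n = len(ped)
    alleles = np.empty((n, 2, n_drops), dtype=np.int32)
    for i in order:
        for slot, parent in ((0, sire[i]), (1, dam[i])):
            if parent < 0:
                alleles[i, slot, :] = 2 * i + slot  # private founder allele
            else:
                pick = rng.integers(0, 2, size=n_drops)
                alleles[i, slot, :] = alleles[parent, pick, np.arange(n_drops)]
    return (alleles[:, 0, :] == alleles[:, 1, :]).mean(axis=1)


def random_pedigree(
    rng: np.random.Generator,
    n: int,
    *,
    founder_frac: float = 0.2,
    single_parent_frac: float = 0.1,
    years: bool = True,
) -> Pedigree:
    """Random valid pedigree of ``n`` animals for oracle comparisons.

    Non-founders draw their sire uniformly from earlier males and their dam
    from earlier females; a fraction keep only one known parent.  Sexes are
    fair coins (forced for the first two animals so parents always exist).
    """
    ids = [f"R{i:04d}" for i in range(n)]
    sex = ["male", "female"] + [
        ("male" if rng.random() < 0.5 else "female") for _ in range(n - 2)
    ]
    sire = [MISSING] * n
    dam = [MISSING] * n
    year = [1980] * n
    for i in range(n):
        if i >= 2:
            year[i] = 1980 + int(i / n * 20)
            if rng.random() >= founder_frac:
                males = [j for j in range(i) if sex[j] == "male"]
                females = [j for j in range(i) if sex[j] == "female"]
                s = ids[males[rng.integers(len(males))]] if males else MISSING
                d = ids[females[rng.integers(len(females))]] if females else MISSING
                if rng.random() < single_parent_frac:
                    if rng.random() < 0.5:
                        s = MISSING
                    else:
                        d = MISSING
                sire[i], dam[i] = s, d
    df = pd.DataFrame(
        {
            "id": pd.array(ids, dtype=object),
            "sire": pd.array(sire, dtype=object),
            "dam": pd.array(dam, dtype=object),
            "sex": pd.array(sex, dtype=object),
            "birth_date": pd.to_datetime([pd.NaT] * n),
            "birth_year": pd.array(year if years else [pd.NA] * n, dtype="Int64"),
            "breed": pd.array(["oracle"] * n, dtype=object),
        }
    )
    ped = Pedigree(df=df, resolution="year")
    ped.topological_row_order()
    return ped
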