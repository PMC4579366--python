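"""Pedigree data model, delimited-text I/O, structural validation and processing order.

A pedigree ("studbook") is one row per registered animal: an opaque string
identifier, sire and dam identifiers (possibly missing), sex, birth date and a
breed label.  All downstream computation (inbreeding, kinship, demography)
works off the validated :class:`Pedigree` container built here.

Conventions
-----------
* Missing parents are encoded in files as an empty field, ``0`` or ``NA``;
  all three map to *missing* on read.  The writer emits an empty field.
* A *founder* is an animal with **both** parents missing.  Animals with
  exactly one recorded parent are not founders; the unknown side simply
  contributes no co-ancestry.
* Identifiers are compared by exact string match after trimming surrounding
  whitespace.  No case folding is applied (registry names can be
  case-significant).
* Birth dates are ISO ``YYYY-MM-DD`` dates or bare 4-digit years.  If any
  record carries a year-only date the whole pedigree is flagged as
  year-resolution and age-based statistics are computed on integer year
  differences.  Records with no date at all (typically founder stubs) are
  permitted and are excluded from age-based statistics.
"""

from __future__ import annotations

import heapq
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "PedigreeError",
    "Issue",
    "Pedigree",
    "read_pedigree",
    "pedigree_from_frame",
    "write_pedigree",
    "validate_pedigree",
    "topological_order",
]

#: canonical in-memory missing-parent marker (the empty string)
MISSING = ""

_MISSING_TOKENS = {"", "0", "NA"}

_SEX_MAP = {
    "m": "male",
    "male": "male",
    "dog": "male",
    "f": "female",
    "female": "female",
    "bitch": "female",
    "": "unknown",
    "u": "unknown",
    "unknown": "unknown",
}

_YEAR_RE = re.compile(r"^\d{4}$")
_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


class PedigreeError(ValueError):
    """Hard structural error in a pedigree file (duplicate id, cycle, bad date)."""


@dataclass(frozen=True)
class Issue:
    """A soft data-quality issue found by :func:`validate_pedigree`.

    Codes: ``sex_conflict`` (an id used both as sire and dam, or used in a
    role conflicting with its recorded sex), ``chronology`` (offspring born on
    or before a parent's birth date) and ``parent_age`` (parental age at birth
    above a plausibility maximum).
    """

    code: str
    animal_id: str
    message: str


@dataclass
class Pedigree:
    """A validated studbook.

    ``df`` holds one row per animal in input order with columns ``id``,
    ``sire``, ``dam`` (missing encoded as ``""``), ``sex``
    (male/female/unknown), ``birth_date`` (datetime64, NaT when unknown),
    ``birth_year`` (nullable integer) and ``breed``.
    """

    df: pd.DataFrame
    resolution: Literal["date", "year"] = "date"

    _row_of: dict | None = field(default=None, repr=False, compare=False)
    _topo: list | None = field(default=None, repr=False, compare=False)
    _parent_idx: tuple | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> pd.Series:
        return self.df["id"]

    def row_of(self, animal_id: str) -> int:
        """Input-order row index of ``animal_id`` (raises KeyError if absent)."""
        if self._row_of is None:
            self._row_of = {a: i for i, a in enumerate(self.df["id"])}
        return self._row_of[animal_id]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer sire/dam row indices aligned with ``df`` rows; -1 = missing."""
        if self._parent_idx is None:
            if self._row_of is None:
                self.row_of(self.df["id"].iloc[0])
            lut = self._row_of
            sire = np.array(
                [lut[s] if s != MISSING else -1 for s in self.df["sire"]],
                dtype=np.int64,
            )
            dam = np.array(
                [lut[d] if d != MISSING else -1 for d in self.df["dam"]],
                dtype=np.int64,
            )
            self._parent_idx = (sire, dam)
        return self._parent_idx

    def is_founder(self) -> np.ndarray:
        sire, dam = self.parent_indices()
        return (sire < 0) & (dam < 0)

    def topological_row_order(self) -> np.ndarray:
        """Row indices in parent-before-offspring order (stable by input row)."""
        if self._topo is None:
            self._topo = _kahn_order(*self.parent_indices())
        return np.asarray(self._topo, dtype=np.int64)


def _parse_birth(value: str, row: int) -> tuple[pd.Timestamp, object, bool]:
    """Return (birth_date, birth_year, year_only) for one raw field."""
    v = value.strip()
    if v == "" or v in {"NA", "0"}:
        return pd.NaT, pd.NA, False
    if _YEAR_RE.match(v):
        return pd.NaT, int(v), True
    if _DATE_RE.match(v):
        ts = pd.to_datetime(v, format="%Y-%m-%d", errors="coerce")
        if ts is not pd.NaT:
            return ts, ts.year, False
    raise PedigreeError(f"row {row}: unparseable birth date {value!r} "
                        "(expected YYYY-MM-DD or a 4-digit year)")


def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_pedigree(path, *, sep: str | None = None) -> Pedigree:
    """Read a delimited pedigree file into a validated :class:`Pedigree`.

    The file must have a header row with at least ``id``, ``sire`` and ``dam``
    columns; ``sex``, ``birth_date`` and ``breed`` are optional.  The
    delimiter is auto-detected (comma or tab) unless ``sep`` is given.

    Parents that are referenced but have no row of their own are materialised
    as founder stubs (missing parents, no birth date, sex inferred from the
    role they were seen in).

    Raises
    ------
    PedigreeError
        On duplicate identifiers, unparseable dates, self-parentage or
        ancestry cycles.
    """
    path = Path(path)
    if sep is None:
        sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [c.strip().lower() for c in raw.columns]
    for col in ("id", "sire", "dam"):
        if col not in raw.columns:
            raise PedigreeError(f"missing required column {col!r}")
    return _build(raw)


def pedigree_from_frame(frame: pd.DataFrame) -> Pedigree:
    """Build a validated Pedigree from an in-memory string-typed frame."""
    raw = frame.copy()
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    return _build(raw.astype(str) if raw.dtypes.ne(object).any() else raw)


def _build(raw: pd.DataFrame) -> Pedigree:
    n = len(raw)
    ids = raw["id"].astype(str).str.strip()
    if (ids == "").any():
        row = int(np.argmax((ids == "").to_numpy()))
        raise PedigreeError(f"row {row + 2}: empty animal identifier")
    dup = ids[ids.duplicated()]
    if len(dup):
        raise PedigreeError(f"duplicate animal identifier {dup.iloc[0]!r}")

    def clean_parent(col: str) -> pd.Series:
        if col not in raw.columns:
            return pd.Series([MISSING] * n, dtype=object)
        s = raw[col].astype(str).str.strip()
        return s.where(~s.isin(_MISSING_TOKENS), MISSING)

    sire = clean_parent("sire")
    dam = clean_parent("dam")
    for parent, label in ((sire, "sire"), (dam, "dam")):
        self_par = (parent != MISSING) & (parent.to_numpy() == ids.to_numpy())
        if self_par.any():
            bad = ids[self_par].iloc[0]
            raise PedigreeError(f"animal {bad!r} is recorded as its own {label}")

    if "sex" in raw.columns:
        sex = raw["sex"].astype(str).str.strip().str.lower().map(
            lambda v: _SEX_MAP.get(v, "unknown"))
    else:
        sex = pd.Series(["unknown"] * n, dtype=object)

    dates, years, year_only_any = [], [], False
    if "birth_date" in raw.columns:
        for i, v in enumerate(raw["birth_date"].astype(str)):
            ts, yr, year_only = _parse_birth(v, i + 2)  # +2: header + 1-based
            dates.append(ts)
            years.append(yr)
            year_only_any = year_only_any or year_only
    else:
        dates = [pd.NaT] * n
        years = [pd.NA] * n

    breed = (raw["breed"].astype(str).str.strip()
             if "breed" in raw.columns else pd.Series([""] * n, dtype=object))

    df = pd.DataFrame(
        {
            "id": ids.to_numpy(dtype=object),
            "sire": sire.to_numpy(dtype=object),
            "dam": dam.to_numpy(dtype=object),
            "sex": sex.to_numpy(dtype=object),
            "birth_date": pd.to_datetime(pd.Series(dates)),
            "birth_year": pd.array(years, dtype="Int64"),
            "breed": breed.to_numpy(dtype=object),
        }
    )

    # founder stubs for referenced-but-unlisted parents
    known = set(df["id"])
    stubs = []
    seen_stub: dict[str, str] = {}
    for col, stub_sex in (("sire", "male"), ("dam", "female")):
        for pid in df[col]:
            if pid != MISSING and pid not in known and pid not in seen_stub:
                seen_stub[pid] = stub_sex
    for pid, stub_sex in seen_stub.items():
        stubs.append(
            {"id": pid, "sire": MISSING, "dam": MISSING, "sex": stub_sex,
             "birth_date": pd.NaT, "birth_year": pd.NA, "breed": ""})
    if stubs:
        df = pd.concat([df, pd.DataFrame(stubs).astype(df.dtypes.to_dict())],
                       ignore_index=True)

    ped = Pedigree(df=df, resolution="year" if year_only_any else "date")
    ped.topological_row_order()  # raises with a named cycle if cyclic
    return ped


def _kahn_order(sire: np.ndarray, dam: np.ndarray) -> list[int]:
    """Parents-first order via Kahn's algorithm, ties broken by input row."""
    n = len(sire)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    heap = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    order: list[int] = []
    while heap:
        i = heapq.heappop(heap)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    if len(order) < n:
        raise PedigreeError(
            "pedigree contains an ancestry cycle: " + _describe_cycle(sire, dam))
    return order


def _describe_cycle(sire: np.ndarray, dam: np.ndarray) -> str:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(len(sire)))
    for i in range(len(sire)):
        for p in (sire[i], dam[i]):
            if p >= 0:
                g.add_edge(p, i)
    cycle = nx.find_cycle(g)
    return " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]} (row indices)"


def topological_order(p: Pedigree) -> list[str]:
    """Animal identifiers in an order where every parent precedes its offspring.

    Deterministic for a fixed input: ties are broken by input row order.
    """
    rows = p.topological_row_order()
    ids = p.df["id"].to_numpy()
    return [ids[i] for i in rows]


def validate_pedigree(p: Pedigree, *, max_parent_age: float = 20.0) -> list[Issue]:
    """Scan for soft data-quality issues without mutating the pedigree.

    Chronology problems are reported, not raised: real registry data contain
    them, and affected records are excluded only from age-based statistics,
    never from relatedness computation.
    """
    issues: list[Issue] = []
    df = p.df
    used_as_sire = set(df.loc[df["sire"] != MISSING, "sire"])
    used_as_dam = set(df.loc[df["dam"] != MISSING, "dam"])
    for aid in sorted(used_as_sire & used_as_dam):
        issues.append(Issue("sex_conflict", aid,
                            f"{aid!r} appears both as a sire and as a dam"))
    sex_lut = dict(zip(df["id"], df["sex"]))
    for aid in sorted(used_as_sire):
        if sex_lut.get(aid) == "female":
            issues.append(Issue("sex_conflict", aid,
                                f"{aid!r} used as sire but recorded female"))
    for aid in sorted(used_as_dam):
        if sex_lut.get(aid) == "male":
            issues.append(Issue("sex_conflict", aid,
                                f"{aid!r} used as dam but recorded male"))

    ages = parental_ages(p)
    for _, r in ages.iterrows():
        if r["age_years"] <= 0:
            issues.append(Issue(
                "chronology", r["offspring"],
                f"{r['offspring']!r} born on/before its {r['role']} {r['parent']!r}"))
        elif r["age_years"] > max_parent_age:
            issues.append(Issue(
                "parent_age", r["offspring"],
                f"{r['role']} {r['parent']!r} aged {r['age_years']:.1f} y at birth "
                f"of {r['offspring']!r} (max {max_parent_age})"))
    return issues


def parental_ages(p: Pedigree, resolution: str | None = None) -> pd.DataFrame:
    """Long table of parental ages at each birth where both dates are known.

    Columns: offspring, parent, role (sire/dam), offspring_year, age_years.
    At date resolution ages are day differences / 365.25; at year resolution
    they are integer year differences.  ``resolution`` overrides the
    pedigree's own flag (e.g. to force year-resolution ages on dated data).
    """
    df = p.df
    out = []
    lut_date = dict(zip(df["id"], df["birth_date"]))
    lut_year = dict(zip(df["id"], df["birth_year"]))
    use_dates = (resolution or p.resolution) == "date"
    for role in ("sire", "dam"):
        sub = df.loc[df[role] != MISSING, ["id", role, "birth_date", "birth_year"]]
        for oid, pid, odate, oyear in sub.itertuples(index=False):
            if use_dates:
                pdate = lut_date.get(pid, pd.NaT)
                if pd.isna(odate) or pd.isna(pdate):
                    continue
                age = (odate - pdate).days / 365.25
            else:
                pyear = lut_year.get(pid, pd.NA)
                if pd.isna(oyear) or pd.isna(pyear):
                    continue
                age = float(oyear - pyear)
            out.append((oid, pid, role, oyear, age))
    return pd.DataFrame(out, columns=["offspring", "parent", "role",
                                      "offspring_year", "age_years"])


def write_pedigree(p: Pedigree, path, *, sep: str = ",") -> None:
    """Write a pedigree back to delimited text, topologically ordered.

    Round-trips: reading the written file reproduces the record collection
    field for field (row order may change to the topological order).
    """
    rows = p.topological_row_order()
    df = p.df.iloc[rows]
    out = pd.DataFrame(
        {
            "id": df["id"],
            "sire": df["sire"],
            "dam": df["dam"],
            "sex": df["sex"],
            "birth_date": [
                d.strftime("%Y-%m-%d") if not pd.isna(d)
                else ("" if pd.isna(y) else str(int(y)))
                for d, y in zip(df["birth_date"], df["birth_year"])
            ],
            "breed": df["breed"],
        }
    )
    out.to_csv(path, sep=sep, index=False)
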