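"""Stem-map census tables: ingestion, validation, and annualized growth.

A census is one full enumeration of a mapped forest plot: every free-standing
woody stem above a minimum DBH (default 3.2 cm) with its tag, species, map
coordinates, DBH and alive/dead status.  Growth is measured between two
censuses: focal trees are stems alive in both (re-sprouts ignored), and the
response is annualized diameter increment (dbh2 - dbh1) / delta_t in cm/yr.
Negative increments are retained — they reflect measurement error, not a
biological signal to be censored.

Competitor stems are all stems alive at the first census, regardless of their
later fate: a stem that died before the second census still competed during
the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "StemRecord",
    "CensusTable",
    "GrowthDataset",
    "read_census",
    "select_focal",
    "select_competitors",
    "annual_growth",
]

STATUSES = {"alive", "dead", "resprout"}
MANDATORY = ["tag", "species", "x", "y", "dbh", "status"]
DEFAULT_MIN_DBH = 3.2


@dataclass(frozen=True)
class StemRecord:
    """One stem: tag, species/family codes, position (m), DBH (cm), status."""

    tag: str
    species: str
    x: float
    y: float
    dbh: float
    status: str
    family: Optional[str] = None
    date: Optional[float] = None
    tree_id: Optional[str] = None


@dataclass
class CensusTable:
    """One census's validated stem records.

    ``data`` holds one row per stem with at least the mandatory columns;
    ``census_date`` is the plot-level decimal year used when per-record dates
    are absent.  ``report`` lists rows excluded at read time, with reasons.
    """

    data: pd.DataFrame
    plot_extent: Tuple[float, float, float, float]
    census_label: str = ""
    census_date: Optional[float] = None
    report: pd.DataFrame = dc_field(
        default_factory=lambda: pd.DataFrame(columns=["row", "reason"])
    )
    min_dbh: float = DEFAULT_MIN_DBH

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY if c not in self.data.columns]
        if missing:
            raise ValueError(f"census table missing mandatory columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        self.data["tag"] = self.data["tag"].astype(str)
        dup = self.data["tag"][self.data["tag"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate stem tags in census: {sorted(set(dup))[:10]}")
        bad_status = set(self.data["status"]) - STATUSES
        if bad_status:
            raise ValueError(f"unknown status values: {sorted(bad_status)}")
        xmin, xmax, ymin, ymax = self.plot_extent
        xs = self.data["x"].to_numpy(dtype=float)
        ys = self.data["y"].to_numpy(dtype=float)
        if not (np.isfinite(xs).all() and np.isfinite(ys).all()):
            raise ValueError("non-finite stem coordinates")
        if ((xs < xmin) | (xs > xmax) | (ys < ymin) | (ys > ymax)).any():
            raise ValueError("stem coordinates outside plot extent")
        alive = self.data["status"] == "alive"
        dbh = self.data["dbh"].to_numpy(dtype=float)
        if np.any(alive & ~(dbh > 0)):
            raise ValueError("alive stems must have positive dbh")
        if np.any(alive & (dbh < self.min_dbh)):
            raise ValueError(f"alive stems below the {self.min_dbh} cm census threshold")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def records(self) -> Iterable[StemRecord]:
        cols = self.data.columns
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            yield StemRecord(
                tag=d["tag"], species=d["species"], x=d["x"], y=d["y"],
                dbh=d["dbh"], status=d["status"],
                family=d.get("family"), date=d.get("date"), tree_id=d.get("tree_id"),
            )

    def alive(self) -> pd.DataFrame:
        return self.data[self.data["status"] == "alive"]


DEFAULT_DIALECT: Dict[str, object] = {
    "delimiter": ",",
    "columns": {c: c for c in MANDATORY + ["family", "date", "tree_id"]},
    "status_map": {"alive": "alive", "dead": "dead", "resprout": "resprout",
                   "A": "alive", "D": "dead", "R": "resprout"},
}


def read_census(
    path,
    dialect: Optional[dict] = None,
    census_label: str = "",
    census_date: Optional[float] = None,
    plot_extent: Optional[Tuple[float, float, float, float]] = None,
    min_dbh: float = DEFAULT_MIN_DBH,
) -> CensusTable:
    """Read and validate a delimited-text census export.

    ``dialect`` maps standard column names to the file's headers and supplies
    the delimiter and status recoding.  Rows failing row-level validation
    (non-numeric dbh or coordinates, below-threshold alive stems) are
    collected in the returned table's ``report``, never silently dropped.
    A missing mandatory column is a hard error.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
        if "columns" in dialect:
            cols = dict(DEFAULT_DIALECT["columns"])
            cols.update(dialect["columns"])
            d["columns"] = cols
    raw = pd.read_csv(path, sep=d.get("delimiter", ","), dtype=str)

    colmap = d["columns"]
    missing = [std for std in MANDATORY if colmap.get(std, std) not in raw.columns]
    if missing:
        raise ValueError(f"census file missing mandatory column(s): {missing}")

    out = pd.DataFrame()
    for std in MANDATORY + ["family", "date", "tree_id"]:
        src = colmap.get(std, std)
        if src in raw.columns:
            out[std] = raw[src]
    status_map = d.get("status_map", {})
    out["status"] = out["status"].map(lambda s: status_map.get(s, s))

    problems = []
    numeric_cols = ["x", "y", "dbh"] + (["date"] if "date" in out.columns else [])
    for col in numeric_cols:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    alive = out["status"] == "alive"
    bad = pd.Series(False, index=out.index)
    for col in ["x", "y"]:
        m = out[col].isna()
        for i in out.index[m]:
            problems.append((i, f"non-numeric {col}"))
        bad |= m
    m = alive & out["dbh"].isna()
    for i in out.index[m]:
        problems.append((i, "non-numeric dbh on alive stem"))
    bad |= m
    m = alive & (out["dbh"] < min_dbh)
    for i in out.index[m]:
        problems.append((i, f"alive dbh below {min_dbh} cm threshold"))
    bad |= m
    m = ~out["status"].isin(STATUSES)
    for i in out.index[m]:
        problems.append((i, f"unknown status {out.loc[i, 'status']!r}"))
    bad |= m

    clean = out[~bad].reset_index(drop=True)
    report = pd.DataFrame(problems, columns=["row", "reason"])
    if plot_extent is None:
        plot_extent = (
            float(clean["x"].min()), float(clean["x"].max()),
            float(clean["y"].min()), float(clean["y"].max()),
        )
    return CensusTable(
        data=clean, plot_extent=plot_extent, census_label=census_label,
        census_date=census_date, report=report, min_dbh=min_dbh,
    )


def select_focal(c1: CensusTable, c2: CensusTable) -> Set[str]:
    """Tags of focal trees: alive in both censuses, not a re-sprout in the second."""
    alive1 = set(c1.alive()["tag"])
    d2 = c2.data
    alive2 = set(d2.loc[d2["status"] == "alive", "tag"])
    return alive1 & alive2


def select_competitors(c1: CensusTable) -> Set[str]:
    """Tags of competitor stems: everything alive at the first census.

    Stems that die before the second census still count — they competed
    during the growth interval.  The focal stem itself is excluded later,
    per neighborhood, by tag.
    """
    return set(c1.alive()["tag"])


def annual_growth(
    c1: CensusTable, c2: CensusTable, focal: Iterable[str]
) -> pd.Series:
    """Annualized diameter growth (dbh2 - dbh1)/delta_t in cm/yr per focal tag.

    Uses per-record dates where both censuses provide them, else the
    plot-level census dates.  Negative growth is retained.  delta_t <= 0 for
    any focal tree is a hard error.
    """
    focal = sorted(set(map(str, focal)))
    d1 = c1.data.set_index("tag")
    d2 = c2.data.set_index("tag")
    missing = [t for t in focal if t not in d1.index or t not in d2.index]
    if missing:
        raise KeyError(f"focal tags absent from a census: {missing[:10]}")

    dbh1 = d1.loc[focal, "dbh"].to_numpy(dtype=float)
    dbh2 = d2.loc[focal, "dbh"].to_numpy(dtype=float)

    def dates(d: pd.DataFrame, table: CensusTable) -> np.ndarray:
        if "date" in d.columns:
            t = d.loc[focal, "date"].to_numpy(dtype=float)
            if table.census_date is not None:
                t = np.where(np.isfinite(t), t, table.census_date)
            if np.isfinite(t).all():
                return t
        if table.census_date is None:
            raise ValueError(
                f"census {table.census_label!r} has neither per-record dates "
                "nor a plot-level census_date"
            )
        return np.full(len(focal), float(table.census_date))

    dt = dates(d2, c2) - dates(d1, c1)
    if np.any(dt <= 0):
        bad = [focal[i] for i in np.where(dt <= 0)[0][:10]]
        raise ValueError(f"non-positive census interval for tags {bad}")
    return pd.Series((dbh2 - dbh1) / dt, index=pd.Index(focal, name="tag"))


@dataclass
class GrowthDataset:
    """Model-ready focal trees: response, focal covariates, and BA matrix.

    ``frame`` has one row per focal tree (columns focal_tag, y, dbh0,
    focal_group, x, y_coord); ``ba`` is the aligned n x K matrix of
    per-competitor-group neighborhood basal areas with columns
    ``ba_columns``.  ``group_labels`` fixes the focal-group ordering (J
    labels); the fitted models here always use matched groupings, J = K.
    """

    frame: pd.DataFrame
    ba: np.ndarray
    ba_columns: list
    group_labels: list

    def __post_init__(self) -> None:
        self.ba = np.atleast_2d(np.asarray(self.ba, dtype=float))
        if len(self.frame) != self.ba.shape[0]:
            raise ValueError("frame and BA matrix row counts differ")
        if self.ba.shape[1] != len(self.ba_columns):
            raise ValueError("BA matrix width does not match ba_columns")
        if np.any(self.ba < 0):
            raise ValueError("basal areas must be non-negative")
        if self.frame["focal_tag"].duplicated().any():
            raise ValueError("each focal tree may appear at most once")
        unknown = set(self.frame["focal_group"]) - set(self.group_labels)
        if unknown:
            raise ValueError(f"focal groups outside the scheme: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def J(self) -> int:
        return len(self.group_labels)

    @property
    def K(self) -> int:
        return len(self.ba_columns)

    @property
    def n_j(self) -> pd.Series:
        return self.frame["focal_group"].value_counts().reindex(
            self.group_labels, fill_value=0
        )

    @property
    def y(self) -> np.ndarray:
        return self.frame["y"].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        ba = pd.DataFrame(
            self.ba, columns=[f"ba_{k}" for k in self.ba_columns],
            index=self.frame.index,
        )
        return pd.concat([self.frame, ba], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, group_labels: Optional[Sequence] = None) -> "GrowthDataset":
        tab = pd.read_csv(path, dtype={"focal_tag": str, "focal_group": str})
        ba_cols = [c for c in tab.columns if c.startswith("ba_")]
        labels = [c[3:] for c in ba_cols]
        frame = tab.drop(columns=ba_cols)
        if group_labels is None:
            group_labels = sorted(set(frame["focal_group"]))
        return cls(
            frame=frame, ba=tab[ba_cols].to_numpy(dtype=float),
            ba_columns=labels, group_labels=list(group_labels),
        )
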