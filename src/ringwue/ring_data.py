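"""Domain types and CSV I/O for trees, ring series and atmospheric records.

The data model mirrors a size-stratified tree-ring isotope study: one row per
sampled tree (with the bulk δ13C of its outermost five rings), optional
per-ring δ13C series for dominant trees, and a calendar record of atmospheric
CO2 and δ13C_air against which discrimination is computed.

All tables are plain CSV (UTF-8, comma-separated, "." decimal, one header
row); writers are deterministic so identical inputs give bit-identical files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CII_CLASSES",
    "FOREST_TYPES",
    "TreeRecord",
    "RingObservation",
    "AtmosphericRecord",
    "OuterRingMean",
    "SchemaError",
    "RowError",
    "SoftRangeWarning",
    "cii_to_ordinal",
    "estimate_missing_rings",
    "outer_ring_mean",
    "read_tree_table",
    "write_tree_table",
    "read_ring_table",
    "write_ring_table",
    "read_atmosphere",
    "write_atmosphere",
    "load_packaged_atmosphere",
]

#: Crown illumination classes in increasing order of light exposure, from
#: fully shaded understory (1) to full overhead and lateral light (5).
CII_CLASSES: tuple[str, ...] = ("1", "2a", "2b", "2c", "3a", "3b", "4", "5")
_CII_ORDINAL = {c: i + 1 for i, c in enumerate(CII_CLASSES)}

FOREST_TYPES: tuple[str, ...] = ("temperate", "tropical", "open")

#: Hard physical bounds and soft plausibility range for wood δ13C (‰ V-PDB).
D13C_HARD_RANGE = (-40.0, -10.0)
D13C_SOFT_RANGE = (-35.0, -18.0)


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unusable header."""


class RowError(ValueError):
    """One or more rows violate a hard invariant; message carries row numbers."""


class SoftRangeWarning(UserWarning):
    """δ13C outside the typical C3-wood range but inside the hard bounds."""


@dataclass(frozen=True)
class TreeRecord:
    """One sampled tree with its outer-ring bulk δ13C.

    ``dbh_cm`` may be ``None`` for seedlings too small to core.
    """

    tree_id: str
    species: str
    site_id: str
    forest_type: str
    sampling_year: int
    age_years: int
    dbh_cm: float | None
    height_m: float
    cii_class: str
    d13c_outer_permil: float

    def __post_init__(self) -> None:
        if self.forest_type not in FOREST_TYPES:
            raise ValueError(
                f"forest_type {self.forest_type!r} not in {FOREST_TYPES}"
            )
        if self.age_years < 1:
            raise ValueError(f"age_years must be >= 1, got {self.age_years}")
        if not self.height_m > 0:
            raise ValueError(f"height_m must be > 0, got {self.height_m}")
        if self.dbh_cm is not None and not self.dbh_cm > 0:
            raise ValueError(f"dbh_cm must be > 0 when present, got {self.dbh_cm}")
        if self.cii_class not in _CII_ORDINAL:
            raise ValueError(
                f"cii_class {self.cii_class!r} is not one of {CII_CLASSES}"
            )
        lo, hi = D13C_HARD_RANGE
        if not lo <= self.d13c_outer_permil <= hi:
            raise ValueError(
                f"d13c_outer_permil {self.d13c_outer_permil} outside hard "
                f"range [{lo}, {hi}]"
            )
        slo, shi = D13C_SOFT_RANGE
        if not slo <= self.d13c_outer_permil <= shi:
            warnings.warn(
                f"tree {self.tree_id}: d13c_outer_permil "
                f"{self.d13c_outer_permil} outside typical C3-wood range "
                f"[{slo}, {shi}]",
                SoftRangeWarning,
                stacklevel=2,
            )

    @property
    def cii_ordinal(self) -> int:
        return _CII_ORDINAL[self.cii_class]


@dataclass(frozen=True)
class RingObservation:
    """One dated ring (or multi-year ring block) with its δ13C.

    A 10-year block carries the block's midpoint calendar year and
    ``block_span_years = 10``; annual rings have ``block_span_years = 1``.
    """

    tree_id: str
    calendar_year: int
    ring_index: int
    d13c_permil: float
    block_span_years: int = 1

    def __post_init__(self) -> None:
        if self.ring_index < 1:
            raise ValueError(f"ring_index must be >= 1, got {self.ring_index}")
        if self.block_span_years < 1:
            raise ValueError(
                f"block_span_years must be >= 1, got {self.block_span_years}"
            )


class AtmosphericRecord:
    """Calendar series of atmospheric CO2 (ca, ppm) and δ13C_air (‰).

    In *constant mode* the record returns the pre-industrial constants
    (280 ppm, −6.4 ‰) for any year, emulating the treatment of sub-fossil
    material that grew under near-constant CO2. Otherwise lookups linearly
    interpolate between tabulated years and refuse to extrapolate.
    """

    PREINDUSTRIAL_CA_PPM = 280.0
    PREINDUSTRIAL_D13C_AIR = -6.4

    def __init__(
        self,
        years: Sequence[int],
        ca_ppm: Sequence[float],
        d13c_air_permil: Sequence[float],
        constant: bool = False,
    ) -> None:
        years = np.asarray(years, dtype=int)
        ca = np.asarray(ca_ppm, dtype=float)
        d13c = np.asarray(d13c_air_permil, dtype=float)
        if not (len(years) == len(ca) == len(d13c)):
            raise ValueError("years, ca_ppm, d13c_air_permil must be equal length")
        if len(years) and np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing with no duplicates")
        if np.any(ca <= 0):
            raise ValueError("ca_ppm must be > 0 everywhere")
        self.years = years
        self.ca_ppm = ca
        self.d13c_air_permil = d13c
        self.constant = bool(constant)

    @classmethod
    def constant_preindustrial(cls) -> "AtmosphericRecord":
        return cls(
            [0],
            [cls.PREINDUSTRIAL_CA_PPM],
            [cls.PREINDUSTRIAL_D13C_AIR],
            constant=True,
        )

    def lookup(self, year: int | float) -> tuple[float, float]:
        """(ca ppm, δ13C_air ‰) at ``year``; interpolates, never extrapolates."""
        if self.constant:
            return float(self.ca_ppm[0]), float(self.d13c_air_permil[0])
        if not self.years.size:
            raise LookupError("empty atmospheric record")
        lo, hi = int(self.years[0]), int(self.years[-1])
        if not lo <= year <= hi:
            raise LookupError(
                f"year {year} outside atmospheric record span [{lo}, {hi}]"
            )
        ca = float(np.interp(year, self.years, self.ca_ppm))
        d13c = float(np.interp(year, self.years, self.d13c_air_permil))
        return ca, d13c

    def span(self) -> tuple[int, int]:
        return int(self.years[0]), int(self.years[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AtmosphericRecord):
            return NotImplemented
        return (
            self.constant == other.constant
            and np.array_equal(self.years, other.years)
            and np.array_equal(self.ca_ppm, other.ca_ppm)
            and np.array_equal(self.d13c_air_permil, other.d13c_air_permil)
        )


@dataclass(frozen=True)
class OuterRingMean:
    """Unweighted mean δ13C of a tree's outermost annual rings."""

    mean_permil: float
    first_year: int
    last_year: int
    n_used: int
    short_series: bool = False


def cii_to_ordinal(cii_class: str) -> int:
    """Map a crown illumination class to its ordinal light rank in 1..8.

    Classes run 1, 2a, 2b, 2c, 3a, 3b, 4, 5 from understory shade to full
    overhead-plus-lateral exposure; the map is the order-preserving bijection
    onto 1..8.
    """
    try:
        return _CII_ORDINAL[str(cii_class)]
    except KeyError:
        raise ValueError(
            f"unknown crown illumination class {cii_class!r}; "
            f"expected one of {CII_CLASSES}"
        ) from None


def estimate_missing_rings(
    distance_to_pith_mm: float, mean_ring_width_mm: float
) -> int:
    """Estimate rings missed by a core that did not reach the pith.

    Divides the geometric distance to the pith by the mean ring width for the
    species/diameter class and rounds half away from zero.
    """
    if mean_ring_width_mm <= 0:
        raise ValueError(
            f"mean_ring_width_mm must be > 0, got {mean_ring_width_mm}"
        )
    if distance_to_pith_mm < 0:
        raise ValueError(
            f"distance_to_pith_mm must be >= 0, got {distance_to_pith_mm}"
        )
    x = distance_to_pith_mm / mean_ring_width_mm
    return int(np.floor(x + 0.5))  # half away from zero (x >= 0 here)


def outer_ring_mean(
    rings: Iterable[RingObservation], n: int = 5
) -> OuterRingMean:
    """Mean δ13C of the ``n`` most recent annual rings of one tree.

    Emulates bulking the last five rings of each tree. Multi-year blocks are
    ignored; if fewer than ``n`` annual rings exist, all are used and the
    result is flagged as a short series. Order of the input does not matter.
    """
    annual = [r for r in rings if r.block_span_years == 1]
    if not annual:
        raise ValueError("no annual rings to average")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    tree_ids = {r.tree_id for r in annual}
    if len(tree_ids) > 1:
        raise ValueError(f"rings from multiple trees: {sorted(tree_ids)}")
    annual.sort(key=lambda r: r.calendar_year)
    used = annual[-n:]
    mean = float(np.mean([r.d13c_permil for r in used]))
    return OuterRingMean(
        mean_permil=mean,
        first_year=used[0].calendar_year,
        last_year=used[-1].calendar_year,
        n_used=len(used),
        short_series=len(used) < n,
    )


# ---------------------------------------------------------------------------
# CSV I/O

TREE_COLUMNS = [
    "tree_id",
    "species",
    "site_id",
    "forest_type",
    "sampling_year",
    "age_years",
    "dbh_cm",
    "height_m",
    "cii_class",
    "d13c_outer_permil",
]
RING_COLUMNS = [
    "tree_id",
    "calendar_year",
    "ring_index",
    "block_span_years",
    "d13c_permil",
]
ATMOS_COLUMNS = ["year", "ca_ppm", "d13c_air_permil"]


def _check_columns(df: pd.DataFrame, required: list[str], path: str) -> pd.DataFrame:
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return df


def read_tree_table(path: str | Path) -> list[TreeRecord]:
    """Read and validate a tree table CSV into TreeRecords.

    Hard-invariant violations raise :class:`RowError` naming the offending
    rows and values; soft δ13C range violations emit
    :class:`SoftRangeWarning` only.
    """
    df = _check_columns(pd.read_csv(path, dtype=str), TREE_COLUMNS, str(path))
    records: list[TreeRecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # header is line 1
        try:
            dbh_raw = row["dbh_cm"]
            dbh = None if pd.isna(dbh_raw) or str(dbh_raw).strip() == "" else float(dbh_raw)
            records.append(
                TreeRecord(
                    tree_id=str(row["tree_id"]),
                    species=str(row["species"]),
                    site_id=str(row["site_id"]),
                    forest_type=str(row["forest_type"]).strip().lower(),
                    sampling_year=int(row["sampling_year"]),
                    age_years=int(row["age_years"]),
                    dbh_cm=dbh,
                    height_m=float(row["height_m"]),
                    cii_class=str(row["cii_class"]).strip(),
                    d13c_outer_permil=float(row["d13c_outer_permil"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {rowno}: {exc}")
    if problems:
        raise RowError(f"{path}: {len(problems)} invalid row(s):\n" + "\n".join(problems))
    return records


def write_tree_table(records: Iterable[TreeRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in TREE_COLUMNS}
        d["dbh_cm"] = "" if r.dbh_cm is None else repr(float(r.dbh_cm))
        d["height_m"] = repr(float(r.height_m))
        d["d13c_outer_permil"] = repr(float(r.d13c_outer_permil))
        rows.append(d)
    pd.DataFrame(rows, columns=TREE_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def read_ring_table(path: str | Path) -> list[RingObservation]:
    df = _check_columns(pd.read_csv(path), RING_COLUMNS, str(path))
    records: list[RingObservation] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2
        try:
            records.append(
                RingObservation(
                    tree_id=str(row["tree_id"]),
                    calendar_year=int(row["calendar_year"]),
                    ring_index=int(row["ring_index"]),
                    d13c_permil=float(row["d13c_permil"]),
                    block_span_years=int(row["block_span_years"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {rowno}: {exc}")
    if problems:
        raise RowError(f"{path}: {len(problems)} invalid row(s):\n" + "\n".join(problems))
    _check_ring_ordering(records)
    return records


def _check_ring_ordering(records: list[RingObservation]) -> None:
    """Within one tree, ring_index must strictly increase with calendar_year."""
    by_tree: dict[str, list[RingObservation]] = {}
    for r in records:
        by_tree.setdefault(r.tree_id, []).append(r)
    for tid, obs in by_tree.items():
        obs = sorted(obs, key=lambda r: r.calendar_year)
        idx = [r.ring_index for r in obs]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise RowError(
                f"tree {tid}: ring_index does not strictly increase with "
                f"calendar_year"
            )


def write_ring_table(records: Iterable[RingObservation], path: str | Path) -> None:
    rows = [
        {
            "tree_id": r.tree_id,
            "calendar_year": r.calendar_year,
            "ring_index": r.ring_index,
            "block_span_years": r.block_span_years,
            "d13c_permil": repr(float(r.d13c_permil)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RING_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def read_atmosphere(path: str | Path, constant: bool = False) -> AtmosphericRecord:
    df = _check_columns(pd.read_csv(path), ATMOS_COLUMNS, str(path))
    return AtmosphericRecord(
        df["year"].to_numpy(dtype=int),
        df["ca_ppm"].to_numpy(dtype=float),
        df["d13c_air_permil"].to_numpy(dtype=float),
        constant=constant,
    )


def load_packaged_atmosphere() -> AtmosphericRecord:
    """The packaged constant pre-industrial atmosphere (280 ppm, −6.4 ‰)."""
    from importlib.resources import files

    path = files("ringwue").joinpath("data/atmosphere_preindustrial.csv")
    with path.open("r") as fh:
        return read_atmosphere(fh, constant=True)


def write_atmosphere(record: AtmosphericRecord, path: str | Path) -> None:
    pd.DataFrame(
        {
            "year": record.years,
            "ca_ppm": [repr(float(v)) for v in record.ca_ppm],
            "d13c_air_permil": [repr(float(v)) for v in record.d13c_air_permil],
        }
    ).to_csv(path, index=False, lineterminator="\n")
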