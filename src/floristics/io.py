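"""Data model, validation, and readers/writers for occurrence, geographic-component,
and reserve-metadata tables.

The canonical exchange format is a long-format CSV of occurrence records
(one row per reserve x species), from which wide presence/absence matrices
are derived at the species, genus, or areal-type level.  Wide matrices are
never authored by hand: a regional flora can easily exceed 9000 species and
a long table is the only format that stays reviewable.

Column conventions
------------------
``occurrences.csv``
    reserve_id, species, genus, family, areal_type, endemic, cultivated
    (``endemic_flag``/``cultivated_flag`` are accepted as aliases).
``components.csv``
    genus, component, origin_lon, origin_lat and an optional ``species``
    column for species-level overrides of a genus-level component label.
``reserves.csv``
    reserve_id, lon, lat, elev_base, elev_mean, elev_peak plus any number of
    environmental columns (see :data:`ENV_VARIABLES` for the default set).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    ConsistencyError,
    DomainError,
    EmptyInputError,
    SchemaError,
)

__all__ = [
    "OccurrenceTable",
    "PresenceMatrix",
    "ReserveMeta",
    "ComponentTable",
    "ValidationReport",
    "ENV_VARIABLES",
    "PRESENCE_LEVELS",
    "read_occurrences",
    "write_occurrences",
    "filter_cultivated",
    "to_presence",
    "richness_summary",
    "read_components",
    "read_reserves",
]

#: Required columns of an occurrence table, in canonical order.
OCCURRENCE_COLUMNS = (
    "reserve_id",
    "species",
    "genus",
    "family",
    "areal_type",
    "endemic",
    "cultivated",
)

#: Accepted aliases for occurrence columns (alias -> canonical).
_COLUMN_ALIASES = {"endemic_flag": "endemic", "cultivated_flag": "cultivated"}

#: Incidence levels a presence matrix can be built at.
PRESENCE_LEVELS = ("species", "genus", "areal_type")

#: Default environmental variables: four climate quantities, each for the
#: current period and the Last Glacial Maximum (LGM).  Precipitation in mm,
#: temperatures in degrees Celsius.
ENV_VARIABLES = (
    "precip_current",
    "precip_lgm",
    "tmean_current",
    "tmean_lgm",
    "tcoldq_current",
    "tcoldq_lgm",
    "twarmq_current",
    "twarmq_lgm",
)

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", ""}


def _coerce_bool(series: pd.Series, column: str) -> pd.Series:
    if series.dtype == bool:
        return series
    out = series.astype(str).str.strip().str.lower()
    bad = ~out.isin(_TRUTHY | _FALSY)
    if bad.any():
        raise SchemaError(
            f"column {column!r} has non-boolean values: "
            f"{sorted(out[bad].unique())[:5]}"
        )
    return out.isin(_TRUTHY)


@dataclass(frozen=True)
class ValidationReport:
    """Counts attached to a validated occurrence table."""

    n_records: int
    n_reserves: int
    n_species: int
    n_genera: int
    n_families: int
    n_duplicates_removed: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)


@dataclass
class OccurrenceTable:
    """Validated long-format occurrence records.

    Wraps a :class:`pandas.DataFrame` with the canonical occurrence columns.
    Invariants enforced at construction: each species belongs to exactly one
    genus, each genus to exactly one family, and (reserve_id, species) pairs
    are unique.
    """

    df: pd.DataFrame
    report: ValidationReport = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        missing = [c for c in OCCURRENCE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"occurrence table missing columns: {missing}")
        self.df = self.df.loc[:, list(self.df.columns)].reset_index(drop=True)
        _check_unique_parent(self.df, "species", "genus")
        _check_unique_parent(self.df, "genus", "family")
        dup = self.df.duplicated(subset=["reserve_id", "species"])
        if dup.any():
            raise ConsistencyError(
                f"{int(dup.sum())} duplicate (reserve_id, species) pairs; "
                "deduplicate before constructing OccurrenceTable"
            )
        if self.report is None:
            self.report = _make_report(self.df, 0)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def reserves(self) -> list[str]:
        """Reserve ids in order of first appearance."""
        return list(dict.fromkeys(self.df["reserve_id"]))

    def species_of(self, reserve_id: str) -> set[str]:
        return set(self.df.loc[self.df["reserve_id"] == reserve_id, "species"])


def _check_unique_parent(df: pd.DataFrame, child: str, parent: str) -> None:
    counts = df.groupby(child, sort=False)[parent].nunique()
    offenders = counts[counts > 1]
    if len(offenders):
        pairs = {
            c: sorted(df.loc[df[child] == c, parent].unique())
            for c in offenders.index[:10]
        }
        raise ConsistencyError(
            f"each {child} must map to exactly one {parent}; offenders: {pairs}"
        )


def _make_report(df: pd.DataFrame, n_dupes: int) -> ValidationReport:
    return ValidationReport(
        n_records=len(df),
        n_reserves=df["reserve_id"].nunique(),
        n_species=df["species"].nunique(),
        n_genera=df["genus"].nunique(),
        n_families=df["family"].nunique(),
        n_duplicates_removed=n_dupes,
    )


def read_occurrences(path: str | Path, dialect: dict | None = None) -> OccurrenceTable:
    """Read and validate a long-format occurrence CSV.

    Duplicate (reserve_id, species) rows are collapsed (first wins) and
    counted in the attached :class:`ValidationReport`.  String fields are
    whitespace-normalized; name matching is otherwise case-sensitive.

    Parameters
    ----------
    path
        CSV file with the seven occurrence columns (aliases accepted).
    dialect
        Extra keyword arguments forwarded to :func:`pandas.read_csv`
        (e.g. ``{"sep": ";"}``).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **(dialect or {}))
    df = df.rename(columns={c: c.strip() for c in df.columns})
    df = df.rename(columns=_COLUMN_ALIASES)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df = df.loc[:, list(OCCURRENCE_COLUMNS)]
    for col in ("reserve_id", "species", "genus", "family", "areal_type"):
        df[col] = df[col].str.strip().str.replace(r"\s+", " ", regex=True)
    for col in ("endemic", "cultivated"):
        df[col] = _coerce_bool(df[col], col)
    n_before = len(df)
    df = df.drop_duplicates(subset=["reserve_id", "species"], keep="first")
    n_dupes = n_before - len(df)
    if df.empty:
        raise EmptyInputError(f"{path}: no occurrence records")
    table = OccurrenceTable(df.reset_index(drop=True))
    table.report = _make_report(table.df, n_dupes)
    return table


def write_occurrences(table: OccurrenceTable, path: str | Path) -> None:
    """Write an occurrence table as canonical CSV (UTF-8, comma-separated)."""
    table.df.to_csv(path, index=False)


def filter_cultivated(table: OccurrenceTable) -> tuple[OccurrenceTable, int]:
    """Drop all records of cultivated species.

    A species is treated as cultivated if any of its records carries the
    cultivated flag.  Returns the filtered table and the number of distinct
    species removed.
    """
    cult_species = set(table.df.loc[table.df["cultivated"], "species"])
    if not cult_species:
        return table, 0
    keep = ~table.df["species"].isin(cult_species)
    out = table.df.loc[keep].reset_index(drop=True)
    if out.empty:
        raise EmptyInputError("all species are cultivated; nothing remains")
    filtered = OccurrenceTable(out)
    filtered.report = _make_report(out, 0)
    return filtered, len(cult_species)


@dataclass
class PresenceMatrix:
    """Reserves x taxa boolean incidence at a stated level.

    ``values`` is a boolean DataFrame whose index is reserve ids (order of
    first appearance in the source table) and whose columns are taxa in
    lexicographic order.
    """

    values: pd.DataFrame
    level: str

    def __post_init__(self) -> None:
        if self.level not in PRESENCE_LEVELS:
            raise DomainError(f"level must be one of {PRESENCE_LEVELS}, got {self.level!r}")
        empty = self.values.sum(axis=1) == 0
        if empty.any():
            raise EmptyInputError(
                f"reserve(s) with no taxa at level {self.level!r}: "
                f"{list(self.values.index[empty])}"
            )
        self.values = self.values.loc[:, sorted(self.values.columns)].astype(bool)

    @property
    def reserves(self) -> list[str]:
        return list(self.values.index)

    def row_sets(self) -> dict[str, set[str]]:
        """Taxon set per reserve (used by the brute-force similarity oracle)."""
        arr = self.values.to_numpy()
        cols = np.asarray(self.values.columns)
        return {r: set(cols[arr[i]]) for i, r in enumerate(self.values.index)}


def to_presence(table: OccurrenceTable, level: str) -> PresenceMatrix:
    """Collapse an occurrence table into a presence/absence matrix.

    At the ``genus`` level congeneric species collapse into one column; at the
    ``areal_type`` level all genera sharing an areal-type code collapse, so a
    reserve's row is its set of areal types (a subset of the closed
    vocabulary, typically 15 codes).
    """
    if level not in PRESENCE_LEVELS:
        raise DomainError(f"level must be one of {PRESENCE_LEVELS}, got {level!r}")
    col = {"species": "species", "genus": "genus", "areal_type": "areal_type"}[level]
    reserves = list(dict.fromkeys(table.df["reserve_id"]))
    sub = table.df[["reserve_id", col]].drop_duplicates()
    wide = (
        pd.crosstab(sub["reserve_id"], sub[col])
        .astype(bool)
        .reindex(index=reserves, fill_value=False)
    )
    wide.index.name = "reserve_id"
    wide.columns.name = level
    return PresenceMatrix(wide, level)


def richness_summary(table: OccurrenceTable, by_reserve: bool = False) -> pd.DataFrame:
    """Counts of families, genera, species, and endemics, globally or per reserve."""
    if len(table) == 0:
        raise EmptyInputError("richness_summary on empty table")

    def _counts(df: pd.DataFrame) -> pd.Series:
        end = df.loc[df["endemic"]]
        return pd.Series(
            {
                "families": df["family"].nunique(),
                "genera": df["genus"].nunique(),
                "species": df["species"].nunique(),
                "endemic_species": end["species"].nunique(),
                "endemic_genera": end["genus"].nunique(),
            }
        )

    if by_reserve:
        out = (
            table.df.groupby("reserve_id", sort=False)
            .apply(_counts, include_groups=False)
            .astype(int)
        )
        return out
    return _counts(table.df).astype(int).to_frame("total").T


@dataclass
class ReserveMeta:
    """Reserve metadata: WGS84 coordinates, elevations (m), and environmental
    variables.

    ``df`` is indexed by reserve_id with columns lon, lat, elev_base,
    elev_mean, elev_peak and one column per environmental variable.
    """

    df: pd.DataFrame

    _CORE = ("lon", "lat", "elev_base", "elev_mean", "elev_peak")

    def __post_init__(self) -> None:
        missing = [c for c in self._CORE if c not in self.df.columns]
        if missing:
            raise SchemaError(f"reserve metadata missing columns: {missing}")
        for c in self.df.columns:
            self.df[c] = pd.to_numeric(self.df[c])
        bad = ~(
            (self.df["elev_base"] <= self.df["elev_mean"])
            & (self.df["elev_mean"] <= self.df["elev_peak"])
        )
        if bad.any():
            raise ConsistencyError(
                f"elev_base <= elev_mean <= elev_peak violated for: "
                f"{list(self.df.index[bad])}"
            )

    @property
    def env_variables(self) -> list[str]:
        return [c for c in self.df.columns if c not in self._CORE]

    def require_env(self, variables: list[str] | None = None) -> pd.DataFrame:
        """Environmental feature table, erroring on missing values."""
        variables = list(variables) if variables is not None else self.env_variables
        missing = [v for v in variables if v not in self.df.columns]
        if missing:
            raise SchemaError(f"environmental variable(s) not present: {missing}")
        env = self.df[variables]
        if env.isna().any().any():
            bad = env.index[env.isna().any(axis=1)]
            raise ConsistencyError(f"missing environmental values for: {list(bad)}")
        return env

    def align_to(self, reserves: list[str], on_extra: str = "warn") -> "ReserveMeta":
        """Restrict metadata to the given reserves (occurrence-table order).

        Reserves present in metadata but absent from occurrences are dropped
        with a warning; reserves missing from metadata are an error.
        """
        missing = [r for r in reserves if r not in self.df.index]
        if missing:
            raise AlignmentError(f"reserves without metadata: {missing[:10]}")
        extra = [r for r in self.df.index if r not in set(reserves)]
        if extra and on_extra == "warn":
            warnings.warn(
                f"dropping {len(extra)} reserve(s) present in metadata but "
                f"absent from occurrences: {extra[:5]}",
                stacklevel=2,
            )
        return ReserveMeta(self.df.loc[list(reserves)].copy())


def read_reserves(path: str | Path) -> ReserveMeta:
    """Read reserve metadata CSV (reserve_id, lon, lat, elevations, env columns)."""
    df = pd.read_csv(path)
    if "reserve_id" not in df.columns:
        raise SchemaError(f"{path}: missing 'reserve_id' column")
    df["reserve_id"] = df["reserve_id"].astype(str).str.strip()
    return ReserveMeta(df.set_index("reserve_id"))


@dataclass
class ComponentTable:
    """Genus -> geographic-component assignments with origin centers.

    One component label per genus row; optional species-level override rows
    carry a non-empty ``species`` value and take precedence for that species.
    ``origin_lon``/``origin_lat`` give the component's origin center (decimal
    degrees WGS84); origins are literature-derived inputs, never estimated.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["genus", "component", "origin_lon", "origin_lat"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"component table missing columns: {missing}")
        if "species" not in self.df.columns:
            self.df = self.df.assign(species="")
        self.df["species"] = self.df["species"].fillna("").astype(str).str.strip()
        genus_rows = self.df[self.df["species"] == ""]
        dup = genus_rows["genus"].duplicated()
        if dup.any():
            raise ConsistencyError(
                f"multiple genus-level component rows for: "
                f"{sorted(genus_rows.loc[dup, 'genus'].unique())}"
            )

    @property
    def components(self) -> list[str]:
        return sorted(self.df["component"].unique())

    def origin_of(self, component: str) -> tuple[float, float]:
        rows = self.df.loc[self.df["component"] == component]
        if rows.empty:
            raise DomainError(f"unknown component {component!r}")
        return float(rows["origin_lon"].iloc[0]), float(rows["origin_lat"].iloc[0])

    def genus_map(self) -> dict[str, str]:
        sub = self.df[self.df["species"] == ""]
        return dict(zip(sub["genus"], sub["component"]))

    def species_overrides(self) -> dict[str, str]:
        sub = self.df[self.df["species"] != ""]
        return dict(zip(sub["species"], sub["component"]))


def read_components(path: str | Path) -> ComponentTable:
    """Read a genus -> geographic-component CSV."""
    df = pd.read_csv(path, keep_default_na=False)
    for col in ("genus", "component"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.strip()
    return ComponentTable(df)
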