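"""Geographic components of endemic genera and distance-decay dispersal gradients.

Each Chinese-endemic genus carries a geographic component — the region where
it originated and diversified (e.g. Central-East China, Southwest China,
Qinling).  Component labels and origin centers are literature-derived inputs
read from a component table; species-level overrides let a single genus
contribute to two components when its species demonstrably arose in
different centers (the *Biondia* situation: one species of Qinling origin,
congeners of Sichuan origin).

Qualitative "spreads X-ward with decreasing proportion" statements are
operationalized as a distance-decay test: the Spearman correlation between a
reserve's great-circle distance from the component's origin center and its
count of that component's genera, with a seeded permutation p-value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DomainError, EmptyInputError
from .io import ComponentTable, OccurrenceTable, ReserveMeta

__all__ = [
    "EARTH_RADIUS_KM",
    "UNCERTAIN",
    "haversine_km",
    "assign_components",
    "component_summary",
    "ComponentCountMatrix",
    "component_counts",
    "GradientResult",
    "gradient_test",
    "export_component_map",
    "write_geojson",
]

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: Component label for endemic genera absent from the component table.
UNCERTAIN = "Uncertain"


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in km between WGS84 points (decimal degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def assign_components(table: OccurrenceTable, components: ComponentTable) -> pd.DataFrame:
    """Label every endemic occurrence record with its geographic component.

    Species-level overrides take precedence over the genus-level label;
    endemic genera absent from the component table are labeled
    :data:`UNCERTAIN`.  Non-endemic genera listed in the component table
    trigger a warning (the table is meant to cover endemic genera only).
    Returns a copy of the records with a ``component`` column (empty string
    for non-endemic records).
    """
    df = table.df.copy()
    genus_map = components.genus_map()
    overrides = components.species_overrides()

    endemic_genera = set(df.loc[df["endemic"], "genus"])
    stray = sorted(set(genus_map) - endemic_genera)
    if stray:
        warnings.warn(
            f"component table lists {len(stray)} genus(era) with no endemic "
            f"records: {stray[:5]}",
            stacklevel=2,
        )

    comp = df["species"].map(overrides).fillna(df["genus"].map(genus_map)).fillna(UNCERTAIN)
    df["component"] = np.where(df["endemic"], comp, "")
    return df


def component_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Distinct endemic genera per component over the whole dataset.

    Proportions are percentages of the total count, rounded to two decimals.
    A genus whose species carry overrides into two components counts once in
    each; the denominator is then the total of per-component counts, so
    proportions still sum to 100.  Components are ordered by descending
    count, ties alphabetical.
    """
    end = annotated.loc[annotated["endemic"] & (annotated["component"] != "")]
    if end.empty:
        raise EmptyInputError("no endemic genera with assigned components")
    counts = (
        end[["genus", "component"]]
        .drop_duplicates()
        .groupby("component")
        .size()
        .rename("n_genera")
    )
    total = int(counts.sum())
    out = counts.reset_index()
    out["proportion_pct"] = (100.0 * out["n_genera"] / total).round(2)
    out = out.sort_values(
        ["n_genera", "component"], ascending=[False, True]
    ).reset_index(drop=True)
    return out


@dataclass
class ComponentCountMatrix:
    """Reserves x components counts of distinct endemic genera present.

    ``proportions`` divides each row by its total; rows with zero endemic
    genera stay all-zero there.
    """

    counts: pd.DataFrame

    @property
    def reserves(self) -> list[str]:
        return list(self.counts.index)

    @property
    def components(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def proportions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        out = self.counts.div(totals.where(totals > 0, np.nan), axis=0)
        return out.fillna(0.0)


def component_counts(annotated: pd.DataFrame, reserves: list[str] | None = None) -> ComponentCountMatrix:
    """Per-reserve counts of distinct endemic genera by component."""
    if reserves is None:
        reserves = list(dict.fromkeys(annotated["reserve_id"]))
    end = annotated.loc[annotated["endemic"] & (annotated["component"] != "")]
    cells = end[["reserve_id", "genus", "component"]].drop_duplicates()
    counts = (
        pd.crosstab(cells["reserve_id"], cells["component"])
        .reindex(index=reserves, fill_value=0)
        .astype(int)
    )
    counts = counts.loc[:, sorted(counts.columns)]
    counts.index.name = "reserve_id"
    counts.columns.name = "component"
    return ComponentCountMatrix(counts)


@dataclass(frozen=True)
class GradientResult:
    """Distance-decay test result for one component.

    ``rho`` is the Spearman correlation between distance from the origin
    center and per-reserve genus count; ``p_perm`` the two-sided permutation
    p-value; ``direction`` is ``decay`` (rho < 0, significant), ``increase``
    (rho > 0, significant) or ``flat``.
    """

    component: str
    rho: float
    p_perm: float
    n_reserves: int
    n_perm: int
    direction: str


def _spearman_perm(dist: np.ndarray, counts: np.ndarray, n_perm: int, rng: np.random.Generator) -> tuple[float, float]:
    """Observed Spearman rho and two-sided permutation p, vectorized.

    Ranking the permuted counts equals permuting the ranks (same multiset),
    so all permutation correlations reduce to one matrix-vector product on
    standardized ranks.
    """
    n = len(dist)
    rd = rankdata(dist)
    rc = rankdata(counts)
    zd = (rd - rd.mean())
    zc = (rc - rc.mean())
    sd = np.sqrt((zd**2).sum())
    sc = np.sqrt((zc**2).sum())
    if sd == 0 or sc == 0:
        return np.nan, 1.0
    zd /= sd
    zc /= sc
    rho_obs = float(zd @ zc)
    perm_idx = np.stack([rng.permutation(n) for _ in range(n_perm)])
    rho_perm = zc[perm_idx] @ zd
    p = (1 + np.sum(np.abs(rho_perm) >= abs(rho_obs) - 1e-12)) / (1 + n_perm)
    return rho_obs, float(p)


def gradient_test(
    cm: ComponentCountMatrix,
    meta: ReserveMeta,
    component: str,
    origin: tuple[float, float],
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> GradientResult:
    """Test whether a component's genus counts decay with distance from its origin.

    Parameters
    ----------
    origin
        (lon, lat) of the component's origin center, decimal degrees.
    n_perm
        Number of seeded count permutations (>= 199).
    """
    if component not in cm.counts.columns:
        raise DomainError(f"component {component!r} not in count matrix")
    if n_perm < 199:
        raise DomainError("n_perm must be >= 199 for a usable p resolution")
    meta_aligned = meta.align_to(cm.reserves)
    if len(cm.reserves) < 5:
        raise DomainError("gradient test requires >= 5 reserves with coordinates")
    dist = haversine_km(
        meta_aligned.df["lon"].to_numpy(),
        meta_aligned.df["lat"].to_numpy(),
        origin[0],
        origin[1],
    )
    counts = cm.counts[component].to_numpy(dtype=float)
    if np.ptp(counts) == 0:
        return GradientResult(component, float("nan"), 1.0, len(counts), n_perm, "flat")
    rng = np.random.default_rng(seed)
    rho, p = _spearman_perm(np.asarray(dist), counts, n_perm, rng)
    if p < alpha and rho < 0:
        direction = "decay"
    elif p < alpha and rho > 0:
        direction = "increase"
    else:
        direction = "flat"
    return GradientResult(component, rho, p, len(counts), n_perm, direction)


def export_component_map(
    cm: ComponentCountMatrix,
    meta: ReserveMeta,
    origins: dict[str, tuple[float, float]] | None = None,
) -> dict:
    """Export per-reserve component counts as a GeoJSON FeatureCollection.

    One Point feature per (reserve, component) cell with a positive count
    (the count drives point size on a map); origin centers, if given, become
    separate features with ``"role": "origin"``.  Reserves without
    coordinates are skipped with a warning.
    """
    features = []
    for reserve in cm.reserves:
        if reserve not in meta.df.index:
            warnings.warn(f"no coordinates for reserve {reserve!r}; skipped", stacklevel=2)
            continue
        lon = float(meta.df.loc[reserve, "lon"])
        lat = float(meta.df.loc[reserve, "lat"])
        for component in cm.components:
            count = int(cm.counts.loc[reserve, component])
            if count == 0:
                continue
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [lon, lat]},
                    "properties": {
                        "reserve_id": reserve,
                        "component": component,
                        "count": count,
                        "role": "reserve",
                    },
                }
            )
    for component, (olon, olat) in (origins or {}).items():
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(olon), float(olat)]},
                "properties": {"component": component, "role": "origin"},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(collection: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(collection, sort_keys=True) + "\n")
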