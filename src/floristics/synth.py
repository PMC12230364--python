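"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a mountain-system flora survey: reserves grouped into
latent regions with region-specific species pools, nested
species-genus-family taxonomy, areal-type labels whose spectra differ
between regions, endemic genera assigned to geographic components whose
per-reserve presence decays exponentially with distance from the component's
origin center, environmental covariates correlated with region membership,
and a block of introduced cultivated species to exercise the exclusion
filter.

Overlap model
-------------
Each region's species pool has a disjoint core plus one globally shared
pool; a reserve includes each species of its region pool independently with
probability ``within_region_overlap``.  Under this model the expected
species-level Sørensen similarity of two reserves in the same region equals
the inclusion probability, and between regions it is approximately
``shared_fraction * within_region_overlap``, so setting the shared fraction
to ``between_region_overlap / within_region_overlap`` realizes the requested
(within, between) similarity targets directly.

Randomness
----------
All draws flow from one integer seed through named substreams (one
``numpy`` Generator per purpose, keyed ``SeedSequence([seed, index])``), so
adding a later stage never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .io import ComponentTable, OccurrenceTable, ReserveMeta, ENV_VARIABLES
from .dispersal import haversine_km

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate", "make_fixture", "FIXTURES"]

#: Study frame (decimal degrees): lon 102-116 E, lat 29-37 N.
_FRAME = (102.0, 116.0, 29.0, 37.0)

#: Default component origin centers: compass corners/edges of the study
#: frame, so decay directions are interpretable (a "Southwest" component
#: decays toward the northeast, etc.).
DEFAULT_ORIGINS = {
    "Central-East China": (116.0, 33.0),
    "Southwest China": (102.0, 29.0),
    "North China": (114.0, 37.0),
    "Northwest China": (102.0, 37.0),
    "Qinling": (108.0, 34.0),
    "South China": (112.0, 29.0),
}

#: Substream names in fixed order; extend only by appending.
_STREAMS = (
    "geography",
    "pools",
    "incidence",
    "taxonomy",
    "areal",
    "endemics",
    "decay",
    "environment",
    "elevation",
    "cultivated",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic flora generator.

    Defaults describe the reference condition used throughout the test
    suite: 5 regions x 8 reserves, a 2000-species pool, within-region
    species overlap 0.7 vs 0.2 between regions, 15 areal types, 6 geographic
    components with a 500 km decay length, and 372 cultivated species.
    """

    n_regions: int = 5
    reserves_per_region: int = 8
    species_pool_size: int = 2000
    within_region_overlap: float = 0.7
    between_region_overlap: float = 0.2
    species_per_genus: int = 5
    genera_per_family: int = 8
    n_areal_types: int = 15
    n_components: int = 6
    n_endemic_genera: int = 89
    origin_centers: dict = field(default_factory=lambda: dict(DEFAULT_ORIGINS))
    decay_length_km: float = 500.0
    #: per-variable separation of adjacent region means, in noise-SD units
    env_effects: dict = field(
        default_factory=lambda: {
            "precip_current": 2.0,
            "precip_lgm": 1.8,
            "tmean_current": 0.8,
            "tmean_lgm": 0.7,
            "tcoldq_current": 1.2,
            "tcoldq_lgm": 1.1,
            "twarmq_current": 0.5,
            "twarmq_lgm": 0.4,
        }
    )
    elev_within_spread_m: float = 600.0
    elev_between_offset_m: float = 1500.0
    n_cultivated: int = 372
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.between_region_overlap <= self.within_region_overlap <= 1):
            raise DomainError(
                "require 0 <= between_region_overlap <= within_region_overlap <= 1"
            )
        for name, v in (
            ("n_regions", self.n_regions),
            ("reserves_per_region", self.reserves_per_region),
            ("species_pool_size", self.species_pool_size),
            ("species_per_genus", self.species_per_genus),
            ("genera_per_family", self.genera_per_family),
            ("n_areal_types", self.n_areal_types),
            ("n_components", self.n_components),
        ):
            if v <= 0:
                raise DomainError(f"{name} must be positive, got {v}")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth."""

    occurrences: OccurrenceTable
    components: ComponentTable
    meta: ReserveMeta
    truth: dict


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    return {
        name: np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        for i, name in enumerate(_STREAMS)
    }


def _taxonomy(n_species: int, prefix: str, start_genus: int, cfg: GeneratorConfig):
    """Sequential species -> genus -> family nesting within one pool block."""
    names, genera, families = [], [], []
    for i in range(n_species):
        g = start_genus + i // cfg.species_per_genus
        names.append(f"{prefix}_g{g:04d} sp{i % cfg.species_per_genus + 1}")
        genera.append(f"{prefix}_g{g:04d}")
        families.append(f"fam{g // cfg.genera_per_family:03d}")
    n_genera = (n_species + cfg.species_per_genus - 1) // cfg.species_per_genus
    return names, genera, families, start_genus + n_genera


def generate(cfg: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset, reproducible from ``cfg.seed``."""
    cfg = cfg or GeneratorConfig()
    rng = _rngs(cfg.seed)
    lon_min, lon_max, lat_min, lat_max = _FRAME
    R, per = cfg.n_regions, cfg.reserves_per_region
    n_res = R * per
    reserves = [f"R{r + 1}_{i + 1:02d}" for r in range(R) for i in range(per)]
    region_of = np.repeat(np.arange(R), per)

    # --- geography: regions occupy west-to-east longitude bands -------------
    band = (lon_max - lon_min) / R
    lons = np.empty(n_res)
    lats = np.empty(n_res)
    g = rng["geography"]
    for idx, r in enumerate(region_of):
        lons[idx] = lon_min + band * r + g.uniform(0.15, 0.85) * band
        lats[idx] = g.uniform(lat_min + 0.5, lat_max - 0.5)

    # --- species pools ------------------------------------------------------
    p_in = cfg.within_region_overlap
    shared_frac = (
        cfg.between_region_overlap / cfg.within_region_overlap if p_in > 0 else 0.0
    )
    pool = cfg.species_pool_size // R
    n_shared = int(round(shared_frac * pool))
    n_core = pool - n_shared

    next_genus = 0
    core_species: list[list] = []
    core_tax: dict[str, tuple[str, str]] = {}
    for r in range(R):
        names, genera, families, next_genus = _taxonomy(n_core, f"reg{r + 1}", next_genus, cfg)
        core_species.append(names)
        core_tax.update(dict(zip(names, zip(genera, families))))
    sh_names, sh_genera, sh_families, next_genus = _taxonomy(n_shared, "shared", next_genus, cfg)
    shared_tax = dict(zip(sh_names, zip(sh_genera, sh_families)))
    taxonomy = {**core_tax, **shared_tax}

    # --- areal types: 5 common codes + 2 region-private codes per region ----
    # (region-private rare types are what make areal-type incidence
    # informative about regions; with only common codes every reserve would
    # hold the full vocabulary)
    n_common = min(5, cfg.n_areal_types)
    common_types = [f"T{i + 1:02d}" for i in range(n_common)]
    n_private = cfg.n_areal_types - n_common
    private_types = [f"T{n_common + i + 1:02d}" for i in range(n_private)]
    region_private = {
        r: [private_types[(2 * r + j) % n_private] for j in range(2)] if n_private else []
        for r in range(R)
    }
    ar = rng["areal"]
    genus_areal: dict[str, str] = {}
    for r in range(R):
        for name in core_species[r]:
            genus = taxonomy[name][0]
            if genus not in genus_areal:
                if region_private[r] and ar.random() < 0.5:
                    genus_areal[genus] = str(ar.choice(region_private[r]))
                else:
                    genus_areal[genus] = str(ar.choice(common_types))
    for name in sh_names:
        genus = taxonomy[name][0]
        if genus not in genus_areal:
            genus_areal[genus] = str(ar.choice(common_types))

    # --- endemic genera and components -------------------------------------
    en = rng["endemics"]
    all_genera = sorted({gn for gn, _ in taxonomy.values()})
    n_end = min(cfg.n_endemic_genera, len(all_genera))
    endemic_genera = set(en.choice(all_genera, size=n_end, replace=False))
    comp_names = list(cfg.origin_centers)[: cfg.n_components]
    genus_component = {
        gn: comp_names[i % len(comp_names)]
        for i, gn in enumerate(sorted(endemic_genera))
    }

    # --- incidence ----------------------------------------------------------
    inc = rng["incidence"]
    dec = rng["decay"]
    records = []
    for idx in range(n_res):
        r = int(region_of[idx])
        pool_names = core_species[r] + sh_names
        present = [s for s in pool_names if inc.random() < p_in] if p_in > 0 else []
        if not present:  # occupancy so low the reserve came up empty
            present = [pool_names[int(inc.integers(len(pool_names)))]]
        for s in present:
            genus, family = taxonomy[s]
            endemic = genus in endemic_genera
            if endemic:
                comp = genus_component[genus]
                olon, olat = cfg.origin_centers[comp]
                d = float(haversine_km(lons[idx], lats[idx], olon, olat))
                keep = np.exp(-d / cfg.decay_length_km) if cfg.decay_length_km > 0 else 1.0
                if dec.random() >= keep:
                    continue
            records.append(
                (
                    reserves[idx],
                    s,
                    genus,
                    family,
                    genus_areal[genus],
                    endemic,
                    False,
                )
            )

    # --- cultivated block ---------------------------------------------------
    cu = rng["cultivated"]
    for i in range(cfg.n_cultivated):
        genus = f"cult_g{i // cfg.species_per_genus:04d}"
        family = f"cultfam{i // (cfg.species_per_genus * cfg.genera_per_family):03d}"
        species = f"{genus} sp{i % cfg.species_per_genus + 1}"
        hosts = cu.choice(n_res, size=int(cu.integers(1, 4)), replace=False)
        for h in hosts:
            records.append((reserves[h], species, genus, family, str(cu.choice(common_types)), False, True))

    df = pd.DataFrame(
        records,
        columns=["reserve_id", "species", "genus", "family", "areal_type", "endemic", "cultivated"],
    )
    df = df.drop_duplicates(subset=["reserve_id", "species"])
    # canonical order: reserve blocks in generation order, species sorted within
    order = {r: i for i, r in enumerate(reserves)}
    df = df.sort_values(
        ["reserve_id", "species"],
        key=lambda s: s.map(order) if s.name == "reserve_id" else s,
        kind="mergesort",
    )
    occurrences = OccurrenceTable(df.reset_index(drop=True))

    # --- component table ----------------------------------------------------
    comp_rows = [
        {
            "genus": gn,
            "species": "",
            "component": comp,
            "origin_lon": cfg.origin_centers[comp][0],
            "origin_lat": cfg.origin_centers[comp][1],
        }
        for gn, comp in sorted(genus_component.items())
    ]
    components = ComponentTable(
        pd.DataFrame(
            comp_rows, columns=["genus", "species", "component", "origin_lon", "origin_lat"]
        )
    )

    # --- environment & elevation -------------------------------------------
    env = rng["environment"]
    base_level = {
        "precip_current": (800.0, 80.0),
        "precip_lgm": (600.0, 80.0),
        "tmean_current": (12.0, 1.5),
        "tmean_lgm": (6.0, 1.5),
        "tcoldq_current": (0.0, 1.5),
        "tcoldq_lgm": (-8.0, 1.5),
        "twarmq_current": (22.0, 1.5),
        "twarmq_lgm": (16.0, 1.5),
    }
    env_data = {}
    for var in ENV_VARIABLES:
        mu0, sd = base_level[var]
        effect = cfg.env_effects.get(var, 0.0)
        means = mu0 + np.arange(R) * effect * sd
        env_data[var] = means[region_of] + env.normal(0.0, sd, size=n_res)

    el = rng["elevation"]
    base_region = 300.0 + np.arange(R) * cfg.elev_between_offset_m
    elev_base = base_region[region_of] + el.uniform(0, cfg.elev_within_spread_m, n_res)
    elev_mean = elev_base + el.uniform(350, 450, n_res)
    elev_peak = elev_mean + el.uniform(450, 550, n_res)

    meta_df = pd.DataFrame(
        {
            "lon": lons,
            "lat": lats,
            "elev_base": elev_base,
            "elev_mean": elev_mean,
            "elev_peak": elev_peak,
            **env_data,
        },
        index=pd.Index(reserves, name="reserve_id"),
    )
    meta = ReserveMeta(meta_df)

    truth = {
        "region_labels": pd.Series(region_of + 1, index=reserves, name="region"),
        "decay_length_km": cfg.decay_length_km,
        "origin_centers": dict(cfg.origin_centers),
        "genus_component": genus_component,
        "config": cfg,
    }
    return SyntheticDataset(occurrences, components, meta, truth)


# ---------------------------------------------------------------------------
# Canned micro-datasets for unit tests and worked examples
# ---------------------------------------------------------------------------

FIXTURES = ("tiny", "table1_like", "decay_demo", "null_env")

#: Component counts of the ``table1_like`` fixture: seven components over 89
#: endemic genera, matching a published regional flora's composition.
_TABLE1_COUNTS = {
    "Central-East China": 41,
    "Southwest China": 24,
    "North China": 8,
    "Northwest China": 6,
    "Qinling": 3,
    "South China": 1,
    "Uncertain": 6,
}


def make_fixture(name: str, seed: int = 0) -> SyntheticDataset:
    """Deterministic micro-datasets for tests and demos.

    ``tiny``
        3 reserves, 10 species; fast smoke-test input.
    ``table1_like``
        89 synthetic endemic genera distributed over components with counts
        (41, 24, 8, 6, 3, 1, 6); ``component_summary`` on it reproduces the
        canonical proportions (46.07% for the largest component, etc.).
    ``decay_demo``
        Strong exponential distance decay (500 km length) for gradient tests.
    ``null_env``
        Environmental variables independent of region membership, for null
        calibration of the group tests.
    """
    if name == "tiny":
        cfg = GeneratorConfig(
            n_regions=3,
            reserves_per_region=1,
            species_pool_size=12,
            within_region_overlap=0.9,
            between_region_overlap=0.3,
            species_per_genus=2,
            genera_per_family=2,
            n_endemic_genera=3,
            n_cultivated=2,
            seed=seed,
        )
        return generate(cfg)
    if name == "table1_like":
        return _table1_like(seed)
    if name == "decay_demo":
        cfg = GeneratorConfig(decay_length_km=500.0, seed=seed)
        return generate(cfg)
    if name == "null_env":
        cfg = GeneratorConfig(
            env_effects={v: 0.0 for v in ENV_VARIABLES}, seed=seed
        )
        return generate(cfg)
    raise DomainError(f"unknown fixture {name!r}; choose from {FIXTURES}")


def _table1_like(seed: int) -> SyntheticDataset:
    """89 endemic genera with fixed per-component counts, over 10 reserves."""
    base = generate(
        GeneratorConfig(
            n_regions=5,
            reserves_per_region=2,
            species_pool_size=300,
            n_endemic_genera=0,
            n_cultivated=0,
            seed=seed,
        )
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    reserves = base.meta.df.index.tolist()
    records = list(base.occurrences.df.itertuples(index=False, name=None))
    comp_rows = []
    origins = dict(DEFAULT_ORIGINS)
    origins["Uncertain"] = (110.0, 31.0)
    gidx = 0
    for comp, n_genera in _TABLE1_COUNTS.items():
        for _ in range(n_genera):
            genus = f"end_g{gidx:03d}"
            family = f"endfam{gidx // 8:03d}"
            species = f"{genus} sp1"
            hosts = rng.choice(len(reserves), size=int(rng.integers(1, 5)), replace=False)
            for h in hosts:
                records.append((reserves[h], species, genus, family, "T01", True, False))
            if comp != "Uncertain":  # unlisted genera must default to Uncertain
                comp_rows.append(
                    {
                        "genus": genus,
                        "species": "",
                        "component": comp,
                        "origin_lon": origins[comp][0],
                        "origin_lat": origins[comp][1],
                    }
                )
            gidx += 1
    df = pd.DataFrame(
        records,
        columns=["reserve_id", "species", "genus", "family", "areal_type", "endemic", "cultivated"],
    ).drop_duplicates(subset=["reserve_id", "species"])
    occurrences = OccurrenceTable(df.reset_index(drop=True))
    components = ComponentTable(pd.DataFrame(comp_rows))
    truth = dict(base.truth)
    truth["component_counts"] = dict(_TABLE1_COUNTS)
    return SyntheticDataset(occurrences, components, base.meta, truth)
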