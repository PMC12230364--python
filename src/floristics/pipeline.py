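"""End-to-end orchestration: read/validate -> similarity -> regionalize ->
component dispersal -> environmental drivers, with a reproducibility manifest.

Everything that can affect results lives in :class:`RunConfig` (serialized
and hashed into the manifest); command-line flags only select stages and
paths.  Given identical inputs, config, and seed, a run writes byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dispersal import (
    assign_components,
    component_counts,
    component_summary,
    export_component_map,
    gradient_test,
    write_geojson,
)
from .drivers import elevation_report, importance, region_tests
from .io import (
    ComponentTable,
    OccurrenceTable,
    ReserveMeta,
    filter_cultivated,
    read_components,
    read_occurrences,
    read_reserves,
    richness_summary,
    to_presence,
)
from .regionalize import regionalize, to_newick, upgma_linkage
from .similarity import (
    DEFAULT_LEVEL_COEFFICIENTS,
    similarity_matrix,
    to_distance,
    write_matrix,
)
from .synth import GeneratorConfig, generate

__all__ = ["RunConfig", "RunReport", "run_all"]

log = logging.getLogger("floristics")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a pipeline run.

    ``occurrences``/``components``/``reserves`` are CSV paths; leave them
    ``None`` to run on a synthetic dataset generated from ``seed``.  The
    default level -> coefficient map pairs species with Sørensen, genus with
    the Szymkiewicz overlap, and areal type with Jaccard.
    """

    occurrences: str | None = None
    components: str | None = None
    reserves: str | None = None
    level_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_COEFFICIENTS)
    )
    k_range: tuple[int, int] = (2, 10)
    linkage: str = "average"
    n_perm: int = 999
    n_trees: int = 500
    n_repeats: int = 100
    seed: int = 0
    outdir: str = "floristics_out"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["k_range"] = list(d["k_range"])
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        if "k_range" in data:
            data = {**data, "k_range": tuple(data["k_range"])}
        return cls(**data)


@dataclass
class RunReport:
    """Manifest of a completed run: stages, artifact paths, config hash."""

    stages: list[dict]
    files: list[str]
    config_hash: str
    seed: int
    outdir: str

    def manifest(self) -> dict:
        return {
            "package": "floristics",
            "version": __version__,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
            "files": sorted(self.files),
        }


def _load_inputs(cfg: RunConfig):
    if cfg.occurrences is None:
        ds = generate(GeneratorConfig(seed=cfg.seed))
        return ds.occurrences, ds.components, ds.meta
    occ = read_occurrences(cfg.occurrences)
    comp = read_components(cfg.components) if cfg.components else None
    meta = read_reserves(cfg.reserves) if cfg.reserves else None
    return occ, comp, meta


def run_all(cfg: RunConfig) -> RunReport:
    """Execute the whole pipeline and write all artifacts under ``cfg.outdir``.

    Any stage error aborts the run with a stage-named message; files already
    written are listed in a ``PARTIAL`` marker next to the manifest.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    files: list[str] = []

    def _write(frame: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        frame.to_csv(path, **kw)
        files.append(name)

    stage = "flora_io"
    try:
        occ, comp, meta = _load_inputs(cfg)
        occ, n_removed = filter_cultivated(occ)
        (out / "validation_report.json").write_text(occ.report.to_json() + "\n")
        files.append("validation_report.json")
        _write(richness_summary(occ, by_reserve=True), "richness_by_reserve.csv")
        stages.append(
            {"stage": stage, "records": len(occ), "cultivated_species_removed": n_removed}
        )

        stage = "similarity"
        distances = {}
        for level, coefficient in cfg.level_coefficients.items():
            pm = to_presence(occ, level)
            sim = similarity_matrix(pm, coefficient)
            dist = to_distance(sim)
            write_matrix(dist, out / f"distance_{level}.csv")
            files += [f"distance_{level}.csv", f"distance_{level}.csv.json"]
            distances[level] = dist
        stages.append({"stage": stage, "levels": list(distances)})

        stage = "regionalize"
        lon = meta.df["lon"] if meta is not None else None
        assignment = regionalize(distances, cfg.k_range, cfg.linkage, lon=lon)
        _write(assignment.labels.to_frame(), "regions.csv", index_label="reserve_id")
        _write(
            assignment.consensus.values, "consensus_matrix.csv", index_label="reserve_id"
        )
        _write(assignment.k_diagnostics, "k_diagnostics.csv", index=False)
        for level, lab in assignment.per_level_labels.items():
            _write(lab.to_frame(), f"labels_{level}.csv", index_label="reserve_id")
        tree = upgma_linkage(assignment.consensus.to_distance().values.to_numpy())
        (out / "consensus_tree.nwk").write_text(
            to_newick(tree, assignment.reserves) + "\n"
        )
        files.append("consensus_tree.nwk")
        stages.append({"stage": stage, "k": assignment.k, "per_level_k": assignment.per_level_k})

        stage = "endemic_dispersal"
        gradients = []
        if comp is not None:
            ann = assign_components(occ, comp)
            _write(component_summary(ann), "component_summary.csv", index=False)
            cm = component_counts(ann, reserves=occ.reserves)
            _write(cm.counts, "component_counts.csv")
            if meta is not None:
                origins = {c: comp.origin_of(c) for c in comp.components}
                for c, origin in origins.items():
                    res = gradient_test(
                        cm, meta, c, origin, n_perm=cfg.n_perm, seed=cfg.seed
                    )
                    gradients.append(dataclasses.asdict(res))
                _write(pd.DataFrame(gradients), "gradients.csv", index=False)
                write_geojson(
                    export_component_map(cm, meta, origins), out / "component_map.geojson"
                )
                files.append("component_map.geojson")
        stages.append({"stage": stage, "n_gradients": len(gradients)})

        stage = "env_drivers"
        if meta is not None:
            meta_aligned = meta.align_to(assignment.reserves)
            imp = importance(
                meta_aligned.require_env(),
                assignment.labels.to_numpy(),
                n_trees=cfg.n_trees,
                n_repeats=cfg.n_repeats,
                seed=cfg.seed,
            )
            _write(imp.ranked(), "importance.csv", index=False)
            _write(region_tests(meta, assignment), "region_tests.csv", index=False)
            elevation_report(meta, assignment).write(out / "elevation_report")
            files += ["elevation_report.csv", "elevation_report.json"]
        stages.append({"stage": stage, "ran": meta is not None})
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        (out / "PARTIAL").write_text(
            json.dumps({"failed_stage": stage, "files": sorted(files)}) + "\n"
        )
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    report = RunReport(
        stages=stages,
        files=files,
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        outdir=str(out),
    )
    (out / "manifest.json").write_text(
        json.dumps(report.manifest(), sort_keys=True, indent=2) + "\n"
    )
    for s in stages:
        log.info("stage complete: %s", s)
    return report
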