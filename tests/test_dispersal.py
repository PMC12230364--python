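"""Component assignment, Table-style summaries, and distance-decay gradients."""

import json

import numpy as np
import pandas as pd
import pytest

from floristics.dispersal import (
    ComponentCountMatrix,
    EARTH_RADIUS_KM,
    UNCERTAIN,
    assign_components,
    component_counts,
    component_summary,
    export_component_map,
    gradient_test,
    haversine_km,
    write_geojson,
)
from floristics.exceptions import DomainError
from floristics.io import ComponentTable, ReserveMeta
from floristics.synth import make_fixture

from conftest import make_table


def _component_table(rows):
    return ComponentTable(
        pd.DataFrame(rows, columns=["genus", "species", "component", "origin_lon", "origin_lat"])
    )


@pytest.fixture
def annotated(toy_table):
    comp = _component_table(
        [
            ("Biondia", "", "Southwest China", 102.0, 29.0),
            ("Biondia", "Biondia chinensis", "Qinling", 108.0, 34.0),
        ]
    )
    return assign_components(toy_table, comp)


class TestAssignComponents:
    def test_genus_level_label_applies_to_all_species(self, toy_table):
        comp = _component_table([("Biondia", "", "Southwest China", 102.0, 29.0)])
        ann = assign_components(toy_table, comp)
        row = ann.loc[ann["species"] == "Biondia chinensis"].iloc[0]
        assert row["component"] == "Southwest China"

    def test_species_override_wins(self, annotated):
        # a genus of Sichuan origin whose one species arose in the Qinling
        row = annotated.loc[annotated["species"] == "Biondia chinensis"].iloc[0]
        assert row["component"] == "Qinling"

    def test_unlisted_endemic_genus_is_uncertain(self, annotated):
        row = annotated.loc[annotated["species"] == "Taihangia rupestris"].iloc[0]
        assert row["component"] == UNCERTAIN

    def test_non_endemic_records_stay_unlabeled(self, annotated):
        assert (annotated.loc[~annotated["endemic"], "component"] == "").all()

    def test_non_endemic_genus_in_table_warns(self, toy_table):
        comp = _component_table([("Acer", "", "North China", 114.0, 37.0)])
        with pytest.warns(UserWarning, match="Acer"):
            assign_components(toy_table, comp)


class TestComponentSummary:
    def test_reference_counts_give_published_proportions(self):
        """Counts (41, 24, 8, 6, 3, 1, 6) over 89 genera -> 46.07%, 26.97%,
        8.99%, 6.74%, 3.37%, 1.12%, 6.74%."""
        ds = make_fixture("table1_like")
        ann = assign_components(ds.occurrences, ds.components)
        out = component_summary(ann).set_index("component")
        assert out.loc["Central-East China", "n_genera"] == 41
        expected = {
            "Central-East China": 46.07,
            "Southwest China": 26.97,
            "North China": 8.99,
            "Northwest China": 6.74,
            "Qinling": 3.37,
            "South China": 1.12,
            UNCERTAIN: 6.74,
        }
        for comp, pct in expected.items():
            assert out.loc[comp, "proportion_pct"] == pytest.approx(pct, abs=0.005)
        assert out["n_genera"].sum() == 89

    def test_single_component_is_100(self, toy_table):
        comp = _component_table(
            [("Biondia", "", "Qinling", 108.0, 34.0), ("Taihangia", "", "Qinling", 108.0, 34.0)]
        )
        out = component_summary(assign_components(toy_table, comp))
        assert out["proportion_pct"].tolist() == [100.0]

    def test_proportions_sum_to_100(self, annotated):
        out = component_summary(annotated)
        assert out["proportion_pct"].sum() == pytest.approx(100.0, abs=0.05)


class TestComponentCounts:
    def test_hand_counted_matrix(self):
        table = make_table(
            [
                ("A", "G1 a", "G1", "F", "T01", True, False),
                ("A", "G2 b", "G2", "F", "T01", True, False),
                ("B", "G2 b", "G2", "F", "T01", True, False),
                ("B", "G3 c", "G3", "F", "T01", True, False),
            ]
        )
        comp = _component_table(
            [
                ("G1", "", "East", 115.0, 33.0),
                ("G2", "", "East", 115.0, 33.0),
                ("G3", "", "West", 103.0, 33.0),
            ]
        )
        cm = component_counts(assign_components(table, comp))
        assert cm.counts.loc["A", "East"] == 2
        assert cm.counts.loc["A", "West"] == 0
        assert cm.counts.loc["B", "East"] == 1  # shared genus counts once per reserve
        assert cm.counts.loc["B", "West"] == 1

    def test_row_sums_equal_distinct_endemic_genera(self, annotated):
        cm = component_counts(annotated)
        end = annotated.loc[annotated["endemic"]]
        for r in cm.reserves:
            expected = end.loc[end["reserve_id"] == r, "genus"].nunique()
            assert cm.counts.loc[r].sum() == expected

    def test_proportion_rows_sum_to_one(self):
        ds = make_fixture("table1_like")
        cm = component_counts(assign_components(ds.occurrences, ds.components))
        props = cm.proportions.sum(axis=1)
        nonzero = cm.counts.sum(axis=1) > 0
        assert np.allclose(props[nonzero], 1.0)


class TestHaversine:
    def test_agrees_with_law_of_cosines_oracle(self, rng):
        for _ in range(200):
            lon1, lon2 = rng.uniform(102, 116, 2)
            lat1, lat2 = rng.uniform(29, 37, 2)
            d = haversine_km(lon1, lat1, lon2, lat2)
            p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
            cosarg = np.clip(
                np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(l2 - l1), -1, 1
            )
            oracle = EARTH_RADIUS_KM * np.arccos(cosarg)
            assert abs(d - oracle) < 1e-3  # < 1 m on regional-scale pairs

    def test_zero_distance(self):
        assert haversine_km(108.0, 33.0, 108.0, 33.0) == 0.0


def _meta_line(n=10):
    lons = np.linspace(103.0, 115.0, n)
    df = pd.DataFrame(
        {
            "lon": lons,
            "lat": np.full(n, 33.0),
            "elev_base": np.full(n, 500.0),
            "elev_mean": np.full(n, 900.0),
            "elev_peak": np.full(n, 1400.0),
        },
        index=pd.Index([f"r{i}" for i in range(n)], name="reserve_id"),
    )
    return ReserveMeta(df)


class TestGradientTest:
    def test_perfect_monotone_decay(self):
        meta = _meta_line()
        counts = pd.DataFrame(
            {"X": np.arange(10, 0, -1)}, index=meta.df.index
        )  # strictly decreasing with distance from the western origin
        res = gradient_test(ComponentCountMatrix(counts), meta, "X", (103.0, 33.0), n_perm=999, seed=0)
        assert res.rho == pytest.approx(-1.0)
        assert res.direction == "decay"
        assert res.p_perm < 0.05

    def test_constant_counts_are_flat(self):
        meta = _meta_line()
        counts = pd.DataFrame({"X": np.full(10, 3)}, index=meta.df.index)
        res = gradient_test(ComponentCountMatrix(counts), meta, "X", (103.0, 33.0), n_perm=199, seed=0)
        assert res.direction == "flat"
        assert res.p_perm == 1.0
        assert np.isnan(res.rho)

    def test_low_n_perm_rejected(self):
        meta = _meta_line()
        counts = pd.DataFrame({"X": np.arange(10)}, index=meta.df.index)
        with pytest.raises(DomainError):
            gradient_test(ComponentCountMatrix(counts), meta, "X", (103.0, 33.0), n_perm=99)

    def test_null_pvalues_superuniform(self):
        """Permutation p-values under independence: empirical CDF never
        exceeds the uniform by more than sampling noise."""
        meta = _meta_line(n=20)
        rng = np.random.default_rng(7)
        pvals = []
        for i in range(300):
            counts = pd.DataFrame({"X": rng.poisson(5.0, 20).astype(float)}, index=meta.df.index)
            res = gradient_test(
                ComponentCountMatrix(counts), meta, "X", (103.0, 33.0), n_perm=199, seed=i
            )
            pvals.append(res.p_perm)
        pvals = np.sort(pvals)
        ecdf = np.arange(1, len(pvals) + 1) / len(pvals)
        assert np.all(ecdf - pvals <= 0.08)  # super-uniform up to MC noise


class TestGeoJSONExport:
    def test_round_trip_counts(self, tmp_path):
        meta = _meta_line(n=2)
        counts = pd.DataFrame({"East": [2, 0], "West": [1, 3]}, index=meta.df.index)
        cm = ComponentCountMatrix(counts)
        fc = export_component_map(cm, meta, origins={"East": (115.0, 33.0)})
        reserve_feats = [f for f in fc["features"] if f["properties"]["role"] == "reserve"]
        origin_feats = [f for f in fc["features"] if f["properties"]["role"] == "origin"]
        assert len(reserve_feats) == 3  # zero-count cells omitted
        assert len(origin_feats) == 1
        write_geojson(fc, tmp_path / "map.geojson")
        back = json.loads((tmp_path / "map.geojson").read_text())
        assert back["type"] == "FeatureCollection"
        for f in back["features"]:
            props = f["properties"]
            if props["role"] == "reserve":
                assert props["count"] == int(counts.loc[props["reserve_id"], props["component"]])

    def test_missing_coordinates_skipped_with_warning(self):
        meta = _meta_line(n=2)
        counts = pd.DataFrame({"East": [1, 1, 1]}, index=["r0", "r1", "ghost"])
        with pytest.warns(UserWarning, match="ghost"):
            fc = export_component_map(ComponentCountMatrix(counts), meta)
        assert len(fc["features"]) == 2
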