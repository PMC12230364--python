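"""Group tests with the homogeneity gate, permutation importance, and the
elevation-difference report."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from floristics.drivers import (
    elevation_report,
    importance,
    kruskal_wallis,
    levene,
    oneway_anova,
    region_tests,
)
from floristics.exceptions import DomainError
from floristics.io import ReserveMeta
from floristics.regionalize import RegionAssignment, consensus_matrix


class TestOnewayAnova:
    def test_worked_example(self):
        """{1,2,3} vs {2,3,4}: SSB = 1.5, SSW = 4, df = (1, 4) -> F = 1.5."""
        F, p = oneway_anova([[1, 2, 3], [2, 3, 4]])
        assert F == pytest.approx(1.5, abs=1e-12)
        assert p == pytest.approx(1 - stats.f.cdf(1.5, 1, 4), abs=1e-12)

    def test_equal_groups_give_zero(self):
        F, _ = oneway_anova([[1, 2, 3], [1, 2, 3]])
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_matches_projection_oracle(self, rng):
        """F from explicit sums of squares on random data, to 1e-10."""
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(3, 8)) for _ in range(3)]
            F, _ = oneway_anova(groups)
            flat = np.concatenate(groups)
            gm = flat.mean()
            ssb = sum(len(g) * (g.mean() - gm) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            dfb, dfw = len(groups) - 1, len(flat) - len(groups)
            assert F == pytest.approx((ssb / dfb) / (ssw / dfw), abs=1e-10)

    def test_all_identical_flagged(self):
        with pytest.warns(UserWarning, match="identical"):
            F, p = oneway_anova([[2, 2], [2, 2]])
        assert np.isnan(F)


class TestKruskalWallis:
    def test_worked_example(self):
        """{1,2,3} vs {4,5,6}: rank sums (6, 15), no ties -> H = 3.857."""
        H, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert H == pytest.approx(12 / (6 * 7) * (36 / 3 + 225 / 3) - 3 * 7, abs=1e-9)
        assert H == pytest.approx(3.857, abs=5e-4)

    def test_identical_groups_give_zero(self):
        H, p = kruskal_wallis([[3, 3, 3], [3, 3, 3]])
        assert H == 0.0
        assert p == 1.0

    def test_tied_data_matches_midrank_oracle(self, rng):
        """Brute-force midrank H with tie correction, against our value."""
        for _ in range(20):
            groups = [rng.integers(0, 5, size=rng.integers(3, 8)).astype(float) for _ in range(3)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            H, _ = kruskal_wallis(groups)
            flat = np.concatenate(groups)
            ranks = stats.rankdata(flat)
            N = len(flat)
            idx = 0
            h = 0.0
            for g in groups:
                r = ranks[idx: idx + len(g)]
                h += r.sum() ** 2 / len(g)
                idx += len(g)
            h = 12 / (N * (N + 1)) * h - 3 * (N + 1)
            _, counts = np.unique(flat, return_counts=True)
            tie = 1 - np.sum(counts**3 - counts) / (N**3 - N)
            assert H == pytest.approx(h / tie, abs=1e-10)


class TestLevene:
    def test_identical_groups_give_zero(self):
        stat, _ = levene([[1, 2, 3], [1, 2, 3]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_extreme_variance_difference_detected(self):
        stat, p = levene([[0, 0, 0, 0], [-5, 5, -5, 5]])
        assert p < 0.05
        # hand oracle: |x - median| deviations are (0,0,0,0) and (5,5,5,5);
        # the one-way F on them has zero within-group variance -> infinite F
        assert stat > 1e3 or np.isinf(stat)

    def test_matches_brown_forsythe_oracle(self, rng):
        for _ in range(10):
            groups = [rng.normal(scale=s, size=8) for s in (1.0, 3.0)]
            stat, _ = levene(groups)
            devs = [np.abs(g - np.median(g)) for g in groups]
            oracle = stats.f_oneway(*devs)[0]
            assert stat == pytest.approx(oracle, rel=1e-10)

    def test_type_i_error_calibrated(self):
        """Equal-variance normal groups: rejection rate at alpha=0.05 is ~5%."""
        rng = np.random.default_rng(42)
        rej = 0
        n = 1000
        for _ in range(n):
            groups = [rng.normal(size=10) for _ in range(3)]
            _, p = levene(groups)
            rej += p < 0.05
        assert 0.03 <= rej / n <= 0.07

    def test_small_group_rejected(self):
        with pytest.raises(DomainError):
            levene([[1.0], [1, 2, 3]])


def _assignment(labels, reserves):
    labels = pd.Series(labels, index=reserves, name="region")
    cm = consensus_matrix([labels.to_numpy(), labels.to_numpy()], list(reserves))
    return RegionAssignment(
        labels=labels,
        k=labels.nunique(),
        per_level_labels={},
        per_level_k={},
        consensus=cm,
        k_diagnostics=pd.DataFrame(),
    )


def _meta(elev_by_region, labels, env=None, seed=0):
    rng = np.random.default_rng(seed)
    reserves = [f"r{i}" for i in range(len(labels))]
    base = np.array([elev_by_region[l] for l in labels], dtype=float)
    df = pd.DataFrame(
        {
            "lon": rng.uniform(102, 116, len(labels)),
            "lat": rng.uniform(29, 37, len(labels)),
            "elev_base": base,
            "elev_mean": base + 400,
            "elev_peak": base + 900,
        },
        index=pd.Index(reserves, name="reserve_id"),
    )
    for name, values in (env or {}).items():
        df[name] = values
    return ReserveMeta(df), reserves


class TestImportance:
    def test_informative_variable_ranks_first(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        y = (X["c"] > X["c"].median()).astype(int)
        res = importance(X, y, n_trees=300, n_repeats=20, seed=0)
        assert res.ranked().iloc[0]["variable"] == "c"
        assert res.table["relative_pct"].sum() == pytest.approx(100.0, abs=0.01)

    def test_noise_features_near_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("wxyz"))
        y = (X["w"] > X["w"].median()).astype(int)
        res = importance(X, y, n_trees=300, n_repeats=20, seed=1)
        noise = res.table.set_index("variable").loc[["x", "y", "z"], "raw_mda"]
        assert (noise.abs() < 0.1).all()

    def test_duplicated_informative_feature_masks(self, rng):
        """Two copies of the signal split the credit; each falls below the
        solo-feature run (the classic masking property of permutation MDA)."""
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["s", "n1", "n2"])
        y = (X["s"] > X["s"].median()).astype(int)
        solo = importance(X, y, n_trees=300, n_repeats=20, seed=2)
        solo_raw = solo.table.set_index("variable").loc["s", "raw_mda"]
        X2 = X.assign(s_copy=X["s"])
        dup = importance(X2, y, n_trees=300, n_repeats=20, seed=2)
        t = dup.table.set_index("variable")
        assert t.loc["s", "raw_mda"] < solo_raw
        assert t.loc["s_copy", "raw_mda"] < solo_raw
        assert t.loc["s", "raw_mda"] + t.loc["s_copy", "raw_mda"] > 0

    def test_single_region_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        with pytest.raises(DomainError):
            importance(X, np.zeros(10))

    def test_constant_feature_warns(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20), "k": np.ones(20)})
        y = (X["a"] > 0).astype(int)
        with pytest.warns(UserWarning, match="constant"):
            res = importance(X, y, n_trees=100, n_repeats=5, seed=0)
        k_raw = res.table.set_index("variable").loc["k", "raw_mda"]
        assert abs(k_raw) < 1e-9

    def test_column_order_equivariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = (X["b"] > 0).astype(int)
        r1 = importance(X, y, n_trees=100, n_repeats=10, seed=3)
        r2 = importance(X[["d", "c", "b", "a"]], y, n_trees=100, n_repeats=10, seed=3)
        t1 = r1.table.set_index("variable")["relative_pct"]
        t2 = r2.table.set_index("variable")["relative_pct"]
        # same seed, different column order: the top variable is stable
        assert t1.idxmax() == t2.idxmax() == "b"


class TestRegionTests:
    def test_gate_chooses_anova_for_homogeneous_groups(self):
        rng = np.random.default_rng(0)
        labels = [1] * 10 + [2] * 10
        precip = np.r_[rng.normal(600, 30, 10), rng.normal(900, 30, 10)]
        meta, reserves = _meta({1: 500, 2: 2000}, labels, env={"precip_current": precip})
        out = region_tests(meta, _assignment(labels, reserves))
        row = out.set_index("variable").loc["precip_current"]
        assert row["test_used"] == "anova"
        assert row["p_value"] < 0.01

    def test_gate_chooses_kruskal_for_heteroscedastic_groups(self):
        rng = np.random.default_rng(1)
        labels = [1] * 12 + [2] * 12
        var = np.r_[rng.normal(0, 0.5, 12), rng.normal(3, 8.0, 12)]
        meta, reserves = _meta({1: 500, 2: 2000}, labels, env={"tmean_current": var})
        out = region_tests(meta, _assignment(labels, reserves))
        row = out.set_index("variable").loc["tmean_current"]
        assert row["levene_p"] < 0.05
        assert row["test_used"] == "kruskal_wallis"

    def test_constant_variable_flagged_and_excluded(self):
        labels = [1] * 5 + [2] * 5
        meta, reserves = _meta(
            {1: 500, 2: 2000},
            labels,
            env={"flat_var": np.ones(10), "precip_current": np.r_[np.arange(5), 10 + np.arange(5)]},
        )
        out = region_tests(meta, _assignment(labels, reserves)).set_index("variable")
        assert bool(out.loc["flat_var", "constant"])
        assert np.isnan(out.loc["flat_var", "p_adjusted"])
        assert not np.isnan(out.loc["precip_current", "p_adjusted"])

    def test_null_pvalues_roughly_uniform(self):
        """With region labels independent of the variable, raw p is uniform."""
        rng = np.random.default_rng(5)
        pvals = []
        for i in range(300):
            labels = list(rng.permutation([1] * 10 + [2] * 10))
            x = rng.normal(size=20)
            meta, reserves = _meta({1: 500, 2: 2000}, labels, env={"v": x}, seed=i)
            out = region_tests(meta, _assignment(labels, reserves))
            pvals.append(out["p_value"].iloc[0])
        assert 0.02 <= np.mean(np.asarray(pvals) < 0.05) <= 0.09
        assert abs(np.mean(pvals) - 0.5) < 0.06


class TestElevationReport:
    def test_hand_pairwise_max(self):
        labels = [1, 1, 1, 2]
        meta, reserves = _meta({1: 0, 2: 5000}, labels)
        meta.df.loc[reserves[0], ["elev_base", "elev_mean", "elev_peak"]] = [100, 500, 1400]
        meta.df.loc[reserves[1], ["elev_base", "elev_mean", "elev_peak"]] = [300, 700, 1600]
        meta.df.loc[reserves[2], ["elev_base", "elev_mean", "elev_peak"]] = [800, 1200, 2100]
        rep = elevation_report(meta, _assignment(labels, reserves))
        assert rep.within_max.loc[1, "elev_base"] == 700  # {100, 300, 800}

    def test_within_between_pair_count_conservation(self):
        labels = [1] * 3 + [2] * 4 + [3] * 2
        meta, reserves = _meta({1: 300, 2: 1800, 3: 3300}, labels)
        rep = elevation_report(meta, _assignment(labels, reserves))
        n = len(labels)
        within_pairs = sum(k * (k - 1) // 2 for k in (3, 4, 2))
        assert len(rep.between["elev_base"]) == n * (n - 1) // 2 - within_pairs

    def test_planted_spread_passes_all_flags(self):
        rng = np.random.default_rng(2)
        labels = [1] * 6 + [2] * 6
        base = np.r_[300 + rng.uniform(0, 600, 6), 1800 + rng.uniform(0, 600, 6)]
        meta, reserves = _meta({1: 0, 2: 0}, labels)
        meta.df["elev_base"] = base
        meta.df["elev_mean"] = base + 400
        meta.df["elev_peak"] = base + 900
        rep = elevation_report(meta, _assignment(labels, reserves))
        assert all(rep.flags.values())
        assert rep.corridor_statement
        assert rep.exceptions == []

    def test_threshold_violation_listed_not_raised(self):
        labels = [1, 1]
        meta, reserves = _meta({1: 0}, labels)
        meta.df["elev_base"] = [0.0, 950.0]  # exceeds the 900 m base threshold
        meta.df["elev_mean"] = [400.0, 1350.0]
        meta.df["elev_peak"] = [1300.0, 2250.0]
        rep = elevation_report(meta, _assignment(labels, reserves))
        assert not rep.flags["elev_base"]
        assert any(e["variable"] == "elev_base" for e in rep.exceptions)

    def test_single_reserve_region_noted_not_crashed(self):
        labels = [1, 1, 2]
        meta, reserves = _meta({1: 300, 2: 1800}, labels)
        rep = elevation_report(meta, _assignment(labels, reserves))
        assert rep.singletons == [2]
        assert np.isnan(rep.within_max.loc[2, "elev_base"])

    def test_json_serializes(self, tmp_path):
        labels = [1, 1, 2, 2]
        meta, reserves = _meta({1: 300, 2: 1800}, labels)
        rep = elevation_report(meta, _assignment(labels, reserves))
        rep.write(tmp_path / "elev")
        assert (tmp_path / "elev.json").exists()
        assert (tmp_path / "elev.csv").exists()
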