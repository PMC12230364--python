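"""Environmental-driver importance, homogeneity-gated group tests, and the
within/between-region elevation-difference analysis.

Variable importance is the classical "mean decrease in accuracy": a bagged
ensemble of randomized decision trees classifies region membership from the
environmental features; a variable's raw importance is the drop in
out-of-bag (OOB) accuracy when its column is permuted, averaged over seeded
permutation repeats.  Negative raw importances are clipped to zero before
normalizing to percentages, matching the convention of reporting
non-negative relative importance.

Group differences per variable use a homogeneity gate: Levene's test in the
Brown–Forsythe variant (median-centered) at alpha = 0.05 decides between
classical one-way ANOVA (homogeneous variances) and the Kruskal–Wallis rank
test.  Raw p-values are Benjamini–Hochberg adjusted across variables.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .exceptions import DomainError
from .io import ReserveMeta
from .regionalize import RegionAssignment

__all__ = [
    "levene",
    "oneway_anova",
    "kruskal_wallis",
    "ImportanceResult",
    "importance",
    "region_tests",
    "ElevationReport",
    "elevation_report",
]


def _check_groups(groups, min_n: int) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < min_n:
            raise DomainError(f"group {i} has n={len(g)} < {min_n}")
    return groups


def levene(groups) -> tuple[float, float]:
    """Brown–Forsythe homogeneity-of-variance test.

    One-way F on absolute deviations from each group's median; robust to
    non-normality, which is why it gates the ANOVA/Kruskal–Wallis choice.
    """
    groups = _check_groups(groups, min_n=2)
    stat, p = stats.levene(*groups, center="median")
    return float(stat), float(p)


def oneway_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA: F = (SSB/dfB) / (SSW/dfW), p from F(dfB, dfW)."""
    groups = _check_groups(groups, min_n=2)
    flat = np.concatenate(groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ssb = sum(len(g) * (g.mean() - flat.mean()) ** 2 for g in groups)
    if ssw == 0 and ssb == 0:
        warnings.warn("all values identical; F is undefined", stacklevel=2)
        return float("nan"), float("nan")
    stat, p = stats.f_oneway(*groups)
    return float(stat), float(p)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H with midrank tie correction, p from chi-square(g-1)."""
    groups = _check_groups(groups, min_n=1)
    if sum(len(g) for g in groups) < 3:
        raise DomainError("Kruskal–Wallis requires total N >= 3")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        # all values tie: H degenerates to 0 and no group differs
        return 0.0, 1.0
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


@dataclass
class ImportanceResult:
    """Permutation (mean-decrease-in-accuracy) importances.

    ``table`` has one row per variable with ``raw_mda`` (drop in OOB
    accuracy, accuracy units) and ``relative_pct`` (negatives clipped,
    normalized to sum to 100).
    """

    table: pd.DataFrame
    baseline_oob_accuracy: float
    n_trees: int
    n_repeats: int
    seed: int

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("relative_pct", ascending=False).reset_index(drop=True)


def importance(
    features: pd.DataFrame,
    labels,
    n_trees: int = 500,
    n_repeats: int = 100,
    seed: int = 0,
    max_features: str | int | float = "sqrt",
) -> ImportanceResult:
    """Out-of-bag permutation importance of each feature for region classification.

    A forest of ``n_trees`` CART trees is grown on bootstrap samples
    (``max_features`` candidate variables per split).  Baseline accuracy is
    the OOB majority-vote accuracy; permuting variable v's column and
    re-voting measures its contribution.  The permutation is redrawn
    ``n_repeats`` times and the accuracy drops averaged.

    Raises :class:`DomainError` with fewer than two region labels; constant
    features are kept (their importance is ~0) but flagged with a warning.
    """
    X = features.to_numpy(dtype=np.float32)
    y = np.asarray(labels)
    n, p = X.shape
    if len(y) != n:
        raise DomainError("labels length must match feature rows")
    classes, y_enc = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise DomainError("importance requires at least 2 regions")
    if features.isna().any().any():
        raise DomainError("missing feature values")
    const = [c for c in features.columns if features[c].nunique() <= 1]
    if const:
        warnings.warn(f"constant feature(s): {const}; importance will be ~0", stacklevel=2)

    rng = np.random.default_rng(seed)
    trees: list[DecisionTreeClassifier] = []
    oob_masks = np.zeros((n_trees, n), dtype=bool)
    for t in range(n_trees):
        idx = rng.integers(0, n, size=n)
        oob_masks[t] = ~np.isin(np.arange(n), idx)
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y_enc[idx])
        trees.append(tree)

    n_classes = len(classes)

    def _oob_accuracy(Xe: np.ndarray) -> float:
        votes = np.zeros((n, n_classes))
        Xe = np.ascontiguousarray(Xe, dtype=np.float32)
        for t, tree in enumerate(trees):
            mask = oob_masks[t]
            if not mask.any():
                continue
            proba = np.asarray(tree.tree_.predict(Xe[mask]))
            if proba.ndim == 3:  # (n, n_outputs, n_classes) in some versions
                proba = proba[:, 0, :]
            pred = tree.classes_[np.argmax(proba, axis=1)]
            votes[np.flatnonzero(mask), pred] += 1
        covered = votes.sum(axis=1) > 0
        pred = np.argmax(votes[covered], axis=1)  # argmax ties -> smallest class
        return float(np.mean(pred == y_enc[covered]))

    baseline = _oob_accuracy(X)
    raw = np.zeros(p)
    for j in range(p):
        drops = np.empty(n_repeats)
        for r in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            drops[r] = baseline - _oob_accuracy(Xp)
        raw[j] = drops.mean()

    clipped = np.clip(raw, 0, None)
    total = clipped.sum()
    rel = 100 * clipped / total if total > 0 else np.zeros(p)
    if total == 0:
        warnings.warn("no variable improves OOB accuracy; relative importances are 0", stacklevel=2)
    table = pd.DataFrame(
        {"variable": list(features.columns), "raw_mda": raw, "relative_pct": rel}
    )
    return ImportanceResult(table, baseline, n_trees, n_repeats, seed)


def region_tests(
    meta: ReserveMeta,
    regions: RegionAssignment,
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable between-region difference tests with a homogeneity gate.

    For each variable the reserves are grouped by region; Brown–Forsythe
    Levene at ``alpha`` chooses ANOVA (p >= alpha) or Kruskal–Wallis
    (p < alpha).  Constant variables are flagged and excluded from the
    Benjamini–Hochberg adjustment.  Returns one row per variable with the
    gate p, test used, statistic, raw and adjusted p, and group means.
    """
    meta_aligned = meta.align_to(regions.reserves)
    env = meta_aligned.require_env(variables)
    labels = regions.labels
    rows = []
    for var in env.columns:
        groups = [env.loc[labels.index[labels == r], var].to_numpy() for r in sorted(labels.unique())]
        values = env[var].to_numpy()
        if np.ptp(values) == 0:
            rows.append(
                {
                    "variable": var,
                    "test_used": "none",
                    "levene_p": np.nan,
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "constant": True,
                }
            )
            continue
        lv_stat, lv_p = levene(groups)
        if lv_p >= alpha:
            stat, p = oneway_anova(groups)
            used = "anova"
        else:
            stat, p = kruskal_wallis(groups)
            used = "kruskal_wallis"
        rows.append(
            {
                "variable": var,
                "test_used": used,
                "levene_p": lv_p,
                "statistic": stat,
                "p_value": p,
                "constant": False,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    testable = ~out["constant"] & out["p_value"].notna()
    if testable.any():
        out.loc[testable, "p_adjusted"] = multipletests(
            out.loc[testable, "p_value"], method="fdr_bh"
        )[1]
    means = env.groupby(labels).mean()
    for region in means.index:
        out[f"mean_region_{region}"] = out["variable"].map(means.loc[region])
    return out


@dataclass
class ElevationReport:
    """Within- and between-region pairwise elevation differences.

    For each of base/mean/peak elevation: the maximum within-region pairwise
    absolute difference per region, the distribution of between-region
    differences, and threshold flags.  The default thresholds (900 m base,
    800 m mean, 1000 m peak within a region) encode the empirical corridor
    pattern: reserves grouped in one region sit within ~1000 m of each other
    while regions are offset by more, so a <1000 m elevation difference
    marks terrain over which floras mix freely.
    """

    within_max: pd.DataFrame  # region x variable -> max |delta| (NaN: single reserve)
    between: dict[str, np.ndarray]  # variable -> all between-region |delta|
    flags: dict[str, bool]
    exceptions: list[dict] = field(default_factory=list)
    corridor_threshold_m: float = 1000.0
    corridor_statement: bool = False
    singletons: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "within_max": {
                str(r): {v: (None if pd.isna(x) else float(x)) for v, x in row.items()}
                for r, row in self.within_max.iterrows()
            },
            "between_max": {v: float(a.max()) if len(a) else None for v, a in self.between.items()},
            "flags": self.flags,
            "exceptions": self.exceptions,
            "corridor_threshold_m": self.corridor_threshold_m,
            "corridor_statement": self.corridor_statement,
            "single_reserve_regions": self.singletons,
        }
        return json.dumps(payload, sort_keys=True)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.within_max.to_csv(path.with_suffix(".csv"), index_label="region")
        path.with_suffix(".json").write_text(self.to_json() + "\n")


_ELEV_VARS = ("elev_base", "elev_mean", "elev_peak")
_ELEV_THRESHOLDS = {"elev_base": 900.0, "elev_mean": 800.0, "elev_peak": 1000.0}


def elevation_report(
    meta: ReserveMeta,
    regions: RegionAssignment,
    thresholds: dict[str, float] | None = None,
    corridor_threshold_m: float = 1000.0,
) -> ElevationReport:
    """Pairwise |elevation difference| analysis within and between regions.

    Flags report whether every within-region pairwise difference stays below
    its threshold; violations are listed as exceptions rather than raised
    (empirically a few reserves in a topographically extreme region can
    exceed the mean-elevation threshold).  The corridor statement is emitted
    when all within-region maxima fall below ``corridor_threshold_m`` while
    the largest between-region difference reaches it.
    """
    thresholds = {**_ELEV_THRESHOLDS, **(thresholds or {})}
    meta_aligned = meta.align_to(regions.reserves)
    elev = meta_aligned.df[list(_ELEV_VARS)]
    labels = regions.labels

    region_ids = sorted(labels.unique())
    within_rows = {}
    singletons = []
    exceptions: list[dict] = []
    between: dict[str, list[float]] = {v: [] for v in _ELEV_VARS}
    for var in _ELEV_VARS:
        vals = elev[var]
        for (ra, ia), (rb, ib) in itertools.combinations(
            ((r, labels.index[labels == r]) for r in region_ids), 2
        ):
            diffs = np.abs(vals[ia].to_numpy()[:, None] - vals[ib].to_numpy()[None, :])
            between[var].extend(diffs.ravel())

    for r in region_ids:
        members = labels.index[labels == r]
        row = {}
        if len(members) < 2:
            singletons.append(int(r))
            row = {v: np.nan for v in _ELEV_VARS}
        else:
            for var in _ELEV_VARS:
                vals = elev.loc[members, var].to_numpy()
                pair_max = float(
                    max(abs(a - b) for a, b in itertools.combinations(vals, 2))
                )
                row[var] = pair_max
                thr = thresholds[var]
                if pair_max >= thr:
                    exceptions.append(
                        {"region": int(r), "variable": var, "max_diff_m": pair_max, "threshold_m": thr}
                    )
        within_rows[r] = row
    within_max = pd.DataFrame.from_dict(within_rows, orient="index")[list(_ELEV_VARS)]

    flags = {
        var: bool(
            within_max[var].dropna().lt(thresholds[var]).all()
        )
        for var in _ELEV_VARS
    }
    between_arr = {v: np.asarray(a) for v, a in between.items()}
    within_all_below = all(
        within_max[v].dropna().lt(corridor_threshold_m).all() for v in _ELEV_VARS
    )
    between_reaches = all(
        len(between_arr[v]) and between_arr[v].max() >= corridor_threshold_m
        for v in _ELEV_VARS
    )
    return ElevationReport(
        within_max=within_max,
        between=between_arr,
        flags=flags,
        exceptions=exceptions,
        corridor_threshold_m=corridor_threshold_m,
        corridor_statement=bool(within_all_below and between_reaches),
        singletons=singletons,
    )
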