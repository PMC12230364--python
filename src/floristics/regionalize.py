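"""Consensus regionalization of reserves from multi-level distance matrices.

Pipeline: each taxonomic level (species / genus / areal type) is clustered
independently by average-linkage (UPGMA) agglomeration of its distance
matrix, cut at the silhouette-best number of clusters; the three hard
labelings are fused into a co-assignment consensus matrix (entry (i, j) =
fraction of levels in which reserves i and j share a cluster); the consensus
distance ``1 - consensus`` is clustered once more and cut at its own
silhouette-best k to yield the final regions.

UPGMA is implemented here rather than taken from :mod:`scipy` for one
reason: a platform-independent tie rule.  Among equal-distance candidate
merges, the pair whose (smallest member index, largest member index) is
lexicographically smallest is merged first, so results are reproducible to
the byte regardless of BLAS or argsort internals.  Average linkage is also
the safe choice here because the Szymkiewicz distance is non-metric.  A test
cross-checks this implementation against :func:`scipy.cluster.hierarchy.linkage`
on tie-free inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .exceptions import AlignmentError, DomainError
from .similarity import DistanceMatrix

__all__ = [
    "Linkage",
    "upgma_linkage",
    "cut",
    "hcluster",
    "to_newick",
    "ConsensusMatrix",
    "consensus_matrix",
    "select_k",
    "RegionAssignment",
    "regionalize",
]

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class Linkage:
    """Full agglomeration history of a UPGMA run.

    ``merges`` is a list of (id_a, id_b, distance) triples in merge order,
    where a cluster's id is the smallest original leaf index among its
    members; ``assignments[m]`` gives each leaf's cluster id after m merges.
    """

    n: int
    merges: tuple[tuple[int, int, float], ...]
    assignments: tuple[tuple[int, ...], ...]


def upgma_linkage(D: np.ndarray) -> Linkage:
    """Average-linkage agglomeration with a deterministic tie rule.

    After merging clusters a and b, the distance from the merged cluster to
    any other cluster x is the size-weighted mean
    ``(n_a d(a,x) + n_b d(b,x)) / (n_a + n_b)`` — i.e. the unweighted average
    over all original leaf pairs (UPGMA).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise DomainError("distance matrix must be square")
    work = D.copy()
    np.fill_diagonal(work, np.inf)
    active = list(range(n))  # cluster ids = min leaf index, kept sorted
    sizes = {i: 1 for i in active}
    labels = np.arange(n)
    merges: list[tuple[int, int, float]] = []
    assignments: list[tuple[int, ...]] = []
    for _ in range(n - 1):
        # candidate pairs scanned in lexicographic (i, j) order, i < j;
        # strict '<' keeps the first (lexicographically smallest) tie winner
        best_d = np.inf
        best: tuple[int, int] = (-1, -1)
        for ai, i in enumerate(active):
            row = work[i]
            for j in active[ai + 1:]:
                d = row[j]
                if d < best_d - _TIE_EPS:
                    best_d = d
                    best = (i, j)
        i, j = best
        ni, nj = sizes[i], sizes[j]
        for x in active:
            if x in (i, j):
                continue
            new = (ni * work[i, x] + nj * work[j, x]) / (ni + nj)
            work[i, x] = work[x, i] = new
        sizes[i] = ni + nj
        del sizes[j]
        active.remove(j)
        labels[labels == j] = i
        merges.append((i, j, float(best_d)))
        assignments.append(tuple(int(v) for v in labels))
    return Linkage(n, tuple(merges), tuple(assignments))


def cut(linkage: Linkage, k: int) -> np.ndarray:
    """Labels 0..k-1 after cutting the tree at k clusters.

    Labels are canonicalized by ascending cluster id (smallest member leaf
    index), so the output is independent of merge history details.
    """
    if not (1 <= k <= linkage.n):
        raise DomainError(f"k must be in [1, {linkage.n}], got {k}")
    if k == linkage.n:
        return np.arange(linkage.n)
    # after m merges there are n - m clusters; k clusters => m = n - k merges
    ids = np.asarray(linkage.assignments[linkage.n - k - 1])
    remap = {cid: rank for rank, cid in enumerate(sorted(set(ids)))}
    return np.asarray([remap[c] for c in ids])


def hcluster(d: DistanceMatrix | np.ndarray, k: int, linkage: str = "average") -> np.ndarray:
    """Agglomerative clustering of a distance matrix cut at k clusters."""
    if linkage != "average":
        raise DomainError(f"only average linkage is supported, got {linkage!r}")
    D = d.values.to_numpy() if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    n = D.shape[0]
    if not (2 <= k <= n):
        raise DomainError(f"k must be in [2, {n}], got {k}")
    return cut(upgma_linkage(D), k)


def to_newick(linkage: Linkage, leaf_names: list[str]) -> str:
    """Serialize the agglomeration tree as Newick with merge-height branch lengths."""
    if len(leaf_names) != linkage.n:
        raise DomainError("leaf_names length must match linkage size")
    node = {i: name for i, name in enumerate(leaf_names)}
    height = {i: 0.0 for i in range(linkage.n)}
    for i, j, d in linkage.merges:
        h = d / 2.0
        left = f"{node[i]}:{h - height[i]:.6g}"
        right = f"{node[j]}:{h - height[j]:.6g}"
        node[i] = f"({left},{right})"
        height[i] = h
    return node[min(node)] + ";"


@dataclass
class ConsensusMatrix:
    """Co-assignment fractions across hard clusterings (views).

    Entry (i, j) is the fraction of views in which reserves i and j received
    the same label; with ``n_views`` hard labelings the entries take values
    in {0, 1/n_views, ..., 1}.
    """

    values: pd.DataFrame
    n_views: int

    @property
    def reserves(self) -> list[str]:
        return list(self.values.index)

    def to_distance(self) -> DistanceMatrix:
        return DistanceMatrix(1.0 - self.values, "consensus", "consensus")


def consensus_matrix(labelings: dict[str, np.ndarray] | list, reserves: list[str]) -> ConsensusMatrix:
    """Fuse hard labelings over an identical reserve set into co-assignment fractions."""
    if isinstance(labelings, dict):
        vecs = list(labelings.values())
    else:
        vecs = list(labelings)
    if len(vecs) < 2:
        raise DomainError("consensus requires at least 2 labelings")
    n = len(reserves)
    for v in vecs:
        if len(v) != n:
            raise AlignmentError(
                f"labeling length {len(v)} does not match {n} reserves"
            )
    acc = np.zeros((n, n))
    for v in vecs:
        v = np.asarray(v)
        acc += (v[:, None] == v[None, :]).astype(float)
    acc /= len(vecs)
    np.fill_diagonal(acc, 1.0)
    return ConsensusMatrix(pd.DataFrame(acc, index=reserves, columns=reserves), len(vecs))


def select_k(
    cd: DistanceMatrix,
    k_range: tuple[int, int] = (2, 10),
    linkage: str = "average",
) -> tuple[int, pd.DataFrame]:
    """Choose k by maximal mean silhouette width on the distance matrix.

    Returns the winning k (ties broken toward the smallest k) and the full
    (k, silhouette) diagnostics table.  If all off-diagonal distances are
    equal the silhouette is uninformative: the smallest k is returned with a
    warning and NaN diagnostics.
    """
    D = cd.values.to_numpy()
    n = D.shape[0]
    lo, hi = k_range
    lo = max(2, lo)
    hi = min(hi, n - 1)
    if lo > hi:
        raise DomainError(f"k_range {k_range} empty for n={n}")
    off = D[~np.eye(n, dtype=bool)]
    if np.ptp(off) < 1e-12:
        warnings.warn(
            "all pairwise distances equal; silhouette is undefined, "
            f"returning smallest k={lo}",
            stacklevel=2,
        )
        diag = pd.DataFrame({"k": range(lo, hi + 1), "silhouette": np.nan})
        return lo, diag
    tree = upgma_linkage(D)
    rows = []
    for k in range(lo, hi + 1):
        labels = cut(tree, k)
        score = silhouette_score(D, labels, metric="precomputed")
        rows.append((k, float(score)))
    diag = pd.DataFrame(rows, columns=["k", "silhouette"])
    best = int(diag.loc[diag["silhouette"].idxmax(), "k"])  # idxmax -> first max = smallest k
    return best, diag


@dataclass
class RegionAssignment:
    """Final reserve -> region labels plus all pipeline intermediates."""

    labels: pd.Series  # reserve_id -> region id (1..k)
    k: int
    per_level_labels: dict[str, pd.Series]
    per_level_k: dict[str, int]
    consensus: ConsensusMatrix
    k_diagnostics: pd.DataFrame
    per_level_diagnostics: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        used = self.labels.nunique()
        if used != self.k:
            raise DomainError(f"{used} labels used but k={self.k}")

    @property
    def reserves(self) -> list[str]:
        return list(self.labels.index)

    def groups(self) -> dict[int, list[str]]:
        return {r: list(idx) for r, idx in self.labels.groupby(self.labels).groups.items()}


def _renumber(labels: np.ndarray, reserves: list[str], lon: pd.Series | None) -> pd.Series:
    """Region ids 1..k, ordered by westernmost member longitude when known.

    Ordering by the westernmost member gives stable, interpretable ids along
    the mountain system's east-west axis; without coordinates, ids follow
    first appearance in the reserve order.
    """
    labels = np.asarray(labels)
    if lon is not None:
        lon = lon.reindex(reserves)
        order = sorted(set(labels), key=lambda c: float(lon.to_numpy()[labels == c].min()))
    else:
        order = list(dict.fromkeys(labels))
    remap = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([remap[c] for c in labels], index=reserves, name="region")


def regionalize(
    levels: dict[str, DistanceMatrix],
    k_range: tuple[int, int] = (2, 10),
    linkage: str = "average",
    lon: pd.Series | None = None,
) -> RegionAssignment:
    """Run the full consensus-regionalization pipeline.

    Parameters
    ----------
    levels
        Mapping level name -> distance matrix; all matrices must cover the
        same reserves in the same order.  Typically the three matrices are
        species/Sørensen, genus/Szymkiewicz and areal-type/Jaccard distances.
    k_range
        Inclusive range searched for the number of clusters at every stage.
    lon
        Optional reserve longitudes used to renumber final regions
        west-to-east.
    """
    if len(levels) < 2:
        raise DomainError("regionalize requires at least 2 level matrices")
    items = list(levels.items())
    reserves = items[0][1].reserves
    for name, d in items[1:]:
        if d.reserves != reserves:
            raise AlignmentError(f"level {name!r} covers a different reserve set/order")

    per_level_labels: dict[str, pd.Series] = {}
    per_level_k: dict[str, int] = {}
    per_level_diag: dict[str, pd.DataFrame] = {}
    hard = []
    for name, d in items:
        k, diag = select_k(d, k_range, linkage)
        lab = hcluster(d, k, linkage)
        per_level_labels[name] = pd.Series(lab, index=reserves, name=name)
        per_level_k[name] = k
        per_level_diag[name] = diag
        hard.append(lab)

    cons = consensus_matrix(hard, reserves)
    cdist = cons.to_distance()
    k_final, diag_final = select_k(cdist, k_range, linkage)
    final = hcluster(cdist, k_final, linkage)
    labels = _renumber(final, reserves, lon)
    return RegionAssignment(
        labels=labels,
        k=k_final,
        per_level_labels=per_level_labels,
        per_level_k=per_level_k,
        consensus=cons,
        k_diagnostics=diag_final,
        per_level_diagnostics=per_level_diag,
    )
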