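"""Incidence-based similarity coefficients and reserve x reserve matrices.

Three classical beta-diversity coefficients, each paired with a taxonomic
level in the regionalization pipeline:

* Sørensen ``2a / (2a + b + c)`` — species level,
* Szymkiewicz–Simpson overlap ``a / min(|A|, |B|)`` — genus level,
* Jaccard ``a / (a + b + c)`` — areal-type level,

where ``a`` is the number of shared taxa and ``b``, ``c`` the taxa unique to
either reserve.  For any pair of non-empty sets
``jaccard <= sorensen <= szymkiewicz``.

Similarities are converted to distances as ``d = 1 - s``.  Note that
``1 - szymkiewicz`` is not a metric (the triangle inequality can fail);
downstream clustering therefore uses average linkage and never assumes
metricity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .io import PresenceMatrix

__all__ = [
    "COEFFICIENTS",
    "DEFAULT_LEVEL_COEFFICIENTS",
    "sorensen",
    "jaccard",
    "szymkiewicz",
    "SimilarityMatrix",
    "DistanceMatrix",
    "similarity_matrix",
    "to_distance",
    "write_matrix",
    "read_matrix",
]

COEFFICIENTS = ("sorensen", "jaccard", "szymkiewicz")

#: The level -> coefficient pairing used throughout the pipeline:
#: species richness compared by Sørensen, genus composition by the
#: Szymkiewicz overlap, areal-type spectra by Jaccard.
DEFAULT_LEVEL_COEFFICIENTS = {
    "species": "sorensen",
    "genus": "szymkiewicz",
    "areal_type": "jaccard",
}


def _as_sets(A: Iterable, B: Iterable) -> tuple[set, set]:
    A, B = set(A), set(B)
    if not A or not B:
        raise DomainError("similarity of an empty taxon set is undefined")
    return A, B


def sorensen(A: Iterable, B: Iterable) -> float:
    """Sørensen similarity ``2a / (2a + b + c)`` of two non-empty taxon sets."""
    A, B = _as_sets(A, B)
    a = len(A & B)
    return 2 * a / (len(A) + len(B))


def jaccard(A: Iterable, B: Iterable) -> float:
    """Jaccard similarity ``a / (a + b + c)`` of two non-empty taxon sets."""
    A, B = _as_sets(A, B)
    a = len(A & B)
    return a / (len(A) + len(B) - a)


def szymkiewicz(A: Iterable, B: Iterable) -> float:
    """Szymkiewicz–Simpson overlap ``a / min(|A|, |B|)``.

    Saturates at 1 whenever one set is contained in the other, which makes it
    insensitive to richness differences between a species-poor and a
    species-rich reserve.
    """
    A, B = _as_sets(A, B)
    a = len(A & B)
    return a / min(len(A), len(B))


_COEFFICIENT_FUNCS = {"sorensen": sorensen, "jaccard": jaccard, "szymkiewicz": szymkiewicz}


@dataclass
class SimilarityMatrix:
    """Symmetric reserve x reserve similarity in [0, 1] with provenance.

    ``values`` is a square DataFrame indexed by reserve ids; ``coefficient``
    and ``level`` record how it was computed.
    """

    values: pd.DataFrame
    coefficient: str
    level: str

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise DomainError("similarity matrix must be square")
        if not np.allclose(v, v.T):
            raise DomainError("similarity matrix must be symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise DomainError("similarity entries must lie in [0, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = pd.DataFrame(
            np.clip(v, 0.0, 1.0), index=self.values.index, columns=self.values.index
        )

    @property
    def reserves(self) -> list[str]:
        return list(self.values.index)


@dataclass
class DistanceMatrix:
    """Symmetric reserve x reserve distance ``1 - similarity`` in [0, 1]."""

    values: pd.DataFrame
    coefficient: str
    level: str

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T):
            raise DomainError("distance matrix must be square and symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise DomainError("distance entries must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = pd.DataFrame(
            np.clip(v, 0.0, 1.0), index=self.values.index, columns=self.values.index
        )

    @property
    def reserves(self) -> list[str]:
        return list(self.values.index)

    def to_similarity(self) -> SimilarityMatrix:
        return SimilarityMatrix(1.0 - self.values, self.coefficient, self.level)


def similarity_matrix(m: PresenceMatrix, coefficient: str) -> SimilarityMatrix:
    """Pairwise similarity over the reserve rows of a presence matrix.

    Vectorized over the boolean incidence matrix: shared-taxon counts are the
    Gram matrix ``B @ B.T``; set sizes are row sums.  Agrees with pairwise
    calls of the scalar coefficients to machine precision.
    """
    if coefficient not in _COEFFICIENT_FUNCS:
        raise DomainError(f"coefficient must be one of {COEFFICIENTS}, got {coefficient!r}")
    B = m.values.to_numpy(dtype=np.int64)
    if B.shape[0] < 2:
        raise DomainError("similarity matrix requires at least 2 reserves")
    sizes = B.sum(axis=1)
    if (sizes == 0).any():
        empty = list(np.asarray(m.reserves)[sizes == 0])
        raise DomainError(f"reserve(s) with empty taxon set: {empty}")
    a = (B @ B.T).astype(float)
    si = sizes[:, None].astype(float)
    sj = sizes[None, :].astype(float)
    if coefficient == "sorensen":
        v = 2 * a / (si + sj)
    elif coefficient == "jaccard":
        v = a / (si + sj - a)
    else:  # szymkiewicz
        v = a / np.minimum(si, sj)
    v = (v + v.T) / 2  # enforce exact symmetry against fp noise
    df = pd.DataFrame(v, index=m.reserves, columns=m.reserves)
    return SimilarityMatrix(df, coefficient, m.level)


def to_distance(s: SimilarityMatrix) -> DistanceMatrix:
    """Convert similarity to distance as ``d = 1 - s``, preserving provenance."""
    return DistanceMatrix(1.0 - s.values, s.coefficient, s.level)


def write_matrix(m: SimilarityMatrix | DistanceMatrix, path: str | Path) -> None:
    """Write a square matrix as CSV with a JSON sidecar recording provenance."""
    path = Path(path)
    m.values.to_csv(path, index_label="reserve_id")
    kind = "distance" if isinstance(m, DistanceMatrix) else "similarity"
    sidecar = {"coefficient": m.coefficient, "level": m.level, "kind": kind}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, sort_keys=True) + "\n"
    )


def read_matrix(path: str | Path) -> SimilarityMatrix | DistanceMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    path = Path(path)
    values = pd.read_csv(path, index_col="reserve_id")
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cls = DistanceMatrix if meta["kind"] == "distance" else SimilarityMatrix
    return cls(values, meta["coefficient"], meta["level"])
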