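"""Metric multidimensional scaling (principal coordinate analysis) with
out-of-sample projection.

Given a square distance matrix D over n active elements, the squared
distances D2 are double-centered into the cross-product matrix

    S = -1/2 * J @ D2 @ J,      J = I - (1/n) 11'

whose eigen-decomposition S = V diag(lambda) V' yields factor scores
F = V diag(sqrt(lambda)) on the components with positive eigenvalue.
Negative eigenvalues measure how far D is from a Euclidean matrix and are
retained (signed) for variance accounting, but never used for coordinates.

A supplementary element is positioned in the active space purely from its
squared distances d2 to the n active elements:

    s_sup = -1/2 * J @ (d2 - r),     r = row means of D2
    f_sup = s_sup @ F @ diag(1/lambda)   (over retained components)

so projecting an active element's own distance column returns its row of F,
and an element equidistant from all actives lands at the origin.

All intermediaries needed for projection (row means, full spectrum, factor
scores) are kept on the :class:`MdsSpace` and survive JSON round trips, so
projection can run in a separate process from the original embedding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .distance_scoring import DistanceMatrix
from .errors import (
    InvalidDistanceMatrixError,
    SpaceMismatchError,
    TooFewElementsError,
)

#: Relative eigenvalue threshold separating true rank from floating-point
#: noise: components are retained when lambda > EIGEN_TOL * max(lambda).
EIGEN_TOL = 1e-8

_SYMMETRY_TOL = 1e-8


@dataclass
class MdsSpace:
    """An active embedding and the intermediaries needed to project onto it."""

    ids: list[str]
    eigenvalues: np.ndarray  # full signed spectrum, non-increasing
    components: np.ndarray  # eigenvectors of retained components (n x m)
    factor_scores: np.ndarray  # active coordinates (n x m)
    row_means: np.ndarray  # row means of the squared-distance matrix
    source_scoring: str = ""

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_components(self) -> int:
        return self.factor_scores.shape[1]

    @property
    def retained_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[: self.n_components]

    @property
    def total_variance(self) -> float:
        return float(np.abs(self.eigenvalues).sum())

    @property
    def component_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_components)]

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.factor_scores, index=self.ids, columns=self.component_names
        )

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "format": "seqspace.MdsSpace/1",
            "ids": self.ids,
            "eigenvalues": self.eigenvalues.tolist(),
            "components": self.components.tolist(),
            "factor_scores": self.factor_scores.tolist(),
            "row_means": self.row_means.tolist(),
            "source_scoring": self.source_scoring,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "MdsSpace":
        data = json.loads(Path(path).read_text())
        return cls(
            ids=list(data["ids"]),
            eigenvalues=np.asarray(data["eigenvalues"], dtype=float),
            components=np.asarray(data["components"], dtype=float),
            factor_scores=np.asarray(data["factor_scores"], dtype=float),
            row_means=np.asarray(data["row_means"], dtype=float),
            source_scoring=data.get("source_scoring", ""),
        )


@dataclass
class ProjectionResult:
    """Coordinates of supplementary elements in an active space."""

    ids: list[str]
    factor_scores: np.ndarray  # (k x m)
    active_ref: str = ""
    component_names: list[str] = field(default_factory=list)

    def scores_frame(self) -> pd.DataFrame:
        cols = self.component_names or [
            f"PC{i + 1}" for i in range(self.factor_scores.shape[1])
        ]
        return pd.DataFrame(self.factor_scores, index=self.ids, columns=cols)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (stable plots)."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def mmds(dist: DistanceMatrix, n_components: int | None = None) -> MdsSpace:
    """Metric MDS of a square symmetric zero-diagonal distance matrix."""
    if not dist.square:
        raise InvalidDistanceMatrixError("distance matrix must be square")
    values = dist.values
    n = values.shape[0]
    if n < 3:
        raise TooFewElementsError(f"need at least 3 elements, got {n}")
    if not np.allclose(values, values.T, atol=_SYMMETRY_TOL):
        raise InvalidDistanceMatrixError("distance matrix is not symmetric")
    if not np.allclose(np.diag(values), 0.0, atol=_SYMMETRY_TOL):
        raise InvalidDistanceMatrixError("distance matrix diagonal is not zero")

    d2 = values.astype(float) ** 2
    row_means = d2.mean(axis=1)
    # S = -1/2 J D2 J, expanded to avoid forming J explicitly
    grand = d2.mean()
    s = -0.5 * (d2 - row_means[:, None] - row_means[None, :] + grand)
    s = (s + s.T) / 2.0

    eigval, eigvec = eigh(s)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = _fix_signs(eigvec[:, order])

    top = max(eigval[0], 0.0)
    keep = eigval > EIGEN_TOL * top if top > 0 else np.zeros(n, bool)
    m = int(keep.sum())
    if n_components is not None:
        m = min(m, int(n_components))
    comps = eigvec[:, :m]
    scores = comps * np.sqrt(eigval[:m])

    return MdsSpace(
        ids=list(dist.row_ids),
        eigenvalues=eigval,
        components=comps,
        factor_scores=scores,
        row_means=row_means,
        source_scoring=dist.scoring,
    )


def project(space: MdsSpace, cross: DistanceMatrix) -> ProjectionResult:
    """Project supplementary elements (rows of ``cross``) onto ``space``.

    ``cross`` holds plain distances from each supplementary element to every
    active element, with columns matching the active ids in order.
    """
    if list(cross.col_ids) != list(space.ids):
        raise SpaceMismatchError(
            "cross-distance columns do not match the active space ids"
        )
    d2 = cross.values.astype(float) ** 2  # (k, n)
    centered = d2 - space.row_means[None, :]
    centered = centered - centered.mean(axis=1, keepdims=True)  # apply J
    s_sup = -0.5 * centered
    lam = space.retained_eigenvalues
    f_sup = s_sup @ (space.factor_scores / lam[None, :])
    return ProjectionResult(
        ids=list(cross.row_ids),
        factor_scores=f_sup,
        active_ref=space.source_scoring,
        component_names=space.component_names,
    )


def variance_summary(space: MdsSpace) -> pd.DataFrame:
    """Per-component variance shares plus the negative-eigenvalue fraction.

    The share of component i is |lambda_i| / sum_j |lambda_j| * 100; the
    frame's ``negative_fraction`` attribute reports the percentage of total
    absolute variance carried by negative eigenvalues — the departure of the
    input distances from Euclidean geometry.
    """
    lam = space.eigenvalues
    total = np.abs(lam).sum()
    share = np.abs(lam) / total * 100.0 if total > 0 else np.zeros_like(lam)
    df = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(len(lam))],
            "eigenvalue": lam,
            "pct_variance": share,
            "cumulative_pct": np.cumsum(share),
        }
    )
    df.attrs["negative_fraction"] = negative_fraction(space)
    return df


def negative_fraction(space: MdsSpace) -> float:
    """% of total absolute variance on negative eigenvalues."""
    lam = space.eigenvalues
    total = np.abs(lam).sum()
    if total == 0:
        return 0.0
    return float(np.abs(lam[lam < 0]).sum() / total * 100.0)


def distance_matrix_from_coordinates(
    points: np.ndarray, ids: Sequence[str]
) -> DistanceMatrix:
    """Distance matrix of a point configuration (convenience for callers)."""
    from scipy.spatial.distance import pdist, squareform

    values = squareform(pdist(np.asarray(points, dtype=float)))
    ids = list(ids)
    return DistanceMatrix(row_ids=ids, col_ids=ids, values=values, scoring="euclidean")
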