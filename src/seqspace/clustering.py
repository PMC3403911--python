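"""Consensus K-means on MDS factor scores, with silhouette model selection.

K-means is a stochastic algorithm: different starts can yield different
partitions.  ``kmeans_run`` therefore performs many independent fits,
reconciles their arbitrary label numberings by maximum-agreement matching
(Hungarian assignment on the run-vs-reference contingency table), reports
the most frequent matched labeling as the consensus, and attaches to every
element the fraction of runs that agree with its consensus label — a
per-element robustness measure.  ``sil_score`` averages silhouette widths
over the same kind of repeated runs to pick the number of clusters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .alignment_io import Alignment, write_fasta
from .errors import InvalidKError, InvalidRangeError, MissingIdentifierError
from .mds_core import MdsSpace

_MAX_ITER = 100


@dataclass
class ClusteringResult:
    """Consensus partition with per-element stability."""

    K: int
    ids: list[str]
    assignment: dict[str, int]  # element -> label in 1..K
    membership: dict[str, float]  # fraction of runs agreeing with consensus
    runs: int
    inertia: float  # within-cluster sum of squares of the consensus solution

    def members(self, label: int) -> list[str]:
        return [i for i in self.ids if self.assignment[i] == label]

    @property
    def labels(self) -> np.ndarray:
        return np.array([self.assignment[i] for i in self.ids])

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["element_id,cluster,membership"]
        for sid in self.ids:
            lines.append(
                f"{sid},{self.assignment[sid]},{self.membership[sid]:.4f}"
            )
        path.write_text("\n".join(lines) + "\n")
        return path


@dataclass
class SilhouetteProfile:
    """Mean silhouette width per candidate K, averaged over repeated runs."""

    scores: dict[int, float]
    runs: int
    optimal_K: int = field(init=False)

    def __post_init__(self) -> None:
        best = max(self.scores.values())
        # ties resolved toward the most parsimonious model
        self.optimal_K = min(k for k, v in self.scores.items() if v == best)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["K,mean_silhouette"]
        for k in sorted(self.scores):
            lines.append(f"{k},{self.scores[k]:.6f}")
        path.write_text("\n".join(lines) + "\n")
        return path


def _clustering_data(space: MdsSpace, components: int | None) -> np.ndarray:
    data = space.factor_scores
    if components is not None:
        if not 1 <= components <= data.shape[1]:
            raise InvalidKError(
                f"components must be in [1, {data.shape[1]}], got {components}"
            )
        data = data[:, :components]
    return data


def _single_fit(data: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, float]:
    """One stochastic K-means fit: k-means++ seeding, single start.

    k-means++ is used instead of uniform-random starts because random
    partitions place every initial center near the grand centroid, where
    Lloyd iterations often converge to merged-cluster local optima even on
    cleanly separated data; that would report spurious instability.
    """
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=1, max_iter=_MAX_ITER,
        random_state=seed % (2**32),
    )
    labels = km.fit_predict(data)
    return labels, float(km.inertia_)


def _match_labels(reference: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel ``labels`` to maximally agree with ``reference``."""
    contingency = np.zeros((k, k), dtype=np.int64)
    for r, l in zip(reference, labels):
        contingency[l, r] += 1
    row, col = linear_sum_assignment(contingency, maximize=True)
    mapping = dict(zip(row, col))
    return np.array([mapping[l] for l in labels])


def kmeans_run(
    space: MdsSpace,
    K: int,
    runs: int = 100,
    components: int | None = None,
    seed: int = 0,
) -> ClusteringResult:
    """Consensus of ``runs`` independent K-means fits on the factor scores.

    Per-run seeds are ``seed + run_index``, making the whole procedure
    deterministic for a fixed seed while keeping honest run-to-run
    variability.
    """
    data = _clustering_data(space, components)
    n = data.shape[0]
    if not 2 <= K < n:
        raise InvalidKError(f"K must satisfy 2 <= K < n={n}, got {K}")
    if runs < 1:
        raise InvalidKError(f"runs must be >= 1, got {runs}")

    all_labels = np.empty((runs, n), dtype=np.int64)
    inertias = np.empty(runs)
    for r in range(runs):
        labels, inertia = _single_fit(data, K, seed + r)
        if r > 0:
            labels = _match_labels(all_labels[0], labels, K)
        all_labels[r] = labels
        inertias[r] = inertia

    # consensus = modal matched labeling; ties broken by lowest inertia
    counter: Counter[bytes] = Counter(row.tobytes() for row in all_labels)
    top_count = max(counter.values())
    modal_keys = {key for key, c in counter.items() if c == top_count}
    best_run = min(
        (r for r in range(runs) if all_labels[r].tobytes() in modal_keys),
        key=lambda r: (inertias[r], r),
    )
    consensus = all_labels[best_run]

    agree = (all_labels == consensus[None, :]).mean(axis=0)
    # renumber labels contiguously 1..K' in order of first appearance
    relabel: dict[int, int] = {}
    for l in consensus:
        if l not in relabel:
            relabel[l] = len(relabel) + 1
    inertia = float(
        sum(
            ((data[consensus == j] - data[consensus == j].mean(axis=0)) ** 2).sum()
            for j in np.unique(consensus)
        )
    )
    return ClusteringResult(
        K=K,
        ids=list(space.ids),
        assignment={sid: relabel[l] for sid, l in zip(space.ids, consensus)},
        membership={sid: float(a) for sid, a in zip(space.ids, agree)},
        runs=runs,
        inertia=inertia,
    )


def sil_score(
    space: MdsSpace,
    K_range: range | list[int] = range(2, 9),
    runs: int = 100,
    components: int | None = None,
    seed: int = 0,
) -> SilhouetteProfile:
    """Mean silhouette width per K over repeated K-means runs."""
    data = _clustering_data(space, components)
    n = data.shape[0]
    ks = [k for k in K_range]
    if not ks:
        raise InvalidRangeError("empty K range")
    if any(not 2 <= k <= n - 1 for k in ks):
        raise InvalidRangeError(
            f"all K must lie in [2, {n - 1}] for n={n}: got {ks}"
        )
    scores: dict[int, float] = {}
    for k in ks:
        vals = np.empty(runs)
        for r in range(runs):
            labels, _ = _single_fit(data, k, seed + r)
            if len(np.unique(labels)) < 2:
                vals[r] = -1.0  # degenerate single-cluster outcome
            else:
                vals[r] = silhouette_score(data, labels)
        scores[k] = float(vals.mean())
    return SilhouetteProfile(scores=scores, runs=runs)


def cluster_to_fasta(
    result: ClusteringResult, aln: Alignment, out_dir: str | Path
) -> list[Path]:
    """One FASTA per cluster (cluster_1.fasta, ...), rows in alignment order."""
    missing = [i for i in result.ids if i not in set(aln.ids)]
    if missing:
        raise MissingIdentifierError(
            f"clustered ids absent from alignment: {missing[:5]}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label in sorted(set(result.assignment.values())):
        ids = result.members(label)
        paths.append(
            write_fasta(aln, out_dir / f"cluster_{label}.fasta", ids_subset=ids)
        )
    return paths
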