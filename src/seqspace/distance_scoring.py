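"""Distance matrices from alignments.

Three scorings are supported:

``difference``
    fraction of alignment columns at which two sequences differ.  The gap is
    treated as a 21st symbol: gap-vs-residue counts as a difference,
    gap-vs-gap as a match, and all columns enter the denominator.
``sqrt_difference``
    square root of the difference score.  Distances of this form are
    Euclidean, so the metric MDS of such a matrix has no negative eigenvalue.
``dissimilarity``
    substitution-matrix based distance for protein alignments: per column,
    the residue-pair score s(a,b) is converted to the quadratic-form distance
    delta(a,b) = s(a,a) + s(b,b) - 2 s(a,b), and the sequence distance is the
    square root of the mean of delta over columns where both sequences carry
    a standard residue (gaps and ambiguity codes are skipped).

The embedded substitution matrices are the canonical published log-odds
tables restricted to the 20 standard amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment_io import GAP, Alignment
from .errors import (
    AlignmentFrameError,
    FormatError,
    MatrixUnavailableError,
    MissingIdentifierError,
    UnsupportedScoringError,
)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Matrices with embedded data files.
AVAILABLE_MATRICES = (
    "BLOSUM30",
    "BLOSUM45",
    "BLOSUM62",
    "BLOSUM80",
    "PAM40",
    "PAM80",
    "PAM120",
    "PAM160",
    "PAM250",
    "GONNET",
    "JTT",
)

#: Recognized names for which no canonical data source is embedded.
KNOWN_UNAVAILABLE = ("JTT_TM", "PHAT")

SCORINGS = ("difference", "sqrt_difference", "dissimilarity")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric residue-pair score table over the 20 standard amino acids."""

    name: str
    alphabet: str
    scores: np.ndarray  # (20, 20), symmetric

    def score(self, a: str, b: str) -> float:
        i, j = self.alphabet.index(a), self.alphabet.index(b)
        return float(self.scores[i, j])

    def delta(self) -> np.ndarray:
        """Quadratic-form residue distance d(a,b) = s(a,a)+s(b,b)-2 s(a,b)."""
        diag = np.diag(self.scores)
        return diag[:, None] + diag[None, :] - 2.0 * self.scores


def load_matrix(name: str) -> SubstitutionMatrix:
    """Load an embedded substitution matrix by name (case-insensitive)."""
    key = name.upper().replace("-", "_")
    if key in KNOWN_UNAVAILABLE:
        raise MatrixUnavailableError(
            f"{key}: recognized matrix name, but no canonical data table is "
            f"embedded in this build; available: {', '.join(AVAILABLE_MATRICES)}"
        )
    if key not in AVAILABLE_MATRICES:
        raise MatrixUnavailableError(
            f"unknown substitution matrix {name!r}; "
            f"available: {', '.join(AVAILABLE_MATRICES)}"
        )
    text = (
        resources.files("seqspace") / "matrices" / f"{key}.txt"
    ).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    if "".join(header) != AMINO_ACIDS:
        raise FormatError(f"{key}: unexpected matrix alphabet {''.join(header)!r}")
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        rows.append([float(x) for x in parts[1:]])
    scores = np.asarray(rows, dtype=float)
    if scores.shape != (20, 20) or not np.allclose(scores, scores.T):
        raise FormatError(f"{key}: matrix data malformed")
    return SubstitutionMatrix(name=key, alphabet=AMINO_ACIDS, scores=scores)


@dataclass
class DistanceMatrix:
    """Labeled matrix of inter-sequence distances.

    Square matrices (row_ids == col_ids) are symmetric with zero diagonal;
    rectangular blocks hold supplementary-to-active distances with rows =
    supplementary elements.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    scoring: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("values shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(self.values < -1e-12):
            raise ValueError("distance matrix contains negative entries")

    @property
    def square(self) -> bool:
        return self.row_ids == self.col_ids

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.to_dataframe()
        df.index.name = "id"
        df.to_csv(path, float_format="%.10g")
        return path

    @classmethod
    def read_csv(cls, path: str | Path, scoring: str = "") -> "DistanceMatrix":
        path = Path(path)
        try:
            df = pd.read_csv(path, index_col=0)
            values = df.to_numpy(dtype=float)
        except (ValueError, pd.errors.ParserError) as exc:
            raise FormatError(f"{path}: not a numeric labeled CSV matrix ({exc})")
        return cls(
            row_ids=[str(i) for i in df.index],
            col_ids=[str(c) for c in df.columns],
            values=values,
            scoring=scoring,
        )


def _encode(rows: Sequence[str]) -> np.ndarray:
    """Alignment rows as a (n_seq, n_col) array of single characters."""
    return np.frombuffer(
        "".join(rows).encode("ascii"), dtype="S1"
    ).reshape(len(rows), -1)


def difference_score(aln: Alignment, pair: tuple[str, str]) -> float:
    """Fraction of columns at which the two named sequences differ."""
    a, b = aln.row(pair[0]), aln.row(pair[1])
    diff = sum(1 for x, y in zip(a, b) if x != y)
    return diff / len(a)


def _difference_block(rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
    """Pairwise difference scores between two encoded row sets."""
    n_col = rows_a.shape[1]
    out = np.empty((rows_a.shape[0], rows_b.shape[0]))
    for i in range(rows_a.shape[0]):
        out[i] = (rows_a[i][None, :] != rows_b).sum(axis=1) / n_col
    return out


def _dissimilarity_block(
    rows_a: np.ndarray, rows_b: np.ndarray, sub: SubstitutionMatrix
) -> np.ndarray:
    """Pairwise sqrt-mean-delta distances; invalid columns skipped per pair."""
    lut = np.full(256, -1, dtype=np.int64)
    for idx, aa in enumerate(sub.alphabet):
        lut[ord(aa)] = idx
    codes_a = lut[rows_a.view(np.uint8)]
    codes_b = lut[rows_b.view(np.uint8)]
    delta = sub.delta()
    out = np.empty((codes_a.shape[0], codes_b.shape[0]))
    for i in range(codes_a.shape[0]):
        ci = codes_a[i]
        for j in range(codes_b.shape[0]):
            cj = codes_b[j]
            valid = (ci >= 0) & (cj >= 0)
            n_valid = int(valid.sum())
            if n_valid == 0:
                out[i, j] = 0.0
                continue
            out[i, j] = np.sqrt(delta[ci[valid], cj[valid]].mean())
    return out


def _check_scoring(
    aln: Alignment, scoring: str, sub_matrix: SubstitutionMatrix | None
) -> None:
    if scoring not in SCORINGS:
        raise UnsupportedScoringError(
            f"unknown scoring {scoring!r}; choose from {', '.join(SCORINGS)}"
        )
    if scoring == "dissimilarity":
        if sub_matrix is None:
            raise UnsupportedScoringError(
                "dissimilarity scoring requires a substitution matrix"
            )
        if aln.alphabet != "protein":
            raise UnsupportedScoringError(
                "dissimilarity scoring requires a protein alphabet; "
                "use difference or sqrt_difference for nucleotide alignments"
            )


def _block(
    a: Alignment,
    b: Alignment,
    scoring: str,
    sub_matrix: SubstitutionMatrix | None,
) -> np.ndarray:
    enc_a, enc_b = _encode(a.rows), _encode(b.rows)
    if scoring == "dissimilarity":
        assert sub_matrix is not None
        return _dissimilarity_block(enc_a, enc_b, sub_matrix)
    values = _difference_block(enc_a, enc_b)
    if scoring == "sqrt_difference":
        values = np.sqrt(values)
    return values


def distance_matrix(
    aln: Alignment,
    scoring: str = "sqrt_difference",
    sub_matrix: SubstitutionMatrix | None = None,
) -> DistanceMatrix:
    """Square symmetric distance matrix over ``aln.ids`` in order."""
    _check_scoring(aln, scoring, sub_matrix)
    values = _block(aln, aln, scoring, sub_matrix)
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0  # exact symmetry against float jitter
    tag = scoring if scoring != "dissimilarity" else f"dissimilarity:{sub_matrix.name}"
    return DistanceMatrix(
        row_ids=list(aln.ids), col_ids=list(aln.ids), values=values, scoring=tag
    )


def cross_distance_matrix(
    active: Alignment,
    sup: Alignment,
    scoring: str = "sqrt_difference",
    sub_matrix: SubstitutionMatrix | None = None,
) -> DistanceMatrix:
    """Rectangular supplementary-by-active distance block.

    Entry (i, j) equals the distance ``distance_matrix`` would assign to the
    pair if both sequences were rows of a single alignment.
    """
    if active.n_col != sup.n_col:
        raise AlignmentFrameError(
            f"active has {active.n_col} columns, supplementary {sup.n_col}; "
            "the two sets must share one alignment frame"
        )
    _check_scoring(active, scoring, sub_matrix)
    values = _block(sup, active, scoring, sub_matrix)
    tag = scoring if scoring != "dissimilarity" else f"dissimilarity:{sub_matrix.name}"
    return DistanceMatrix(
        row_ids=list(sup.ids), col_ids=list(active.ids), values=values, scoring=tag
    )
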