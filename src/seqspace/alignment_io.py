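"""Reading and writing multiple sequence alignments and group annotations.

An :class:`Alignment` is an ordered set of equal-length gapped sequences; the
identifier order fixes the row/column order of every distance matrix and
embedding derived from it.  FASTA and MSF (GCG) dialects are parsed through
biopython; this module enforces the rectangular-shape and unique-identifier
contracts on top.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

from .errors import (
    AlignmentShapeError,
    AnnotationConflictError,
    DuplicateIdentifierError,
    EmptyInputError,
    FormatError,
    MissingIdentifierError,
)

GAP = "-"
#: Characters treated as gaps on input and normalized to ``-``.
_GAP_INPUT = {".", "~", "-"}

_NUCLEOTIDE_CHARS = set("ACGTUN")

#: matplotlib/X11 color names accepted in group CSV files in addition to
#: hex "#RRGGBB" tokens.  Validation is deliberately permissive: any CSS-style
#: name matplotlib resolves is accepted.
_HEX_COLOR = re.compile(r"^#[0-9A-Fa-f]{6}$")

DEFAULT_GROUP = "unknown"
DEFAULT_COLOR = "black"


def _detect_alphabet(rows: Sequence[str]) -> str:
    """Nucleotide if >= 90% of non-gap characters are in {A,C,G,T,U,N}."""
    total = 0
    nuc = 0
    for row in rows:
        for ch in row:
            if ch == GAP:
                continue
            total += 1
            if ch in _NUCLEOTIDE_CHARS:
                nuc += 1
    if total == 0:
        return "protein"
    return "nucleotide" if nuc / total >= 0.9 else "protein"


@dataclass
class Alignment:
    """Equal-length gapped sequences with order-stable unique identifiers."""

    ids: list[str]
    rows: list[str]
    alphabet: str = ""  # auto-detected when empty

    def __post_init__(self) -> None:
        if len(self.ids) == 0:
            raise EmptyInputError("alignment contains no sequences")
        if len(self.ids) != len(self.rows):
            raise AlignmentShapeError(
                f"{len(self.ids)} ids but {len(self.rows)} sequences"
            )
        seen: set[str] = set()
        for sid in self.ids:
            if sid in seen:
                raise DuplicateIdentifierError(f"duplicate identifier {sid!r}")
            seen.add(sid)
        norm = []
        width = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            row = row.upper()
            for g in _GAP_INPUT:
                if g != GAP:
                    row = row.replace(g, GAP)
            if len(row) != width:
                raise AlignmentShapeError(
                    f"sequence {sid!r} has length {len(row)}, expected {width}"
                )
            norm.append(row)
        if width == 0:
            raise AlignmentShapeError("alignment has zero columns")
        self.rows = norm
        if not self.alphabet:
            self.alphabet = _detect_alphabet(self.rows)
        if self.alphabet not in {"protein", "nucleotide"}:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    @property
    def n_seq(self) -> int:
        return len(self.ids)

    @property
    def n_col(self) -> int:
        return len(self.rows[0])

    def row(self, sid: str) -> str:
        """Sequence string for one identifier."""
        try:
            return self.rows[self.ids.index(sid)]
        except ValueError:
            raise MissingIdentifierError(f"identifier {sid!r} not in alignment")

    def subset(self, ids: Iterable[str]) -> "Alignment":
        ids = list(ids)
        return Alignment(
            ids=ids, rows=[self.row(i) for i in ids], alphabet=self.alphabet
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.ids == other.ids and self.rows == other.rows


@dataclass
class GroupAnnotation:
    """element_id -> (group, color); unmapped elements resolve to a default.

    Elements absent from the user's CSV fall into the default group
    ("unknown", plotted black), mirroring the convention of coloring
    unclassified sequences black.
    """

    mapping: dict[str, tuple[str, str]] = field(default_factory=dict)

    def resolve(self, element_id: str) -> tuple[str, str]:
        return self.mapping.get(element_id, (DEFAULT_GROUP, DEFAULT_COLOR))

    def group_of(self, element_id: str) -> str:
        return self.resolve(element_id)[0]

    def color_of(self, element_id: str) -> str:
        return self.resolve(element_id)[1]

    @property
    def groups(self) -> list[str]:
        """Distinct group names in order of first appearance."""
        out: list[str] = []
        for g, _ in self.mapping.values():
            if g not in out:
                out.append(g)
        return out


def import_fasta(path: str | Path, alphabet: str = "") -> Alignment:
    """Read an aligned FASTA file.

    Identifiers are the first whitespace-delimited token of each header;
    sequences are upper-cased and '.'/'~' gaps normalized to '-'.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    return Alignment(ids=ids, rows=rows, alphabet=alphabet)


def import_msf(path: str | Path, alphabet: str = "") -> Alignment:
    """Read a GCG/MSF alignment (interleaved blocks after a ``//`` separator).

    Checksums in the header are not enforced; biopython warns on mismatch.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyInputError(f"empty MSF file {path}")
    if "//" not in text:
        raise FormatError(f"{path}: missing '//' header separator (not MSF?)")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            msa = AlignIO.read(str(path), "msf")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    ids = [r.id for r in msa]
    rows = [str(r.seq) for r in msa]
    return Alignment(ids=ids, rows=rows, alphabet=alphabet)


def write_fasta(
    aln: Alignment,
    path: str | Path,
    ids_subset: Sequence[str] | None = None,
) -> Path:
    """Write the alignment (or a subset of its rows) as wrapped FASTA."""
    path = Path(path)
    ids = list(ids_subset) if ids_subset is not None else aln.ids
    lines = []
    for sid in ids:
        seq = aln.row(sid)  # raises MissingIdentifierError for unknown ids
        lines.append(f">{sid}")
        for start in range(0, len(seq), 60):
            lines.append(seq[start : start + 60])
    path.write_text("\n".join(lines) + "\n")
    return path


def read_groups(path: str | Path) -> GroupAnnotation:
    """Read a CSV of (element_id, group, color) rows.

    A header row is tolerated: a first row whose third field is neither a hex
    color nor a known color word is treated as a header.  Colors must be
    "#RRGGBB" or a named-color token (validated via matplotlib).
    """
    from matplotlib.colors import is_color_like

    path = Path(path)
    mapping: dict[str, tuple[str, str]] = {}
    group_colors: dict[str, str] = {}
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and any(f.strip() for f in r)]
    if not rows:
        raise EmptyInputError(f"no rows in group file {path}")
    start = 0
    first = [f.strip() for f in rows[0]]
    # header row: only plausible when data rows follow it
    if (
        len(rows) > 1
        and len(first) >= 3
        and not (_HEX_COLOR.match(first[2]) or is_color_like(first[2]))
    ):
        start = 1
    for lineno, raw in enumerate(rows[start:], start=start + 1):
        fields = [f.strip() for f in raw]
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: expected element_id,group,color"
            )
        element, group, color = fields[0], fields[1], fields[2]
        if not (_HEX_COLOR.match(color) or is_color_like(color)):
            raise FormatError(f"{path}:{lineno}: invalid color {color!r}")
        if element in mapping and mapping[element] != (group, color):
            raise AnnotationConflictError(
                f"{path}: element {element!r} annotated as both "
                f"{mapping[element]} and {(group, color)}"
            )
        if group in group_colors and group_colors[group] != color:
            raise AnnotationConflictError(
                f"{path}: group {group!r} has two colors "
                f"({group_colors[group]!r}, {color!r})"
            )
        mapping[element] = (group, color)
        group_colors[group] = color
    return GroupAnnotation(mapping=mapping)
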