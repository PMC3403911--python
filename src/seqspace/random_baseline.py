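"""Null models and synthetic alignments.

``random_alignment`` builds the noise floor of a sequence space: an
alignment with the same shape and pooled residue composition as a template,
but with every column structure destroyed.  Its MDS cloud is diffuse and
roughly isotropic, against which the anisotropy of real family data can be
judged.

``synthetic_families`` generates the opposite: an alignment structured as
well-separated clusters of mutually similar sequences, emulating paralogous
sub-families that diverged from distinct ancestors.  It is the package's
standard test bed for clustering and embedding behavior.
"""

from __future__ import annotations

import numpy as np

from .alignment_io import Alignment
from .errors import EmptyInputError

#: Approximate background amino-acid frequencies of globular proteins
#: (order ARNDCQEGHILKMFPSTWYV).  Used when no template supplies one.
_AA = "ARNDCQEGHILKMFPSTWYV"
_AA_FREQS = np.array(
    [
        0.083, 0.055, 0.041, 0.055, 0.014, 0.039, 0.067, 0.071, 0.023, 0.059,
        0.097, 0.058, 0.024, 0.039, 0.047, 0.066, 0.054, 0.011, 0.029, 0.069,
    ]
)
_AA_FREQS = _AA_FREQS / _AA_FREQS.sum()


def random_alignment(template: Alignment, seed: int = 0) -> Alignment:
    """Alignment of i.i.d. characters matching the template's shape and
    pooled character composition (gaps sampled like any other character)."""
    if template.n_seq == 0:
        raise EmptyInputError("template alignment is empty")
    pool = "".join(template.rows)
    chars, counts = np.unique(np.frombuffer(pool.encode("ascii"), "S1"), return_counts=True)
    freqs = counts / counts.sum()
    rng = np.random.default_rng(seed)
    draw = rng.choice(chars, size=(template.n_seq, template.n_col), p=freqs)
    rows = [b"".join(row).decode("ascii") for row in draw]
    ids = [f"rand_{i + 1}" for i in range(template.n_seq)]
    return Alignment(ids=ids, rows=rows, alphabet=template.alphabet)


def synthetic_families(
    n_families: int = 4,
    seqs_per_family: int = 25,
    n_col: int = 100,
    mutation_rate: float = 0.1,
    seed: int = 0,
) -> tuple[Alignment, dict[str, int]]:
    """Protein alignment of ``n_families`` clusters of similar sequences.

    Each family descends from an independent random ancestor drawn from
    background amino-acid frequencies; each member carries i.i.d. point
    substitutions at ``mutation_rate`` per column.  Expected within-family
    difference score is about ``2 * mutation_rate``; between unrelated
    families it is near 0.95, so families are well separated for any
    ``mutation_rate`` well below that.

    Returns the alignment and the generating family label (1-based) per id.
    """
    if n_families < 1 or seqs_per_family < 1 or n_col < 1:
        raise ValueError("n_families, seqs_per_family and n_col must be >= 1")
    if not 0.0 <= mutation_rate < 1.0:
        raise ValueError(f"mutation_rate must be in [0, 1), got {mutation_rate}")
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(_AA.encode("ascii"), "S1")
    ids: list[str] = []
    rows: list[str] = []
    labels: dict[str, int] = {}
    for fam in range(1, n_families + 1):
        ancestor = rng.choice(aa, size=n_col, p=_AA_FREQS)
        for member in range(1, seqs_per_family + 1):
            seq = ancestor.copy()
            mutate = rng.random(n_col) < mutation_rate
            if mutate.any():
                seq[mutate] = rng.choice(aa, size=int(mutate.sum()), p=_AA_FREQS)
            sid = f"fam{fam}_seq{member}"
            ids.append(sid)
            rows.append(b"".join(seq).decode("ascii"))
            labels[sid] = fam
    return Alignment(ids=ids, rows=rows, alphabet="protein"), labels
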