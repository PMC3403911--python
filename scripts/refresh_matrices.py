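"""Regenerate the plain-text substitution-matrix data files shipped with seqspace.

The values are the canonical published log-odds tables (Henikoff & Henikoff
BLOSUM series; Dayhoff PAM series; Gonnet 1992; Jones-Taylor-Thornton 1992),
taken from the matrix databases distributed with biotite and biopython and
restricted to the 20 standard amino acids.  Run from the repository root:

    python scripts/refresh_matrices.py
"""

from pathlib import Path

import numpy as np

AA = "ARNDCQEGHILKMFPSTWYV"
OUT = Path(__file__).resolve().parent.parent / "src" / "seqspace" / "matrices"

# name -> (source library, source key)
SOURCES = {
    "BLOSUM30": ("biotite", "BLOSUM30"),
    "BLOSUM45": ("biopython", "BLOSUM45"),
    "BLOSUM62": ("biopython", "BLOSUM62"),
    "BLOSUM80": ("biopython", "BLOSUM80"),
    "PAM40": ("biotite", "PAM40"),
    "PAM80": ("biotite", "PAM80"),
    "PAM120": ("biotite", "PAM120"),
    "PAM160": ("biotite", "PAM160"),
    "PAM250": ("biopython", "PAM250"),
    "GONNET": ("biopython", "GONNET1992"),
    "JTT": ("biopython", "JONES"),
}


def fetch(source: str, key: str) -> np.ndarray:
    if source == "biopython":
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load(key)
        return np.array([[float(m[a, b]) for b in AA] for a in AA])
    import biotite.sequence.align as ba

    d = ba.SubstitutionMatrix.dict_from_db(key)
    return np.array([[float(d[a, b]) for b in AA] for a in AA])


def write_ncbi_format(name: str, scores: np.ndarray) -> None:
    is_int = np.allclose(scores, np.round(scores))
    lines = [f"# {name} substitution matrix (20 standard amino acids)"]
    lines.append("   " + "  ".join(f"{a:>4s}" for a in AA))
    for i, a in enumerate(AA):
        if is_int:
            row = "  ".join(f"{int(round(v)):>4d}" for v in scores[i])
        else:
            row = "  ".join(f"{v:>4.1f}" for v in scores[i])
        lines.append(f"{a}  {row}")
    (OUT / f"{name}.txt").write_text("\n".join(lines) + "\n")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, (source, key) in SOURCES.items():
        scores = fetch(source, key)
        if not np.allclose(scores, scores.T):
            raise ValueError(f"{name}: source table not symmetric")
        write_ncbi_format(name, scores)
        print(f"wrote {name}.txt")


if __name__ == "__main__":
    main()
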