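"""Distance scorings, substitution matrices, and cross-distance blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqspace import (
    AVAILABLE_MATRICES,
    Alignment,
    cross_distance_matrix,
    difference_score,
    distance_matrix,
    load_matrix,
)
from seqspace.errors import (
    AlignmentFrameError,
    MatrixUnavailableError,
    MissingIdentifierError,
    UnsupportedScoringError,
)


class TestDifferenceScore:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            (("AC", "AD"), 0.5),  # 1 mismatch / 2 columns
            (("ACDE", "ACDE"), 0.0),  # identity
            (("A-", "AA"), 0.5),  # gap vs residue differs
            (("--", "--"), 0.0),  # gap vs gap matches
            (("----", "AC--"), 0.5),  # mixed, all columns in denominator
        ],
    )
    def test_gap_convention_and_basics(self, rows, expected):
        aln = Alignment(ids=["x", "y"], rows=list(rows), alphabet="protein")
        assert difference_score(aln, ("x", "y")) == expected

    def test_symmetric_and_zero_on_self(self, small_alignment):
        aln, _ = small_alignment
        a, b = aln.ids[0], aln.ids[-1]
        assert difference_score(aln, (a, b)) == difference_score(aln, (b, a))
        assert difference_score(aln, (a, a)) == 0.0

    def test_unknown_id(self, small_alignment):
        aln, _ = small_alignment
        with pytest.raises(MissingIdentifierError):
            difference_score(aln, ("nope", aln.ids[0]))

    def test_invariant_under_column_permutation(self, small_alignment):
        aln, _ = small_alignment
        rng = np.random.default_rng(0)
        perm = rng.permutation(aln.n_col)
        shuffled = Alignment(
            ids=list(aln.ids),
            rows=["".join(r[p] for p in perm) for r in aln.rows],
            alphabet=aln.alphabet,
        )
        pair = (aln.ids[0], aln.ids[-1])
        assert difference_score(aln, pair) == difference_score(shuffled, pair)


class TestSubstitutionMatrices:
    def test_all_embedded_matrices_load_symmetric(self):
        for name in AVAILABLE_MATRICES:
            m = load_matrix(name)
            assert m.scores.shape == (20, 20)
            assert np.allclose(m.scores, m.scores.T)
            # quadratic-form residue distances are non-negative with zero diagonal
            delta = m.delta()
            assert np.all(delta >= 0)
            assert np.allclose(np.diag(delta), 0)

    def test_blosum62_canonical_entries(self):
        """Spot-check against the published BLOSUM62 log-odds table."""
        m = load_matrix("BLOSUM62")
        assert m.score("A", "A") == 4
        assert m.score("R", "R") == 5
        assert m.score("A", "R") == -1
        assert m.score("W", "W") == 11
        assert m.score("C", "C") == 9

    def test_embedded_data_matches_library_reference_copies(self):
        """Embedded tables equal the canonical copies shipped with
        biotite/biopython (independent provenance check)."""
        import biotite.sequence.align as ba
        from Bio.Align import substitution_matrices as sm

        aa = "ARNDCQEGHILKMFPSTWYV"
        sources = {
            "BLOSUM30": ("biotite", "BLOSUM30"),
            "PAM120": ("biotite", "PAM120"),
            "PAM250": ("biopython", "PAM250"),
            "GONNET": ("biopython", "GONNET1992"),
            "JTT": ("biopython", "JONES"),
        }
        for name, (lib, key) in sources.items():
            mine = load_matrix(name).scores
            if lib == "biotite":
                d = ba.SubstitutionMatrix.dict_from_db(key)
                ref = np.array([[float(d[a, b]) for b in aa] for a in aa])
            else:
                m = sm.load(key)
                ref = np.array([[float(m[a, b]) for b in aa] for a in aa])
            assert np.allclose(mine, ref), name

    def test_unavailable_and_unknown_names(self):
        with pytest.raises(MatrixUnavailableError, match="JTT_TM"):
            load_matrix("JTT_TM")
        with pytest.raises(MatrixUnavailableError, match="available"):
            load_matrix("NOSUCH99")


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        aln = Alignment(ids=["a", "b"], rows=["ACDE", "ACDE"])
        for scoring in ("difference", "sqrt_difference"):
            dm = distance_matrix(aln, scoring)
            assert np.all(dm.values == 0)

    def test_sqrt_difference_closed_form(self):
        aln = Alignment(ids=["a", "b"], rows=["AC", "AD"], alphabet="protein")
        dm = distance_matrix(aln, "sqrt_difference")
        assert dm.values[0, 1] == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_dissimilarity_single_column_hand_check(self):
        """sqrt(s(A,A)+s(R,R)-2 s(A,R)) from published BLOSUM62 entries:
        sqrt(4 + 5 - 2*(-1)) = sqrt(11)."""
        aln = Alignment(ids=["a", "b"], rows=["A", "R"], alphabet="protein")
        dm = distance_matrix(aln, "dissimilarity", load_matrix("BLOSUM62"))
        assert dm.values[0, 1] == pytest.approx(np.sqrt(11.0), abs=1e-12)

    def test_dissimilarity_skips_gap_and_ambiguous_columns(self):
        # only the first column (A vs R) is scored; gap and X columns skipped
        aln = Alignment(ids=["a", "b"], rows=["A-X", "RRR"], alphabet="protein")
        dm = distance_matrix(aln, "dissimilarity", load_matrix("BLOSUM62"))
        assert dm.values[0, 1] == pytest.approx(np.sqrt(11.0), abs=1e-12)

    def test_dissimilarity_requires_protein(self):
        aln = Alignment(ids=["a", "b"], rows=["ACGT", "ACGA"])
        assert aln.alphabet == "nucleotide"
        with pytest.raises(UnsupportedScoringError):
            distance_matrix(aln, "dissimilarity", load_matrix("BLOSUM62"))

    def test_dissimilarity_requires_matrix(self, small_alignment):
        aln, _ = small_alignment
        with pytest.raises(UnsupportedScoringError):
            distance_matrix(aln, "dissimilarity")

    @pytest.mark.parametrize("scoring", ["difference", "sqrt_difference"])
    def test_symmetry_zero_diagonal_nonnegative(self, small_alignment, scoring):
        aln, _ = small_alignment
        dm = distance_matrix(aln, scoring)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)
        assert np.all(dm.values >= 0)

    def test_sqrt_relation(self, small_alignment):
        aln, _ = small_alignment
        diff = distance_matrix(aln, "difference").values
        sqrt = distance_matrix(aln, "sqrt_difference").values
        assert np.allclose(sqrt, np.sqrt(diff))

    def test_csv_round_trip(self, tmp_path, small_alignment):
        aln, _ = small_alignment
        dm = distance_matrix(aln, "sqrt_difference")
        p = dm.write_csv(tmp_path / "d.csv")
        back = type(dm).read_csv(p)
        assert back.row_ids == dm.row_ids and back.col_ids == dm.col_ids
        assert np.allclose(back.values, dm.values, atol=1e-9)


class TestCrossDistanceMatrix:
    def test_self_cross_equals_square(self, small_alignment):
        aln, _ = small_alignment
        square = distance_matrix(aln, "sqrt_difference")
        cross = cross_distance_matrix(aln, aln, "sqrt_difference")
        assert np.allclose(cross.values, square.values)

    def test_identical_supplementary_has_zero_at_its_column(self):
        active = Alignment(ids=["a", "b", "c"], rows=["AAAA", "CCCC", "DDDD"])
        sup = Alignment(ids=["s"], rows=["CCCC"])
        cross = cross_distance_matrix(active, sup, "difference")
        assert cross.values[0, 1] == 0.0
        assert np.all(cross.values[0, [0, 2]] > 0)

    @pytest.mark.parametrize("scoring", ["difference", "sqrt_difference"])
    def test_concatenate_and_slice_oracle(self, scoring):
        """Cross block equals the corresponding sub-block of the square
        matrix computed on the concatenated alignment."""
        rng = np.random.default_rng(42)
        aa = list("ACDEFGHIKLMNPQRSTVWY-")
        rows = ["".join(rng.choice(aa, 12)) for _ in range(8)]
        active = Alignment(
            ids=[f"a{i}" for i in range(5)], rows=rows[:5], alphabet="protein"
        )
        sup = Alignment(
            ids=[f"s{i}" for i in range(3)], rows=rows[5:], alphabet="protein"
        )
        joint = Alignment(
            ids=active.ids + sup.ids, rows=rows, alphabet="protein"
        )
        full = distance_matrix(joint, scoring).values
        cross = cross_distance_matrix(active, sup, scoring).values
        assert np.allclose(cross, full[5:, :5], atol=1e-12)

    def test_dissimilarity_cross_matches_oracle(self):
        rng = np.random.default_rng(7)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        rows = ["".join(rng.choice(aa, 15)) for _ in range(6)]
        active = Alignment(ids=["a0", "a1", "a2", "a3"], rows=rows[:4],
                           alphabet="protein")
        sup = Alignment(ids=["s0", "s1"], rows=rows[4:], alphabet="protein")
        joint = Alignment(ids=active.ids + sup.ids, rows=rows, alphabet="protein")
        sub = load_matrix("JTT")
        full = distance_matrix(joint, "dissimilarity", sub).values
        cross = cross_distance_matrix(active, sup, "dissimilarity", sub).values
        assert np.allclose(cross, full[4:, :4], atol=1e-12)

    def test_frame_mismatch_rejected(self):
        a = Alignment(ids=["a"], rows=["AAAA"])
        b = Alignment(ids=["b"], rows=["AAA"])
        with pytest.raises(AlignmentFrameError):
            cross_distance_matrix(a, b, "difference")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    rows=st.lists(
        st.text(alphabet="ACDEFG-", min_size=5, max_size=5),
        min_size=2,
        max_size=6,
    ),
    scoring=st.sampled_from(["difference", "sqrt_difference"]),
)
def test_metric_axioms_property(rows, scoring):
    """d(x,x)=0 and d(x,y)=d(y,x) for every scoring on arbitrary alignments."""
    aln = Alignment(
        ids=[f"s{i}" for i in range(len(rows))], rows=rows, alphabet="protein"
    )
    values = distance_matrix(aln, scoring).values
    assert np.all(np.diag(values) == 0)
    assert np.allclose(values, values.T)
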