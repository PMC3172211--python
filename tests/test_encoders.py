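import numpy as np
import pytest

from mannosite.alphabet import AA_INDEX, ALPHABET
from mannosite.encoders import (
    PssmFormatError,
    PSSMMatrix,
    encode_binary,
    encode_composition,
    encode_pssm,
    normalize_pssm,
    read_pssm,
    write_pssm,
)
from mannosite.patterns import Pattern, generate_patterns
from mannosite.sequence_io import AnnotatedSequence

PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


def pat(window, chain="c", pos=1, positive=False):
    return Pattern(window=window, positive=positive, source=(chain, pos))


class TestBinary:
    def test_single_residue_alanine_block(self):
        vec = encode_binary(pat("A"))
        assert vec.shape == (21,)
        assert vec[0] == 1 and vec.sum() == 1

    def test_all_x_window_hits_index_20(self):
        vec = encode_binary(pat("X" * 5))
        blocks = vec.reshape(5, 21)
        assert (blocks[:, 20] == 1).all() and blocks.sum() == 5

    def test_one_hot_property_window17(self):
        vec = encode_binary(pat("ACDEFGHIKLMNPQRSTVW".replace("V", "")[:17]))
        assert vec.shape == (357,)
        assert vec.sum() == 17
        assert set(np.unique(vec)) == {0.0, 1.0}
        assert (vec.reshape(17, 21).sum(axis=1) == 1).all()

    def test_order_sensitive(self):
        assert not np.array_equal(encode_binary(pat("ACD")), encode_binary(pat("CAD")))

    def test_rejects_foreign_character(self):
        with pytest.raises(ValueError):
            encode_binary(pat("A#D"))


class TestComposition:
    def test_uniform_window(self):
        vec = encode_composition(pat("A" * 17))
        assert vec[0] == 1.0 and vec.sum() == 1.0

    def test_padded_poly_a_window(self):
        seq = AnnotatedSequence("c", "A" * 30, [False] * 30)
        first = generate_patterns(seq, 17)[0]
        vec = encode_composition(first)
        assert vec[AA_INDEX["A"]] == pytest.approx(9 / 17)
        assert vec[AA_INDEX["X"]] == pytest.approx(8 / 17)

    @pytest.mark.parametrize("L", [17, 19, 21, 23, 25])
    def test_dimension_21_for_any_window(self, L):
        vec = encode_composition(pat("G" * L))
        assert vec.shape == (21,)
        assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_order_invariant(self):
        a = encode_composition(pat("ACDACDACDACDACDAC"))
        b = encode_composition(pat("".join(sorted("ACDACDACDACDACDAC"))))
        np.testing.assert_allclose(a, b)

    def test_sums_to_one_for_random_windows(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            w = "".join(rng.choice(list(ALPHABET), size=17))
            assert encode_composition(pat(w)).sum() == pytest.approx(1.0, abs=1e-9)


class TestNormalize:
    def test_zero_maps_to_half(self):
        assert normalize_pssm(0) == 0.5

    def test_limits(self):
        assert normalize_pssm(1000) == pytest.approx(1.0)
        assert normalize_pssm(-1000) == pytest.approx(0.0)

    def test_strictly_monotone_on_grid(self):
        import math

        grid = np.linspace(-20, 20, 401)
        vals = [normalize_pssm(x) for x in grid]
        direct = [1 / (1 + math.exp(-x)) for x in grid]
        np.testing.assert_allclose(vals, direct, rtol=1e-12)
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(0 <= v <= 1 for v in vals)


def toy_pssm_text(residues="ACD", scores=None):
    """Hand-built PSI-BLAST -Q style ASCII block."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted, ...",
        "            " + "  ".join(PSIBLAST_ORDER) + "   " + "  ".join(PSIBLAST_ORDER),
    ]
    for i, res in enumerate(residues):
        row = scores[i] if scores else [0] * 20
        pct = ["0"] * 20
        lines.append(
            f"{i + 1:5d} {res}  "
            + " ".join(str(s) for s in row)
            + "  " + " ".join(pct) + "  0.36 0.10"
        )
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.13     0.31"]
    return "\n".join(lines) + "\n"


class TestReadPssm:
    def test_parses_toy_fixture(self, tmp_path):
        scores = [[i - 10 for i in range(20)], [0] * 20, [3] * 20]
        f = tmp_path / "c.pssm"
        f.write_text(toy_pssm_text("ACD", scores))
        m = read_pssm(f, "c")
        assert len(m) == 3 and m.residues == "ACD"
        assert m.raw.shape == (3, 21)
        # column mapping: first PSI-BLAST column is A -> alphabet index 0
        assert m.raw[0, AA_INDEX["A"]] == -10
        assert m.raw[0, AA_INDEX["V"]] == 9  # V is the last PSI-BLAST column
        assert m.raw[0, AA_INDEX["X"]] == 0  # X slot defined as 0
        assert np.all((m.rows >= 0) & (m.rows <= 1))

    def test_all_zero_rows_normalize_to_half(self, tmp_path):
        f = tmp_path / "z.pssm"
        f.write_text(toy_pssm_text("AC"))
        m = read_pssm(f)
        np.testing.assert_allclose(m.rows, 0.5)

    def test_truncated_row_rejected(self, tmp_path):
        text = toy_pssm_text("AC")
        lines = text.splitlines()
        lines[4] = " ".join(lines[4].split()[:21])  # drop one score column
        f = tmp_path / "bad.pssm"
        f.write_text("\n".join(lines))
        with pytest.raises(PssmFormatError):
            read_pssm(f)

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        raw = np.zeros((4, 21))
        raw[:, :20] = rng.integers(-9, 10, size=(4, 20))
        m = PSSMMatrix.from_raw("r", "WYHK", raw)
        f = tmp_path / "r.pssm"
        write_pssm(m, f)
        again = read_pssm(f, "r")
        np.testing.assert_array_equal(again.raw, m.raw)
        assert again.residues == "WYHK"

    def test_minmax_normalization_bounds(self, tmp_path):
        scores = [[i - 10 for i in range(20)], [5] * 20]
        f = tmp_path / "m.pssm"
        f.write_text(toy_pssm_text("AC", scores))
        m = read_pssm(f, normalization="minmax")
        assert m.rows.min() == 0.0 and m.rows.max() == 1.0


class TestEncodePssm:
    @pytest.fixture()
    def profile(self):
        rng = np.random.default_rng(3)
        raw = np.zeros((9, 21))
        raw[:, :20] = rng.integers(-8, 9, size=(9, 20))
        return PSSMMatrix.from_raw("c", "ACDEFGHIK", raw)

    def test_dimension_and_center_row(self, profile):
        seq = AnnotatedSequence("c", profile.residues, [False] * 9)
        pats = generate_patterns(seq, 17)
        vec = encode_pssm(pats[4], profile)
        assert vec.shape == (357,)
        center_block = vec.reshape(17, 21)[8]
        np.testing.assert_allclose(center_block, profile.rows[4])

    def test_padding_rows_are_pure_x(self, profile):
        seq = AnnotatedSequence("c", profile.residues, [False] * 9)
        first = generate_patterns(seq, 17)[0]
        blocks = encode_pssm(first, profile).reshape(17, 21)
        for k in range(8):  # all padded slots
            assert blocks[k, 20] == 1.0 and blocks[k, :20].sum() == 0.0

    def test_degenerate_single_residue_chain(self):
        raw = np.zeros((1, 21))
        m = PSSMMatrix.from_raw("s", "W", raw)
        seq = AnnotatedSequence("s", "W", [True])
        (p,) = generate_patterns(seq, 17)
        blocks = encode_pssm(p, m).reshape(17, 21)
        assert (blocks[:, 20] == 1).sum() == 16
        np.testing.assert_allclose(blocks[8], m.rows[0])

    def test_chain_mismatch_rejected(self, profile):
        with pytest.raises(ValueError, match="chain"):
            encode_pssm(pat("A" * 17, chain="other", pos=1), profile)
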