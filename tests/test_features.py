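import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prrkit.features import (
    DIPEPTIDES,
    CompositionEncoder,
    ProfileCompositionEncoder,
    PssmParseError,
    PssmProfile,
    Schema,
    compute_aac,
    compute_dpc,
    compute_pssm400,
    concat_features,
    feature_frame,
    mean_composition,
    normalize_pssm,
    parse_pssm,
)
from prrkit.seqio import CANONICAL_ALPHABET, ProteinRecord
from prrkit.synthetic import generate_pssm, write_ascii_pssm

sequences = st.text(alphabet=CANONICAL_ALPHABET, min_size=2, max_size=80)


class TestAAC:
    def test_single_residue_sequence(self):
        vec = compute_aac(ProteinRecord("p", "AAAA"))
        assert vec.schema is Schema.AAC20 and len(vec.values) == 20
        assert vec.values[0] == 100.0 and vec.values[1:].sum() == 0.0

    def test_uniform_four_residues(self):
        vec = compute_aac(ProteinRecord("p", "ACDE")).values
        assert np.allclose(vec[:4], 25.0) and vec[4:].sum() == 0.0

    @given(sequences)
    def test_sums_to_100_and_is_order_invariant(self, seq):
        vec = compute_aac(ProteinRecord("p", seq)).values
        assert math.isclose(vec.sum(), 100.0, abs_tol=1e-6)
        shuffled = "".join(sorted(seq))
        assert np.allclose(vec, compute_aac(ProteinRecord("p", shuffled)).values)


class TestDPC:
    def test_single_pair_type(self):
        vec = compute_dpc(ProteinRecord("p", "AAA")).values
        assert len(vec) == 400
        assert vec[DIPEPTIDES.index("AA")] == 100.0 and vec.sum() == 100.0

    def test_overlapping_pair_counts(self):
        # ACAC has 3 overlapping pairs: AC, CA, AC
        vec = compute_dpc(ProteinRecord("p", "ACAC")).values
        assert math.isclose(vec[DIPEPTIDES.index("AC")], 200.0 / 3)
        assert math.isclose(vec[DIPEPTIDES.index("CA")], 100.0 / 3)

    def test_length_one_rejected(self):
        with pytest.raises(ValueError, match="length >= 2"):
            compute_dpc(ProteinRecord("p", "A"))

    @given(sequences)
    def test_sums_to_100(self, seq):
        assert math.isclose(
            compute_dpc(ProteinRecord("p", seq)).values.sum(), 100.0, abs_tol=1e-6
        )

    def test_sensitive_to_residue_order(self):
        a = compute_dpc(ProteinRecord("p", "ACDE")).values
        b = compute_dpc(ProteinRecord("p", "AEDC")).values
        assert not np.allclose(a, b)


class TestPssmParsing:
    def test_generated_file_round_trips(self, tmp_path):
        profile = generate_pssm(ProteinRecord("p1", "ACDEFG"), 0.8, seed=3)
        path = tmp_path / "p1.pssm"
        write_ascii_pssm(profile, path)
        back = parse_pssm(path)
        assert back.sequence == "ACDEFG"
        assert np.array_equal(back.scores, profile.scores)

    def test_columns_remapped_from_psiblast_order(self, tmp_path):
        # column for 'A' is first in both orders; 'C' is column 5 in the file
        # order ARNDCQEGHILKMFPSTWYV but must land at index 1 canonically
        profile = PssmProfile("p", "AC", np.arange(40).reshape(2, 20))
        path = tmp_path / "p.pssm"
        write_ascii_pssm(profile, path)
        raw_lines = [l for l in path.read_text().splitlines() if l.strip()[:1].isdigit()]
        file_cols = [int(t) for t in raw_lines[0].split()[2:22]]
        assert file_cols[0] == profile.scores[0, 0]  # A stays first
        assert file_cols[4] == profile.scores[0, 1]  # C sits in file column 5
        assert np.array_equal(parse_pssm(path).scores, profile.scores)

    def test_truncated_file_rejected(self, tmp_path):
        path = tmp_path / "bad.pssm"
        path.write_text("\nheader text\n")
        with pytest.raises(PssmParseError, match="truncated|no column"):
            parse_pssm(path)

    def test_out_of_order_rows_rejected(self, tmp_path):
        profile = generate_pssm(ProteinRecord("p", "ACD"), 0.5, seed=1)
        path = tmp_path / "p.pssm"
        write_ascii_pssm(profile, path)
        lines = path.read_text().splitlines()
        body = [i for i, l in enumerate(lines) if l.strip()[:1].isdigit()]
        lines[body[1]], lines[body[2]] = lines[body[2]], lines[body[1]]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(PssmParseError, match="expected position"):
            parse_pssm(path)

    def test_profile_row_count_must_match_sequence(self):
        with pytest.raises(ValueError, match="does not match"):
            PssmProfile("p", "ACD", np.zeros((2, 20)))


class TestNormalization:
    def test_logistic_values(self):
        profile = PssmProfile("p", "A", np.array([[0.0] * 20]))
        assert np.allclose(normalize_pssm(profile).scores, 0.5)
        profile = PssmProfile("p", "A", np.array([[-3.0] * 20]))
        assert np.allclose(normalize_pssm(profile).scores, 1 / (1 + math.exp(3)))

    def test_monotone_and_bounded(self):
        xs = np.arange(-12, 13, dtype=float).reshape(-1, 1) * np.ones((1, 20))
        out = normalize_pssm(PssmProfile("p", "A" * 25, xs)).scores
        assert (out > 0).all() and (out < 1).all()
        assert (np.diff(out[:, 0]) > 0).all()


class TestPssm400:
    def test_single_position_block(self):
        row = np.linspace(0.1, 0.9, 20)
        vec = compute_pssm400(PssmProfile("p", "A", row.reshape(1, 20))).values
        assert len(vec) == 400
        assert np.allclose(vec[:20], 100.0 * row)
        assert vec[20:].sum() == 0.0

    def test_hand_summed_three_residue_profile(self):
        rows = np.array([[0.2] * 20, [0.4] * 20, [0.9] * 20])
        vec = compute_pssm400(PssmProfile("p", "AAC", rows)).values
        assert np.allclose(vec[:20], 100.0 * (0.2 + 0.4) / 3)  # block A
        assert np.allclose(vec[20:40], 100.0 * 0.9 / 3)  # block C
        assert vec[40:].sum() == 0.0

    def test_constant_profile_closed_form(self):
        # all cells k: block of residue r is 100 * k * count(r) / L per cell
        seq, k = "ACCA", 0.3
        vec = compute_pssm400(PssmProfile("p", seq, np.full((4, 20), k))).values
        assert np.allclose(vec[:20], 100.0 * k * 2 / 4)
        assert np.allclose(vec[20:40], 100.0 * k * 2 / 4)

    def test_unnormalized_profile_rejected(self):
        with pytest.raises(ValueError, match="normalize"):
            compute_pssm400(PssmProfile("p", "A", np.array([[3.0] * 20])))


class TestCombination:
    def test_concat_layout(self):
        rec = ProteinRecord("p1", "ACDE")
        aac = compute_aac(rec)
        pssm = compute_pssm400(
            normalize_pssm(generate_pssm(rec, 0.8, seed=1))
        )
        combo = concat_features(aac, pssm)
        assert combo.schema is Schema.COMBO420 and len(combo.values) == 420
        assert np.array_equal(combo.values[:20], aac.values)

    def test_id_mismatch_rejected(self):
        aac = compute_aac(ProteinRecord("p1", "ACDE"))
        pssm = compute_pssm400(
            normalize_pssm(generate_pssm(ProteinRecord("p2", "ACDE"), 0.8, seed=1))
        )
        with pytest.raises(ValueError, match="id mismatch"):
            concat_features(aac, pssm)


def test_mean_composition():
    recs = [ProteinRecord("a", "AAAA"), ProteinRecord("b", "CCCC")]
    vec = mean_composition(recs).values
    assert vec[0] == 50.0 and vec[1] == 50.0
    same = mean_composition([recs[0]] * 7).values
    assert np.allclose(same, compute_aac(recs[0]).values)
    with pytest.raises(ValueError):
        mean_composition([])


def test_feature_extraction_is_deterministic():
    rec = ProteinRecord("p", "ACDEFGHIKLMNPQRSTVWY" * 3)
    assert np.array_equal(compute_aac(rec).values, compute_aac(rec).values)
    assert np.array_equal(compute_dpc(rec).values, compute_dpc(rec).values)


def test_encoders_match_per_record_functions(default_dataset):
    _, records, _ = default_dataset
    sample = records[:10]
    X = CompositionEncoder("aac").fit_transform(sample)
    assert X.shape == (10, 20)
    assert np.array_equal(X[3], compute_aac(sample[3]).values)
    profiles = [generate_pssm(r, 0.8, seed=i) for i, r in enumerate(sample)]
    Xp = ProfileCompositionEncoder().fit_transform(profiles)
    assert Xp.shape == (10, 400)
    expected = compute_pssm400(normalize_pssm(profiles[3])).values
    assert np.allclose(Xp[3], expected)
    Xc = ProfileCompositionEncoder(with_aac=True).fit_transform(profiles)
    assert Xc.shape == (10, 420)
    assert np.allclose(Xc[:, :20], X)


def test_feature_frame_csv_round_trip(tmp_path):
    import pandas as pd

    recs = [ProteinRecord("a", "ACDE"), ProteinRecord("b", "AAAA")]
    df = feature_frame([compute_aac(r) for r in recs])
    path = tmp_path / "aac.csv"
    df.to_csv(path)
    back = pd.read_csv(path, index_col="id")
    assert list(back.columns) == list(CANONICAL_ALPHABET)
    assert np.allclose(back.to_numpy(), df.to_numpy())
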