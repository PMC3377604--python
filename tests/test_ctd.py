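import numpy as np
import pytest
from hypothesis import given, strategies as st

from mfescan.ctd import (
    GROUPINGS,
    N_FEATURES,
    PROPERTY_ORDER,
    EncodingError,
    FeatureVector,
    aa_composition,
    ctd_composition,
    ctd_distribution,
    ctd_transition,
    encode_batch,
    encode_sequence,
    feature_names,
    read_features,
    write_features,
)
from mfescan.sequence_io import STANDARD_AA, ProteinRecord

from bruteforce import brute_encode

CHARGE = GROUPINGS["charge"]

sequences = st.text(alphabet=STANDARD_AA, min_size=2, max_size=30)


class TestAAComposition:
    def test_homopolymer(self):
        vec = aa_composition("AAAA")
        assert vec[0] == 1.0 and vec[1:].sum() == 0.0

    def test_equal_counts(self):
        vec = aa_composition("ACDE")
        assert dict(zip(STANDARD_AA, vec))["A"] == 0.25
        assert np.count_nonzero(vec) == 4

    def test_empty_sequence_rejected(self):
        with pytest.raises(EncodingError):
            aa_composition("")

    @given(sequences, st.randoms(use_true_random=False))
    def test_permutation_and_duplication_invariance(self, seq, rnd):
        base = aa_composition(seq)
        shuffled = list(seq)
        rnd.shuffle(shuffled)
        assert np.allclose(aa_composition("".join(shuffled)), base)
        assert np.allclose(aa_composition(seq + seq), base)


class TestGroupedComposition:
    def test_single_group_sequence(self):
        assert np.allclose(ctd_composition("KKKK", CHARGE), [1.0, 0.0, 0.0])

    def test_two_residues_per_group(self):
        assert np.allclose(ctd_composition("DEKRAG", CHARGE), [1 / 3, 1 / 3, 1 / 3])

    @given(sequences)
    def test_groups_partition_the_sequence(self, seq):
        for prop in PROPERTY_ORDER:
            assert ctd_composition(seq, GROUPINGS[prop]).sum() == pytest.approx(1.0)


class TestTransition:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("KKKK", [0.0, 0.0, 0.0]),   # no cross-group adjacency
            ("KDKD", [0.0, 1.0, 0.0]),   # positive<->negative at all 3 junctions
            ("KD", [0.0, 1.0, 0.0]),
        ],
    )
    def test_charge_examples(self, seq, expected):
        assert np.allclose(ctd_transition(seq, CHARGE), expected)

    def test_too_short_rejected(self):
        with pytest.raises(EncodingError):
            ctd_transition("K", CHARGE)

    @given(sequences)
    def test_reversal_invariance_and_bound(self, seq):
        for prop in PROPERTY_ORDER:
            t = ctd_transition(seq, GROUPINGS[prop])
            assert np.allclose(ctd_transition(seq[::-1], GROUPINGS[prop]), t)
            assert t.sum() <= 1.0 + 1e-12


class TestDistribution:
    def test_single_occurrence(self):
        # K at position 1 of 4: all five quantiles sit at 25%
        vec = ctd_distribution("KAAA", CHARGE)
        assert np.allclose(vec[:5], [25, 25, 25, 25, 25])

    def test_two_occurrences(self):
        # positive residues at positions 1 and 3 of 4
        vec = ctd_distribution("KAKA", CHARGE)
        assert np.allclose(vec[:5], [25, 25, 25, 75, 75])

    def test_absent_group_is_zero(self):
        vec = ctd_distribution("AAAA", CHARGE)
        assert np.allclose(vec[:5], 0.0)  # no positive residues
        assert np.allclose(vec[10:], 0.0)  # no negative residues

    @given(sequences)
    def test_monotone_and_last_occurrence(self, seq):
        n = len(seq)
        for prop in PROPERTY_ORDER:
            grouping = GROUPINGS[prop]
            vec = ctd_distribution(seq, grouping)
            for j, group in enumerate(grouping.groups):
                five = vec[5 * j : 5 * j + 5]
                assert np.all(np.diff(five) >= -1e-12)
                positions = [i for i, c in enumerate(seq, 1) if c in group]
                if positions:
                    assert five[4] == pytest.approx(100.0 * positions[-1] / n)


class TestEncode:
    def test_vector_length_and_determinism(self, toy_records):
        rec = toy_records[0]
        v1, v2 = encode_sequence(rec), encode_sequence(rec)
        assert v1.values.shape == (N_FEATURES,)
        assert np.array_equal(v1.values, v2.values)

    def test_matches_suboperations(self):
        seq = "MKDLRE"
        vec = encode_sequence(ProteinRecord(id="x", sequence=seq)).values
        parts = [aa_composition(seq)]
        for prop in PROPERTY_ORDER:
            g = GROUPINGS[prop]
            parts += [ctd_composition(seq, g), ctd_transition(seq, g),
                      ctd_distribution(seq, g)]
        assert np.array_equal(vec, np.concatenate(parts))

    def test_value_ranges(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list(STANDARD_AA), size=80))
        vec = encode_sequence(ProteinRecord(id="x", sequence=seq)).values
        assert vec[:20].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(vec >= 0) and np.all(vec <= 100)

    def test_length_one_rejected(self):
        with pytest.raises(EncodingError):
            encode_sequence(ProteinRecord(id="x", sequence="M"))

    def test_wrong_length_vector_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(values=np.zeros(20))

    @given(st.lists(sequences, min_size=1, max_size=5))
    def test_batch_consistent_with_single(self, seqs):
        records = [ProteinRecord(id=f"p{i}", sequence=s)
                   for i, s in enumerate(seqs)]
        matrix = encode_batch(records)
        assert matrix.shape == (len(records), N_FEATURES)
        assert list(matrix.index) == [r.id for r in records]
        for rec in records:
            assert np.array_equal(
                matrix.loc[rec.id].to_numpy(), encode_sequence(rec).values
            )

    def test_batch_empty(self):
        matrix = encode_batch([])
        assert matrix.shape == (0, N_FEATURES)
        assert list(matrix.columns) == feature_names()

    def test_batch_error_names_record(self):
        with pytest.raises(EncodingError, match="bad"):
            encode_batch([ProteinRecord(id="bad", sequence="M")])

    def test_feature_tsv_roundtrip(self, tmp_path, toy_records):
        matrix = encode_batch(toy_records)
        path = tmp_path / "feat.tsv"
        write_features(matrix, path)
        back = read_features(path)
        assert np.allclose(back.to_numpy(), matrix.to_numpy())
        assert list(back.index) == list(matrix.index)


class TestOracleEquivalence:
    @given(sequences)
    def test_random_sequences_match_bruteforce(self, seq):
        vec = encode_sequence(ProteinRecord(id="x", sequence=seq)).values
        assert np.allclose(vec, brute_encode(seq), atol=1e-12, rtol=0)

    def test_reversal_changes_distribution_not_ct(self):
        seq = "MKDLREAAGTWY"
        fwd = encode_sequence(ProteinRecord(id="f", sequence=seq)).values
        rev = encode_sequence(ProteinRecord(id="r", sequence=seq[::-1])).values
        names = feature_names()
        ct = [i for i, n in enumerate(names) if "_D" not in n]
        assert np.allclose(fwd[ct], rev[ct])
        assert not np.allclose(fwd, rev)


def test_layout_accounting():
    names = feature_names()
    assert len(names) == 188
    assert sum(n.startswith("AAC_") for n in names) == 20
    for prop_short in ("HYDRO", "VDW", "POLARITY", "POLARIZ", "CHARGE",
                       "SURFTEN", "SECSTR", "SOLVACC"):
        block = [n for n in names if n.startswith(prop_short + "_")]
        assert len(block) == 21
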