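import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncpi.io_formats import Alphabet, SequenceRecord
from lncpi.sequence_features import (
    KGAP_FAMILIES,
    DescriptorConfig,
    FeatureMatrix,
    apply_normalization,
    build_pair_matrix,
    encode_kgap,
    encode_lncrna,
    encode_lncrna_set,
    encode_protein,
    encode_protein_set,
    encode_pseudoknc,
    encode_scalar_descriptors,
    kgap_names,
    lncrna_feature_names,
    min_max_normalize,
    protein_feature_names,
    pseudoknc_names,
    read_feature_matrix,
    write_feature_matrix,
)

nt_seq = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestScalarDescriptors:
    def test_balanced_composition(self):
        v = encode_scalar_descriptors("ACGT")
        assert np.allclose(v, [0, 0, 0, 0.5, 1.0, 0, 0])

    def test_zcurve_from_counts(self):
        # nA=2, nG=2: purine excess 4, amino and weak axes balanced
        v = encode_scalar_descriptors("AAGG")
        assert tuple(v[:3]) == (4.0, 0.0, 0.0)

    def test_degenerate_denominators_return_zero(self):
        v = encode_scalar_descriptors("AATT")
        gc_content, atgc_ratio, gc_skew = v[3], v[4], v[5]
        assert gc_content == 0.0 and atgc_ratio == 0.0 and gc_skew == 0.0

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            encode_scalar_descriptors("")


class TestPseudoKNC:
    def test_nucleotide_dimension_84(self):
        assert len(pseudoknc_names(Alphabet.NUCLEOTIDE, 3)) == 84
        assert encode_pseudoknc("ACGT", Alphabet.NUCLEOTIDE, 3).shape == (84,)

    def test_protein_dimension_8420(self):
        assert len(pseudoknc_names(Alphabet.PROTEIN, 3)) == 8420

    def test_single_letter_counts(self):
        v = encode_pseudoknc("AAAA", Alphabet.NUCLEOTIDE, 1)
        assert dict(zip("ACGT", v)) == {"A": 4, "C": 0, "G": 0, "T": 0}

    def test_direct_enumeration_acg(self):
        names = pseudoknc_names(Alphabet.NUCLEOTIDE, 2)
        v = dict(zip(names, encode_pseudoknc("ACG", Alphabet.NUCLEOTIDE, 2)))
        nonzero = {k: c for k, c in v.items() if c}
        assert nonzero == {
            "pseudoKNC|A": 1,
            "pseudoKNC|C": 1,
            "pseudoKNC|G": 1,
            "pseudoKNC|AC": 1,
            "pseudoKNC|CG": 1,
        }

    @settings(max_examples=50, derandomize=True)
    @given(seq=nt_seq, k_tuple=st.integers(1, 3))
    def test_per_t_counts_sum_to_window_count(self, seq, k_tuple):
        v = encode_pseudoknc(seq, Alphabet.NUCLEOTIDE, k_tuple)
        start = 0
        for t in range(1, k_tuple + 1):
            block = v[start : start + 4**t]
            assert block.sum() == max(len(seq) - t + 1, 0)
            start += 4**t


class TestKGap:
    def test_acgt_mono_mono_exhaustive(self):
        names = kgap_names("monoMonoKGap", Alphabet.NUCLEOTIDE, 1)
        v = dict(zip(names, encode_kgap("ACGT", Alphabet.NUCLEOTIDE, 1, 1, 1)))
        nonzero = {k: c for k, c in v.items() if c}
        assert nonzero == {
            "monoMonoKGap|A_g1_G": 1,
            "monoMonoKGap|C_g1_T": 1,
        }

    def test_too_short_sequence_zero_vector(self):
        v = encode_kgap("ACG", Alphabet.NUCLEOTIDE, 2, 3, 5)
        assert v.shape == (5120,) and not v.any()

    def test_ditri_dimension_5120(self):
        assert len(kgap_names("diTriKGap", Alphabet.NUCLEOTIDE, 5)) == 5120

    @settings(max_examples=25, derandomize=True)
    @given(
        seq=nt_seq,
        family=st.sampled_from(sorted(KGAP_FAMILIES)),
        max_gap=st.integers(1, 3),
    )
    def test_matches_brute_force_index_enumeration(self, seq, family, max_gap):
        """k-gap counts equal a double loop over all (position, gap) pairs."""
        a, b = KGAP_FAMILIES[family]
        v = dict(
            zip(
                kgap_names(family, Alphabet.NUCLEOTIDE, max_gap)[
                    : 4 ** (a + b) * max_gap
                ],
                encode_kgap(seq, Alphabet.NUCLEOTIDE, a, b, max_gap),
            )
        )
        brute: dict[str, int] = {}
        for g in range(1, max_gap + 1):
            for i in range(len(seq)):
                head = seq[i : i + a]
                tail = seq[i + a + g : i + a + g + b]
                if len(head) == a and len(tail) == b:
                    key = f"{family}|{head}_g{g}_{tail}"
                    brute[key] = brute.get(key, 0) + 1
        assert {k: c for k, c in v.items() if c} == brute

    @settings(max_examples=25, derandomize=True)
    @given(seq=nt_seq, max_gap=st.integers(1, 4))
    def test_per_gap_counts_sum_to_window_count(self, seq, max_gap):
        v = encode_kgap(seq, Alphabet.NUCLEOTIDE, 2, 1, max_gap)
        for g in range(1, max_gap + 1):
            block = v[(g - 1) * 64 : g * 64]
            assert block.sum() == max(len(seq) - (2 + g + 1) + 1, 0)


class TestFullEncoders:
    def test_lncrna_dimension(self):
        assert len(lncrna_feature_names()) == 14891
        assert encode_lncrna("ACGTACGTACGT").shape == (14891,)

    def test_protein_dimension(self):
        assert len(protein_feature_names()) == 10420
        assert encode_protein("MKNVAWCY").shape == (10420,)

    @pytest.mark.parametrize(
        "family,expected",
        [
            ("atgcRatio", 1),
            ("cumulativeSkew", 2),
            ("diDiKGap", 1280),
            ("diMonoKGap", 320),
            ("diTriKGap", 5120),
            ("gcContent", 1),
            ("monoDiKGap", 320),
            ("monoMonoKGap", 80),
            ("monoTriKGap", 1280),
            ("pseudoKNC", 84),
            ("triMonoKGap", 1280),
            ("triDiKGap", 5120),
            ("zCurve", 3),
        ],
    )
    def test_lncrna_family_block_sizes(self, family, expected):
        names = lncrna_feature_names()
        block = [n for n in names if n == family or n.startswith(family + "|")]
        assert len(block) == expected

    def test_protein_family_block_sizes(self):
        names = protein_feature_names()
        assert sum(n.startswith("pseudoKNC|") for n in names) == 8420
        assert sum(n.startswith("monoMonoKGap|") for n in names) == 2000

    def test_short_sequence_ditri_block_zero(self):
        names = lncrna_feature_names()
        v = encode_lncrna("ACGT")
        ditri = np.array([n.startswith("diTriKGap|") for n in names])
        assert not v[ditri].any()

    def test_deterministic(self):
        assert np.array_equal(encode_lncrna("ACGTTGCA"), encode_lncrna("ACGTTGCA"))

    def test_protein_kgap_zero_without_window(self):
        names = protein_feature_names()
        v = encode_protein("MM")
        kgap = np.array([n.startswith("monoMonoKGap|") for n in names])
        assert not v[kgap].any()


@pytest.fixture(scope="module")
def entity_features():
    lnc = [
        SequenceRecord("l1", "ACGTACGTAC", Alphabet.NUCLEOTIDE),
        SequenceRecord("l2", "GGGGCCCCAA", Alphabet.NUCLEOTIDE),
    ]
    prot = [SequenceRecord("p1", "MKNVAW", Alphabet.PROTEIN)]
    return encode_lncrna_set(lnc), encode_protein_set(prot)


class TestPairMatrix:
    def test_pair_dimension_sums_blocks(self, entity_features):
        lf, pf = entity_features
        X = build_pair_matrix(lf, pf, [("l1", "p1")])
        assert X.shape == (1, 25311)
        assert X.sample_ids == ["l1|p1"]

    def test_empty_pair_list(self, entity_features):
        lf, pf = entity_features
        X = build_pair_matrix(lf, pf, [])
        assert X.shape == (0, 25311)

    def test_duplicate_pair_identical_rows(self, entity_features):
        lf, pf = entity_features
        X = build_pair_matrix(lf, pf, [("l2", "p1"), ("l2", "p1")])
        assert np.array_equal(X.values[0], X.values[1])

    def test_unknown_id_raises(self, entity_features):
        lf, pf = entity_features
        with pytest.raises(KeyError, match="l9"):
            build_pair_matrix(lf, pf, [("l9", "p1")])

    def test_row_content_is_concatenation(self, entity_features):
        lf, pf = entity_features
        X = build_pair_matrix(lf, pf, [("l2", "p1")])
        assert np.array_equal(X.values[0, :14891], lf.values[1])
        assert np.array_equal(X.values[0, 14891:], pf.values[0])


class TestMinMaxNormalize:
    def test_eq7_example_column(self):
        fm = FeatureMatrix(["a", "b", "c"], ["f"], np.array([[0.0], [5.0], [10.0]]))
        out, _ = min_max_normalize(fm)
        assert np.allclose(out.values.ravel(), [0, 0.5, 1])

    def test_endpoints_map_to_unit_interval(self, rng):
        fm = FeatureMatrix(
            [f"s{i}" for i in range(10)],
            [f"f{j}" for j in range(4)],
            rng.normal(size=(10, 4)),
        )
        out, _ = min_max_normalize(fm)
        assert np.allclose(out.values.min(axis=0), 0)
        assert np.allclose(out.values.max(axis=0), 1)

    def test_constant_column_maps_to_zero(self):
        fm = FeatureMatrix(["a", "b", "c"], ["f"], np.full((3, 1), 3.0))
        out, params = min_max_normalize(fm)
        assert not out.values.any()
        new = FeatureMatrix(["d"], ["f"], np.array([[7.0]]))
        assert apply_normalization(params, new).values.item() == 0.0

    def test_unseen_data_not_clipped(self):
        fm = FeatureMatrix(["a", "b"], ["f"], np.array([[0.0], [10.0]]))
        _, params = min_max_normalize(fm)
        new = FeatureMatrix(["c"], ["f"], np.array([[20.0]]))
        assert apply_normalization(params, new).values.item() == 2.0


def test_feature_matrix_tsv_round_trip(tmp_path, rng):
    fm = FeatureMatrix(
        ["s1", "s2"], ["a", "b", "c"], rng.integers(0, 9, size=(2, 3)).astype(float)
    )
    p = tmp_path / "fm.tsv"
    write_feature_matrix(fm, p)
    back = read_feature_matrix(p)
    assert back.sample_ids == fm.sample_ids
    assert back.feature_names == fm.feature_names
    assert np.allclose(back.values, fm.values)


def test_feature_matrix_rejects_nan():
    with pytest.raises(ValueError):
        FeatureMatrix(["s"], ["f"], np.array([[np.nan]]))


def test_descriptor_config_validation():
    with pytest.raises(ValueError):
        DescriptorConfig(k_gap=0)
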