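"""Composition/position feature operators and the assembled descriptor."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icrotok import (
    N_FEATURES,
    PeptideFeaturizer,
    PeptideWindow,
    aapiv,
    assemble_feature_vector,
    encode_svv,
    feature_names,
    feature_segment,
    featurize,
    frequency_vector,
    prim,
    raapiv,
    rprim,
)

ACA = encode_svv("ACA")
AAC = encode_svv("AAC")

codes = st.integers(min_value=0, max_value=20)
sequences = st.lists(codes, min_size=1, max_size=50).map(np.array)


def brute_prim(seq):
    """Oracle: explicit double loop over (first-occurrence, occurrence)."""
    H = np.zeros((20, 20))
    for i in range(1, 21):
        hits = [p + 1 for p, c in enumerate(seq) if c == i]
        if not hits:
            continue
        first_i = hits[0]
        for p, c in enumerate(seq):
            if c > 0 and p + 1 > first_i:
                H[i - 1, c - 1] += (p + 1) - first_i
    return H


class TestFrequencyVector:
    def test_toy_tally(self):
        f = frequency_vector(ACA)
        assert f[0] == 2 and f[1] == 1 and f.sum() == 3

    def test_homopolymer(self):
        f = frequency_vector(np.ones(41, dtype=int))
        assert f[0] == 41 and f.sum() == 41

    def test_padding_excluded(self):
        seq = encode_svv("X" * 20 + "K" + "X" * 20)
        f = frequency_vector(seq)
        assert f[8] == 1 and f.sum() == 1

    @given(sequences)
    def test_counts_plus_padding_equal_length(self, seq):
        f = frequency_vector(seq)
        assert f.sum() + (seq == 0).sum() == seq.size


class TestPositionIncidence:
    def test_aapiv_toy(self):
        mu = aapiv(ACA)
        assert mu[0] == 1 + 3 and mu[1] == 2

    def test_homopolymer_arithmetic_series(self):
        L = 17
        mu = aapiv(np.full(L, 4))
        assert mu[3] == L * (L + 1) / 2

    def test_all_padding_zero(self):
        assert np.all(aapiv(np.zeros(41, dtype=int)) == 0)

    def test_raapiv_examples(self):
        assert raapiv(ACA)[0] == 4  # palindrome
        mu = raapiv(AAC)
        assert mu[0] == 2 + 3 and mu[1] == 1

    @given(st.lists(st.integers(min_value=1, max_value=20), min_size=1, max_size=40))
    def test_forward_reverse_sum_identity(self, values):
        # for unpadded windows: mu_i + mu'_i == occurrences_i * (L + 1)
        seq = np.array(values)
        L = seq.size
        occ = frequency_vector(seq)
        np.testing.assert_allclose(aapiv(seq) + raapiv(seq), occ * (L + 1))


class TestPrim:
    def test_single_residue_run(self):
        L = 9
        H = prim(np.full(L, 7))
        assert H[6, 6] == L * (L - 1) / 2
        H[6, 6] = 0
        assert np.all(H == 0)

    def test_two_residue_example(self):
        H = prim(encode_svv("AC"))
        assert H[0, 1] == 1  # C one step after first A
        assert H[1, 0] == 0  # no A after first C

    def test_all_padding_zero_matrix(self):
        assert np.all(prim(np.zeros(41, dtype=int)) == 0)

    @given(sequences)
    def test_matches_brute_force_oracle(self, seq):
        np.testing.assert_array_equal(prim(seq), brute_prim(seq))

    def test_rprim_two_residue_example(self):
        assert rprim(encode_svv("AC"))[1, 0] == 1

    @given(sequences)
    def test_reversal_dualities(self, seq):
        np.testing.assert_array_equal(rprim(seq), prim(seq[::-1]))
        np.testing.assert_array_equal(raapiv(seq), aapiv(seq[::-1]))

    def test_palindrome_symmetry(self):
        seq = encode_svv("ACKCA")
        np.testing.assert_array_equal(prim(seq), rprim(seq))
        np.testing.assert_array_equal(aapiv(seq), raapiv(seq))


class TestAssembledVector:
    def test_valid_41mer_yields_194(self, small_dataset):
        vec = assemble_feature_vector(small_dataset.windows[0])
        assert vec.shape == (N_FEATURES,)
        assert np.all(np.isfinite(vec))

    def test_all_padding_window_still_194(self):
        vec = assemble_feature_vector("X" * 41)
        assert vec.shape == (194,)
        for segment in ("fv", "aapiv", "raapiv", "svv", "prim_moments"):
            assert np.all(feature_segment(vec, segment) == 0)

    def test_reversed_windows_swap_prim_and_rprim_segments(self, rng):
        from conftest import random_window_codes

        seq = random_window_codes(rng)
        fwd = assemble_feature_vector(seq)
        rev = assemble_feature_vector(seq[::-1])
        np.testing.assert_allclose(
            feature_segment(fwd, "prim_moments"),
            feature_segment(rev, "rprim_moments"),
        )
        np.testing.assert_allclose(
            feature_segment(fwd, "raapiv"), feature_segment(rev, "aapiv")
        )

    def test_permutation_sensitivity(self, rng):
        """Shuffling residues preserves composition (FV) but moves the
        position-sensitive segments."""
        from conftest import random_window_codes

        seq = random_window_codes(rng)
        shuffled = rng.permutation(seq)
        a, b = assemble_feature_vector(seq), assemble_feature_vector(shuffled)
        np.testing.assert_array_equal(
            feature_segment(a, "fv"), feature_segment(b, "fv")
        )
        assert not np.array_equal(
            feature_segment(a, "aapiv"), feature_segment(b, "aapiv")
        )

    def test_deterministic(self, small_dataset):
        w = small_dataset.windows[0]
        np.testing.assert_array_equal(
            assemble_feature_vector(w), assemble_feature_vector(w)
        )


class TestPeptideFeaturizer:
    def test_transform_shape_and_names(self, small_dataset):
        tf = PeptideFeaturizer().fit(small_dataset.windows)
        X = tf.transform(small_dataset.windows[:5])
        assert X.shape == (5, 194)
        names = tf.get_feature_names_out()
        assert len(names) == 194
        assert names[0] == "seq_moments_0" and names[-1] == "svv_stats_2"

    def test_length_mismatch_rejected(self, small_dataset):
        tf = PeptideFeaturizer(window_length=41).fit([])
        with pytest.raises(ValueError):
            tf.transform(["AKA"])

    def test_functional_wrapper_agrees(self, small_dataset):
        w = small_dataset.windows[:3]
        np.testing.assert_array_equal(
            featurize(w), PeptideFeaturizer().fit_transform(w)
        )

    def test_feature_names_cover_layout(self):
        assert len(feature_names(41)) == 194


def test_window_objects_and_strings_agree(small_dataset):
    w = small_dataset.windows[0]
    np.testing.assert_array_equal(
        assemble_feature_vector(w), assemble_feature_vector(w.residues)
    )
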