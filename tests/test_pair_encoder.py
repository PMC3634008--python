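import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contactcascade.msa_features import Alignment
from contactcascade.pair_encoder import (
    BASE_BLOCK,
    CONTENT_STAGE,
    EncodingError,
    LAYOUT,
    N_PAIR_CATEGORIES,
    SEGMENT_STAGE,
    TOTAL_LENGTH,
    encode_base_block,
    encode_pair,
    encode_pairs,
    global_features,
    pair_category_index,
)
from contactcascade.synthetic_data import synth_msa


def random_alignment(n, seed=0, rows=8):
    rng = np.random.default_rng(seed)
    target = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
    return synth_msa(target, n_rows=rows, mutation_rate=0.2, seed=seed)


class TestPairCategoryIndex:
    def test_symmetric(self):
        for a, b in [("A", "C"), ("W", "Y"), ("G", "G")]:
            assert pair_category_index(a, b) == pair_category_index(b, a)

    def test_first_category(self):
        assert pair_category_index("A", "A") == 0

    def test_exactly_210_distinct_categories(self):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        image = {pair_category_index(a, b) for a in aas for b in aas}
        assert image == set(range(210))

    def test_bad_residue(self):
        with pytest.raises(EncodingError, match="bad residue"):
            pair_category_index("A", "X")


class TestBaseBlock:
    def test_length_218(self, small_alignment):
        assert len(encode_base_block(small_alignment, 2, 5)) == BASE_BLOCK

    def test_hand_built_conserved_alignment(self):
        # 2 identical rows, annotated helix at both positions: the block is
        # a unit pair frequency, conservation 1.0 twice and (1,0,0) twice
        aln = Alignment(
            "AC", ["AC", "AC"],
            per_position_conservation=[1.0, 1.0],
            per_position_ss=["H", "H"],
        )
        block = encode_base_block(aln, 1, 2)
        expect = np.zeros(218)
        expect[pair_category_index("A", "C")] = 1.0
        expect[210] = 1.0
        expect[211:214] = [1, 0, 0]
        expect[214] = 1.0
        expect[215:218] = [1, 0, 0]
        np.testing.assert_allclose(block, expect)

    def test_i_and_j_features_swap(self, small_alignment):
        b_ij = encode_base_block(small_alignment, 2, 7)
        b_ji = encode_base_block(small_alignment, 7, 2)
        np.testing.assert_allclose(b_ij[:210], b_ji[:210])  # shared pair part
        np.testing.assert_allclose(b_ij[210:214], b_ji[214:218])
        np.testing.assert_allclose(b_ij[214:218], b_ji[210:214])


class TestEncodePair:
    def test_total_length_and_staged_sublengths(self):
        aln = random_alignment(100, seed=1)
        enc = encode_pair(aln, 10, 40, 100)
        assert len(enc) == TOTAL_LENGTH == 1747
        # the staged lengths are plain prefixes of the layout
        assert enc.layout["base"] == (0, 218)
        assert N_PAIR_CATEGORIES == 210
        content_stop = max(hi for name, (lo, hi) in enc.layout.items()
                           if name.startswith(("base", "content")))
        assert content_stop == CONTENT_STAGE == 1090
        segment_stop = max(hi for name, (lo, hi) in enc.layout.items()
                           if name.startswith("segment"))
        assert segment_stop == SEGMENT_STAGE == 1744
        assert enc.layout["global"] == (1744, 1747)
        n_blocks = sum(1 for name in enc.layout
                       if name.startswith(("base", "content", "segment")))
        assert n_blocks == 8  # 5 content + 3 segment, 8 x 218 = 1744

    def test_boundary_blocks_zeroed(self):
        aln = random_alignment(20, seed=2)
        enc = encode_pair(aln, 1, 8, 20)
        # i-2 and i-1 fall outside the sequence: whole blocks are zero
        assert not enc.block("content_-2").any()
        assert not enc.block("content_-1").any()
        assert enc.block("base").any()
        assert len(enc) == 1747

    def test_symmetry_after_canonical_ordering(self):
        aln = random_alignment(30, seed=3)
        np.testing.assert_allclose(
            encode_pair(aln, 5, 17, 30).vector,
            encode_pair(aln, 17, 5, 30).vector,
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_length_and_range_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        aln = random_alignment(n, seed=seed)
        i = int(rng.integers(1, n))
        j = int(rng.integers(i + 1, n + 1))
        enc = encode_pair(aln, i, j, n)
        assert len(enc) == 1747
        # frequency entries live in [0, 1]
        for name, (lo, hi) in enc.layout.items():
            if name == "global":
                continue
            freqs = enc.vector[lo : lo + 210]
            assert np.all(freqs >= 0) and np.all(freqs <= 1)

    def test_zero_blocks_exactly_where_window_leaves_sequence(self):
        aln = random_alignment(25, seed=4)
        n, i, j = 25, 3, 24
        enc = encode_pair(aln, i, j, n)
        k = (i + j) // 2
        expectations = {
            "base": True,
            "content_-2": 1 <= i - 2 and j - 2 <= n,
            "content_-1": True,
            "content_+1": j + 1 <= n,
            "content_+2": j + 2 <= n,
            "segment_0": True,
            "segment_1": 1 <= k - 1 and k + 1 <= n,
            "segment_2": 1 <= k - 2 and k + 2 <= n,
        }
        for name, nonzero in expectations.items():
            assert enc.block(name).any() == nonzero, name

    def test_errors(self):
        aln = random_alignment(20, seed=5)
        with pytest.raises(EncodingError, match="unordered pair"):
            encode_pair(aln, 5, 5, 20)
        with pytest.raises(EncodingError, match="bad pair"):
            encode_pair(aln, 1, 25, 20)

    def test_alternative_segment_scheme(self):
        aln = random_alignment(30, seed=6)
        enc = encode_pair(aln, 4, 20, 30, segment_scheme="midpoint_self")
        assert len(enc) == 1747

    def test_batch_equals_scalar(self):
        aln = random_alignment(40, seed=7)
        pairs = np.array([(1, 9), (5, 30), (10, 11), (2, 40)])
        batch = encode_pairs(aln, pairs, 40)
        for row, (i, j) in zip(batch, pairs):
            np.testing.assert_allclose(
                row, encode_pair(aln, int(i), int(j), 40).vector
            )


class TestGlobalFeatures:
    def test_direct_arithmetic(self):
        raw = global_features(100, 10, 30) * 450
        np.testing.assert_allclose(raw, [20, 100, 19])

    def test_adjacent_pair_has_empty_segment(self):
        assert global_features(60, 7, 8)[2] == 0.0

    def test_maximal_case(self):
        np.testing.assert_allclose(
            global_features(450, 1, 450), [449 / 450, 1.0, 448 / 450]
        )
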