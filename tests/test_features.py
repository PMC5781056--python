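"""Bigram profiles and the assembled 657-component lysine descriptor."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from succpred.features import (
    FeatureError,
    assemble,
    bigram,
    build_dataset,
    featurize_protein,
    structural_block,
)
from succpred.io_formats import PSSMatrix, ProteinRecord, StructuralProfile


def brute_force_bigram(track):
    """Naive triple loop over (p, q, k) — the independent oracle."""
    track = np.asarray(track, dtype=float)
    W, K = track.shape
    B = np.zeros((K, K))
    for p in range(K):
        for q in range(K):
            for k in range(W - 1):
                B[p, q] += track[k, p] * track[k + 1, q]
    return B


class TestBigram:
    def test_one_hot_rows_give_single_entry(self):
        track = np.zeros((31, 20))
        track[:, 5] = 1.0
        prof = bigram(track)
        assert prof.matrix[5, 5] == 30.0
        assert np.count_nonzero(prof.matrix) == 1
        # row-major flat position of (5, 5)
        assert prof.flattened[5 * 20 + 5] == 30.0

    def test_all_zero_track(self):
        prof = bigram(np.zeros((31, 20)))
        assert prof.flattened.shape == (400,)
        assert not prof.flattened.any()

    def test_one_hot_three_state(self):
        track = np.tile([1.0, 0.0, 0.0], (31, 1))
        prof = bigram(track)
        np.testing.assert_array_equal(
            prof.flattened, [30, 0, 0, 0, 0, 0, 0, 0, 0]
        )

    @pytest.mark.parametrize("K", [3, 20])
    def test_matches_brute_force_oracle(self, K, rng):
        for _ in range(10):
            track = rng.random((31, K))
            np.testing.assert_allclose(
                bigram(track).matrix, brute_force_bigram(track), atol=1e-10
            )

    @pytest.mark.parametrize("K", [3, 20])
    def test_row_normalized_mass_conservation(self, K, rng):
        track = rng.dirichlet(np.ones(K), size=31)
        assert bigram(track).matrix.sum() == pytest.approx(30.0, abs=1e-9)

    def test_reversal_transposes(self, rng):
        track = rng.random((31, 20))
        B = bigram(track).matrix
        B_rev = bigram(track[::-1]).matrix
        np.testing.assert_allclose(B_rev, B.T, atol=1e-12)
        # and generally changes the profile itself
        assert not np.allclose(B_rev, B)

    @given(
        w=st.integers(min_value=2, max_value=41),
        k=st.integers(min_value=1, max_value=6),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_total_mass_equals_consecutive_row_sum_products(self, w, k, seed):
        track = np.random.default_rng(seed).random((w, k))
        s = track.sum(axis=1)
        expected = float(np.sum(s[:-1] * s[1:]))
        assert bigram(track).matrix.sum() == pytest.approx(expected, rel=1e-12)

    def test_degenerate_window_rejected(self):
        with pytest.raises(FeatureError):
            bigram(np.ones((1, 20)))

    @pytest.mark.parametrize("flank", [5, 10, 15, 20])
    def test_dimensionality_independent_of_window_size(self, flank):
        w = 2 * flank + 1
        assert bigram(np.ones((w, 20))).flattened.shape == (400,)
        assert bigram(np.ones((w, 3))).flattened.shape == (9,)


class TestStructuralBlock:
    def test_constant_input(self):
        out = structural_block(np.ones((31, 8)))
        assert out.shape == (248,)
        assert np.all(out == 1.0)

    def test_track_major_ordering(self):
        w = np.zeros((31, 8))
        w[:, 0] = np.arange(1, 32)  # ASA track
        out = structural_block(w)
        np.testing.assert_array_equal(out[:31], np.arange(1, 32))
        assert not out[31:].any()

    def test_wrong_shape_rejected(self):
        with pytest.raises(FeatureError):
            structural_block(np.ones((31, 7)))


class TestAssemble:
    def test_length_657(self, rng):
        v = assemble(rng.random((31, 8)), rng.random((31, 20)), rng.random((31, 3)))
        assert v.shape == (657,)

    def test_zero_inputs(self):
        v = assemble(np.zeros((31, 8)), np.zeros((31, 20)), np.zeros((31, 3)))
        assert v.shape == (657,) and not v.any()

    def test_block_boundaries(self, rng):
        wstruct = rng.random((31, 8))
        wp = rng.random((31, 20))
        ws = rng.random((31, 3))
        v = assemble(wstruct, wp, ws)
        # entry 249 (1-based) starts the PSSM bigram block, 649 the SS block
        assert v[248] == pytest.approx(brute_force_bigram(wp)[0, 0], abs=1e-10)
        assert v[648] == pytest.approx(brute_force_bigram(ws)[0, 0], abs=1e-10)
        np.testing.assert_array_equal(v[:248], structural_block(wstruct))

    def test_no_bigram_ablation_layout(self, rng):
        v = assemble(
            rng.random((31, 8)), rng.random((31, 20)), rng.random((31, 3)),
            use_bigram=False,
        )
        assert v.shape == (248 + 620 + 93,)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(FeatureError):
            assemble(rng.random((31, 8)), rng.random((30, 20)), rng.random((31, 3)))


def _protein(sequence, sites=(), seed=0):
    rng = np.random.default_rng(seed)
    L = len(sequence)
    rec = ProteinRecord(id="p", sequence=sequence, sites=list(sites))
    pssm = PSSMatrix(protein_id="p", values=rng.dirichlet(np.ones(20), size=L))
    prof = StructuralProfile(
        protein_id="p",
        asa=rng.random(L) * 50,
        ss_probs=rng.dirichlet(np.ones(3), size=L),
        angles=rng.uniform(-180, 180, (L, 4)),
    )
    return rec, pssm, prof


class TestFeaturizeProtein:
    def test_one_vector_per_annotated_site(self):
        seq = "A" * 20 + "K" + "A" * 20 + "K" + "A" * 20 + "K" + "A" * 10
        sites = [(21, 1), (42, -1), (63, 1)]
        rec, pssm, prof = _protein(seq, sites)
        vectors = featurize_protein(rec, pssm, prof)
        assert [(v.protein_id, v.position, v.label) for v in vectors] == [
            ("p", 21, 1), ("p", 42, -1), ("p", 63, 1)
        ]
        assert all(v.values.shape == (657,) for v in vectors)

    def test_prediction_mode_enumerates_lysines(self):
        rec, pssm, prof = _protein("MKKV")
        vectors = featurize_protein(rec, pssm, prof, prediction_mode=True)
        assert [v.position for v in vectors] == [2, 3]
        assert all(v.label == 0 for v in vectors)

    def test_no_lysines_gives_empty_list(self):
        rec, pssm, prof = _protein("MAAV")
        assert featurize_protein(rec, pssm, prof, prediction_mode=True) == []

    def test_length_mismatch_rejected(self):
        rec, pssm, _ = _protein("MKAV" * 10)
        _, _, prof = _protein("MKAV" * 11)
        with pytest.raises(FeatureError, match="length"):
            featurize_protein(rec, pssm, prof, prediction_mode=True)

    def test_terminal_site_uses_mirror_padding(self):
        rec, pssm, prof = _protein("K" + "A" * 50, sites=[(1, 1)])
        (v,) = featurize_protein(rec, pssm, prof)
        assert v.values.shape == (657,)
        assert np.all(np.isfinite(v.values))

    def test_build_dataset_ids_and_labels(self, small_synthetic):
        d = small_synthetic
        ds = build_dataset(d.records, d.pssms, d.profiles)
        assert ds.X.shape == (50, 657)
        assert ds.n_positive == 25 and ds.n_negative == 25
        assert len(set(ds.ids)) == 50
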