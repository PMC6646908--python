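import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdprost.mrf import (
    SequenceParams,
    build_dictionary,
    compress_dictionary,
    default_flip_angle_train,
    default_sequence,
    default_t1_grid_ms,
    default_t2_grid_ms,
    epg_simulate,
    epg_simulate_batch,
    match_fingerprints,
    slice_profile,
    slice_profile_correct,
)

from helpers import bloch_isochromat_fisp, fisp_steady_state


class TestEpgClosedForms:
    def test_inversion_recovery_with_zero_flip_train(self):
        t1, tr, m = 700.0, 100.0, 20
        seq = SequenceParams(np.zeros(m), tr_ms=tr, te_ms=2.0, invert=True)
        sig, (_, _, z) = epg_simulate(t1, 45.0, seq, return_state=True)
        assert np.max(np.abs(sig)) == 0.0
        assert abs(z[0] - (1.0 - 2.0 * np.exp(-m * tr / t1))) < 1e-10

    def test_single_90_pulse_te_decay(self):
        te, t2 = 2.0, 45.0
        seq = SequenceParams([90.0], tr_ms=10.0, te_ms=te, invert=False)
        sig = epg_simulate(700.0, t2, seq)
        assert abs(abs(sig[0]) - np.exp(-te / t2)) < 1e-10

    def test_constant_train_reaches_closed_form_steady_state(self):
        t1, t2, tr, te, alpha = 700.0, 45.0, 4.4, 2.0, 30.0
        seq = SequenceParams(np.full(500, alpha), tr_ms=tr, te_ms=te, invert=False)
        sig = epg_simulate(t1, t2, seq)
        assert abs(abs(sig[-1]) - fisp_steady_state(alpha, tr, te, t1, t2)) < 1e-3

    def test_constant_train_matches_isochromat_bloch_oracle(self):
        t1, t2, tr, te = 700.0, 45.0, 4.4, 2.0
        n = 500
        seq = SequenceParams(np.full(n, 30.0), tr_ms=tr, te_ms=te, invert=False)
        ref = bloch_isochromat_fisp(seq.fa_deg, seq.rf_phase_deg, tr, te, t1, t2)
        assert np.max(np.abs(epg_simulate(t1, t2, seq) - ref)) < 1e-3

    def test_variable_train_matches_isochromat_bloch_oracle(self):
        t1, t2 = 900.0, 80.0
        seq = default_sequence(300)
        ref = bloch_isochromat_fisp(seq.fa_deg, seq.rf_phase_deg, seq.tr_ms,
                                    seq.te_ms, t1, t2, invert=True)
        assert np.max(np.abs(epg_simulate(t1, t2, seq) - ref)) < 1e-3

    def test_nonpositive_relaxation_times_rejected(self):
        seq = default_sequence(5)
        with pytest.raises(ValueError):
            epg_simulate(-1.0, 50.0, seq)
        with pytest.raises(ValueError):
            epg_simulate_batch([700.0], [0.0], seq)


class TestEpgBatch:
    def test_batch_kernel_matches_reference_implementation(self):
        seq = default_sequence(200)
        t1s = np.array([255.0, 700.0, 1489.0])
        t2s = np.array([44.0, 90.0, 243.0])
        batch = epg_simulate_batch(t1s, t2s, seq)
        for i, (t1, t2) in enumerate(zip(t1s, t2s)):
            assert np.max(np.abs(batch[:, i] - epg_simulate(t1, t2, seq))) < 1e-12

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.floats(200.0, 2000.0), st.floats(20.0, 400.0))
    def test_signal_continuous_in_t1(self, t1, t2):
        seq = default_sequence(150)
        a = epg_simulate(t1, t2, seq)
        b = epg_simulate(t1 * 1.01, t2, seq)
        assert np.linalg.norm(a - b) < 0.05 * np.linalg.norm(a)


class TestSliceProfile:
    def test_profile_normalized_at_center(self):
        p = slice_profile(51)
        assert p[25] == pytest.approx(1.0)
        assert np.all(p >= 0)

    def test_single_isochromat_equals_plain_epg(self):
        seq = default_sequence(100)
        assert np.allclose(
            slice_profile_correct(700.0, 45.0, seq, n_iso=1),
            epg_simulate(700.0, 45.0, seq),
        )

    def test_51_isochromats_close_to_dense_oracle(self):
        seq = default_sequence(200)
        a = slice_profile_correct(700.0, 45.0, seq, n_iso=51)
        b = slice_profile_correct(700.0, 45.0, seq, n_iso=501)
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 1e-2

    def test_even_isochromat_count_rejected(self):
        with pytest.raises(ValueError):
            slice_profile(10)


class TestDictionary:
    def test_default_grids_enumerate_to_printed_sizes(self):
        assert default_t1_grid_ms().size == 152
        assert default_t2_grid_ms().size == 77

    def test_atoms_unit_norm_and_full_product_grid(self):
        seq = default_sequence(60)
        d = build_dictionary([300.0, 700.0], [40.0, 60.0, 80.0], seq,
                             slice_correct=False)
        assert d.n_atoms == 6
        assert np.allclose(np.linalg.norm(d.atoms, axis=0), 1.0, atol=1e-10)

    def test_duplicate_grid_entries_produce_duplicate_atoms(self):
        seq = default_sequence(60)
        d = build_dictionary([700.0, 700.0], [50.0], seq, slice_correct=False)
        assert np.allclose(d.atoms[:, 0], d.atoms[:, 1])

    def test_compression_lossless_at_full_rank(self):
        seq = default_sequence(40)
        d = build_dictionary(np.arange(200.0, 1001.0, 100.0),
                             np.arange(30.0, 121.0, 30.0), seq, slice_correct=False)
        with pytest.warns(UserWarning, match="rank"):
            dc = compress_dictionary(d, 40)  # rank-deficient: falls back gracefully
        ur = dc.basis.ur
        assert np.allclose(ur.conj().T @ ur, np.eye(ur.shape[1]), atol=1e-12)
        assert np.allclose(ur @ dc.atoms, d.atoms, atol=1e-10)

    def test_rank10_truncation_error_matches_dense_svd_tail(self):
        from scipy.linalg import svdvals

        seq = default_sequence(80)
        d = build_dictionary(np.arange(200.0, 1601.0, 50.0),
                             np.arange(20.0, 201.0, 10.0), seq, slice_correct=False)
        dc = compress_dictionary(d, 10)
        approx = dc.basis.ur @ dc.atoms
        measured = np.linalg.norm(approx - d.atoms) / np.linalg.norm(d.atoms)
        s = svdvals(d.atoms)
        expected = np.sqrt(np.sum(s[10:] ** 2) / np.sum(s**2))
        assert measured == pytest.approx(expected, abs=1e-8)

    def test_invalid_rank_rejected(self):
        seq = default_sequence(40)
        d = build_dictionary([700.0], [50.0], seq, slice_correct=False)
        with pytest.raises(ValueError):
            compress_dictionary(d, 0)


@pytest.fixture(scope="module")
def small_dict():
    seq = default_sequence(150)
    d = build_dictionary(np.arange(200.0, 1501.0, 100.0),
                         np.arange(20.0, 201.0, 20.0), seq, slice_correct=False)
    return d


class TestMatching:
    def test_exact_self_match_on_25_random_atoms(self, small_dict, rng):
        js = rng.choice(small_dict.n_atoms, size=25, replace=False)
        signals = small_dict.atoms[:, js].T
        maps = match_fingerprints(signals, small_dict)
        assert np.array_equal(maps.match_index, js)
        assert np.allclose(maps.t1_ms, small_dict.t1_ms[js])
        assert np.allclose(np.abs(maps.m0) * small_dict.norms[js], 1.0, atol=1e-10)

    def test_complex_scale_equivariance(self, small_dict):
        j = 37
        x = 3.7 * np.exp(1j * np.pi / 5) * small_dict.atoms[:, j]
        maps = match_fingerprints(x[None, :], small_dict)
        assert maps.match_index[0] == j
        assert abs(np.abs(maps.m0[0]) * small_dict.norms[j] - 3.7) < 1e-10

    def test_noisy_match_equals_brute_force(self, small_dict):
        rng = np.random.default_rng(11)
        js = rng.integers(0, small_dict.n_atoms, 100)
        x = small_dict.atoms[:, js].T + 0.01 * (
            rng.standard_normal((100, small_dict.signal_dim))
            + 1j * rng.standard_normal((100, small_dict.signal_dim))
        )
        maps = match_fingerprints(x, small_dict)
        brute = np.argmax(np.abs(x @ np.conj(small_dict.atoms)), axis=1)
        assert np.array_equal(maps.match_index, brute)

    def test_zero_voxel_flagged(self, small_dict):
        x = np.zeros((3, small_dict.signal_dim), complex)
        x[1] = small_dict.atoms[:, 5]
        maps = match_fingerprints(x, small_dict)
        assert maps.match_index[0] == -1 and maps.m0[0] == 0
        assert maps.match_index[1] == 5

    def test_compressed_match_agrees_with_uncompressed(self, small_dict):
        rng = np.random.default_rng(19)
        dc = compress_dictionary(small_dict, 10)
        js = rng.integers(0, small_dict.n_atoms, 500)
        x_full = small_dict.atoms[:, js].T
        x_comp = x_full @ np.conj(dc.basis.ur.conj())  # U_r^H x per row
        full = match_fingerprints(x_full, small_dict).match_index
        comp = match_fingerprints(x_comp, dc).match_index
        assert np.mean(full == comp) >= 0.99

    def test_dimension_mismatch_rejected(self, small_dict):
        with pytest.raises(ValueError, match="dimension"):
            match_fingerprints(np.zeros((2, 7), complex), small_dict)
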