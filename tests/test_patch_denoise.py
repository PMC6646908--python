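import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdprost.patch_denoise import (
    DenoiseParams,
    PatchTensor,
    aggregate,
    block_match,
    build_patch_tensor,
    denoise_multicontrast,
    fold,
    hosvd_truncate,
    mode_singular_values,
    reference_grid,
    unfold,
)

from conftest import random_complex
from helpers import brute_force_block_match


class TestBlockMatch:
    def test_constant_image_ties_break_in_scan_order(self):
        x = np.ones((12, 12, 2), complex)
        p = DenoiseParams(patch_edge=3, n_similar=4, search_radius=3, patch_offset=1)
        sel = block_match(x, (5, 5), p)
        assert tuple(sel[0]) == (5, 5)
        # remaining candidates in row-major order of the window
        assert [tuple(c) for c in sel[1:]] == [(2, 2), (2, 3), (2, 4)]

    def test_exact_translated_copy_ranks_second_with_zero_distance(self, rng):
        x = random_complex(rng, (20, 20, 2))
        x[10:13, 4:7, :] = x[3:6, 4:7, :]  # translated copy of the reference
        p = DenoiseParams(patch_edge=3, n_similar=3, search_radius=8, patch_offset=1)
        sel = block_match(x, (3, 4), p)
        assert tuple(sel[1]) == (10, 4)

    def test_matches_brute_force_on_random_image(self, rng):
        x = random_complex(rng, (32, 32, 2))
        p = DenoiseParams(patch_edge=5, n_similar=8, search_radius=7, patch_offset=1)
        for ref in [(0, 0), (13, 21), (27, 5)]:
            sel = [tuple(c) for c in block_match(x, ref, p)]
            assert sel == brute_force_block_match(x, ref, 5, 7, 8)

    def test_small_window_shrinks_group_with_warning(self):
        x = np.ones((8, 8, 1), complex)
        p = DenoiseParams(patch_edge=5, n_similar=50, search_radius=5, patch_offset=1)
        with pytest.warns(UserWarning, match="shrinks"):
            sel = block_match(x, (0, 0), p)
        assert sel.shape[0] == 16  # all 4x4 valid corners

    def test_reference_outside_image_raises(self):
        x = np.ones((8, 8, 1), complex)
        p = DenoiseParams(patch_edge=5, n_similar=2, search_radius=5, patch_offset=1)
        with pytest.raises(IndexError):
            block_match(x, (6, 0), p)


class TestPatchTensor:
    def test_tensor_shape_49_20_10(self, rng):
        x = random_complex(rng, (64, 64, 10))
        p = DenoiseParams(patch_edge=7, n_similar=20, search_radius=20, patch_offset=3)
        coords = block_match(x, (20, 20), p)
        t = build_patch_tensor(x, coords, p)
        assert t.data.shape == (49, 20, 10)

    def test_single_patch_is_vectorized_reference(self, rng):
        x = random_complex(rng, (12, 12, 3))
        p = DenoiseParams(patch_edge=3, n_similar=1, search_radius=3, patch_offset=1)
        t = build_patch_tensor(x, [(4, 5)], p)
        assert np.array_equal(t.data[:, 0, :], x[4:7, 5:8, :].reshape(9, 3))

    def test_unfold_fold_round_trip_all_modes(self, rng):
        t = random_complex(rng, (5, 4, 3))
        for mode in range(3):
            assert np.array_equal(fold(unfold(t, mode), mode, t.shape), t)

    def test_out_of_bounds_coord_raises(self, rng):
        x = random_complex(rng, (8, 8, 2))
        p = DenoiseParams(patch_edge=3, n_similar=1, search_radius=3, patch_offset=1)
        with pytest.raises(IndexError):
            build_patch_tensor(x, [(7, 0)], p)


class TestHosvd:
    def test_tau_zero_is_identity(self, rng):
        t = random_complex(rng, (9, 6, 4))
        out = hosvd_truncate(t, 0.0)
        assert np.linalg.norm(out - t) / np.linalg.norm(t) < 1e-10

    def test_rank_111_tensor_recovered_exactly(self, rng):
        a, b, c = (random_complex(rng, (n,)) for n in (8, 5, 3))
        t = np.einsum("i,j,k->ijk", a, b, c)
        sigma1 = np.linalg.norm(a) * np.linalg.norm(b) * np.linalg.norm(c)
        out = hosvd_truncate(t, 0.5 * sigma1)
        assert np.linalg.norm(out - t) / np.linalg.norm(t) < 1e-10

    def test_mode_singular_values_match_dense_unfolding_svd(self, rng):
        t = random_complex(rng, (20, 8, 4))
        for mode in range(3):
            dense = np.linalg.svd(
                np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1),
                compute_uv=False,
            )
            assert np.allclose(mode_singular_values(t, mode), dense, atol=1e-10)

    def test_truncation_never_expands_singular_values(self, rng):
        for _ in range(5):
            t = random_complex(rng, (10, 6, 4))
            out = hosvd_truncate(t, 1.5)
            assert np.linalg.norm(out) <= np.linalg.norm(t) + 1e-12
            for mode in range(3):
                s_in = mode_singular_values(t, mode)
                s_out = mode_singular_values(out, mode)
                assert np.all(s_out <= s_in + 1e-10)

    def test_non_finite_input_rejected(self):
        t = np.full((3, 3, 3), np.nan, dtype=complex)
        with pytest.raises(ValueError, match="finite"):
            hosvd_truncate(t, 0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 10.0))
    def test_truncation_nonexpansive_property(self, seed, tau):
        r = np.random.default_rng(seed)
        t = r.standard_normal((6, 5, 3)) + 1j * r.standard_normal((6, 5, 3))
        out = hosvd_truncate(t, tau)
        assert np.linalg.norm(out) <= np.linalg.norm(t) + 1e-10


class TestAggregateAndDenoise:
    def test_two_estimates_average(self):
        shape = (4, 4, 1)
        p = np.zeros((4, 1, 1), complex)
        g1 = PatchTensor(p + 1.0, np.array([[0, 0]]))
        g2 = PatchTensor(p + 3.0, np.array([[0, 0]]))
        g_rest = PatchTensor(np.full((4, 4, 1), 2.0, complex),
                             np.array([[0, 0], [0, 2], [2, 0], [2, 2]]))
        out = aggregate([g1, g2, g_rest], shape)
        assert np.allclose(out[0, 0, 0], (1.0 + 3.0 + 2.0) / 3)

    def test_uncovered_voxel_raises(self):
        g = PatchTensor(np.ones((4, 1, 1), complex), np.array([[0, 0]]))
        with pytest.raises(RuntimeError, match="uncovered"):
            aggregate([g], (4, 4, 1))

    def test_reference_grid_touches_boundary(self):
        grid = reference_grid((10, 10), edge=3, offset=4)
        xs = sorted({g[0] for g in grid})
        assert xs == [0, 4, 7]

    def test_zero_image_maps_to_zero(self):
        p = DenoiseParams(patch_edge=3, n_similar=4, search_radius=4, patch_offset=2,
                          tau=1.0)
        out = denoise_multicontrast(np.zeros((10, 10, 2), complex), p)
        assert np.all(out == 0)

    def test_tau_zero_full_pipeline_is_identity(self, rng):
        x = random_complex(rng, (16, 16, 3))
        p = DenoiseParams(patch_edge=3, n_similar=5, search_radius=4, patch_offset=2,
                          tau=0.0)
        out = denoise_multicontrast(x, p)
        assert np.linalg.norm(out - x) / np.linalg.norm(x) < 1e-10

    def test_noise_reduced_on_piecewise_constant_phantom(self):
        rng = np.random.default_rng(3)
        clean = np.zeros((32, 32, 2), complex)
        clean[4:16, 4:16] = [1.0, 0.5]
        clean[16:28, 16:28] = [0.4, 0.9]
        noisy = clean + 0.05 * (
            rng.standard_normal(clean.shape) + 1j * rng.standard_normal(clean.shape)
        )
        p = DenoiseParams(patch_edge=5, n_similar=8, search_radius=8, patch_offset=2,
                          tau=0.5)
        out = denoise_multicontrast(noisy, p)
        assert np.mean(np.abs(out - clean) ** 2) < np.mean(np.abs(noisy - clean) ** 2)

    def test_structured_noise_free_image_nearly_unchanged(self, rng):
        # image tiled from 5 distinct motifs: informative singular values are
        # large, so a small tau must leave the image essentially untouched
        motifs = random_complex(rng, (5, 4, 4, 2))
        x = np.zeros((16, 16, 2), complex)
        idx = rng.integers(0, 5, size=(4, 4))
        for i in range(4):
            for j in range(4):
                x[4 * i:4 * i + 4, 4 * j:4 * j + 4] = motifs[idx[i, j]]
        p = DenoiseParams(patch_edge=4 - 1, n_similar=6, search_radius=6,
                          patch_offset=2, tau=1e-4)
        out = denoise_multicontrast(x, p)
        assert np.linalg.norm(out - x) / np.linalg.norm(x) < 1e-3

    def test_permuting_candidate_patches_leaves_aggregate_unchanged(self, rng):
        x = random_complex(rng, (12, 12, 2))
        p = DenoiseParams(patch_edge=3, n_similar=5, search_radius=5, patch_offset=3,
                          tau=0.8)
        groups, groups_perm = [], []
        for ref in reference_grid((12, 12), 3, 3):
            coords = block_match(x, ref, p)
            t = build_patch_tensor(x, coords, p)
            groups.append(hosvd_truncate(t, p.tau))
            perm = np.concatenate([[0], 1 + np.random.default_rng(0).permutation(4)])
            t2 = build_patch_tensor(x, coords[perm], p)
            groups_perm.append(hosvd_truncate(t2, p.tau))
        a = aggregate(groups, x.shape)
        b = aggregate(groups_perm, x.shape)
        assert np.allclose(a, b, atol=1e-10)
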