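"""Shift sampling, piecewise affine maps, and the warp pipeline."""

import numpy as np
import pytest

import endowarp.warp_engine as we
from endowarp import (
    KeypointSet,
    WarpRejectedError,
    apply_warp,
    border_lattice,
    build_map,
    combine_keypoints,
    extract_centroids,
    sample_shifts,
    warp_pair,
)
from endowarp.fixtures import LabeledPair
from endowarp.geometry import INTERIOR


def full_keypoints(pair):
    h, w = pair.shape
    return combine_keypoints(extract_centroids(pair), border_lattice(w, h))


def zero_shifts(K):
    return we.ShiftField(deltas=np.zeros((len(K), 2)), s=2.0, d_min_used=1.0, rng_seed=0)


class TestSampleShifts:
    def test_bound_and_frozen_border(self, forty_cell_pair):
        K = full_keypoints(forty_cell_pair)
        sf = sample_shifts(K, 2.0, seed=42)
        assert np.all(np.abs(sf.deltas) <= sf.d_min_used / 2.0)
        assert np.all(sf.deltas[~K.interior_mask] == 0)

    def test_deterministic_given_seed(self, forty_cell_pair):
        K = full_keypoints(forty_cell_pair)
        a, b = sample_shifts(K, 2.0, seed=9), sample_shifts(K, 2.0, seed=9)
        assert np.array_equal(a.deltas, b.deltas)
        assert not np.array_equal(a.deltas, sample_shifts(K, 2.0, seed=10).deltas)

    def test_large_s_is_numerically_identity(self, clean_pair):
        K = full_keypoints(clean_pair)
        sf = sample_shifts(K, 1e6, seed=0)
        assert np.all(np.abs(sf.deltas) <= sf.d_min_used * 1e-6)

    def test_forced_unit_draw_gives_d_min_over_s(self, monkeypatch):
        """R = +1 on both axes with d_min = 8, s = 2 yields delta = (4, 4)."""
        class Ones:
            def uniform(self, lo, hi, size):
                return np.ones(size)

        monkeypatch.setattr(we, "rng_from", lambda *a: Ones())
        K = KeypointSet(points=np.array([[10.0, 10.0], [18.0, 40.0]]),
                        roles=np.array([INTERIOR, INTERIOR]))
        sf = sample_shifts(K, 2.0, seed=0)
        assert sf.d_min_used == 8.0
        assert np.allclose(sf.deltas, [[4.0, 4.0], [4.0, 4.0]])

    def test_degenerate_d_min_floored_to_one(self):
        K = KeypointSet(points=np.array([[5.0, 5.0], [5.0, 40.0]]),
                        roles=np.array([INTERIOR, INTERIOR]))
        sf = sample_shifts(K, 2.0, seed=1)
        assert sf.d_min_used == 1.0

    def test_mean_shift_ratio_tracks_strain(self):
        """Monte-Carlo: E|delta| at s=2 over s=3 is 3/2 within 5%."""
        K = KeypointSet(points=np.array([[10.0, 10.0], [30.0, 40.0]]),
                        roles=np.array([INTERIOR, INTERIOR]))
        m = {}
        for s in (2.0, 3.0):
            mags = [np.abs(sample_shifts(K, s, seed=i).deltas).mean() for i in range(10_000)]
            m[s] = np.mean(mags)
        assert m[2.0] / m[3.0] == pytest.approx(1.5, rel=0.05)

    def test_invalid_strain_rejected(self, clean_pair):
        with pytest.raises(ValueError, match="s must be > 0"):
            sample_shifts(full_keypoints(clean_pair), 0.0, seed=0)


class TestBuildMap:
    def test_zero_shifts_give_identity_affines(self, clean_pair):
        K = full_keypoints(clean_pair)
        pmap = build_map(K, zero_shifts(K))
        assert pmap.valid
        ident = np.tile(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), (len(pmap.forward_coeff), 1, 1))
        assert np.allclose(pmap.forward_coeff, ident, atol=1e-9)

    def test_vertex_exactness(self, forty_cell_pair):
        K = full_keypoints(forty_cell_pair)
        sf = sample_shifts(K, 2.0, seed=5)
        pmap = build_map(K, sf)
        assert pmap.valid
        err = np.abs(pmap.forward(K.points) - (K.points + sf.deltas))
        assert err.max() <= 1e-9

    def test_single_shifted_point_maps_exactly(self):
        border = border_lattice(64, 64)
        K = combine_keypoints(
            KeypointSet(points=np.array([[30.0, 30.0]]), roles=np.array([INTERIOR])), border
        )
        deltas = np.zeros((len(K), 2))
        deltas[0] = (4.0, 0.0)
        sf = we.ShiftField(deltas=deltas, s=2.0, d_min_used=8.0, rng_seed=0)
        pmap = build_map(K, sf)
        assert np.allclose(pmap.forward([[30.0, 30.0]]), [[34.0, 30.0]], atol=1e-9)

    def test_forward_agrees_with_barycentric_oracle(self, forty_cell_pair, rng):
        """Brute force: find containing triangle, interpolate vertex shifts."""
        K = full_keypoints(forty_cell_pair)
        sf = sample_shifts(K, 2.0, seed=5)
        pmap = build_map(K, sf)
        tris = pmap.connectivity.triangles
        src = K.points
        dst = src + sf.deltas
        queries = rng.uniform(1, 94, size=(200, 2))
        got = pmap.forward(queries)
        for q, g in zip(queries, got):
            expected = None
            for tri in tris:
                a, b, c = src[tri]
                det = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
                w1 = ((c[1] - a[1]) * (q[0] - a[0]) - (c[0] - a[0]) * (q[1] - a[1])) / det
                w2 = (-(b[1] - a[1]) * (q[0] - a[0]) + (b[0] - a[0]) * (q[1] - a[1])) / det
                w0 = 1 - w1 - w2
                if min(w0, w1, w2) >= -1e-12:
                    expected = w0 * dst[tri[0]] + w1 * dst[tri[1]] + w2 * dst[tri[2]]
                    break
            assert expected is not None
            assert np.abs(g - expected).max() <= 1e-6

    def test_foldover_flagged_invalid_not_raised(self):
        """A shift large enough to invert a triangle invalidates the map."""
        border = border_lattice(32, 32)
        pts = np.vstack([[[8.0, 8.0], [24.0, 8.0]], border.points])
        roles = np.concatenate([[INTERIOR, INTERIOR], border.roles])
        K = KeypointSet(points=pts, roles=roles)
        deltas = np.zeros((len(K), 2))
        deltas[0], deltas[1] = (20.0, 0.0), (-20.0, 0.0)  # swap the two interior points
        sf = we.ShiftField(deltas=deltas, s=1.0, d_min_used=20.0, rng_seed=0)
        pmap = build_map(K, sf)
        assert not pmap.valid
        with pytest.raises(ValueError, match="invalid"):
            pmap.forward([[10.0, 10.0]])

    def test_source_connectivity_switch(self, clean_pair):
        K = full_keypoints(clean_pair)
        sf = sample_shifts(K, 3.0, seed=2)
        pmap = build_map(K, sf, connectivity_side="source")
        assert pmap.valid
        err = np.abs(pmap.forward(K.points) - (K.points + sf.deltas))
        assert err.max() <= 1e-9

    def test_misaligned_shifts_rejected(self, clean_pair):
        K = full_keypoints(clean_pair)
        bad = we.ShiftField(deltas=np.zeros((3, 2)), s=2.0, d_min_used=1.0, rng_seed=0)
        with pytest.raises(ValueError, match="not aligned"):
            build_map(K, bad)


class TestApplyWarp:
    def test_identity_map_bit_exact(self, noisy_pair):
        K = full_keypoints(noisy_pair)
        pmap = build_map(K, zero_shifts(K))
        out = apply_warp(noisy_pair, pmap)
        assert np.array_equal(out.image, noisy_pair.image)
        assert np.array_equal(out.label_mask, noisy_pair.label_mask)

    def test_labels_never_invented(self, forty_cell_pair):
        K = full_keypoints(forty_cell_pair)
        sf = sample_shifts(K, 2.0, seed=8)
        out = apply_warp(forty_cell_pair, build_map(K, sf))
        assert set(np.unique(out.label_mask)) <= set(np.unique(forty_cell_pair.label_mask))

    def test_constant_image_stays_constant(self, clean_pair):
        const = LabeledPair(image=np.full(clean_pair.shape, 0.5),
                            label_mask=clean_pair.label_mask)
        K = full_keypoints(const)
        sf = sample_shifts(K, 2.0, seed=4)
        out = apply_warp(const, build_map(K, sf))
        assert np.abs(out.image - 0.5).max() <= 1e-6

    def test_boundary_mask_warp_mode(self, clean_pair):
        K = full_keypoints(clean_pair)
        sf = sample_shifts(K, 2.0, seed=4)
        out = apply_warp(clean_pair, build_map(K, sf), mask_warp="boundary")
        # connected-component relabelling: same region count, ids renumbered
        assert len(out.region_ids()) == len(clean_pair.region_ids())


class TestWarpPair:
    def test_huge_s_returns_input(self, noisy_pair):
        out, sf = warp_pair(noisy_pair, 1e6, seed=0)
        assert sf.stream == 0  # accepted on first try
        assert np.abs(out.image - noisy_pair.image).max() < 1 / 255
        assert np.array_equal(out.label_mask, noisy_pair.label_mask)

    def test_deterministic_across_runs(self, noisy_pair):
        a, _ = warp_pair(noisy_pair, 3.0, seed=17)
        b, _ = warp_pair(noisy_pair, 3.0, seed=17)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.label_mask, b.label_mask)

    def test_region_ids_preserved(self, forty_cell_pair):
        out, _ = warp_pair(forty_cell_pair, 2.0, seed=1)
        assert np.array_equal(np.unique(out.label_mask), np.unique(forty_cell_pair.label_mask))

    def test_border_pixels_fixed(self, clean_pair):
        out, sf = warp_pair(clean_pair, 2.0, seed=6)
        for sl in (np.s_[0, :], np.s_[-1, :], np.s_[:, 0], np.s_[:, -1]):
            assert np.array_equal(out.label_mask[sl], clean_pair.label_mask[sl])

    def test_mean_displacement_larger_at_stronger_strain(self, clean_pair):
        """s=2 deforms more than s=3 for the same seed (paired draws)."""
        wins = 0
        n = 12
        for seed in range(n):
            disp = {}
            for s in (2.0, 3.0):
                K = full_keypoints(clean_pair)
                sf = sample_shifts(K, s, seed=seed)
                pmap = build_map(K, sf)
                if not pmap.valid:
                    break
                grid = np.stack(np.meshgrid(np.arange(0, 96, 3.0), np.arange(0, 96, 3.0)), -1).reshape(-1, 2)
                disp[s] = np.linalg.norm(pmap.forward(grid) - grid, axis=1).mean()
            if len(disp) == 2 and disp[2.0] > disp[3.0]:
                wins += 1
        assert wins >= n - 1

    def test_retry_budget_exhaustion_reports_mode(self, clean_pair, monkeypatch):
        monkeypatch.setattr(we, "_regions_intact", lambda *a: False)
        with pytest.raises(WarpRejectedError, match="region-loss"):
            warp_pair(clean_pair, 2.0, seed=0, retry_budget=3)
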