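"""Interstitial geometry: preprocessing, extraction, ellipses, fits, lines."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ifshear as ifs
from ifshear.volume import Volume3D


def flood_fill_components(fg):
    """Exhaustive BFS labelling oracle (26-connectivity)."""
    fg = np.asarray(fg, dtype=bool)
    labels = np.zeros(fg.shape, dtype=int)
    nxt = 0
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    for start in zip(*np.nonzero(fg)):
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            p = stack.pop()
            for off in offsets:
                q = tuple(p[d] + off[d] for d in range(3))
                if all(0 <= q[d] < fg.shape[d] for d in range(3)) and fg[q] and not labels[q]:
                    labels[q] = nxt
                    stack.append(q)
    return labels


class TestPreprocess:
    def test_constant_volume_preserved(self):
        vol = Volume3D(np.full((10, 12, 8), 3.5), (0.5, 0.5, 0.5))
        out = ifs.preprocess_volume(vol, 0.25, 5)
        assert np.allclose(out.data, 3.5)
        assert out.spacing == (0.25, 0.25, 0.25)

    def test_resampling_voxel_counts(self):
        # 20 voxels of 1.036 μm resample to 100 voxels of 0.2072 μm
        vol = Volume3D(np.zeros((20, 20, 20)), (1.036, 1.036, 1.036))
        out = ifs.preprocess_volume(vol, 0.2072, 1)
        assert out.shape == (100, 100, 100)

    def test_box_smoothing_spreads_single_voxel_uniformly(self):
        data = np.zeros((11, 11, 11))
        data[5, 5, 5] = 125.0
        out = ifs.preprocess_volume(Volume3D(data, (1, 1, 1)), 1.0, 5)
        inside = out.data[3:8, 3:8, 3:8]
        assert np.allclose(inside, 1.0)
        assert np.allclose(out.data.sum(), 125.0)
        assert out.data[0, 5, 5] == 0.0

    def test_target_voxel_too_large_rejected(self):
        vol = Volume3D(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            ifs.preprocess_volume(vol, 10.0, 1)

    def test_even_smoothing_width_rejected(self):
        vol = Volume3D(np.zeros((8, 8, 8)), (1, 1, 1))
        with pytest.raises(ValueError):
            ifs.preprocess_volume(vol, 1.0, 4)


class TestExtraction:
    def test_two_level_volume_yields_single_cluster(self):
        data = np.full((10, 10, 10), 10.0)
        data[:2, :10, :10] = 100.0  # exactly 20% bright, one connected blob
        vol = Volume3D(data, (1, 1, 1))
        cs = ifs.extract_interstitial_clusters(vol, min_size=50)
        assert len(cs) == 1
        assert cs.clusters[0].size == 200

    def test_threshold_conservation_exact_for_distinct_intensities(self):
        rng = np.random.default_rng(0)
        data = rng.permutation(np.arange(1000.0)).reshape(10, 10, 10)
        vol = Volume3D(data, (1, 1, 1))
        cs = ifs.extract_interstitial_clusters(vol, top_fraction=0.2,
                                               huge_size=10**9, min_size=1)
        assert int((cs.labels > 0).sum()) == 200  # floor(0.2 * 1000)
        # brute-force oracle: the 200 highest intensities
        expected = set(map(tuple, np.argwhere(data > np.sort(data.ravel())[-201])))
        got = set(map(tuple, np.argwhere(cs.labels > 0)))
        assert got == expected

    def test_huge_cluster_trimmed_to_exact_half(self):
        rng = np.random.default_rng(1)
        data = np.zeros((40, 25, 10))
        block = rng.permutation(np.arange(6000.0)).reshape(24, 25, 10) + 1000.0
        data[:24] = block  # one 6,000-voxel component with distinct ranking
        vol = Volume3D(data, (1, 1, 1))
        cs = ifs.extract_interstitial_clusters(vol, top_fraction=0.6,
                                               huge_size=5000, trim_fraction=0.5,
                                               min_size=1)
        kept = {tuple(i) for c in cs.clusters for i in c.indices}
        # brute-force: keep the 3,000 highest-intensity voxels of the block
        order = np.argsort(block.ravel(), kind="stable")
        expected = set()
        for flat in order[3000:]:
            i, j, k = np.unravel_index(flat, block.shape)
            expected.add((i, j, k))
        assert len(kept) == 3000
        assert kept == expected

    def test_small_cluster_clearance_boundary(self):
        for n, expect in ((49, 0), (50, 1)):
            data = np.full((20, 20, 20), 1.0)
            data.ravel()[:0] = 0
            blob = np.zeros((20, 20, 20), dtype=bool)
            # a compact n-voxel blob
            idx = np.argwhere(np.ones((5, 5, 5)))[:n]
            for i, j, k in idx:
                blob[i + 5, j + 5, k + 5] = True
            data[blob] = 100.0
            vol = Volume3D(data, (1, 1, 1))
            cs = ifs.extract_interstitial_clusters(vol, top_fraction=0.2, min_size=50)
            assert len(cs) == expect

    def test_constant_volume_gives_empty_foreground(self):
        vol = Volume3D(np.full((8, 8, 8), 2.0), (1, 1, 1))
        cs = ifs.extract_interstitial_clusters(vol)
        assert len(cs) == 0

    @given(st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_labeling_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fg = rng.random((6, 6, 6)) < 0.35
        data = np.where(fg, 10.0, 0.0) + rng.random((6, 6, 6)) * 0.1
        vol = Volume3D(data, (1, 1, 1))
        cs = ifs.extract_interstitial_clusters(vol, top_fraction=fg.mean() or 0.5,
                                               huge_size=10**9, min_size=1)
        oracle = flood_fill_components(cs.labels > 0)
        # same partition: component memberships agree up to relabeling
        mapping = {}
        for lab, olab in zip(cs.labels.ravel(), oracle.ravel()):
            if (lab > 0) != (olab > 0):
                raise AssertionError("foreground mismatch")
            if lab > 0:
                assert mapping.setdefault(lab, olab) == olab

    @given(st.integers(0, 10**6))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_monotone_filtering(self, seed):
        rng = np.random.default_rng(seed)
        vol = Volume3D(rng.random((12, 12, 12)), (1, 1, 1))
        n_small = len(ifs.extract_interstitial_clusters(vol, min_size=5, huge_size=10**9))
        n_large = len(ifs.extract_interstitial_clusters(vol, min_size=20, huge_size=10**9))
        assert n_large <= n_small
        fg_20 = (ifs.extract_interstitial_clusters(vol, top_fraction=0.2,
                                                   min_size=1, huge_size=10**9).labels > 0).sum()
        fg_10 = (ifs.extract_interstitial_clusters(vol, top_fraction=0.1,
                                                   min_size=1, huge_size=10**9).labels > 0).sum()
        assert fg_10 <= fg_20


def _single_footprint_clusterset(footprint_2d, spacing=1.0):
    """Embed a 2D footprint at z-slice 0 of a 3-slice volume."""
    fp = np.asarray(footprint_2d, dtype=bool)
    data = np.zeros((*fp.shape, 3))
    data[:, :, 0] = np.where(fp, 100.0, 0.0)
    vol = Volume3D(data, (spacing,) * 3)
    top = max(min(fp.mean() / 3, 0.99), 1e-3)
    return ifs.extract_interstitial_clusters(vol, top_fraction=top,
                                             huge_size=10**9, min_size=1)


class TestEllipses:
    def test_disk_axes_match_diameter_and_angle_convention(self):
        n = 41
        yy, xx = np.mgrid[:n, :n]
        r = 15
        disk = (xx - 20) ** 2 + (yy - 20) ** 2 <= r**2
        cs = _single_footprint_clusterset(disk)
        (fit,) = ifs.fit_cluster_ellipses(cs, plane="xy", slice_index=0)
        # second moments of a disk of radius r: axis length 4*(r/2) = 2r
        assert fit.major_axis == pytest.approx(2 * r, rel=0.05)
        assert fit.minor_axis == pytest.approx(2 * r, rel=0.05)
        assert fit.angle == 0.0

    def test_thin_segment_major_axis_and_angle(self):
        seg = np.zeros((30, 5), dtype=bool)
        seg[2:27, 2] = True  # length 25 along x
        cs = _single_footprint_clusterset(seg)
        (fit,) = ifs.fit_cluster_ellipses(cs, plane="xy", slice_index=0)
        assert fit.angle == pytest.approx(0.0, abs=1e-9)
        assert fit.major_axis == pytest.approx(25 * 4 / math.sqrt(12), rel=0.02)

    def test_rotation_by_90_degrees_shifts_angle_only(self):
        rng = np.random.default_rng(3)
        fp = np.zeros((20, 20), dtype=bool)
        fp[4:16, 8:11] = True
        fp[rng.integers(4, 16), 11] = True  # break symmetry a little
        cs = _single_footprint_clusterset(fp)
        (a,) = ifs.fit_cluster_ellipses(cs, plane="xy", slice_index=0)
        cs_rot = _single_footprint_clusterset(fp.T[:, ::-1])
        (b,) = ifs.fit_cluster_ellipses(cs_rot, plane="xy", slice_index=0)
        assert b.major_axis == pytest.approx(a.major_axis, rel=1e-6)
        assert b.minor_axis == pytest.approx(a.minor_axis, rel=1e-6)
        da = (b.angle - a.angle) % math.pi
        assert min(da, math.pi - da) == pytest.approx(math.pi / 2, abs=1e-6) or \
            da == pytest.approx(math.pi / 2, abs=1e-6)

    def test_tiny_footprints_skipped(self):
        fp = np.zeros((10, 10), dtype=bool)
        fp[5, 5] = True
        cs = _single_footprint_clusterset(fp)
        assert ifs.fit_cluster_ellipses(cs, plane="xy", slice_index=0) == []

    def test_slice_selection_picks_highest_mean_fluorescence(self):
        data = np.zeros((10, 10, 4))
        data[2:8, 2:8, 2] = 50.0  # slice 2 along z is brightest
        vol = Volume3D(data, (1, 1, 1))
        from ifshear.geometry import select_slice

        assert select_slice(vol, stack_axis=2) == 2


class TestPoreDistribution:
    def test_mode_recovered_from_large_lognormal_sample(self):
        rng = np.random.default_rng(12)
        draws = rng.lognormal(-3.0, 0.8, 10_000)
        fit = ifs.estimate_cross_section_distribution(draws)
        assert fit.mode == pytest.approx(math.exp(-3.0 - 0.64), rel=0.10)
        # independent cross-check: scipy's MLE with fixed location
        shape, _, scale = stats.lognorm.fit(draws, floc=0)
        assert fit.log_mu == pytest.approx(math.log(scale), abs=1e-6)
        assert fit.log_sigma == pytest.approx(shape, abs=1e-6)

    def test_fwhm_bounds_sit_at_half_maximum_density(self):
        rng = np.random.default_rng(13)
        fit = ifs.estimate_cross_section_distribution(rng.lognormal(-2.0, 0.5, 5000))
        pdf = stats.lognorm(fit.log_sigma, scale=math.exp(fit.log_mu)).pdf
        half = pdf(fit.mode) / 2
        assert pdf(fit.fwhm_low) == pytest.approx(half, rel=1e-9)
        assert pdf(fit.fwhm_high) == pytest.approx(half, rel=1e-9)
        assert fit.fwhm_low < fit.mode < fit.fwhm_high

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(14)
        draws = rng.lognormal(-1.0, 0.6, 200)
        base = ifs.estimate_cross_section_distribution(draws)
        scaled = ifs.estimate_cross_section_distribution(draws * c)
        assert scaled.mode == pytest.approx(base.mode * c, rel=1e-9)
        assert scaled.fwhm_low == pytest.approx(base.fwhm_low * c, rel=1e-9)
        assert scaled.fwhm_high == pytest.approx(base.fwhm_high * c, rel=1e-9)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            ifs.estimate_cross_section_distribution([1.0] * 20)
        with pytest.raises(ValueError):
            ifs.estimate_cross_section_distribution([1.0] * 5)
        with pytest.raises(ValueError):
            ifs.estimate_cross_section_distribution([1.0] * 9 + [-1.0])

    def test_voxel_count_scaling(self):
        rng = np.random.default_rng(15)
        counts = rng.lognormal(3.0, 0.5, 100)
        a = ifs.estimate_cross_section_distribution(counts, voxel_area=0.01)
        b = ifs.estimate_cross_section_distribution(counts * 0.01)
        assert a.mode == pytest.approx(b.mode, rel=1e-12)


def _sigmoid(y, c, d, y0, s):
    return c + d / (1 + np.exp(-(y - y0) / s))


class TestCenterLine:
    def test_cuboid_gives_straight_centre_line(self):
        data = np.zeros((20, 30, 20))
        data[5:15, :, 8:14] = 1.0
        line = ifs.compute_centroidal_line(Volume3D(data, (1, 1, 1)), "y")
        assert np.allclose(line.residuals, 0.0, atol=1e-6)
        assert np.allclose(line.points[:, 0], 10.0)
        assert np.allclose(line.points[:, 2], 11.0, atol=1e-6)

    def test_exact_sigmoid_centroids_recovered(self):
        ny = 40
        c, d, y0, s = 6.0, 10.0, 20.0, 3.0
        data = np.zeros((30, ny, 30))
        for j in range(ny):
            z = _sigmoid(j + 0.5, c, d, y0, s)
            x = 10.0 + 0.2 * (j + 0.5)
            # 3x3 block centred on (x, z): centroid is exactly (x, z)
            data[int(round(x)) - 1:int(round(x)) + 2, j,
                 int(round(z)) - 1:int(round(z)) + 2] = 1.0
        line = ifs.compute_centroidal_line(Volume3D(data, (1, 1, 1)), "y")
        assert line.sigmoid_converged
        fit_c, fit_d, fit_y0, fit_s = line.sigmoid_params
        # centroids of rounded blocks quantise; parameters still land close
        assert fit_y0 == pytest.approx(y0, rel=0.05)
        assert fit_d == pytest.approx(d, rel=0.10)

    def test_translation_equivariance(self):
        data = np.zeros((20, 25, 20))
        data[4:9, 3:22, 6:12] = 1.0
        base = ifs.compute_centroidal_line(Volume3D(data, (1, 1, 1)), "y")
        shifted = np.roll(data, (3, 0, 2), axis=(0, 1, 2))
        moved = ifs.compute_centroidal_line(Volume3D(shifted, (1, 1, 1)), "y")
        np.testing.assert_allclose(moved.points[:, 0], base.points[:, 0] + 3, atol=1e-9)
        np.testing.assert_allclose(moved.points[:, 2], base.points[:, 2] + 2, atol=1e-9)

    def test_too_few_slices_rejected(self):
        data = np.zeros((5, 6, 5))
        data[2, 2:4, 2] = 1.0
        with pytest.raises(ValueError):
            ifs.compute_centroidal_line(Volume3D(data, (1, 1, 1)), "y")


class TestOrientation:
    def test_parallel_axes_fully_aligned(self):
        fits = [
            ifs.EllipseFit(cluster_id=i, centroid=(0, 0), major_axis=4.0,
                           minor_axis=1.0, angle=0.0, area=1.0, n_voxels=10)
            for i in range(5)
        ]
        summ = ifs.orientation_summary(fits, plane="xy")
        assert summ.resultant_length == pytest.approx(1.0)
        assert np.allclose(summ.acute_angles, 0.0)

    def test_isotropic_angles_have_vanishing_resultant(self):
        rng = np.random.default_rng(21)
        fits = [
            ifs.EllipseFit(cluster_id=i, centroid=(0, 0), major_axis=4.0,
                           minor_axis=1.0, angle=a, area=1.0, n_voxels=10)
            for i, a in enumerate(rng.uniform(-math.pi / 2, math.pi / 2, 2000))
        ]
        summ = ifs.orientation_summary(fits, plane="xy")
        assert summ.resultant_length < 0.06

    def test_jittered_channels_recover_generating_spread(self):
        """End-to-end: 0.1 rad orientation jitter is read back from ellipse fits."""
        fits = []
        for v in range(25):
            spec = ifs.PoreVolumeSpec(seed=500 + v, n_channels=4, shape=(64, 64, 32),
                                      orientation_axis=(1, 0, 0), orientation_jitter=0.1)
            vol, _ = ifs.generate_pore_volume(spec, max_retries=500)
            cs = ifs.extract_interstitial_clusters(vol)
            # keep footprints cut near the tube diameter; tangential rim
            # cuts carry no orientation information
            fits += [f for f in ifs.fit_cluster_ellipses(cs, plane="xy")
                     if f.n_voxels >= 50]
        assert len(fits) >= 50
        summ = ifs.orientation_summary(fits, plane="xy")
        assert summ.circular_sd == pytest.approx(0.1, rel=0.25)

    def test_line_tangent_reference(self):
        data = np.zeros((20, 25, 20))
        data[4:9, 3:22, 6:12] = 1.0
        line = ifs.compute_centroidal_line(Volume3D(data, (1, 1, 1)), "y")
        fits = [ifs.EllipseFit(cluster_id=0, centroid=(0, 0), major_axis=4.0,
                               minor_axis=1.0, angle=0.0, area=1.0, n_voxels=10)]
        # straight line along y; in the xy plane its tangent is the y axis
        summ = ifs.orientation_summary(fits, line=line, plane="xy")
        assert summ.acute_angles[0] == pytest.approx(math.pi / 2, abs=1e-6)
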