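"""Image-quantification chain: thresholds, projections, profiles, fits."""

import numpy as np
import pytest

from sporefront import quantify as q
from sporefront.imaging import ImageStack


def make_stack(const, spor=None, pixel_size=1.43, z_interval=1.34, origin=None):
    """Wrap raw (T, Z, Y, X) arrays into an ImageStack."""
    const = np.asarray(const, dtype=np.uint16)
    if spor is None:
        spor = np.zeros_like(const)
    ny = const.shape[2]
    if origin is None:
        origin = ((ny - 1) / 2.0, 0.0)
    return ImageStack(
        channels={"constitutive": const, "sporulation": np.asarray(spor, np.uint16)},
        pixel_size=pixel_size,
        z_interval=z_interval,
        frame_interval=1.5,
        origin=origin,
        times=np.arange(const.shape[0]) * 1.5,
    )


def disc_stack(radius_um, amp=3000, nz=4, ny=48, nx=450, pixel_size=1.43):
    stack = make_stack(np.zeros((1, nz, ny, nx)), pixel_size=pixel_size)
    rad = stack.radius_map()
    vox = np.where(rad <= radius_um, amp, 0).astype(np.uint16)
    stack.channels["constitutive"][0] = vox[None, :, :]
    return stack


class TestComputeThreshold:
    def test_constant_roi_gives_its_value(self):
        stack = make_stack(np.full((1, 2, 60, 300), 250), pixel_size=1.0)
        thr = q.compute_threshold(stack, 0, "constitutive", q.ThresholdSpec(), 10.0)
        assert thr == 250.0

    def test_median_plus_n_mad(self):
        vox = np.zeros((1, 1, 60, 300))
        pattern = np.tile([90.0, 100.0, 110.0], 100)[:300]
        vox[0, 0] = pattern[None, :]
        stack = make_stack(vox, pixel_size=1.0)
        thr = q.compute_threshold(stack, 0, "constitutive", q.ThresholdSpec(), 10.0)
        assert thr == 100.0 + 4 * 10.0  # median + n*MAD

    def test_roi_outside_frame_signaled(self):
        stack = make_stack(np.zeros((1, 1, 60, 100)), pixel_size=1.0)
        with pytest.raises(ValueError, match="ROI"):
            q.compute_threshold(stack, 0, "constitutive", q.ThresholdSpec(), 95.0)

    def test_wide_field_preset(self):
        spec = q.ThresholdSpec.wide_field()
        assert spec.roi_size == (70.0, 100.0)
        assert spec.n_mad == {"constitutive": 2.0, "sporulation": 1.0}


class TestZProject:
    def test_all_below_threshold_gives_zero(self):
        stack = make_stack(np.full((1, 3, 8, 8), 50))
        proj = q.z_project(stack, 0, "constitutive", "mean", threshold=100.0)
        assert np.all(proj == 0.0)

    def test_single_passing_voxel(self):
        vox = np.full((1, 3, 4, 4), 10)
        vox[0, 1, 2, 2] = 500
        stack = make_stack(vox)
        for mode in ("mean", "sum"):
            proj = q.z_project(stack, 0, "constitutive", mode, threshold=100.0)
            assert proj[2, 2] == 500.0

    def test_sum_counts_z_slices(self):
        stack = disc_stack(300.0, amp=500, nz=4)
        proj = q.z_project(stack, 0, "constitutive", "sum", threshold=100.0)
        rad = stack.radius_map()
        assert np.all(proj[rad < 290] == 4 * 500.0)
        assert np.all(proj[rad > 310] == 0.0)

    def test_max_mode_ignores_threshold(self):
        vox = np.full((1, 3, 4, 4), 50)
        stack = make_stack(vox)
        assert np.all(q.z_project(stack, 0, "constitutive", "max", 1e9) == 50.0)

    def test_unknown_mode(self):
        stack = make_stack(np.zeros((1, 1, 4, 4)))
        with pytest.raises(ValueError):
            q.z_project(stack, 0, "constitutive", "median", 0.0)


class TestCrossSection:
    @pytest.mark.parametrize("pixel_size,width_px", [(1.43, 28), (3.58, 12)])
    def test_slice_width_in_pixels(self, pixel_size, width_px):
        # the averaged band has a distinct value; any wider selection would
        # pick up the sentinel rows and shift the mean
        ny = 48
        oy = (ny - 1) / 2.0
        vox = np.full((1, 2, ny, 20), 10000.0)
        y0 = int(round(oy - width_px / 2))
        vox[0, :, y0 : y0 + width_px, :] = 7.0
        stack = make_stack(vox, pixel_size=pixel_size)
        cs = q.cross_section(stack, 0, "constitutive", slice_width=40.0)
        assert cs.shape == (2, 20)
        assert np.all(cs == 7.0)

    def test_uniform_field(self):
        stack = make_stack(np.full((1, 3, 48, 30), 123))
        assert np.all(q.cross_section(stack, 0, "constitutive") == 123.0)


class TestRatioProfile:
    def test_flat_half_ratio(self):
        const = np.full((1, 3, 24, 200), 1000)
        spor = np.full((1, 3, 24, 200), 500)
        stack = make_stack(const, spor)
        prof = q.ratio_profile(
            stack, 0, {"constitutive": 100.0, "sporulation": 100.0}
        )
        ok = prof.valid()
        assert np.allclose(prof.values[ok], 0.5, atol=1e-9)

    def test_invariant_under_common_scaling(self):
        rng = np.random.default_rng(0)
        const = rng.integers(500, 1000, (1, 2, 24, 120))
        spor = rng.integers(200, 900, (1, 2, 24, 120))
        a = make_stack(const, spor)
        b = make_stack(const * 3, spor * 3)
        pa = q.ratio_profile(a, 0, {"constitutive": 100.0, "sporulation": 100.0})
        pb = q.ratio_profile(b, 0, {"constitutive": 300.0, "sporulation": 300.0})
        np.testing.assert_allclose(pa.values, pb.values, rtol=1e-9)

    def test_no_dual_positive_voxels_undefined(self):
        stack = make_stack(np.full((1, 2, 24, 120), 1000))  # sporulation all zero
        prof = q.ratio_profile(stack, 0, {"constitutive": 100.0, "sporulation": 100.0})
        assert not np.any(prof.valid())
        with pytest.raises(ValueError):
            q.sporulation_front_from_profile(prof)


class TestLeadingEdgeFromImage:
    def test_disc_phantom_radius_recovered(self):
        stack = disc_stack(500.0)
        proj = q.z_project(stack, 0, "constitutive", "mean", 100.0)
        edge = q.leading_edge_from_image(
            proj, 900.0, stack.origin, stack.pixel_size
        )
        assert edge == pytest.approx(500.0, abs=stack.pixel_size)

    def test_empty_frame_undefined(self):
        stack = make_stack(np.zeros((1, 2, 24, 100)))
        proj = q.z_project(stack, 0, "constitutive", "mean", 100.0)
        with pytest.raises(ValueError):
            q.leading_edge_from_image(proj, 100.0, stack.origin, stack.pixel_size)


class TestVegetativeFront:
    def test_monotone_profile_spans_whole_biofilm(self):
        pos = np.arange(0.0, 500.0, 2.0)
        prof = q.RadialProfile(t=0.0, positions=pos, values=pos / 500.0)
        inner, edge = q.vegetative_front(prof)
        assert inner == pos[0]
        assert edge == pos[-1]

    def test_two_gaussian_profile_base_at_valley(self):
        pos = np.arange(0.0, 600.0, 2.0)
        vals = np.exp(-0.5 * ((pos - 150) / 40) ** 2) + 0.9 * np.exp(
            -0.5 * ((pos - 450) / 40) ** 2
        )
        prof = q.RadialProfile(t=0.0, positions=pos, values=vals)
        inner, edge = q.vegetative_front(prof)
        valley = pos[np.argmin(np.abs(pos - 300))]
        assert inner == pytest.approx(valley, abs=20.0)
        assert edge == pos[-1]

    def test_narrowing_front_series(self, imaging_bundle):
        # the vegetative front narrows as interior biomass sporulates
        noisy = imaging_bundle.noisy
        res = imaging_bundle.result
        thr = res.thresholds.pivot(index="frame", columns="channel", values="threshold")
        widths = []
        for i in (2, len(noisy.times) - 2):
            edge_i = float(res.edge["radius_um"].iloc[i])
            prof = q.intensity_profile(
                noisy, i, "constitutive",
                float(thr.loc[i, "constitutive"]), max_radius=edge_i,
            )
            inner, edge = q.vegetative_front(prof)
            widths.append(edge - inner)
        assert widths[-1] < widths[0]


class TestSporulationFrontFromProfile:
    def test_plateau_profile_front_at_end(self):
        pos = np.arange(0.0, 200.0, 1.0)
        prof = q.RadialProfile(t=0.0, positions=pos, values=np.full_like(pos, 2.0))
        assert q.sporulation_front_from_profile(prof) == pos[-1]

    def test_triangular_profile(self):
        pos = np.arange(0.0, 200.0, 0.5)
        p, w = 100.0, 40.0
        vals = np.clip(1 - np.abs(pos - p) / w, 0, None)
        prof = q.RadialProfile(t=0.0, positions=pos, values=vals)
        assert q.sporulation_front_from_profile(prof) == pytest.approx(p + w / 4)


class TestTwoPhaseFit:
    def test_exact_two_line_recovery(self):
        t = np.arange(0.0, 30.0, 1.5)
        y = np.where(t <= 12.0, 100 + 80 * t, 100 + 80 * 12 + 15 * (t - 12.0))
        fit = q.two_phase_fit(t, y)
        assert fit.two_phase
        assert fit.breakpoint_time == pytest.approx(12.0)
        assert fit.slope1 == pytest.approx(80.0, rel=1e-9)
        assert fit.slope2 == pytest.approx(15.0, rel=1e-9)

    def test_single_line_preferred_when_sufficient(self):
        t = np.arange(0.0, 30.0, 1.5)
        fit = q.two_phase_fit(t, 5.0 + 3.0 * t)
        assert not fit.two_phase
        assert fit.slope1 == pytest.approx(3.0)

    def test_noisy_breakpoint_within_one_frame_interval(self):
        t = np.arange(0.0, 30.0, 1.5)
        y = np.where(t <= 12.0, 100 + 80 * t, 100 + 80 * 12 + 15 * (t - 12.0))
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = q.two_phase_fit(t, y + rng.normal(0.0, 1.0, len(t)))
            errs.append(abs(fit.breakpoint_time - 12.0))
        assert max(errs) <= 1.5

    def test_too_few_samples_signaled(self):
        with pytest.raises(ValueError, match="6"):
            q.two_phase_fit([0, 1, 2], [0, 1, 2])


class TestCompareFrontVelocities:
    def test_delayed_trajectory_gives_unit_ratio(self):
        t = np.arange(0.0, 30.0, 1.5)
        pos = 1000.0 + 30.0 * t
        curve = q.compare_front_velocities(
            t, pos, t + 6.0, pos, apply_two_phase_boundary=False
        )
        assert np.allclose(curve.ratio, 1.0, atol=0.02)

    def test_retrograde_samples_excluded(self):
        t = np.arange(0.0, 30.0, 1.5)
        edge = 1000.0 + 40.0 * t
        front = 900.0 + 30.0 * t
        front[12:15] -= 120.0  # transient regression mid-sweep
        curve = q.compare_front_velocities(
            t, edge, t, front, apply_two_phase_boundary=False
        )
        boundary = front[11]
        assert np.all(curve.positions <= boundary + curve.bin_width)

    def test_disjoint_ranges_signaled(self):
        t = np.arange(0.0, 12.0, 1.5)
        with pytest.raises(ValueError):
            q.compare_front_velocities(t, 5000 + 10 * t, t, 100 + 10 * t)


class TestPipelineProperties:
    def test_threshold_monotone_in_n_mad(self, imaging_bundle):
        noisy = imaging_bundle.noisy
        counts = []
        for n in (1.0, 3.0, 6.0):
            spec = q.ThresholdSpec(n_mad={"constitutive": n, "sporulation": n})
            edge = float(imaging_bundle.result.edge["radius_um"].iloc[4])
            thr = q.compute_threshold(noisy, 4, "constitutive", spec, edge)
            counts.append(int((noisy.channels["constitutive"][4] >= thr).sum()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_quantification_deterministic(self, imaging_bundle):
        res2 = q.quantify_stack(imaging_bundle.noisy, imaging_bundle.config)
        for name in ("thresholds", "edge", "front", "profiles"):
            a = getattr(imaging_bundle.result, name)
            b = getattr(res2, name)
            assert a.equals(b)
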