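import numpy as np
import pytest

from tcbc.errors import InvalidArgumentError
from tcbc.geometry import ImageVolume, build_transform
from tcbc.petsim import (
    GM_SECTORS,
    VENTRICLE,
    WM_LEFT,
    WM_RIGHT,
    CountModel,
    PhantomConfig,
    SinogramStack,
    add_poisson_noise,
    default_angles,
    fbp_reconstruct,
    make_phantom,
    project_to_sinograms,
    random_motion,
    run_benchmark,
    scale_counts,
)


class TestPhantom:
    def test_labels_partition_brain(self, small_phantom):
        _, _, seg = small_phantom
        labels = set(np.unique(seg.data)) - {0}
        assert labels == {WM_LEFT, WM_RIGHT, VENTRICLE, *GM_SECTORS}
        # partition by construction: each voxel carries exactly one label,
        # so label counts sum to the brain voxel count
        total = sum(int((seg.data == lab).sum()) for lab in labels)
        assert total == int((seg.data != 0).sum())

    def test_uptake_ratio_without_smoothing(self):
        cfg = PhantomConfig(shape=(48, 48, 48), voxel_size_mm=4.0,
                            uptake_wm=1.0, uptake_ventricle=0.1,
                            pet_smooth_fwhm_mm=0.0)
        pet, _, seg = make_phantom(cfg)
        wm_mean = pet.data[np.isin(seg.data, [WM_LEFT, WM_RIGHT])].mean()
        vent_mean = pet.data[seg.data == VENTRICLE].mean()
        assert wm_mean / vent_mean == pytest.approx(10.0, abs=1e-9)

    def test_wm_nonconvex(self, small_phantom):
        from scipy.spatial import ConvexHull, Delaunay
        _, _, seg = small_phantom
        wm = np.argwhere(np.isin(seg.data, [WM_LEFT, WM_RIGHT]))
        hull = Delaunay(wm[ConvexHull(wm).vertices])
        # brute-force scan: count voxels inside the hull
        grid = np.argwhere(np.ones(seg.shape, dtype=bool))
        inside = (hull.find_simplex(grid) >= 0).sum()
        assert len(wm) < inside

    def test_contrast_invariant_enforced(self):
        with pytest.raises(InvalidArgumentError):
            PhantomConfig(uptake_wm=0.5, uptake_gm=0.6)

    def test_grid_too_small(self):
        with pytest.raises(InvalidArgumentError):
            PhantomConfig(shape=(8, 8, 8))

    def test_seed_determinism(self, small_cfg):
        a = make_phantom(small_cfg)
        b = make_phantom(small_cfg)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[2].data, b[2].data)


class TestProjection:
    def test_zero_volume(self):
        vol = ImageVolume(np.zeros((16, 16, 4)), np.eye(4))
        sino = project_to_sinograms(vol, default_angles(24))
        assert np.all(sino.data == 0)

    def test_mass_conservation(self, small_phantom):
        pet, _, _ = small_phantom
        sino = project_to_sinograms(pet, default_angles(30))
        for k in (10, 24, 30):
            slice_sum = pet.data[:, :, k].sum()
            if slice_sum == 0:
                continue
            per_angle = sino.data[:, :, k].sum(axis=1)
            np.testing.assert_allclose(per_angle, slice_sum,
                                       rtol=0.01)

    def test_point_source_center_trace(self):
        n = 33
        data = np.zeros((n, n, 3))
        data[n // 2, n // 2, 1] = 1.0  # isocenter delta
        vol = ImageVolume(data, np.eye(4))
        sino = project_to_sinograms(vol, default_angles(36))
        bins = np.arange(sino.data.shape[1])
        center_bin = (sino.data.shape[1] - 1) / 2
        for k in range(sino.data.shape[0]):
            proj = np.clip(sino.data[k, :, 1], 0, None)
            com = (bins * proj).sum() / proj.sum()
            # a centered point stays on the central detector bin at every
            # angle (no sinusoidal excursion)
            assert abs(com - center_bin) <= 0.6

    def test_empty_angles(self, small_phantom):
        pet, _, _ = small_phantom
        with pytest.raises(InvalidArgumentError):
            project_to_sinograms(pet, np.array([]))

    def test_negative_volume_rejected(self):
        vol = ImageVolume(np.full((8, 8, 2), -1.0), np.eye(4))
        with pytest.raises(InvalidArgumentError):
            project_to_sinograms(vol, default_angles(8))

    def test_linearity(self, small_phantom):
        pet, _, _ = small_phantom
        angles = default_angles(16)
        one = project_to_sinograms(pet, angles)
        two = project_to_sinograms(pet.copy_with(2.0 * pet.data), angles)
        np.testing.assert_allclose(two.data, 2.0 * one.data, atol=1e-9)


class TestCountScaling:
    def test_20min_total_oracle(self, small_phantom):
        # arithmetic oracle: 370 MBq * 0.05 * 15000 cps/MBq * 1200 s
        pet, _, _ = small_phantom
        sino = project_to_sinograms(pet, default_angles(24))
        scaled = scale_counts(sino, CountModel(duration_s=1200.0))
        assert scaled.total_counts == pytest.approx(3.33e8, abs=1.0)

    def test_5min_total_oracle(self, small_phantom):
        pet, _, _ = small_phantom
        sino = project_to_sinograms(pet, default_angles(24))
        scaled = scale_counts(sino, CountModel(duration_s=300.0))
        assert scaled.total_counts == pytest.approx(8.325e7, abs=1.0)

    def test_quarter_duration_quarter_counts(self, small_phantom):
        pet, _, _ = small_phantom
        sino = project_to_sinograms(pet, default_angles(24))
        long = scale_counts(sino, CountModel(duration_s=1200.0))
        short = scale_counts(sino, CountModel(duration_s=300.0))
        assert short.total_counts == pytest.approx(long.total_counts / 4)

    def test_bin_ratios_preserved(self, small_phantom):
        pet, _, _ = small_phantom
        sino = project_to_sinograms(pet, default_angles(24))
        scaled = scale_counts(sino, CountModel(duration_s=600.0))
        nz = sino.data > 0
        ratio = scaled.data[nz] / sino.data[nz]
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-12)

    def test_zero_total_rejected(self):
        sino = SinogramStack(np.zeros((8, 10, 2)), default_angles(8))
        with pytest.raises(InvalidArgumentError):
            scale_counts(sino, CountModel(duration_s=60.0))

    def test_invalid_count_model(self):
        with pytest.raises(InvalidArgumentError):
            CountModel(duration_s=0.0)


class TestPoissonNoise:
    def test_zero_stays_zero(self):
        sino = SinogramStack(np.zeros((8, 10, 2)), default_angles(8))
        noisy = add_poisson_noise(sino, seed=0)
        assert np.all(noisy.data == 0)

    def test_seed_reproducible(self):
        sino = SinogramStack(np.full((8, 10, 2), 50.0), default_angles(8))
        a = add_poisson_noise(sino, seed=7)
        b = add_poisson_noise(sino, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_moments(self):
        n = 100_000
        sino = SinogramStack(np.full((n, 1, 1), 100.0), default_angles(n))
        noisy = add_poisson_noise(sino, seed=3)
        assert noisy.data.mean() == pytest.approx(100.0, abs=1.0)
        assert noisy.data.var() == pytest.approx(100.0, abs=3.0)

    def test_negative_bin_rejected(self):
        sino = SinogramStack(np.full((4, 4, 1), -1.0), default_angles(4))
        with pytest.raises(InvalidArgumentError):
            add_poisson_noise(sino)


class TestFbp:
    def test_round_trip_nrmse(self, small_phantom):
        pet, _, _ = small_phantom
        sino = project_to_sinograms(pet, default_angles(180))
        recon = fbp_reconstruct(sino, "ramp", output_size=pet.shape[0],
                                affine=pet.affine)
        interior = pet.data > 0.05 * pet.data.max()
        err = np.sqrt(np.mean((recon.data - pet.data)[interior] ** 2))
        assert err / pet.data[interior].mean() <= 0.10

    def test_zero_sinogram(self):
        sino = SinogramStack(np.zeros((90, 24, 2)), default_angles(90))
        recon = fbp_reconstruct(sino, "hamming", output_size=16)
        assert np.all(recon.data == 0)

    def test_nonnegative_output(self, small_phantom):
        pet, _, _ = small_phantom
        sino = project_to_sinograms(pet, default_angles(60))
        noisy = add_poisson_noise(
            scale_counts(sino, CountModel(duration_s=300.0)), seed=1)
        recon = fbp_reconstruct(noisy, "hamming", output_size=pet.shape[0])
        assert recon.data.min() >= 0.0

    def test_hamming_smoother_than_ramp(self, small_phantom):
        # compare pure noise variance: deviation of each noisy recon from
        # the noise-free recon with the same filter, inside uniform WM
        pet, _, seg = small_phantom
        sino = scale_counts(project_to_sinograms(pet, default_angles(60)),
                            CountModel(duration_s=300.0))
        wm = np.isin(seg.data, [WM_LEFT, WM_RIGHT])
        clean = {f: fbp_reconstruct(sino, f, output_size=pet.shape[0]).data
                 for f in ("hamming", "ramp")}
        var_h, var_r = [], []
        for s in range(8):
            noisy = add_poisson_noise(sino, seed=s)
            rh = fbp_reconstruct(noisy, "hamming", output_size=pet.shape[0])
            rr = fbp_reconstruct(noisy, "ramp", output_size=pet.shape[0])
            var_h.append((rh.data - clean["hamming"])[wm].var())
            var_r.append((rr.data - clean["ramp"])[wm].var())
        assert np.mean(var_h) < np.mean(var_r)

    def test_insufficient_coverage(self):
        angles = np.linspace(0, 90, 45, endpoint=False)
        sino = SinogramStack(np.ones((45, 24, 1)), angles)
        with pytest.raises(InvalidArgumentError):
            fbp_reconstruct(sino)

    def test_unknown_filter(self):
        sino = SinogramStack(np.ones((90, 24, 1)), default_angles(90))
        with pytest.raises(InvalidArgumentError):
            fbp_reconstruct(sino, "butterworth")

    def test_noise_variance_scales_with_duration(self, small_phantom):
        # 4x fewer counts -> ~4x noise variance in uniform WM, where the
        # noise is the deviation from the noise-free reconstruction
        pet, _, seg = small_phantom
        sino = project_to_sinograms(pet, default_angles(60))
        wm = np.isin(seg.data, [WM_LEFT, WM_RIGHT])
        ratios = []
        for s in range(20):
            v = {}
            for d in (300.0, 1200.0):
                scaled = scale_counts(sino, CountModel(duration_s=d))
                clean = fbp_reconstruct(scaled, "hamming",
                                        output_size=pet.shape[0]).data
                noisy = add_poisson_noise(scaled, seed=s)
                recon = fbp_reconstruct(noisy, "hamming",
                                        output_size=pet.shape[0])
                # normalize to unit mean so count scales are comparable
                v[d] = ((recon.data - clean) / clean[wm].mean())[wm].var()
            ratios.append(v[300.0] / v[1200.0])
        assert 3.0 <= np.mean(ratios) <= 5.0


class TestRandomMotion:
    def test_bounds(self):
        motions = random_motion(500, seed=0)
        arr = np.array([m.as_array() for m in motions])
        assert np.all(arr >= -10.0) and np.all(arr <= 10.0)

    def test_seed_reproducible(self):
        a = random_motion(20, seed=4)
        b = random_motion(20, seed=4)
        assert a == b

    def test_clt_mean_bound(self):
        arr = np.array([m.as_array() for m in random_motion(500, seed=1)])
        sigma = 20.0 / np.sqrt(12.0)
        assert np.all(np.abs(arr.mean(axis=0)) <= 3 * sigma / np.sqrt(500))

    def test_invalid(self):
        with pytest.raises(InvalidArgumentError):
            random_motion(0)
        with pytest.raises(InvalidArgumentError):
            random_motion(5, t_range=(3.0, -3.0))


class TestRunBenchmark:
    @pytest.fixture(scope="class")
    def tiny_run(self):
        from tcbc.core import TcbcConfig
        cfg = PhantomConfig(shape=(48, 48, 48), voxel_size_mm=4.0, seed=3)
        reg = TcbcConfig(n_starts=4, seed=0, xatol=1e-3, fatol=1e-6,
                         max_eval_points=8000)
        return run_benchmark(trials=2, noise_durations_s=[None, 300.0],
                             methods=["tcbc", "nmi"], phantom_cfg=cfg,
                             reg_config=reg, n_angles=48, seg_upsample=3,
                             seed=21)

    def test_schema_complete(self, tiny_run):
        assert len(tiny_run) == 2 * 2 * 2
        for name in ("tx", "ty", "tz", "rx", "ry", "rz"):
            assert tiny_run[f"true_{name}"].notna().all()
            assert tiny_run[f"est_{name}"].notna().all()
            assert tiny_run[f"resid_{name}"].notna().all()
        assert not tiny_run["failed"].any()

    def test_noise_free_tcbc_accuracy(self, tiny_run):
        rows = tiny_run[(tiny_run["method"] == "tcbc")
                        & tiny_run["duration_s"].isna()]
        resid = rows[[f"resid_{n}" for n in
                      ("tx", "ty", "tz", "rx", "ry", "rz")]].abs()
        assert resid.to_numpy().max() <= 0.5

    def test_ground_truth_self_consistency(self, tiny_run):
        # truth params compose with the applied matrix to identity; the
        # benchmark stores est - true, so reconstruct and verify one row
        from tcbc.geometry import RigidParams, build_transform
        row = tiny_run.iloc[0]
        truth = RigidParams(*[row[f"true_{n}"] for n in
                              ("tx", "ty", "tz", "rx", "ry", "rz")])
        est = RigidParams(*[row[f"est_{n}"] for n in
                            ("tx", "ty", "tz", "rx", "ry", "rz")])
        center = np.zeros(3)
        m_true = build_transform(truth, center)
        m_est = build_transform(est, center)
        resid = RigidParams(*[row[f"resid_{n}"] for n in
                              ("tx", "ty", "tz", "rx", "ry", "rz")])
        expected = m_est @ np.linalg.inv(m_true)
        np.testing.assert_allclose(build_transform(resid, center), expected,
                                   atol=1e-6)

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidArgumentError):
            run_benchmark(1, [None], ["powell"])


class TestEndToEndLinearity:
    def test_activity_doubling(self, small_cfg):
        pet, _, _ = make_phantom(small_cfg)
        angles = default_angles(48)
        one = project_to_sinograms(pet, angles)
        two = project_to_sinograms(pet.copy_with(2 * pet.data), angles)
        assert two.total_counts == pytest.approx(2 * one.total_counts,
                                                 rel=1e-12)
        r1 = fbp_reconstruct(one, "ramp", output_size=pet.shape[0])
        r2 = fbp_reconstruct(two, "ramp", output_size=pet.shape[0])
        mask = r1.data > 0.1 * r1.data.max()
        assert r2.data[mask].mean() == pytest.approx(
            2 * r1.data[mask].mean(), rel=0.01)
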