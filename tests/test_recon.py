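"""Reconstruction: phase corrections, coils, gridding, CG-SENSE, CS, velocity."""

import numpy as np
import pytest
from scipy import fft as sfft

from aqueflow.nufft import NufftPlan
from aqueflow.phantom import (
    AcquisitionConfig,
    FlowWaveform,
    PhantomConfig,
    RadialKSpace,
    build_scene,
    simulate_coil_maps,
    simulate_kspace,
)
from aqueflow.recon import (
    EncodingOperator,
    ReconConfig,
    cg_sense,
    compress_coils,
    correct_echo_shifts,
    correct_zeroth_order,
    cs_temporal_tv,
    gridded_recon,
    normalize_kspace,
    reconstruct,
    temporal_tv,
    velocity_map,
    walsh_sensitivities,
    ImageSeries,
)
from aqueflow.trajectory import frame_bins, golden_angles, spoke_coords


def disk_bandlimit(img):
    """Wrap-free restriction of an image to the circular k-space support."""
    n = img.shape[0]
    pad = np.zeros((2 * n, 2 * n), complex)
    pad[n // 2 : n // 2 + n, n // 2 : n // 2 + n] = img
    f = sfft.fftshift(sfft.fftfreq(2 * n))
    kx, ky = np.meshgrid(f, f)
    disk = (kx**2 + ky**2) <= 0.25
    F = sfft.fftshift(sfft.fft2(sfft.ifftshift(pad)))
    out = sfft.fftshift(sfft.ifft2(sfft.ifftshift(F * disk)))
    return out[n // 2 : n // 2 + n, n // 2 : n // 2 + n]


def single_coil_spoke_raw(scene, angle=25.0):
    """One-coil, one-spoke raw data of a real scene (echo exactly centered)."""
    n = scene.image.shape[0]
    coords = spoke_coords(angle, 2 * n)
    plan = NufftPlan((n, n), coords, width=6, dtype=np.complex128)
    d = plan.forward(np.abs(scene.image))
    return RadialKSpace(
        d.reshape(1, 2 * n, 1),
        np.array([angle]),
        np.zeros(1),
        np.ones(1, dtype=int),
        {"matrix_size": n},
    )


def symmetric_test_spoke(m=128):
    """Exactly conjugate-symmetric single-coil spoke (echo on the center)."""
    k = (np.arange(m) - m // 2) / m
    s = np.exp(-((k / 0.2) ** 2)) * np.cos(6 * np.pi * k)
    s[0] = 0.0  # the -0.5 edge sample has no +0.5 partner
    return RadialKSpace(
        s.astype(complex).reshape(1, m, 1),
        np.zeros(1),
        np.zeros(1),
        np.ones(1, int),
        {"matrix_size": m // 2},
    )


class TestEchoShiftCorrection:
    @pytest.mark.parametrize("shift", [-1.0, -0.5, 0.3, 0.9])
    def test_injected_linear_phase_removed(self, shift):
        # a centered spoke has no linear-phase component of its own, so the
        # estimate isolates the injected shift (an off-center object adds its
        # center-of-mass slope, which is indistinguishable from an echo shift
        # on a single spoke)
        raw = symmetric_test_spoke()
        n = raw.n_samples
        k = (np.arange(n) - n // 2) / n
        shifted = RadialKSpace(
            raw.data * np.exp(2j * np.pi * shift * k)[None, :, None],
            raw.angles_deg,
            raw.times_s,
            raw.enc_sign,
            raw.attrs,
        )
        corrected = correct_echo_shifts(shifted)
        # residual shift below 0.01 samples: the leftover linear phase is at
        # most 2*pi*0.01*|k| <= 0.0315 rad, bounding |corrected - original|
        diff = np.abs(corrected.data - raw.data)
        assert np.all(diff <= 0.0315 * np.abs(raw.data) + 1e-12)

    def test_centered_spoke_unchanged(self):
        raw = symmetric_test_spoke()
        corrected = correct_echo_shifts(raw)
        assert np.abs(corrected.data - raw.data).max() < 1e-10 * np.abs(
            raw.data
        ).max()

    def test_all_zero_spoke_left_alone(self):
        raw = RadialKSpace(
            np.zeros((1, 16, 1), complex),
            np.zeros(1),
            np.zeros(1),
            np.ones(1, int),
            {},
        )
        assert np.array_equal(correct_echo_shifts(raw).data, raw.data)


class TestZerothOrderCorrection:
    def test_random_constant_phases_aligned(self, tiny_static_raw, rng):
        phases = np.exp(1j * rng.uniform(-np.pi, np.pi, tiny_static_raw.n_spokes))
        scrambled = RadialKSpace(
            tiny_static_raw.data * phases[:, None, None],
            tiny_static_raw.angles_deg,
            tiny_static_raw.times_s,
            tiny_static_raw.enc_sign,
            tiny_static_raw.attrs,
        )
        fixed = correct_zeroth_order(scrambled)
        c = fixed.n_samples // 2
        for sign in (1, -1):
            sub = fixed.data[fixed.enc_sign == sign]
            ph = np.angle(sub[:, c, :].sum(axis=1))
            assert np.ptp(np.unwrap(ph)) < 1e-9

    def test_magnitude_spectrum_preserved(self, tiny_static_raw, rng):
        phases = np.exp(1j * rng.uniform(-np.pi, np.pi, tiny_static_raw.n_spokes))
        scrambled = RadialKSpace(
            tiny_static_raw.data * phases[:, None, None],
            tiny_static_raw.angles_deg,
            tiny_static_raw.times_s,
            tiny_static_raw.enc_sign,
            tiny_static_raw.attrs,
        )
        fixed = correct_zeroth_order(scrambled)
        assert np.allclose(np.abs(fixed.data), np.abs(scrambled.data), rtol=1e-12)

    def test_identical_spokes_unchanged(self, tiny_static_raw):
        fixed = correct_zeroth_order(tiny_static_raw)
        assert np.allclose(fixed.data, tiny_static_raw.data, atol=1e-12)


class TestNormalize:
    def test_scaling_invariance(self, tiny_static_raw):
        scaled = RadialKSpace(
            tiny_static_raw.data * 7.0,
            tiny_static_raw.angles_deg,
            tiny_static_raw.times_s,
            tiny_static_raw.enc_sign,
            tiny_static_raw.attrs,
        )
        a, _ = normalize_kspace(tiny_static_raw)
        b, _ = normalize_kspace(scaled)
        assert np.allclose(a.data, b.data, rtol=1e-12)
        assert np.abs(b.data).max() == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        raw = RadialKSpace(
            np.zeros((1, 8, 1), complex), np.zeros(1), np.zeros(1), np.ones(1, int), {}
        )
        with pytest.raises(ValueError):
            normalize_kspace(raw)


class TestCoilCompression:
    def test_energy_preserved_at_full_rank(self, tiny_static_raw):
        out = compress_coils(tiny_static_raw, tiny_static_raw.n_coils)
        e_in = np.sum(np.abs(tiny_static_raw.data) ** 2)
        e_out = np.sum(np.abs(out.data) ** 2)
        assert abs(e_in - e_out) / e_in < 1e-10

    def test_rank_one_collapses_to_first_virtual_coil(self, rng):
        base = rng.standard_normal((40, 32)) + 1j * rng.standard_normal((40, 32))
        gains = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        data = base[:, :, None] * gains[None, None, :]
        raw = RadialKSpace(
            data, np.zeros(40), np.zeros(40), np.ones(40, int), {}
        )
        out = compress_coils(raw, 6)
        energy = np.sum(np.abs(out.data) ** 2, axis=(0, 1))
        assert energy[0] / energy.sum() > 0.9999

    def test_too_many_virtual_coils_rejected(self, tiny_static_raw):
        with pytest.raises(ValueError):
            compress_coils(tiny_static_raw, 99)


class TestGriddedRecon:
    def test_static_scene_nrmse_within_support(
        self, tiny_static_raw, tiny_scene, tiny_maps
    ):
        """Fully sampled gridding reproduces the (band-limited) scene to 5%."""
        raw, _ = normalize_kspace(tiny_static_raw)
        imgs = gridded_recon(raw)
        support = np.abs(tiny_scene.image) > 0
        ref = np.stack(
            [disk_bandlimit(m * tiny_scene.image) for m in tiny_maps]
        )
        scale = np.vdot(ref[:, support], imgs[:, support]) / np.vdot(
            ref[:, support], ref[:, support]
        )
        err = np.linalg.norm((imgs - scale * ref)[:, support])
        assert err / np.linalg.norm((scale * ref)[:, support]) < 0.05

    def test_zero_data_zero_image(self, tiny_static_raw):
        raw = RadialKSpace(
            np.zeros_like(tiny_static_raw.data),
            tiny_static_raw.angles_deg,
            tiny_static_raw.times_s,
            tiny_static_raw.enc_sign,
            tiny_static_raw.attrs,
        )
        assert np.abs(gridded_recon(raw)).max() == 0.0

    def test_point_object_peaks_at_center(self):
        n = 32
        angles = golden_angles(60)
        coords = np.concatenate([spoke_coords(a, 2 * n) for a in angles])
        plan = NufftPlan((n, n), coords, width=6, dtype=np.complex128)
        img = np.zeros((n, n), complex)
        img[n // 2, n // 2] = 1.0
        d = plan.forward(img)
        raw = RadialKSpace(
            d.reshape(60, 2 * n, 1),
            angles,
            np.zeros(60),
            np.ones(60, int),
            {"matrix_size": n},
        )
        rec = np.abs(gridded_recon(raw, n)[0])
        assert np.unravel_index(rec.argmax(), rec.shape) == (n // 2, n // 2)
        # Ram-Lak weighted quadrature reproduces the k-space disk integral
        assert rec.max() / (np.pi / 4) == pytest.approx(1.0, abs=0.05)


class TestWalshSensitivities:
    def test_uniform_single_coil(self):
        imgs = np.ones((1, 32, 32), complex)
        maps = walsh_sensitivities(imgs, 8)
        assert np.allclose(np.abs(maps), 1.0)

    def test_rss_is_unity(self, tiny_static_raw):
        raw, _ = normalize_kspace(tiny_static_raw)
        maps = walsh_sensitivities(gridded_recon(raw), 8)
        rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
        assert np.allclose(rss, 1.0, atol=1e-6)

    def test_recovers_known_maps(self, tiny_static_raw, tiny_scene, tiny_maps):
        raw, _ = normalize_kspace(tiny_static_raw)
        est = walsh_sensitivities(gridded_recon(raw), 8)
        truth = tiny_maps / np.sqrt((np.abs(tiny_maps) ** 2).sum(axis=0))[None]
        # maps are observable only where the object carries signal
        mag = np.abs(tiny_scene.image)
        support = mag > 0.01 * mag.max()
        err = np.abs(np.abs(est) - np.abs(truth))[:, support]
        assert err.max() < 0.05

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            walsh_sensitivities(np.ones((2, 16, 16), complex), 32)


@pytest.fixture(scope="module")
def small_operator(rng):
    """3-frame, 3-coil operator on a 32 grid with 8 golden spokes per frame."""
    n = 32
    maps = simulate_coil_maps(3, n)
    maps /= np.sqrt((np.abs(maps) ** 2).sum(axis=0))[None]
    angles = golden_angles(24).reshape(3, 8)
    return EncodingOperator(list(angles), maps, 2 * n, 4, np.complex128)


class TestEncodingOperator:
    def test_adjoint_identity(self, small_operator, rng):
        op = small_operator
        x = rng.standard_normal(op.frame_shape) + 1j * rng.standard_normal(
            op.frame_shape
        )
        d = [
            rng.standard_normal((op.n_coils, p.m))
            + 1j * rng.standard_normal((op.n_coils, p.m))
            for p in op.plans
        ]
        lhs = sum(np.vdot(df, af) for df, af in zip(d, op.forward(x)))
        rhs = np.vdot(op.adjoint(d), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_normal_matches_adjoint_forward(self, small_operator, rng):
        op = small_operator
        x = rng.standard_normal(op.frame_shape) + 1j * rng.standard_normal(
            op.frame_shape
        )
        direct = op.adjoint(op.forward(x))
        assert np.linalg.norm(op.normal(x) - direct) / np.linalg.norm(direct) < 5e-3


@pytest.fixture(scope="module")
def well_sampled_problem():
    """Two fully sampled frames of a band-limited static scene (3 coils).

    The object is restricted to the circular k-space support that radial
    sampling covers, so the least-squares solution equals the object itself
    and gridding, CG-SENSE and FISTA all converge to the same image.
    """
    n = 32
    scene = build_scene(PhantomConfig(matrix_size=n, fov_mm=19.2))
    obj = disk_bandlimit(scene.image)
    maps = simulate_coil_maps(3, n)
    maps /= np.sqrt((np.abs(maps) ** 2).sum(axis=0))[None]
    frame_angles = [golden_angles(60), golden_angles(60) + 0.5]
    op = EncodingOperator(frame_angles, maps, 2 * n, 4, np.complex128)
    x_true = np.stack([obj, obj])
    data = op.forward(x_true)
    return op, x_true, data


class TestCgSense:
    def test_fully_sampled_recovery(self, well_sampled_problem):
        op, x_true, data = well_sampled_problem
        x = cg_sense(data, op, n_iters=30)
        err = np.linalg.norm(x - x_true) / np.linalg.norm(x_true)
        assert err < 0.05

    def test_zero_data_zero_solution(self, well_sampled_problem):
        op, _, data = well_sampled_problem
        zeros = [np.zeros_like(d) for d in data]
        assert np.abs(cg_sense(zeros, op, 5)).max() == 0.0

    def test_data_residual_decreases_monotonically(self, well_sampled_problem):
        op, _, data = well_sampled_problem
        _, residuals = cg_sense(data, op, n_iters=20, return_residuals=True)
        for hist in residuals:
            h = np.asarray(hist)
            assert h.size > 1
            assert np.all(np.diff(h) <= 1e-9)


class TestCsTemporalTv:
    def test_lambda_zero_matches_cg_sense(self, well_sampled_problem):
        op, _, data = well_sampled_problem
        x_cg = cg_sense(data, op, n_iters=100)
        x_cs = cs_temporal_tv(data, op, lam=0.0, n_iters=100)
        assert np.linalg.norm(x_cs - x_cg) / np.linalg.norm(x_cg) < 0.01

    def test_huge_lambda_freezes_time(self, well_sampled_problem):
        op, _, data = well_sampled_problem
        # distinct frames (so lambda = 0 has temporal variation), data
        # max-normalized as in the reconstruction pipeline
        scale = max(np.abs(f).max() for f in data)
        d2 = [data[0] / scale, 0.5 * data[1] / scale]
        x0 = cs_temporal_tv(d2, op, lam=0.0, n_iters=40)
        x_inf = cs_temporal_tv(d2, op, lam=1e3, n_iters=40)
        assert temporal_tv(x_inf) < 1e-3 * temporal_tv(x0)

    def test_objective_non_increasing(self, well_sampled_problem):
        op, _, data = well_sampled_problem
        _, history = cs_temporal_tv(
            data, op, lam=1e-4, n_iters=25, monitor=True
        )
        h = np.asarray(history)
        assert np.all(np.diff(h) <= 1e-9 * abs(h[0]))

    def test_negative_lambda_rejected(self, well_sampled_problem):
        op, _, data = well_sampled_problem
        with pytest.raises(ValueError):
            cs_temporal_tv(data, op, lam=-1.0)


class TestVelocityMap:
    def test_identical_encodings_zero_velocity(self):
        frames = np.ones((2, 8, 8), complex)
        t = np.arange(2.0)
        s = ImageSeries(frames, t, 0.6)
        v = velocity_map(s, s, 15.0)
        assert np.abs(v.velocity).max() == 0.0

    def test_pi_phase_difference_maps_to_venc(self):
        t = np.arange(1.0)
        plus = ImageSeries(np.full((1, 4, 4), np.exp(0.999j * np.pi / 1)), t, 0.6)
        minus = ImageSeries(np.ones((1, 4, 4), complex), t, 0.6)
        v = velocity_map(plus, minus, 15.0)
        assert v.velocity.max() == pytest.approx(15.0 * 0.999)

    def test_shape_mismatch_rejected(self):
        t = np.arange(1.0)
        a = ImageSeries(np.ones((1, 4, 4), complex), t, 0.6)
        b = ImageSeries(np.ones((1, 8, 8), complex), t, 0.6)
        with pytest.raises(ValueError):
            velocity_map(a, b, 15.0)


class TestEndToEnd:
    def test_constant_velocity_recovered_within_5_percent(self):
        """A programmed 5 cm/s plug flow reads back as 5 +/- 0.25 cm/s."""
        n = 64
        cfg = PhantomConfig(matrix_size=n, fov_mm=38.4)
        scene = build_scene(cfg)
        maps = simulate_coil_maps(8, n)
        # slow cosine at peak: velocity within 0.01% of 5 cm/s for 3.2 s
        wf = FlowWaveform(
            resp_amplitude=5.0,
            resp_frequency_cpm=0.1,
            card_amplitude=0.0,
            card_frequency_cpm=60.0,
            resp_phase=np.pi / 2,
        )
        acq = AcquisitionConfig(duration_s=3.2, spokes_per_frame=150)
        raw = simulate_kspace(scene, wf, maps, acq)
        vel, _, _ = reconstruct(raw, ReconConfig(mode="gridding"))
        mean_v = vel.velocity[0][scene.aqueduct_mask].mean()
        assert mean_v == pytest.approx(5.0, abs=0.25)

    def test_velocity_invariant_to_scaling_and_global_phase(self, tiny_raw):
        cfg = ReconConfig(mode="gridding", precision="double")
        vel_a, _, _ = reconstruct(tiny_raw, cfg)
        scaled = RadialKSpace(
            tiny_raw.data * (7.0 * np.exp(0.7j)),
            tiny_raw.angles_deg,
            tiny_raw.times_s,
            tiny_raw.enc_sign,
            tiny_raw.attrs,
        )
        vel_b, _, _ = reconstruct(scaled, cfg)
        # compare where there is signal; the phase of near-zero pixels is noise
        m = vel_a.magnitude > 1e-3 * vel_a.magnitude.max()
        assert np.allclose(vel_a.velocity[m], vel_b.velocity[m], atol=1e-6)

    def test_frame_count_equals_complete_bins(self, tiny_raw):
        vel, xp, xm = reconstruct(tiny_raw, ReconConfig(mode="gridding"))
        n_enc = (tiny_raw.enc_sign == 1).sum()
        assert vel.velocity.shape[0] == n_enc // 8
        assert xp.frames.shape == xm.frames.shape
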